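# radbiokit

Quantitative radiobiology for cell-survival experiments: clonogenic
survival-curve modelling, RBE/OER derivation, particle-traversal dosimetry,
cell-cycle deconvolution and γH2AX foci kinetics.

## Who this is for

Radiation biologists analysing clonogenic (colony-forming) assays, flow
cytometry DNA-content histograms and DNA-damage focus counts after photon or
ion irradiation — the standard read-outs of an in-vitro radiosensitivity
study comparing radiation qualities (e.g. X-rays vs carbon ions) and
oxygenation states (normoxia vs hypoxia). Every analysis stage ships with a
matched synthetic-data generator, so pipelines can be validated end to end
without raw cell data.

## The models

**Survival.** Colony counts are normalised by plating efficiency
PE = colonies/seeded at 0 Gy, giving surviving fractions
SF(D) = (colonies/seeded)/PE. These are fitted with the single-hit
multi-target (SHMT) model

    S(D) = 1 − (1 − e^(−D/D₀))ⁿ

by weighted least squares on log₁₀ S: D₀ is the 37% dose of the exponential
final slope, n the extrapolation number (the back-extrapolated y-intercept).
Radiation-quality and oxygen effects are ratios of fitted D₀ values,

    RBE = D₀(X-rays) / D₀(test radiation)      OER = D₀(hypoxia) / D₀(normoxia)

with delta-method standard errors.

**Dosimetry.** For an ion beam of fluence Φ (cm⁻²) at LET L (keV/µm) in
water, D [Gy] = 1.602×10⁻⁹ · Φ · L, and the number of ion traversals
through a nucleus of area A is Poisson with mean λ = Φ·A, evaluated at the
mean nucleus area and at mean ± 1 SD.

**Cell cycle.** DNA-content histograms are deconvolved Dean-Jett-Fox-style:
Gaussian G1 and G2/M peaks (G2/G1 position ratio constrained to
[1.8, 2.05]) plus a Gaussian-broadened rectangular S-phase component; phase
fractions are component areas.

**Foci.** Per-nucleus γH2AX focus counts are summarised per condition and
timepoint, background-corrected against unirradiated controls, fitted with
an exponential-plus-plateau repair model E(t) = E₀e^(−kt) + c, and compared
against the Poisson-expected ion traversals per nucleus.

## Worked example

```python
from radbiokit import (SimulationTruth, simulate_colonies, plating_efficiency,
                       surviving_fractions, SHMTModel, rbe)

truth = SimulationTruth(rng_seed=1)            # A549-style defaults
counts = simulate_colonies(truth)              # Binomial colony noise
pe = plating_efficiency(counts)
sf = surviving_fractions(counts, pe)

grp = sf[(sf.oxygen == "normoxia") & (sf.quality == "xray")]
res = SHMTModel.from_dataframe(grp, label="normoxia/xray/immediate").fit()
print(res.summary())
```

prints

```
Single-hit multi-target survival fit
====================================
condition:  normoxia/xray/immediate
doses:      [0.5 1.  2.  4.  8. ]
D0 [Gy]:    2.9270  (SE 0.1080)
n:          1.5477  (SE 0.0846)
RSS:        1.061  (dof 3)
SF(2 Gy):   0.6632
```

i.e. the fitted final-slope 37% dose is 2.93 ± 0.11 Gy (the generator's
true value is 2.98 Gy) with a shoulder (n > 1), and 66% of cells survive
2 Gy of X-rays under normoxia. Fitting the carbon-ion condition the same
way and forming the ratio `rbe(res_xray, res_carbon)` gives
`RBE = 2.21 ± 0.42` for this dataset: carbon ions are about twice as
effective per gray as X-rays.

The traversal table for a 73 keV/µm carbon beam through 118.8 ± 52.5 µm²
nuclei:

```sh
radbiokit traversals --let 73 --area 118.8 --sd 52.5 --doses 0.5,1,2,4,8 --out table.csv
```

```
 fluence_per_cm2  dose_Gy  unhit_fraction  hit_fraction  mean_hits  mean_hits_lo  mean_hits_hi
       4280000.0      0.5            0.01          0.99        5.1           2.8           7.3
       8550000.0      1.0            0.00          1.00       10.2           5.7          14.6
      17100000.0      2.0            0.00          1.00       20.3          11.3          29.3
      34200000.0      4.0            0.00          1.00       40.6          22.7          58.6
      68400000.0      8.0            0.00          1.00       81.3          45.4         117.2
```

At 2 Gy an average nucleus is traversed by ~20 ions and essentially every
nucleus is hit. Other subcommands: `simulate`, `fit-survival`, `rbe-oer`,
`fit-cellcycle`, `foci-kinetics`, and `run` (the whole pipeline with a
results bundle).

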