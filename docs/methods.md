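# Methods

This note records the models, defaults, numerical choices and limitations
behind radbiokit, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Clonogenic survival

**Model.** S(D) = 1 − (1 − e^(−D/D₀))ⁿ, the single-hit multi-target (SHMT)
survival curve. D₀ > 0 is the dose that reduces survival by e-fold along
the exponential final slope; n > 0 is the extrapolation number (n < 1 is
allowed — high-LET curves are often shoulderless with n below one). In
log₁₀ space the curve approaches a line of slope −1/(D₀ ln 10) with
intercept log₁₀ n, which is exactly how D₀ and n are defined graphically.

**Plating efficiency and surviving fractions.** PE is the mean over
unirradiated replicate dishes of colonies/seeded, SE = SD/√n. SF per dish
is (colonies/seeded)/PE, aggregated to mean ± SE per dose. 0 Gy points
anchor PE only and are excluded from the regression (their SF is 1 by
construction; keeping them would double-count PE noise). Dishes with zero
colonies at positive dose are excluded from log-domain fitting (log
undefined) and counted in a QC column.

**Fitting.** Weighted least squares on log₁₀ SF via
`scipy.optimize.least_squares`, bounds D₀, n ∈ (10⁻³, 10³), tolerances
1e-14 so noise-free inputs are recovered to optimizer precision.
Weights are 1/SE(log₁₀ SF) with SE mapped from the SF scale by the delta
method (SE/(SF·ln10)); the fit is unweighted when no usable SEs are
supplied. Initialisation: a line through the two highest doses in ln SF
gives 1/D₀ from the slope and n from the intercept, falling back to
(1.5, 1) when degenerate. Parameter covariance is the standard asymptotic
(JᵀJ)⁻¹·RSS/dof. A linear-domain fit is available (`log_domain=False`).

*Caution on weights:* with very few replicates (e.g. 3 dishes/dose) the
empirical SEM is noise-dominated, and weighting by it correlates the
weights with the noise; in simulation this inflates recovered D₀ by a few
percent relative to an unweighted fit of the per-dish surviving fractions.
The recovery studies in the acceptance script therefore fit per-dish SFs
unweighted in log space; the pipeline default keeps per-dose SEM weighting
for consistency with how such data are usually summarised.

**RBE and OER.** RBE = D₀(reference X-rays)/D₀(test radiation);
OER = D₀(hypoxia)/D₀(normoxia). Standard errors are first-order delta
method: SE(ratio) = ratio·√((SE₁/D₀₁)² + (SE₂/D₀₂)²). Reported ratios are
conventionally rounded to 2 decimals.

**Inverse curve.** The dose giving survival t is
D = −D₀·ln(1 − (1−t)^(1/n)), the exact inversion of the model (for n = 1
it reduces to D = −D₀·ln t). It is verified against forward evaluation to
1e-9.

## Particle-traversal dosimetry

Dose/fluence conversion uses D [Gy] = 1.602×10⁻⁹ · Φ[cm⁻²] · L[keV/µm]
for water at 1 g/cm³ (1.602×10⁻¹⁶ J/keV × 10⁴ µm/cm ÷ 10⁻³ kg/cm³). Ion
traversals through a nucleus of area A are Poisson with λ = Φ·A. Area
variation is summarised at mean ± 1 SD only; mixing Poisson rates over a
full area distribution would be a straightforward extension but is
deliberately off — the mean ± SD convention matches how such tables are
reported. When mean − SD ≤ 0 the lower bound is reported as absent rather
than negative. Published tabulations of this kind are sometimes internally
inconsistent between their fluence and hits columns (the fluences matching
an LET of ≈71 keV/µm while the hits match 73); this package always computes
fluence from dose at the configured LET, so its fluence and hits columns
are mutually consistent by construction. Display rounding: hits 1 dp,
fractions 2 dp, fluence 3 significant digits.

`hit_distribution` truncates the Poisson pmf where the tail mass drops
below 1e-9 (via `scipy.stats.poisson.ppf`), without renormalising.

## Cell-cycle deconvolution

The DNA-content histogram model is
f(x) = A₁·N(x; μ₁, cv₁μ₁) + A_S·R(x) + A₂·N(x; rμ₁, cv₂rμ₁), where R is a
unit-area rectangle on [μ₁, rμ₁] convolved with the G1 Gaussian width
(expressed with normal CDFs). This replaces the classical second-degree-
polynomial S-phase with a single broadened block: it is identifiable with
few parameters and recovers fractions well in simulation; the polynomial
S-phase is a possible extension. Phase fractions are the component areas
normalised to 1, which makes them invariant to count scaling and to
multiplicative gain shifts of the x-axis (μ₁ refits).

Constraints: r ∈ [1.8, 2.05] (dye stoichiometry puts the G2/M peak near
twice G1, with instrument nonlinearity absorbing the rest), CVs ∈ (0, 0.2],
initial r = 1.95, initial CV = 0.05, μ₁ initialised at the histogram mode.
Histograms with fewer than 1000 events are refused (the fit is unstable);
at least 50 bins are required. Debris and doublets are NOT modelled —
inputs must be pre-gated upstream (export gated singlet histograms as
bin_center,count CSV from the acquisition software). A G2 area collapsing
to zero (single-peak input) is reported with a boundary warning rather
than an error.

## Foci kinetics

Group summaries are per-nucleus means ± SE per condition/timepoint, with a
warning below 20 nuclei. Background handling: subtract the time-matched
unirradiated control mean when one exists for the same oxygen/quality and
timepoint, otherwise the pooled control mean; without any control the raw
mean is reported with a warning. Whether published focus figures average
per nucleus or per image is often unstated — this package is explicitly
per-nucleus, and the background source is recorded on the result object.
Excess is floored at 0 for reporting.

Repair is summarised by E(t) = E₀e^(−kt) + c fitted to the positive
excesses (≥ 3 timepoints required), with t½ = ln2/k. The model is a
quantitative convenience: the qualitative claim "most damage resolves
within 6 h" corresponds to fraction_remaining(6 h) < 0.5. A constant
excess is flagged non-identifiable (k = 0) instead of fitting noise.

`expected_vs_observed` compares the initial excess with the dosimetry λ at
the same dose; at 2 Gy and 73 keV/µm through a 118.8 µm² nucleus the
expectation rounds to 20 hits per nucleus.

## Synthetic-data generator

The generator emulates the study conditions the analyses target:

- **Colonies**: Binomial(seeded, PE·S(D)) per dish — Binomial, not Poisson,
  because colonies ≤ seeded is a hard invariant. Defaults: 4 conditions
  (normoxia/hypoxia × X-rays/carbon, immediate plating) with
  (PE, D₀ Gy, n) = (0.35, 2.98, 1.07), (0.25, 1.68, 1.20),
  (0.35, 1.11, 0.64), (0.25, 1.10, 0.34); doses 0–8 Gy; 3 replicates of
  200 seeded cells.
- **DNA histograms**: G1 ~ N(μ₁, cvμ₁), G2 ~ N(rμ₁, cv·rμ₁), S uniform on
  (μ₁, rμ₁) plus Gaussian measurement noise; defaults μ₁ = 50 (arbitrary
  fluorescence units), r = 1.95, cv = 0.05, 10⁵ events in 200 bins,
  fractions (0.5964, 0.1725, 0.2311) — a typical cycling normoxic
  distribution (the G2 entry absorbs the rounding needed to sum to 1).
- **Foci**: Poisson(background + E₀e^(−kt) + plateau) per nucleus, with E₀
  defaulting to the dosimetry λ at the configured beam/dose (≈20.3 at
  2 Gy carbon), k = 0.3 h⁻¹ (half-time ≈ 2.3 h, consistent with most
  repair completing within 6 h), plateau 1 focus (residual damage),
  background 0.5 foci/nucleus (typical unirradiated epithelial cells),
  200 nuclei per timepoint at 1, 2, 6, 12, 18, 24 h.

One global seed drives fixed per-generator substreams
(`numpy.random.SeedSequence(seed, spawn_key=(stream,))`), so outputs are
byte-identical under a fixed seed and adding one generator never perturbs
another.

**What passing tests show — and don't.** The generators reproduce the
statistical structure the estimators assume (Binomial/Poisson counting
noise, Gaussian mixture peaks, exponential repair). Real data additionally
contain debris/doublets in histograms, focus-counting saturation at high
dose, plate-to-plate PE drift, and non-Poisson overdispersion of foci —
none of which are simulated. Recovery results on synthetic data therefore
validate the estimation machinery, not robustness to those artefacts.

## Problem sizes and estimator behaviour

The recovery studies use 100 simulated survival datasets (3 dishes × 200
cells at 0.5–4 Gy) and 500 plating-efficiency datasets; the cell-cycle
recovery uses single 10⁵-event histograms. These sizes give Monte-Carlo
standard errors comfortably below the effects being checked while keeping
the whole suite fast. Under the survival-study conditions the D₀ estimator
is right-skewed (doses ≤ 4 Gy barely reach the final slope, so D₀ and n
trade off), giving a mean recovery a few percent above truth; the test
checks the mean against a 5% band, and the skew is documented here rather
than hidden by switching to the median.

## Known limitations

- No linear-quadratic survival model; SHMT only.
- No significance testing between curves or conditions.
- Cell-cycle inputs must be pre-gated; no FCS ingestion (CSV only).
- No depth-dose (Bragg curve) or track-structure modelling; single LET
  value per beam.
- Foci image segmentation is upstream; counts are taken as given.
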