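"""Synthetic data generators for every pipeline stage.

The generators emulate an A549-style radiobiology study: colony-count tables
from clonogenic assays under four conditions (normoxia/hypoxia × X-rays/
carbon ions), trimodal DNA-content histograms, and per-nucleus γH2AX foci
counts with exponential repair.  Default parameters are the study conditions
the analyses target: SHMT survival parameters per condition, plating
efficiencies of 35% (normoxia) and 25% (hypoxia), a 73 keV/µm carbon beam
traversing 118.8 ± 52.5 µm² nuclei, and cell-cycle fractions near
60/17/24% (G1/S/G2) under normoxia.

Noise models: colony counts are Binomial(seeded, PE·S(D)) — colonies can
never exceed seeded cells; foci counts are Poisson; DNA content is a
three-component Gaussian/uniform mixture with measurement noise.

All generators are deterministic under a fixed seed.  A single global seed
drives fixed per-generator substreams, so adding draws to one generator does
not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cellcycle import DnaHistogram
from .clonogenic import shmt_survival
from .dosimetry import BeamSpec, NucleusGeometry, mean_traversals

__all__ = [
    "ConditionTruth",
    "CellCycleTruth",
    "FociTruth",
    "SimulationTruth",
    "simulate_colonies",
    "simulate_dna_histogram",
    "simulate_foci",
]

# substream offsets: one fixed lane per generator
_STREAM_COLONIES = 0
_STREAM_HISTOGRAM = 1
_STREAM_FOCI = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class ConditionTruth:
    """Ground truth for one clonogenic condition."""

    oxygen: str
    quality: str
    plating: str
    pe: float
    d0_Gy: float
    n: float

    def __post_init__(self) -> None:
        if not 0 < self.pe <= 1:
            raise ValueError("plating efficiency must be in (0, 1]")
        if self.d0_Gy <= 0 or self.n <= 0:
            raise ValueError("SHMT parameters must be positive")


@dataclass(frozen=True)
class CellCycleTruth:
    """Ground truth for DNA-content histogram generation."""

    f_g1: float = 0.5964
    f_s: float = 0.1725
    f_g2: float = 0.2311  # fractions sum to 1
    mu_g1: float = 50.0
    ratio_g2g1: float = 1.95
    cv: float = 0.05
    events: int = 100_000
    n_bins: int = 200

    def __post_init__(self) -> None:
        total = self.f_g1 + self.f_s + self.f_g2
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"phase fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class FociTruth:
    """Ground truth for foci-count generation."""

    background: float = 0.5
    initial_excess: float | None = None  # None -> dosimetry λ for beam/dose
    k_per_h: float = 0.3
    plateau: float = 1.0
    nuclei_per_timepoint: int = 200
    timepoints_h: tuple = (1.0, 2.0, 6.0, 12.0, 18.0, 24.0)


#: Immediate- and late-plating SHMT truths for the four condition combinations
#: (A549-style defaults; D0 in Gy).
DEFAULT_CONDITIONS = (
    ConditionTruth("normoxia", "xray", "immediate", pe=0.35, d0_Gy=2.98, n=1.07),
    ConditionTruth("hypoxia", "xray", "immediate", pe=0.25, d0_Gy=1.68, n=1.20),
    ConditionTruth("normoxia", "carbon", "immediate", pe=0.35, d0_Gy=1.11, n=0.64),
    ConditionTruth("hypoxia", "carbon", "immediate", pe=0.25, d0_Gy=1.10, n=0.34),
)


@dataclass
class SimulationTruth:
    """Full generator configuration; fixed seed gives byte-identical outputs."""

    conditions: tuple = DEFAULT_CONDITIONS
    doses_Gy: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    seeded: int = 200
    replicates: int = 3
    cellcycle: CellCycleTruth = field(default_factory=CellCycleTruth)
    foci: FociTruth = field(default_factory=FociTruth)
    beam: BeamSpec = field(default_factory=lambda: BeamSpec(73.0, "carbon 25.7 MeV/n"))
    geometry: NucleusGeometry = field(default_factory=lambda: NucleusGeometry(118.8, 52.5))
    foci_dose_Gy: float = 2.0
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        return d


def simulate_colonies(truth: SimulationTruth) -> pd.DataFrame:
    """Colony-count table: colonies ~ Binomial(seeded, PE · S(D)) per dish.

    Includes 0 Gy dishes for plating-efficiency estimation. Columns match the
    clonogenic input schema.
    """
    rng = _rng(truth.rng_seed, _STREAM_COLONIES)
    rows = []
    for cond in truth.conditions:
        for dose in truth.doses_Gy:
            p = cond.pe * shmt_survival(dose, cond.d0_Gy, cond.n)
            if p > 1:
                raise ValueError(
                    f"PE x survival = {p:.3f} > 1 for {cond}: impossible configuration"
                )
            colonies = rng.binomial(truth.seeded, p, size=truth.replicates)
            for rep, c in enumerate(colonies, start=1):
                rows.append(
                    {
                        "oxygen": cond.oxygen,
                        "quality": cond.quality,
                        "plating": cond.plating,
                        "dose_Gy": dose,
                        "seeded": truth.seeded,
                        "colonies": int(c),
                        "replicate": f"r{rep}",
                    }
                )
    return pd.DataFrame(rows)


def simulate_dna_histogram(
    truth: SimulationTruth, condition: str = "", timepoint_h: float = np.nan,
    replicate: str = "", cellcycle: CellCycleTruth | None = None,
) -> DnaHistogram:
    """One DNA-content histogram from the three-phase mixture.

    G1 events ~ N(μ₁, cv·μ₁); G2 ~ N(rμ₁, cv·rμ₁); S uniform on (μ₁, rμ₁)
    plus Gaussian measurement noise of the G1 width. Binned onto a uniform
    grid covering 0 … 1.6·rμ₁.
    """
    cc = cellcycle if cellcycle is not None else truth.cellcycle
    rng = _rng(truth.rng_seed, _STREAM_HISTOGRAM)
    mu1, mu2 = cc.mu_g1, cc.ratio_g2g1 * cc.mu_g1
    n_phase = rng.multinomial(cc.events, [cc.f_g1, cc.f_s, cc.f_g2])
    g1 = rng.normal(mu1, cc.cv * mu1, n_phase[0])
    s = rng.uniform(mu1, mu2, n_phase[1]) + rng.normal(0, cc.cv * mu1, n_phase[1])
    g2 = rng.normal(mu2, cc.cv * mu2, n_phase[2])
    values = np.concatenate([g1, s, g2])
    edges = np.linspace(0.0, 1.6 * mu2, cc.n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DnaHistogram(
        bin_centers=centers, counts=counts.astype(float),
        condition=condition, timepoint_h=timepoint_h, replicate=replicate,
    )


def simulate_foci(truth: SimulationTruth) -> pd.DataFrame:
    """Per-nucleus foci counts over time: Poisson(background + E₀e^(−kt) + plateau).

    The initial excess E₀ defaults to the Poisson traversal mean λ for the
    configured beam, geometry and foci dose. Includes time-matched
    unirradiated control nuclei (dose 0, Poisson background only).
    """
    ft = truth.foci
    e0 = ft.initial_excess
    if e0 is None:
        e0 = mean_traversals(truth.foci_dose_Gy, truth.beam, truth.geometry).mean_hits
    if ft.background < 0 or e0 < 0 or ft.plateau < 0 or ft.k_per_h < 0:
        raise ValueError("foci rates must be non-negative")
    rng = _rng(truth.rng_seed, _STREAM_FOCI)
    rows = []
    for oxy in ("normoxia", "hypoxia"):
        for tp in ft.timepoints_h:
            lam = ft.background + e0 * np.exp(-ft.k_per_h * tp) + ft.plateau
            counts = rng.poisson(lam, ft.nuclei_per_timepoint)
            ctrl = rng.poisson(ft.background, ft.nuclei_per_timepoint)
            for i, c in enumerate(counts, start=1):
                rows.append(
                    {
                        "oxygen": oxy, "quality": "carbon",
                        "dose_Gy": truth.foci_dose_Gy, "timepoint_h": tp,
                        "nucleus_id": f"{oxy[0]}{tp:g}h_{i}", "foci_count": int(c),
                    }
                )
            for i, c in enumerate(ctrl, start=1):
                rows.append(
                    {
                        "oxygen": oxy, "quality": "carbon",
                        "dose_Gy": 0.0, "timepoint_h": tp,
                        "nucleus_id": f"{oxy[0]}{tp:g}h_ctrl_{i}", "foci_count": int(c),
                    }
                )
    return pd.DataFrame(rows)
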