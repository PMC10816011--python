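"""Particle fluence/dose conversion and Poisson traversal statistics.

For a broad parallel ion beam of fluence :math:`\\Phi` (particles/cm²) and
linear energy transfer :math:`L` (keV/µm) in water at unit density, the
absorbed dose is

.. math:: D\\,[\\mathrm{Gy}] = 1.602\\times 10^{-9} \\cdot \\Phi \\cdot L

The number of independent ion traversals through a cell nucleus of area
:math:`A` is Poisson distributed with mean :math:`\\lambda = \\Phi A`, so the
probability that a nucleus is not hit at all is :math:`e^{-\\lambda}`.
Nucleus-to-nucleus area variation is summarised by evaluating
:math:`\\lambda` at the mean area and at mean ± 1 SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Gy per (particle/cm² · keV/µm) in water at density 1 g/cm³:
#: 1.602e-16 J/keV × 1e4 µm/cm ÷ 1e-3 kg/cm³ = 1.602e-9.
DOSE_FLUENCE_CONSTANT = 1.602e-9

UM2_TO_CM2 = 1e-8


@dataclass(frozen=True)
class BeamSpec:
    """Ion beam description: LET in water and a free-text label."""

    let_keV_um: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.let_keV_um > 0:
            raise ValueError(f"LET must be > 0 keV/um, got {self.let_keV_um}")


@dataclass(frozen=True)
class NucleusGeometry:
    """Cell-nucleus cross-sectional area, mean ± SD in µm²."""

    mean_area_um2: float
    sd_area_um2: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_area_um2 > 0:
            raise ValueError("mean nucleus area must be positive")
        if self.sd_area_um2 < 0:
            raise ValueError("nucleus area SD must be non-negative")

    @property
    def lower_area_um2(self) -> float | None:
        """Area one SD below the mean; None if that would be non-positive."""
        lo = self.mean_area_um2 - self.sd_area_um2
        return lo if lo > 0 else None

    @property
    def upper_area_um2(self) -> float:
        return self.mean_area_um2 + self.sd_area_um2


@dataclass(frozen=True)
class TraversalStats:
    """Poisson traversal summary for one dose point."""

    dose_Gy: float
    fluence_per_cm2: float
    mean_hits: float
    mean_hits_lo: float | None
    mean_hits_hi: float
    unhit_fraction: float = field(init=False)
    hit_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "unhit_fraction", math.exp(-self.mean_hits))
        object.__setattr__(self, "hit_fraction", 1.0 - self.unhit_fraction)


def dose_from_fluence(fluence_per_cm2: float, let_keV_um: float) -> float:
    """Absorbed dose (Gy) delivered by ``fluence_per_cm2`` at the given LET."""
    if fluence_per_cm2 < 0:
        raise ValueError("fluence must be non-negative")
    if not let_keV_um > 0:
        raise ValueError("LET must be positive")
    return DOSE_FLUENCE_CONSTANT * fluence_per_cm2 * let_keV_um


def fluence_from_dose(dose_Gy: float, let_keV_um: float) -> float:
    """Particle fluence (cm⁻²) required to deliver ``dose_Gy`` at the given LET."""
    if dose_Gy < 0:
        raise ValueError("dose must be non-negative")
    if not let_keV_um > 0:
        raise ValueError("LET must be positive")
    return dose_Gy / (DOSE_FLUENCE_CONSTANT * let_keV_um)


def mean_traversals(
    dose_Gy: float, beam: BeamSpec, geometry: NucleusGeometry
) -> TraversalStats:
    """Poisson mean traversals per nucleus at ``dose_Gy``.

    λ is evaluated at the mean nucleus area and at mean ± 1 SD; the lower
    bound is reported as None when mean − SD is non-positive.
    """
    fluence = fluence_from_dose(dose_Gy, beam.let_keV_um)
    lam = fluence * geometry.mean_area_um2 * UM2_TO_CM2
    lo_area = geometry.lower_area_um2
    lam_lo = fluence * lo_area * UM2_TO_CM2 if lo_area is not None else None
    lam_hi = fluence * geometry.upper_area_um2 * UM2_TO_CM2
    return TraversalStats(
        dose_Gy=dose_Gy,
        fluence_per_cm2=fluence,
        mean_hits=lam,
        mean_hits_lo=lam_lo,
        mean_hits_hi=lam_hi,
    )


def traversal_table(
    doses_Gy: Sequence[float], beam: BeamSpec, geometry: NucleusGeometry
) -> pd.DataFrame:
    """Tabulate traversal statistics for a list of doses.

    Columns: fluence_per_cm2, dose_Gy, unhit_fraction, hit_fraction,
    mean_hits, mean_hits_lo, mean_hits_hi — one row per dose.
    """
    rows = []
    for d in doses_Gy:
        ts = mean_traversals(d, beam, geometry)
        rows.append(
            {
                "fluence_per_cm2": ts.fluence_per_cm2,
                "dose_Gy": ts.dose_Gy,
                "unhit_fraction": ts.unhit_fraction,
                "hit_fraction": ts.hit_fraction,
                "mean_hits": ts.mean_hits,
                "mean_hits_lo": ts.mean_hits_lo,
                "mean_hits_hi": ts.mean_hits_hi,
            }
        )
    cols = [
        "fluence_per_cm2",
        "dose_Gy",
        "unhit_fraction",
        "hit_fraction",
        "mean_hits",
        "mean_hits_lo",
        "mean_hits_hi",
    ]
    return pd.DataFrame(rows, columns=cols)


def format_traversal_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round a traversal table for display: hits to 1 dp, fractions to 2 dp,
    fluence to 3 significant digits."""
    out = table.copy()
    out["fluence_per_cm2"] = [
        float(f"{v:.3g}") for v in out["fluence_per_cm2"]
    ]
    out["unhit_fraction"] = out["unhit_fraction"].round(2)
    out["hit_fraction"] = out["hit_fraction"].round(2)
    for c in ("mean_hits", "mean_hits_lo", "mean_hits_hi"):
        out[c] = out[c].round(1)
    return out


def hit_distribution(lambda_mean: float, tail_mass: float = 1e-9) -> pd.Series:
    """Poisson pmf over hit counts k = 0..K, truncated so tail mass < ``tail_mass``.

    Returns a Series indexed by k; the (untruncated) probabilities sum to
    within ``tail_mass`` of 1 on the returned support.
    """
    if lambda_mean < 0:
        raise ValueError("Poisson mean must be non-negative")
    if lambda_mean == 0:
        return pd.Series([1.0], index=pd.Index([0], name="hits"))
    kmax = int(stats.poisson.ppf(1.0 - tail_mass, lambda_mean)) + 1
    while stats.poisson.sf(kmax, lambda_mean) >= tail_mass:
        kmax += 1
    k = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(k, lambda_mean)
    return pd.Series(pmf, index=pd.Index(k, name="hits"))
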