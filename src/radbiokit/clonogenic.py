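"""Clonogenic survival analysis: plating efficiency, surviving fractions,
single-hit multi-target (SHMT) curve fitting, RBE and OER.

The SHMT model describes reproductive survival after a dose :math:`D`:

.. math:: S(D) = 1 - \\left(1 - e^{-D/D_0}\\right)^n

where :math:`D_0` is the dose reducing survival to 37% along the exponential
final slope and :math:`n` (extrapolation number) is the y-intercept of the
back-extrapolated exponential tail.  The fit is performed by weighted least
squares on :math:`\\log_{10} S` because survival curves are judged on a
logarithmic scale and :math:`n` is defined by straight-line extrapolation
there.

Relative biological effectiveness and oxygen enhancement ratio are ratios of
fitted :math:`D_0` values:

.. math:: \\mathrm{RBE} = D_0(\\text{X-rays}) / D_0(\\text{test}),
          \\qquad \\mathrm{OER} = D_0(\\text{hypoxia}) / D_0(\\text{normoxia})

with standard errors by the first-order delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "shmt_survival",
    "dose_at_survival",
    "plating_efficiency",
    "surviving_fractions",
    "SHMTModel",
    "SHMTResults",
    "RatioEstimate",
    "rbe",
    "oer",
]

LN10 = math.log(10.0)

COLONY_COLUMNS = ["oxygen", "quality", "plating", "dose_Gy", "seeded", "colonies", "replicate"]

_BOUNDS = ((1e-3, 1e-3), (1e3, 1e3))  # (d0, n) lower / upper


def shmt_survival(dose_Gy, d0_Gy: float, n: float):
    """SHMT surviving fraction S(D) = 1 − (1 − e^(−D/D0))^n.

    Vectorised over ``dose_Gy``. Requires d0 > 0 and n > 0; S(0) = 1 exactly
    and S is strictly decreasing in dose.
    """
    if not d0_Gy > 0:
        raise ValueError("D0 must be positive")
    if not n > 0:
        raise ValueError("extrapolation number n must be positive")
    dose = np.asarray(dose_Gy, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    # -expm1(-D/d0) = 1 - exp(-D/d0), accurate for small doses
    s = 1.0 - np.power(-np.expm1(-dose / d0_Gy), n)
    return s if s.ndim else float(s)


def dose_at_survival(d0_Gy: float, n: float, target_sf: float) -> float:
    """Dose at which SHMT survival equals ``target_sf`` (closed form).

    Inverting S(D) = 1 − (1 − e^(−D/D0))^n gives
    D = −D0 · ln(1 − (1 − target)^(1/n)); for n = 1 this reduces to
    D = −D0 · ln(target).
    """
    if not 0 < target_sf < 1:
        raise ValueError("target surviving fraction must lie in (0, 1)")
    return -d0_Gy * math.log(1.0 - (1.0 - target_sf) ** (1.0 / n))


def plating_efficiency(records: pd.DataFrame) -> pd.DataFrame:
    """Plating efficiency per condition from unirradiated (0 Gy) dishes.

    PE is the mean over replicate dishes of colonies/seeded; SE is the
    replicate SD divided by √n (NaN for a single replicate).

    Parameters
    ----------
    records : DataFrame with at least oxygen, quality, plating, dose_Gy,
        seeded, colonies. Only 0 Gy rows are used.

    Returns
    -------
    DataFrame indexed by (oxygen, quality, plating) with columns
    ``pe``, ``se_pe``, ``n_replicates``.
    """
    zero = records[records["dose_Gy"] == 0]
    if zero.empty:
        raise ValueError("no unirradiated (0 Gy) records: plating efficiency undefined")
    frac = zero["colonies"] / zero["seeded"]
    grp = frac.groupby([zero["oxygen"], zero["quality"], zero["plating"]])
    out = grp.agg(pe="mean", se_pe="sem", n_replicates="size")
    if (out["pe"] <= 0).any():
        bad = out.index[out["pe"] <= 0].tolist()
        raise ValueError(f"zero colonies across all unirradiated dishes for {bad}")
    return out


def surviving_fractions(records: pd.DataFrame, pe_table: pd.DataFrame) -> pd.DataFrame:
    """Per-dose surviving fractions normalised by plating efficiency.

    SF = (colonies/seeded)/PE per dish, then mean ± SE per (condition, dose).
    Dishes with zero colonies at positive dose cannot enter a log-domain fit;
    they are excluded and counted in the ``n_zero_excluded`` column.
    """
    recs = records[records["dose_Gy"] > 0].copy()
    key = ["oxygen", "quality", "plating"]
    pe = pe_table["pe"]
    pe_vals = pd.MultiIndex.from_frame(recs[key]).map(pe)
    if pd.isna(pe_vals).any():
        missing = sorted(set(map(tuple, recs.loc[pd.isna(pe_vals), key].values)))
        raise ValueError(f"no plating efficiency for condition(s) {missing}")
    recs["sf"] = (recs["colonies"] / recs["seeded"]) / np.asarray(pe_vals)
    zero_mask = recs["colonies"] == 0
    kept = recs[~zero_mask]
    grp = kept.groupby(key + ["dose_Gy"])["sf"]
    table = grp.agg(sf="mean", se_sf="sem", n_replicates="size")
    n_zero = (
        recs[zero_mask].groupby(key + ["dose_Gy"]).size()
        if zero_mask.any()
        else pd.Series(dtype=int)
    )
    table["n_zero_excluded"] = n_zero.reindex(table.index, fill_value=0).astype(int)
    return table.reset_index()


@dataclass
class RatioEstimate:
    """A ratio of two fitted D0 values with a delta-method standard error."""

    value: float
    se: float
    kind: str  # "rbe" or "oer"
    numerator_label: str = ""
    denominator_label: str = ""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind.upper()} = {self.value:.2f} ± {self.se:.2f}"


class SHMTModel:
    """Single-hit multi-target survival model for one experimental condition.

    Parameters
    ----------
    dose_Gy, sf : array-like
        Positive doses and their mean surviving fractions. 0 Gy points are
        dropped (they anchor plating efficiency, not the curve: SF ≡ 1 there
        by construction).
    se_sf : array-like, optional
        Standard errors of the surviving fractions; used as weights via the
        delta method on the log scale. Unweighted fit if omitted or all-zero.
    label : str
        Condition label carried into the results.
    log_domain : bool
        Fit log10(SF) (default) or raw SF.
    """

    def __init__(self, dose_Gy, sf, se_sf=None, label: str = "", log_domain: bool = True):
        dose = np.asarray(dose_Gy, dtype=float)
        sf = np.asarray(sf, dtype=float)
        keep = dose > 0
        dose, sf = dose[keep], sf[keep]
        if se_sf is not None:
            se_sf = np.asarray(se_sf, dtype=float)[keep]
        if np.any(sf <= 0):
            raise ValueError("surviving fractions must be positive for fitting")
        if len(np.unique(dose)) < 3:
            raise ValueError("need >= 3 distinct positive doses to fit D0 and n")
        order = np.argsort(dose)
        self.dose = dose[order]
        self.sf = sf[order]
        self.se_sf = None if se_sf is None else se_sf[order]
        self.label = label
        self.log_domain = log_domain

    @classmethod
    def from_dataframe(cls, sf_table: pd.DataFrame, label: str = "", **kw) -> "SHMTModel":
        """Build from a surviving_fractions() table (columns dose_Gy, sf, se_sf)."""
        se = sf_table["se_sf"].to_numpy() if "se_sf" in sf_table else None
        if se is not None and np.all(~np.isfinite(se)):
            se = None
        return cls(sf_table["dose_Gy"], sf_table["sf"], se_sf=se, label=label, **kw)

    # -- internals ---------------------------------------------------------

    def _initial_guess(self) -> tuple[float, float]:
        """Slope/intercept of ln(SF) on the two highest doses gives 1/D0 and n."""
        d, s = self.dose[-2:], np.log(self.sf[-2:])
        if d[1] > d[0] and s[1] < s[0]:
            slope = (s[1] - s[0]) / (d[1] - d[0])
            d0 = -1.0 / slope
            n = math.exp(s[0] - slope * d[0])
            if 1e-3 < d0 < 1e3 and 1e-3 < n < 1e3:
                return d0, n
        return 1.5, 1.0

    def _residuals(self, params, weights):
        d0, n = params
        model = shmt_survival(self.dose, d0, n)
        if self.log_domain:
            r = np.log10(self.sf) - np.log10(np.maximum(model, 1e-300))
        else:
            r = self.sf - model
        return r * weights

    def fit(self) -> "SHMTResults":
        """Weighted least squares; returns an :class:`SHMTResults`."""
        if self.se_sf is not None and np.all(np.isfinite(self.se_sf)) and np.any(self.se_sf > 0):
            if self.log_domain:
                # delta method: se(log10 S) = se(S) / (S ln 10)
                sig = self.se_sf / (self.sf * LN10)
            else:
                sig = self.se_sf.copy()
            sig[sig <= 0] = np.nanmin(sig[sig > 0]) if np.any(sig > 0) else 1.0
            weights = 1.0 / sig
        else:
            weights = np.ones_like(self.dose)

        res = optimize.least_squares(
            self._residuals,
            x0=self._initial_guess(),
            args=(weights,),
            bounds=_BOUNDS,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not res.success:
            raise RuntimeError(
                f"SHMT fit did not converge for '{self.label}': {res.message}; "
                f"last iterate d0={res.x[0]:.4g}, n={res.x[1]:.4g}"
            )
        d0, n = res.x
        dof = len(self.dose) - 2
        rss = float(res.fun @ res.fun)
        # asymptotic covariance from the Jacobian at the optimum
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        return SHMTResults(model=self, d0_Gy=d0, n_extrapolation=n, cov_params=cov, rss=rss, dof=dof)


@dataclass
class SHMTResults:
    """Fitted SHMT parameters with uncertainties and diagnostics."""

    model: SHMTModel | None
    d0_Gy: float
    n_extrapolation: float
    cov_params: np.ndarray
    rss: float
    dof: int
    se_d0: float = field(init=False)
    se_n: float = field(init=False)
    _label: str = ""

    def __post_init__(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.se_d0 = float(np.sqrt(self.cov_params[0, 0]))
            self.se_n = float(np.sqrt(self.cov_params[1, 1]))

    @classmethod
    def from_parameters(
        cls,
        d0_Gy: float,
        n_extrapolation: float = 1.0,
        se_d0: float = np.nan,
        se_n: float = np.nan,
        label: str = "",
    ) -> "SHMTResults":
        """Wrap externally reported (D0, n) — e.g. published estimates — so
        they can enter RBE/OER ratios and curve evaluation."""
        cov = np.diag([se_d0**2, se_n**2])
        return cls(
            model=None,
            d0_Gy=d0_Gy,
            n_extrapolation=n_extrapolation,
            cov_params=cov,
            rss=np.nan,
            dof=0,
            _label=label,
        )

    @property
    def label(self) -> str:
        return self.model.label if self.model is not None else self._label

    def predict(self, dose_Gy):
        """Surviving fraction at the given dose(s) under the fitted curve."""
        return shmt_survival(dose_Gy, self.d0_Gy, self.n_extrapolation)

    def dose_at_survival(self, target_sf: float) -> float:
        return dose_at_survival(self.d0_Gy, self.n_extrapolation, target_sf)

    def summary(self) -> str:
        lines = [
            "Single-hit multi-target survival fit",
            "====================================",
            f"condition:  {self.label or '(unlabelled)'}",
            f"doses:      "
            + (
                np.array2string(self.model.dose, precision=3)
                if self.model is not None
                else "(external parameters)"
            ),
            f"D0 [Gy]:    {self.d0_Gy:.4f}  (SE {self.se_d0:.4f})",
            f"n:          {self.n_extrapolation:.4f}  (SE {self.se_n:.4f})",
            f"RSS:        {self.rss:.4g}  (dof {self.dof})",
            f"SF(2 Gy):   {self.predict(2.0):.4f}",
        ]
        return "\n".join(lines)


def _ratio(num: SHMTResults, den: SHMTResults, kind: str) -> RatioEstimate:
    value = num.d0_Gy / den.d0_Gy
    rel = 0.0
    for r in (num, den):
        if np.isfinite(r.se_d0):
            rel += (r.se_d0 / r.d0_Gy) ** 2
    return RatioEstimate(
        value=value,
        se=value * math.sqrt(rel),
        kind=kind,
        numerator_label=num.label,
        denominator_label=den.label,
    )


def rbe(fit_reference_xray: SHMTResults, fit_test: SHMTResults) -> RatioEstimate:
    """Relative biological effectiveness: D0(reference X-rays) / D0(test)."""
    return _ratio(fit_reference_xray, fit_test, "rbe")


def oer(fit_hypoxia: SHMTResults, fit_normoxia: SHMTResults) -> RatioEstimate:
    """Oxygen enhancement ratio: D0(hypoxia) / D0(normoxia)."""
    return _ratio(fit_hypoxia, fit_normoxia, "oer")
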