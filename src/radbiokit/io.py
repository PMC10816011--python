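"""CSV readers/writers with schema validation, run configuration and the
umbrella pipeline.

CSV dialect throughout: comma-separated, header row, UTF-8, dot decimal.
Every output bundle carries a provenance record (config echo + seed + config
hash), so two runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellcycle import DnaHistogram, fit_djf, summarize_timecourse
from .clonogenic import (
    SHMTModel,
    plating_efficiency,
    rbe,
    oer,
    surviving_fractions,
)
from .dosimetry import BeamSpec, NucleusGeometry, format_traversal_table, traversal_table
from .foci import expected_vs_observed, fit_decay, summarize_foci
from .dosimetry import mean_traversals
from .simulate import SimulationTruth, simulate_colonies, simulate_dna_histogram, simulate_foci

log = logging.getLogger("radbiokit")

COLONY_SCHEMA = {
    "oxygen": str, "quality": str, "plating": str,
    "dose_Gy": float, "seeded": int, "colonies": int, "replicate": str,
}
FOCI_SCHEMA = {
    "oxygen": str, "quality": str, "dose_Gy": float,
    "timepoint_h": float, "nucleus_id": str, "foci_count": int,
}
HISTOGRAM_SCHEMA = {"bin_center": float, "count": float}


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a CSV against a column schema.

    Missing required columns are a hard error; rows with unparseable numerics
    or violated invariants (colonies > seeded, negative counts) are dropped
    and logged with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("%s is empty", path)
        return pd.DataFrame(columns=list(schema))
    if df.empty and len(df.columns) <= 1:
        log.warning("%s is empty", path)
        return pd.DataFrame(columns=list(schema))
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[list(schema)]
    bad = pd.Series(False, index=df.index)
    for col, typ in schema.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad |= coerced.isna() & df[col].notna()
            df[col] = coerced
        else:
            df[col] = df[col].astype(str)
    if {"colonies", "seeded"} <= set(schema):
        bad |= df["colonies"] > df["seeded"]
        bad |= (df["colonies"] < 0) | (df["seeded"] <= 0) | (df["dose_Gy"] < 0)
    if "foci_count" in schema:
        bad |= (df["foci_count"] < 0) | (df["foci_count"] % 1 != 0)
    if bad.any():
        for idx in df.index[bad]:
            log.warning("%s: rejected row at line %d (invalid value)", path, idx + 2)
        df = df[~bad]
    for col, typ in schema.items():
        if typ is int:
            df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def read_histogram(path, **meta) -> DnaHistogram:
    """Read one bin_center,count CSV into a DnaHistogram."""
    df = read_table(path, HISTOGRAM_SCHEMA)
    return DnaHistogram(df["bin_center"].to_numpy(), df["count"].to_numpy(), **meta)


def write_histogram(hist: DnaHistogram, path) -> None:
    pd.DataFrame({"bin_center": hist.bin_centers, "count": hist.counts}).to_csv(
        path, index=False
    )


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    counts_csv: Path | None = None       # None -> simulate
    foci_csv: Path | None = None         # None -> simulate
    histogram_manifest: Path | None = None  # None -> simulate
    let_keV_um: float = 73.0
    mean_area_um2: float = 118.8
    sd_area_um2: float = 52.5
    doses_Gy: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)
    foci_dose_Gy: float = 2.0
    run_cellcycle: bool = True
    run_foci: bool = True
    n_cellcycle_samples: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["out_dir"] = Path(raw["out_dir"])
        for k in ("counts_csv", "foci_csv", "histogram_manifest"):
            if raw.get(k):
                raw[k] = Path(raw[k])
        if "doses_Gy" in raw:
            raw["doses_Gy"] = tuple(raw["doses_Gy"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = str(v) if isinstance(v, Path) else v
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a results bundle.

    Stages: (simulate) -> plating efficiency -> survival fits -> RBE/OER ->
    traversal table -> cell-cycle fits -> foci kinetics. Any stage failure
    raises with the stage name; files written so far are preserved.

    Returns the results dictionary (also written as results.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    beam = BeamSpec(config.let_keV_um)
    geom = NucleusGeometry(config.mean_area_um2, config.sd_area_um2)
    truth = SimulationTruth(rng_seed=config.seed, foci_dose_Gy=config.foci_dose_Gy)

    stage = "survival"
    try:
        if config.counts_csv is not None:
            counts = read_table(config.counts_csv, COLONY_SCHEMA)
        else:
            counts = simulate_colonies(truth)
            counts.to_csv(out / "counts.csv", index=False)
        pe = plating_efficiency(counts)
        sf = surviving_fractions(counts, pe)
        pe.reset_index().to_csv(out / "plating_efficiency.csv", index=False)
        sf.to_csv(out / "surviving_fractions.csv", index=False)
        fits = {}
        fit_rows = []
        for key, grp in sf.groupby(["oxygen", "quality", "plating"]):
            label = "/".join(key)
            r = SHMTModel.from_dataframe(grp, label=label).fit()
            fits[key] = r
            fit_rows.append(
                {
                    "oxygen": key[0], "quality": key[1], "plating": key[2],
                    "d0_Gy": r.d0_Gy, "se_d0": r.se_d0,
                    "n": r.n_extrapolation, "se_n": r.se_n, "rss": r.rss,
                }
            )
        pd.DataFrame(fit_rows).to_csv(out / "shmt_fits.csv", index=False)
        results["stages"][stage] = {
            "n_records": int(len(counts)),
            "fits": {"/".join(k): {"d0_Gy": v.d0_Gy, "n": v.n_extrapolation} for k, v in fits.items()},
        }

        stage = "rbe_oer"
        metrics = []
        for plating in sorted({k[2] for k in fits}):
            for oxy in ("normoxia", "hypoxia"):
                kx, kc = (oxy, "xray", plating), (oxy, "carbon", plating)
                if kx in fits and kc in fits:
                    m = rbe(fits[kx], fits[kc])
                    metrics.append({"comparison": f"rbe carbon {oxy} {plating}", "value": m.value, "se": m.se})
            for qual in ("xray", "carbon"):
                kh, kn = ("hypoxia", qual, plating), ("normoxia", qual, plating)
                if kh in fits and kn in fits:
                    m = oer(fits[kh], fits[kn])
                    metrics.append({"comparison": f"oer {qual} {plating}", "value": m.value, "se": m.se})
        pd.DataFrame(metrics).to_csv(out / "rbe_oer.csv", index=False)
        results["stages"][stage] = {m["comparison"]: round(m["value"], 4) for m in metrics}

        stage = "traversals"
        tab = traversal_table(list(config.doses_Gy), beam, geom)
        tab.to_csv(out / "traversals.csv", index=False)
        disp = format_traversal_table(tab)
        results["stages"][stage] = {
            "mean_hits": disp["mean_hits"].tolist(),
            "doses_Gy": disp["dose_Gy"].tolist(),
        }

        if config.run_cellcycle:
            stage = "cellcycle"
            cc_fits = []
            if config.histogram_manifest is not None:
                manifest = pd.read_csv(config.histogram_manifest)
                base = Path(config.histogram_manifest).parent
                for _, row in manifest.iterrows():
                    h = read_histogram(
                        base / row["file"], condition=str(row["condition"]),
                        timepoint_h=float(row["timepoint_h"]),
                        replicate=str(row.get("replicate", "")),
                    )
                    cc_fits.append(fit_djf(h))
            else:
                for i in range(config.n_cellcycle_samples):
                    t2 = SimulationTruth(rng_seed=config.seed + 1000 + i)
                    h = simulate_dna_histogram(t2, condition="normoxia", timepoint_h=2.0 + i)
                    write_histogram(h, out / f"histogram_{i}.csv")
                    cc_fits.append(fit_djf(h))
            tc = summarize_timecourse(cc_fits)
            tc.to_csv(out / "cellcycle_timecourse.csv", index=False)
            results["stages"][stage] = {
                "n_samples": len(cc_fits),
                "mean_pct_g1": round(float(np.mean([100 * f.f_g1 for f in cc_fits])), 3),
            }

        if config.run_foci:
            stage = "foci"
            if config.foci_csv is not None:
                foci_df = read_table(config.foci_csv, FOCI_SCHEMA)
            else:
                foci_df = simulate_foci(truth)
                foci_df.to_csv(out / "foci.csv", index=False)
            kinetics = summarize_foci(foci_df)
            kin_rows, comp_rows = [], []
            for kin in kinetics:
                t = kin.table.copy()
                t.insert(0, "condition", kin.condition)
                t.insert(1, "dose_Gy", kin.dose_Gy)
                kin_rows.append(t)
                ts = mean_traversals(kin.dose_Gy, beam, geom)
                comp_rows.append(expected_vs_observed(kin, ts))
            pd.concat(kin_rows, ignore_index=True).to_csv(out / "foci_kinetics.csv", index=False)
            pd.DataFrame(comp_rows).to_csv(out / "foci_expected_vs_observed.csv", index=False)
            results["stages"][stage] = {
                "n_groups": len(kinetics),
                "expected_hits_rounded": comp_rows[0]["expected_hits_rounded"] if comp_rows else None,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    _write_summary(out, results)
    return results


def _write_summary(out: Path, results: dict) -> None:
    lines = [
        f"radbiokit v{results['package_version']} run summary",
        f"config hash {results['config_hash']}, seed {results['seed']}",
        "",
    ]
    st = results["stages"]
    if "survival" in st:
        lines.append("Survival fits (D0 Gy / n):")
        for label, fit in st["survival"]["fits"].items():
            lines.append(f"  {label:35s} {fit['d0_Gy']:.3f} / {fit['n']:.3f}")
    if "rbe_oer" in st:
        lines.append("RBE / OER:")
        for k, v in st["rbe_oer"].items():
            lines.append(f"  {k:35s} {v:.2f}")
    if "traversals" in st:
        lines.append("Mean ion hits per nucleus by dose (Gy):")
        for d, h in zip(st["traversals"]["doses_Gy"], st["traversals"]["mean_hits"]):
            lines.append(f"  {d:5.1f} Gy -> {h:6.1f} hits")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
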