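"""End-to-end orchestration: simulate/load -> gate -> score -> stats -> report.

The pipeline is a pure function of its configuration (including the master
seed): re-running with an identical config reproduces byte-identical result
CSVs.  A JSON manifest records the config hash, seed and per-stage row
counts, which together suffice to re-derive every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .endpoints import (
    HSIL_PLUS,
    LSIL_PLUS,
    EndpointSpec,
    endpoint_label,
    endpoint_roc,
    positivity_curve,
    threshold_sweep,
)
from .gating import GateConfig, gate_cells
from .simulate import SimConfig, simulate_cohort
from .stats import bh_adjust, lowess_trend, mann_whitney_one_sided
from .taxonomy import BETHESDA_CATEGORIES, HSIL, LSIL

log = logging.getLogger("cmdcyto")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cells_path``/``slides_path`` (load real tables) or
    ``sim`` (generate a synthetic cohort) must be provided.
    """

    out_dir: str = "cmdcyto_run"
    cells_path: str | None = None
    slides_path: str | None = None
    sim: SimConfig | None = None
    gate: GateConfig = field(default_factory=GateConfig)
    endpoints: tuple[EndpointSpec, ...] = (LSIL_PLUS, HSIL_PLUS)
    seed: int = 0
    n_resamples: int = 2000
    run_sweep: bool = False
    sweep_resamples: int = 200
    run_age_trends: bool = True
    lowess_frac: float = 0.5

    def __post_init__(self):
        has_paths = self.cells_path is not None and self.slides_path is not None
        has_sim = self.sim is not None
        if has_paths == has_sim:
            raise ValueError(
                "provide exactly one of (cells_path & slides_path) or a sim block"
            )


def _jsonable(o):
    if is_dataclass(o) and not isinstance(o, type):
        return _jsonable(asdict(o))
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (frozenset, set)):
        return sorted(str(v) for v in o)
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (str, int, float, bool)) or o is None:
        return o
    return str(o)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def attach_counts(
    cells: pd.DataFrame, slides: pd.DataFrame, gate: GateConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gate every cell and attach per-class ``count_<class>`` columns to slides."""
    cells = cells.copy()
    cells["label"] = gate_cells(cells, gate)
    counts = (
        cells.groupby("slide_id")["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(gate.taxonomy), fill_value=0)
    )
    counts = counts.reindex(slides["slide_id"], fill_value=0).astype(int)
    slides = slides.copy()
    for cls in gate.taxonomy:
        slides[f"count_{cls}"] = counts[cls].to_numpy()
    return cells, slides


def hpv_comparisons(slides: pd.DataFrame, classes=(LSIL, HSIL)) -> pd.DataFrame:
    """HPV+ vs HPV- count comparisons per centre and lesion class.

    One-sided Mann-Whitney tests (alternative HPV+ > HPV-) with Cliff's
    delta; Benjamini-Hochberg q-values within each lesion-class family.
    """
    rows = []
    avail = slides[slides["hpv"].isin(["positive", "negative"])]
    for cls in classes:
        col = f"count_{cls}"
        for centre, sub in avail.groupby("centre", sort=True):
            neg = sub.loc[sub["hpv"] == "negative", col].to_numpy(float)
            pos = sub.loc[sub["hpv"] == "positive", col].to_numpy(float)
            if neg.size == 0 or pos.size == 0:
                continue
            cmp_ = mann_whitney_one_sided(neg, pos)
            rows.append(
                {
                    "family": f"hpv_{cls}",
                    "centre": centre,
                    "class": cls,
                    "reference": "HPV-",
                    "comparator": "HPV+",
                    "n_ref": cmp_.n_ref,
                    "n_comp": cmp_.n_comp,
                    "U": cmp_.u_ref,
                    "delta": cmp_.delta,
                    "p": cmp_.p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy(), family=df["family"].to_numpy())
    return df


def diagnosis_comparisons(slides: pd.DataFrame, classes=(LSIL, HSIL)) -> pd.DataFrame:
    """Abnormal-category vs NILM count comparisons per centre (abnormal > NILM)."""
    rows = []
    for cls in classes:
        col = f"count_{cls}"
        for centre, sub in slides.groupby("centre", sort=True):
            nilm = sub.loc[sub["diagnosis"] == "NILM", col].to_numpy(float)
            if nilm.size == 0:
                continue
            for cat in BETHESDA_CATEGORIES[1:]:
                comp = sub.loc[sub["diagnosis"] == cat, col].to_numpy(float)
                if comp.size == 0:
                    continue
                cmp_ = mann_whitney_one_sided(nilm, comp)
                rows.append(
                    {
                        "family": f"diag_{cls}_{centre}",
                        "centre": centre,
                        "class": cls,
                        "reference": "NILM",
                        "comparator": cat,
                        "n_ref": cmp_.n_ref,
                        "n_comp": cmp_.n_comp,
                        "U": cmp_.u_ref,
                        "delta": cmp_.delta,
                        "p": cmp_.p,
                    }
                )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy(), family=df["family"].to_numpy())
    return df


def roc_tables(
    slides: pd.DataFrame,
    endpoints,
    n_resamples: int,
    seed,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-centre and combined ROC/AUC summaries with bootstrap CIs."""
    rng = np.random.default_rng(seed)
    auc_rows, curve_rows = [], []
    groups = [("all", slides)] + [(c, s) for c, s in slides.groupby("centre", sort=True)]
    for spec in endpoints:
        for centre, sub in groups:
            labels = sub["diagnosis"].map(lambda d: endpoint_label(d, spec))
            y = labels[labels != "excluded"] == "positive"
            if y.nunique() < 2:
                log.warning("skipping ROC for %s at %s: one class only", spec.name, centre)
                continue
            roc = endpoint_roc(
                sub, spec, band=True, n_resamples=n_resamples,
                seed=int(rng.integers(0, 2**31)),
            )
            auc_rows.append(
                {
                    "endpoint": spec.name,
                    "centre": centre,
                    "n": int(y.size),
                    "n_pos": int(y.sum()),
                    "auc": roc.auc,
                    "auc_lo": roc.auc_ci[0],
                    "auc_hi": roc.auc_ci[1],
                }
            )
            step = max(1, roc.grid.size // 101)  # thin the grid for the report
            for i in range(0, roc.grid.size, step):
                curve_rows.append(
                    {
                        "endpoint": spec.name,
                        "centre": centre,
                        "fpr": roc.grid[i],
                        "tpr": roc.tpr_grid[i],
                        "lower": roc.band_lower[i],
                        "upper": roc.band_upper[i],
                    }
                )
    return pd.DataFrame(auc_rows), pd.DataFrame(curve_rows)


def composition_table(slides: pd.DataFrame, taxonomy) -> pd.DataFrame:
    """Per-slide class composition, grouped by diagnosis and sorted within
    each group by total cell count (the stacked-bar report layout)."""
    count_cols = [f"count_{c}" for c in taxonomy if f"count_{c}" in slides.columns]
    out = slides[["slide_id", "centre", "diagnosis", *count_cols]].copy()
    out["total"] = out[count_cols].sum(axis=1)
    order = {c: i for i, c in enumerate(BETHESDA_CATEGORIES)}
    out["_diag_order"] = out["diagnosis"].map(order)
    out = (
        out.sort_values(["_diag_order", "total", "slide_id"],
                        ascending=[True, False, True])
        .drop(columns="_diag_order")
        .reset_index(drop=True)
    )
    return out


def age_trend_tables(slides: pd.DataFrame, classes, frac: float, seed) -> pd.DataFrame:
    """LOWESS age trends (log scale) of per-class counts with bootstrap bands.

    Slides with zero counts for a class are excluded from that class's curve.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls in classes:
        col = f"count_{cls}"
        if col not in slides.columns:
            continue
        sub = slides.loc[slides[col] > 0, ["age", col]].dropna()
        if len(sub) < 10:
            log.warning("age trend for %s skipped: only %d slides", cls, len(sub))
            continue
        xs, fit, lo, hi = lowess_trend(
            sub["age"], sub[col], log_y=True, frac=frac, n_boot=100,
            seed=int(rng.integers(0, 2**31)),
        )
        for x, f, l, h in zip(xs, fit, lo, hi):
            rows.append({"class": cls, "age": x, "fit": f, "lower": l, "upper": h})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write result CSVs plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    if config.sim is not None:
        slides, cells = simulate_cohort(config.sim)
    else:
        cells = cio.load_cells(config.cells_path)
        slides = cio.load_slides(config.slides_path)
    manifest["stages"]["input"] = {"n_slides": len(slides), "n_cells": len(cells)}

    cells, slides = attach_counts(cells, slides, config.gate)
    count_cols = [c for c in slides.columns if c.startswith("count_")]
    total_counts = int(slides[count_cols].sum().sum())
    if total_counts != len(cells):
        raise RuntimeError("conservation violated: counts do not sum to cells")
    manifest["stages"]["gate"] = {"n_labelled": len(cells), "sum_counts": total_counts}

    cio.write_table(cells, out / "cells.csv", seed=config.seed)
    cio.write_table(slides, out / "slides.csv", seed=config.seed)

    results: dict[str, pd.DataFrame] = {}
    if "hpv" in slides.columns:
        results["hpv_comparisons"] = hpv_comparisons(slides)
    else:
        log.warning("slides table has no hpv column: HPV-stratified analyses skipped")
    results["diagnosis_comparisons"] = diagnosis_comparisons(slides)
    auc, curves = roc_tables(
        slides, config.endpoints, n_resamples=config.n_resamples, seed=config.seed
    )
    results["roc_auc"] = auc
    results["roc_curves"] = curves
    results["composition"] = composition_table(slides, config.gate.taxonomy)
    for cls in (LSIL, HSIL):
        results[f"positivity_{cls}"] = positivity_curve(
            slides, cls, cutoffs=[0, 1, 2, 5, 10, 20, 50, 100, 200, 500]
        )
    if config.run_age_trends:
        results["age_trends"] = age_trend_tables(
            slides, classes=[c for c in config.gate.fallback], frac=config.lowess_frac,
            seed=config.seed,
        )
    if config.run_sweep:
        for spec in config.endpoints:
            results[f"sweep_{spec.name.replace('+', 'plus').replace(' ', '_')}"] = (
                threshold_sweep(
                    cells, slides, spec, gate_config=config.gate,
                    n_resamples=config.sweep_resamples, seed=config.seed,
                )
            )

    for name, df in results.items():
        cio.write_table(df, out / f"{name}.csv", seed=config.seed)
        manifest["stages"][name] = {"n_rows": len(df)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
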