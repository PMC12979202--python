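"""Slide-level diagnostic endpoints, scores, positivity curves and sweeps.

A slide-level endpoint partitions the Bethesda categories into negatives,
positives and exclusions and pairs them with a count-based predictor score:

* ``LSIL+`` — negatives NILM; positives LSIL, ASC-H, HSIL, SCC; ASC-US
  excluded.  Default score: LSIL count + HSIL count (an ``lsil_only``
  variant uses the LSIL count alone).
* ``HSIL+`` — negatives NILM, ASC-US, LSIL; positives HSIL, SCC; ASC-H
  excluded.  Score: HSIL count.
* ``HPV+`` — the HPV test result is the label (slides without a result are
  excluded); the same count scores serve as predictors.

All-samples variants (no exclusions, excluded categories folded into the
negatives) are provided for the ROC-on-everything analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import GateConfig, gate_cells
from .stats import RocResult, bootstrap_roc_band, empirical_roc
from .taxonomy import BETHESDA_CATEGORIES, HSIL, LSIL

__all__ = [
    "EndpointSpec",
    "LSIL_PLUS",
    "LSIL_PLUS_ALL",
    "HSIL_PLUS",
    "HSIL_PLUS_ALL",
    "endpoint_label",
    "slide_score",
    "hpv_endpoint_label",
    "positivity_curve",
    "threshold_sweep",
    "default_sweep_grid",
]

SCORE_RULES = {
    "lsil_plus_hsil": (LSIL, HSIL),
    "lsil_only": (LSIL,),
    "hsil_only": (HSIL,),
}


@dataclass(frozen=True)
class EndpointSpec:
    """A slide-level endpoint: category partition plus predictor rule."""

    name: str
    negatives: frozenset[str]
    positives: frozenset[str]
    excluded: frozenset[str] = frozenset()
    score_rule: str = "lsil_plus_hsil"

    def __post_init__(self):
        groups = (self.negatives, self.positives, self.excluded)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                overlap = groups[a] & groups[b]
                if overlap:
                    raise ValueError(f"endpoint sets overlap on {sorted(overlap)}")
        if not (self.negatives or self.positives):
            raise ValueError("negatives and positives cannot both be empty")
        if self.score_rule not in SCORE_RULES:
            raise ValueError(f"unknown score rule {self.score_rule!r}")


LSIL_PLUS = EndpointSpec(
    name="LSIL+",
    negatives=frozenset({"NILM"}),
    positives=frozenset({"LSIL", "ASC-H", "HSIL", "SCC"}),
    excluded=frozenset({"ASC-US"}),
    score_rule="lsil_plus_hsil",
)

#: All-samples variant: ASC-US counted as negative instead of excluded.
LSIL_PLUS_ALL = EndpointSpec(
    name="LSIL+ (all samples)",
    negatives=frozenset({"NILM", "ASC-US"}),
    positives=frozenset({"LSIL", "ASC-H", "HSIL", "SCC"}),
    score_rule="lsil_plus_hsil",
)

HSIL_PLUS = EndpointSpec(
    name="HSIL+",
    negatives=frozenset({"NILM", "ASC-US", "LSIL"}),
    positives=frozenset({"HSIL", "SCC"}),
    excluded=frozenset({"ASC-H"}),
    score_rule="hsil_only",
)

HSIL_PLUS_ALL = EndpointSpec(
    name="HSIL+ (all samples)",
    negatives=frozenset({"NILM", "ASC-US", "LSIL", "ASC-H"}),
    positives=frozenset({"HSIL", "SCC"}),
    score_rule="hsil_only",
)


def endpoint_label(diagnosis: str, spec: EndpointSpec) -> str:
    """Map a Bethesda diagnosis to 'positive' / 'negative' / 'excluded'."""
    if diagnosis in spec.positives:
        return "positive"
    if diagnosis in spec.negatives:
        return "negative"
    if diagnosis in spec.excluded:
        return "excluded"
    raise ValueError(
        f"diagnosis {diagnosis!r} is in none of the {spec.name} endpoint sets"
    )


def hpv_endpoint_label(hpv: str) -> str:
    """HPV-reference labelling: missing results are excluded."""
    if hpv == "positive":
        return "positive"
    if hpv == "negative":
        return "negative"
    return "excluded"


def slide_score(counts, spec: EndpointSpec | str) -> int:
    """Count-based predictor score for a slide under an endpoint's rule."""
    rule = spec.score_rule if isinstance(spec, EndpointSpec) else spec
    if rule not in SCORE_RULES:
        raise ValueError(f"unknown score rule {rule!r}")
    counts = dict(counts)
    return int(sum(counts.get(c, 0) for c in SCORE_RULES[rule]))


def positivity_curve(
    slides: pd.DataFrame, lesion_class: str, cutoffs
) -> pd.DataFrame:
    """Fraction of slides per Bethesda category with counts above each cutoff.

    A slide is called positive at cutoff ``c`` when ``count_<class> > c``;
    the fraction is therefore non-increasing in the cutoff.  Categories with
    no slides get NaN.  Tidy output: (category, cutoff, n, fraction).
    """
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    if cutoffs.size == 0:
        raise ValueError("cutoffs must be non-empty")
    col = f"count_{lesion_class}"
    if col not in slides.columns:
        raise KeyError(f"slides table has no column {col!r}")
    rows = []
    for cat in BETHESDA_CATEGORIES:
        sub = slides.loc[slides["diagnosis"] == cat, col].to_numpy(float)
        for c in cutoffs:
            frac = float(np.mean(sub > c)) if sub.size else float("nan")
            rows.append({"category": cat, "cutoff": c, "n": sub.size, "fraction": frac})
    return pd.DataFrame(rows)


def default_sweep_grid(start: float = 0.60, stop: float = 0.99, step: float = 0.01):
    """Per-cell probability threshold grid, 0.60 to 0.99 inclusive."""
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


def threshold_sweep(
    cells: pd.DataFrame,
    slides: pd.DataFrame,
    spec: EndpointSpec,
    grid=None,
    gate_config: GateConfig | None = None,
    n_resamples: int = 500,
    seed=None,
) -> pd.DataFrame:
    """Re-gate at each per-cell lesion threshold and recompute the endpoint AUC.

    For every grid value ``t``, all lesion gates are set to ``t``, cells are
    re-gated, slide scores recomputed and the endpoint AUC estimated with a
    stratified bootstrap CI.  Tidy output: one row per threshold with
    (threshold, auc, auc_lo, auc_hi, n_pos, n_neg).
    """
    grid = default_sweep_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("sweep grid must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    gate_config = gate_config or GateConfig()
    labels = slides["diagnosis"].map(lambda d: endpoint_label(d, spec))
    keep = labels != "excluded"
    slide_ids = slides.loc[keep, "slide_id"].to_numpy()
    y = (labels[keep] == "positive").to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for t in grid:
        cfg = gate_config.with_lesion_threshold(float(t))
        cell_labels = gate_cells(cells, cfg)
        score_classes = SCORE_RULES[spec.score_rule]
        per_slide = (
            cells.loc[cell_labels.isin(score_classes), "slide_id"]
            .value_counts()
            .reindex(slide_ids, fill_value=0)
        )
        scores = per_slide.to_numpy(float)
        if y.all() or not y.any():
            rows.append(
                {"threshold": float(t), "auc": float("nan"), "auc_lo": float("nan"),
                 "auc_hi": float("nan"), "n_pos": int(y.sum()), "n_neg": int((~y).sum())}
            )
            continue
        roc = bootstrap_roc_band(
            scores, y, n_resamples=n_resamples, seed=rng.integers(0, 2**31)
        )
        rows.append(
            {
                "threshold": float(t),
                "auc": roc.auc,
                "auc_lo": roc.auc_ci[0],
                "auc_hi": roc.auc_ci[1],
                "n_pos": int(y.sum()),
                "n_neg": int((~y).sum()),
            }
        )
    return pd.DataFrame(rows)


def endpoint_roc(
    slides: pd.DataFrame,
    spec: EndpointSpec,
    band: bool = False,
    n_resamples: int = 2000,
    seed=None,
) -> RocResult:
    """ROC of an endpoint from a slides table carrying ``count_*`` columns."""
    labels = slides["diagnosis"].map(lambda d: endpoint_label(d, spec))
    keep = labels != "excluded"
    counts_cols = {c.removeprefix("count_"): c for c in slides.columns if c.startswith("count_")}
    sub = slides.loc[keep]
    scores = np.zeros(len(sub))
    for cls in SCORE_RULES[spec.score_rule]:
        if cls in counts_cols:
            scores = scores + sub[counts_cols[cls]].to_numpy(float)
    y = (labels[keep] == "positive").to_numpy()
    if band:
        return bootstrap_roc_band(scores, y, n_resamples=n_resamples, seed=seed)
    return empirical_roc(scores, y)
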