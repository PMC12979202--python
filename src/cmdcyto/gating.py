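"""Hierarchical rule-based labelling of cells from CMD vectors.

Each detected cell carries a vector of per-class confidences (independent
sigmoid outputs in [0, 1], not constrained to sum to one).  Labels are
assigned by a fixed hierarchy borrowed from flow-cytometry gating:

1. confidence for ``irrelevant`` above its threshold -> "irrelevant";
2. else confidence for ``leukocyte`` above its threshold -> "leukocyte";
3. else any lesion class (LSIL / HSIL / adenocarcinoma) whose confidence
   crosses its gate -> the crossed lesion class with the highest confidence
   (exact ties broken by severity: adenocarcinoma > HSIL > LSIL);
4. else the argmax over the remaining normal classes.

Per-slide aggregation counts labelled cells per class; the epithelial
fraction is the superficial/intermediate share of non-irrelevant,
non-leukocyte cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .taxonomy import (
    IRRELEVANT,
    LEUKOCYTE,
    LESION_CLASSES,
    LESION_SEVERITY,
    SUPERFICIAL,
    TAXONOMY_11,
    fallback_classes,
    validate_taxonomy,
)

#: Per-cell probability threshold for the positive (lesion) classes.
DEFAULT_LESION_THRESHOLD = 0.80


@dataclass(frozen=True)
class GateConfig:
    """Thresholds and class grouping of the gating hierarchy.

    The lesion gates default to 0.80; the irrelevant and leukocyte gates,
    published only graphically, default to 0.5 and are configurable.
    """

    taxonomy: tuple[str, ...] = TAXONOMY_11
    irrelevant_threshold: float = 0.5
    leukocyte_threshold: float = 0.5
    lesion_thresholds: dict[str, float] = field(
        default_factory=lambda: {c: DEFAULT_LESION_THRESHOLD for c in LESION_CLASSES}
    )

    def __post_init__(self):
        validate_taxonomy(self.taxonomy)
        for name, value in (
            ("irrelevant_threshold", self.irrelevant_threshold),
            ("leukocyte_threshold", self.leukocyte_threshold),
            *self.lesion_thresholds.items(),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"threshold {name} must lie in [0, 1], got {value}")
        unknown = set(self.lesion_thresholds) - set(LESION_CLASSES)
        if unknown:
            raise ValueError(f"unknown lesion classes in thresholds: {sorted(unknown)}")

    @property
    def lesion_classes(self) -> tuple[str, ...]:
        return tuple(c for c in LESION_CLASSES if c in self.taxonomy)

    @property
    def fallback(self) -> tuple[str, ...]:
        return fallback_classes(self.taxonomy)

    def with_lesion_threshold(self, value: float) -> "GateConfig":
        """Copy of this config with every lesion gate set to ``value``."""
        return replace(
            self, lesion_thresholds={c: value for c in self.lesion_thresholds}
        )


def gate_cell(cmd: dict[str, float], config: GateConfig | None = None) -> str:
    """Assign one label to a single CMD vector by the gating hierarchy."""
    config = config or GateConfig()
    missing = set(config.taxonomy) - set(cmd)
    if missing:
        raise KeyError(f"CMD vector missing classes: {sorted(missing)}")
    if cmd[IRRELEVANT] >= config.irrelevant_threshold:
        return IRRELEVANT
    if cmd[LEUKOCYTE] >= config.leukocyte_threshold:
        return LEUKOCYTE
    crossed = [
        c
        for c in config.lesion_classes
        if cmd[c] >= config.lesion_thresholds.get(c, DEFAULT_LESION_THRESHOLD)
    ]
    if crossed:
        best = max(cmd[c] for c in crossed)
        for c in LESION_SEVERITY:  # severity order breaks exact ties
            if c in crossed and cmd[c] == best:
                return c
    return max(config.fallback, key=lambda c: (cmd[c], -config.fallback.index(c)))


def gate_cells(cells: pd.DataFrame, config: GateConfig | None = None) -> pd.Series:
    """Vectorised gating of a cells table with ``cmd_<class>`` columns.

    Returns the per-cell label Series (aligned with ``cells.index``); the
    result is identical to mapping :func:`gate_cell` over rows.
    """
    config = config or GateConfig()
    cols = [f"cmd_{c}" for c in config.taxonomy]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise KeyError(f"cells table missing CMD columns: {missing}")
    n = len(cells)
    labels = np.empty(n, dtype=object)
    undecided = np.ones(n, dtype=bool)

    irr = cells[f"cmd_{IRRELEVANT}"].to_numpy(float) >= config.irrelevant_threshold
    labels[irr] = IRRELEVANT
    undecided &= ~irr

    leuk = cells[f"cmd_{LEUKOCYTE}"].to_numpy(float) >= config.leukocyte_threshold
    take = undecided & leuk
    labels[take] = LEUKOCYTE
    undecided &= ~leuk

    lesions = config.lesion_classes
    if lesions and undecided.any():
        vals = cells[[f"cmd_{c}" for c in lesions]].to_numpy(float)
        thr = np.array(
            [config.lesion_thresholds.get(c, DEFAULT_LESION_THRESHOLD) for c in lesions]
        )
        crossed = vals >= thr
        masked = np.where(crossed, vals, -np.inf)
        any_crossed = crossed.any(axis=1)
        # highest crossed confidence; exact ties resolved by severity order
        sev_rank = np.array([LESION_SEVERITY.index(c) for c in lesions])
        best = masked.max(axis=1, keepdims=True)
        tie_key = np.where(masked == best, -sev_rank, -np.inf)
        pick = tie_key.argmax(axis=1)
        take = undecided & any_crossed
        labels[take] = np.array(lesions, dtype=object)[pick[take]]
        undecided &= ~any_crossed

    if undecided.any():
        fb = config.fallback
        vals = cells[[f"cmd_{c}" for c in fb]].to_numpy(float)
        pick = vals.argmax(axis=1)  # argmax keeps the first class on exact ties
        labels[undecided] = np.array(fb, dtype=object)[pick[undecided]]
    return pd.Series(labels, index=cells.index, name="label")


def gate_slide(
    cells: pd.DataFrame, config: GateConfig | None = None
) -> pd.Series:
    """Gate one slide's cells and aggregate labels into per-class counts.

    All rows must share one ``slide_id``.  The assigned labels are written
    back onto the input frame (``label`` column); the returned Series maps
    every taxonomy class to its count and sums to the number of cells.
    """
    config = config or GateConfig()
    if len(cells) and "slide_id" in cells.columns:
        ids = cells["slide_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"gate_slide expects a single slide, got {list(ids)}")
    counts = pd.Series(0, index=list(config.taxonomy), dtype=int, name="count")
    if len(cells) == 0:
        return counts
    labels = gate_cells(cells, config)
    cells["label"] = labels
    observed = labels.value_counts()
    counts.loc[observed.index] = observed.to_numpy()
    return counts


def epithelial_fraction(counts) -> float | None:
    """Superficial/intermediate share of non-irrelevant, non-leukocyte cells.

    Returns ``None`` when the denominator is zero.
    """
    counts = dict(counts)
    denom = sum(
        v for k, v in counts.items() if k not in (IRRELEVANT, LEUKOCYTE)
    )
    if denom == 0:
        return None
    return counts.get(SUPERFICIAL, 0) / denom
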