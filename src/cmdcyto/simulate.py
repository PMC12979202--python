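"""Synthetic multi-centre cervical-cytology cohort generator.

Generates slides and per-cell CMD confidence vectors with the statistical
structure the downstream analysis assumes, so every pipeline stage can be
exercised against known ground truth:

* per-slide total cellularity follows a heavy-tailed (log-normal)
  distribution spanning several thousand to several hundred thousand cells;
* epithelial composition is age-conditional — the superficial/intermediate
  share declines after ~50 years, parabasal and metaplastic shares rise,
  and navicular cells peak in the early twenties;
* abnormal-cell burdens (LSIL / HSIL / adenocarcinoma counts) follow
  negative-binomial laws conditional on the Bethesda diagnosis and HPV
  status, with HPV-positive slides carrying larger burdens;
* CMD vectors are independent per-class Beta draws (sigmoid semantics, no
  sum-to-one constraint): the true class draws from a high-mean Beta, every
  other class from a low-mean Beta, with configurable confusion mass between
  morphologically adjacent phenotypes (navicular <-> LSIL by default).

Randomness: one master seed; each slide gets a deterministic child stream
spawned by its index, so any subset of slides is reproducible independently
of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import (
    ADENOCARCINOMA,
    BETHESDA_CATEGORIES,
    GLANDULAR,
    HSIL,
    IRRELEVANT,
    LEUKOCYTE,
    LSIL,
    METAPLASTIC,
    MISCELLANEOUS,
    NAVICULAR,
    PARABASAL,
    SUPERFICIAL,
    TAXONOMY_11,
    validate_taxonomy,
)

MIXTURE_TOL = 1e-9

#: Default per-centre slide totals, matching the four study centres.
DEFAULT_N_SLIDES = {"C": 318, "T": 222, "K": 385, "J": 199}

#: Diagnosis mixtures per centre.  The screening centre K sees mostly NILM;
#: the cancer-specialty centre C sees a larger abnormal share.
DEFAULT_DIAGNOSIS_MIXTURE = {
    "C": {"NILM": 0.45, "ASC-US": 0.12, "LSIL": 0.18, "ASC-H": 0.05, "HSIL": 0.17, "SCC": 0.03},
    "T": {"NILM": 0.55, "ASC-US": 0.12, "LSIL": 0.15, "ASC-H": 0.04, "HSIL": 0.12, "SCC": 0.02},
    "K": {"NILM": 0.80, "ASC-US": 0.08, "LSIL": 0.08, "ASC-H": 0.01, "HSIL": 0.03, "SCC": 0.00},
    "J": {"NILM": 0.55, "ASC-US": 0.12, "LSIL": 0.15, "ASC-H": 0.04, "HSIL": 0.12, "SCC": 0.02},
}

#: P(HPV positive | diagnosis); severity raises HPV positivity.
DEFAULT_HPV_MODEL = {
    "NILM": 0.25,
    "ASC-US": 0.55,
    "LSIL": 0.85,
    "ASC-H": 0.85,
    "HSIL": 0.92,
    "SCC": 0.95,
}

#: Fraction of slides without an HPV result (the study analysed the subset
#: with available results).
DEFAULT_HPV_MISSING_RATE = 0.25

#: Per-centre age models: truncated normals matched to the reported
#: medians/IQRs — C 49 (41-59), T 42 (35-53), K 40 (30-48), J 42 (34-55).
#: sigma ~ IQR / 1.349 for a normal.
DEFAULT_AGE_MODEL = {
    "C": {"median": 49.0, "iqr": (41.0, 59.0)},
    "T": {"median": 42.0, "iqr": (35.0, 53.0)},
    "K": {"median": 40.0, "iqr": (30.0, 48.0)},
    "J": {"median": 42.0, "iqr": (34.0, 55.0)},
}
AGE_BOUNDS = (18.0, 90.0)


@dataclass(frozen=True)
class CellularityModel:
    """Log-normal total cell count per slide.

    Defaults give a median of 10^4 cells with a central 95% range of roughly
    [10^3, 10^5] — the two-order-of-magnitude spread seen on real slides.
    """

    median: float = 1e4
    sigma_log: float = 1.15
    minimum: int = 200

    def __post_init__(self):
        if not (math.isfinite(self.median) and self.median > 0):
            raise ValueError(f"cellularity median must be positive, got {self.median}")
        if not (math.isfinite(self.sigma_log) and self.sigma_log >= 0):
            raise ValueError(
                f"cellularity sigma_log must be non-negative, got {self.sigma_log}"
            )

    def sample(self, rng: np.random.Generator) -> int:
        n = rng.lognormal(mean=math.log(self.median), sigma=self.sigma_log)
        return max(self.minimum, int(round(n)))


@dataclass(frozen=True)
class AbnormalBurdenModel:
    """Negative-binomial lesion-cell counts conditional on (diagnosis, HPV).

    ``means[diagnosis][class]`` gives the HPV-negative mean count; the
    HPV-positive mean is multiplied by ``hpv_multiplier[class]``.  Dispersion
    is the NB ``r`` (smaller = more overdispersed); the real burden
    distributions are published only as violins, so these defaults are
    illustrative, not calibrated.
    """

    means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "NILM": {LSIL: 1.5, HSIL: 0.6, ADENOCARCINOMA: 0.1},
            "ASC-US": {LSIL: 8.0, HSIL: 2.0, ADENOCARCINOMA: 0.1},
            "LSIL": {LSIL: 60.0, HSIL: 8.0, ADENOCARCINOMA: 0.1},
            "ASC-H": {LSIL: 30.0, HSIL: 40.0, ADENOCARCINOMA: 0.2},
            "HSIL": {LSIL: 50.0, HSIL: 150.0, ADENOCARCINOMA: 0.3},
            "SCC": {LSIL: 40.0, HSIL: 250.0, ADENOCARCINOMA: 1.0},
        }
    )
    hpv_multiplier: dict[str, float] = field(
        default_factory=lambda: {LSIL: 4.0, HSIL: 3.0, ADENOCARCINOMA: 1.0}
    )
    dispersion: float = 0.7  # NB size parameter r

    def __post_init__(self):
        if not (math.isfinite(self.dispersion) and self.dispersion > 0):
            raise ValueError(f"dispersion must be positive, got {self.dispersion}")
        for diag, per_class in self.means.items():
            for cls, m in per_class.items():
                if not (math.isfinite(m) and m >= 0):
                    raise ValueError(
                        f"abnormal burden mean for ({diag}, {cls}) must be "
                        f"non-negative, got {m}"
                    )

    def mean(self, diagnosis: str, cls: str, hpv: str) -> float:
        m = self.means.get(diagnosis, {}).get(cls, 0.0)
        if hpv == "positive":
            m *= self.hpv_multiplier.get(cls, 1.0)
        return m

    def sample(self, diagnosis: str, cls: str, hpv: str, rng: np.random.Generator) -> int:
        m = self.mean(diagnosis, cls, hpv)
        if m <= 0:
            return 0
        r = self.dispersion
        return int(rng.negative_binomial(r, r / (r + m)))


@dataclass(frozen=True)
class CmdNoiseModel:
    """Independent Beta draws per class with a confusion mass for neighbours.

    Each class entry is ``Beta(mu * k, (1 - mu) * k)`` where ``k`` is the
    concentration and ``mu`` depends on the relationship to the cell's true
    class: ``true_mean`` for the true class, ``confusion[(true, other)]``
    for configured morphological neighbours, ``off_mean`` otherwise.
    ``concentration = inf`` is the noiseless limit (true class 1, rest 0).
    """

    true_mean: float = 0.92
    off_mean: float = 0.04
    concentration: float = 25.0
    confusion: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            (NAVICULAR, LSIL): 0.25,  # glycogen-rich cytoplasm mimics LSIL
            (LSIL, NAVICULAR): 0.15,
            (LSIL, HSIL): 0.12,
            (HSIL, LSIL): 0.12,
        }
    )

    def __post_init__(self):
        for name, v in (("true_mean", self.true_mean), ("off_mean", self.off_mean)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.concentration > 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")
        for pair, v in self.confusion.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"confusion mean for {pair} must lie in [0, 1), got {v}")

    def mean_for(self, true_class: str, other: str) -> float:
        if other == true_class:
            return self.true_mean
        return self.confusion.get((true_class, other), self.off_mean)


@dataclass(frozen=True)
class CompositionModel:
    """Age-conditional mixture over non-lesion classes.

    Baseline weights are modulated by age: a logistic decline of the
    superficial/intermediate share after ``shift_age`` (default 50) with a
    matching rise of parabasal/metaplastic cells, and a Gaussian navicular
    bump centred at 22 years.
    """

    baseline: dict[str, float] = field(
        default_factory=lambda: {
            LEUKOCYTE: 0.30,
            SUPERFICIAL: 0.38,
            PARABASAL: 0.04,
            METAPLASTIC: 0.06,
            GLANDULAR: 0.05,
            MISCELLANEOUS: 0.04,
            NAVICULAR: 0.03,
            IRRELEVANT: 0.10,
        }
    )
    shift_age: float = 50.0
    shift_scale: float = 5.0
    superficial_drop: float = 0.22  # mass moved away from superficial at old age
    navicular_peak_age: float = 22.0
    navicular_peak_width: float = 6.0
    navicular_peak_gain: float = 0.08

    def weights(self, age: float, classes: tuple[str, ...]) -> np.ndarray:
        w = {c: self.baseline.get(c, 0.0) for c in classes}
        old = 1.0 / (1.0 + math.exp(-(age - self.shift_age) / self.shift_scale))
        drop = min(self.superficial_drop * old, w.get(SUPERFICIAL, 0.0))
        if SUPERFICIAL in w:
            w[SUPERFICIAL] -= drop
            # redistribute to the deeper-layer phenotypes seen after menopause
            for c, share in ((PARABASAL, 0.55), (METAPLASTIC, 0.45)):
                if c in w:
                    w[c] += drop * share
        if NAVICULAR in w:
            bump = self.navicular_peak_gain * math.exp(
                -0.5 * ((age - self.navicular_peak_age) / self.navicular_peak_width) ** 2
            )
            w[NAVICULAR] += bump
        arr = np.array([max(w[c], 0.0) for c in classes], dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("composition weights sum to zero")
        return arr / total


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic multi-centre cohort."""

    n_slides: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SLIDES))
    taxonomy: tuple[str, ...] = TAXONOMY_11
    diagnosis_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_DIAGNOSIS_MIXTURE.items()}
    )
    hpv_model: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HPV_MODEL))
    hpv_missing_rate: float = DEFAULT_HPV_MISSING_RATE
    age_model: dict[str, dict] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_AGE_MODEL.items()}
    )
    cellularity: CellularityModel = field(default_factory=CellularityModel)
    composition: CompositionModel = field(default_factory=CompositionModel)
    abnormal_burden: AbnormalBurdenModel = field(default_factory=AbnormalBurdenModel)
    cmd_noise: CmdNoiseModel = field(default_factory=CmdNoiseModel)
    thinprep_fraction: float = 0.5
    seed: int = 0

    @property
    def centres(self) -> tuple[str, ...]:
        return tuple(self.n_slides)

    def __post_init__(self):
        validate_taxonomy(self.taxonomy)
        for centre, n in self.n_slides.items():
            if n < 0:
                raise ValueError(f"n_slides for centre {centre!r} must be >= 0, got {n}")
            if centre not in self.diagnosis_mixture:
                raise ValueError(f"no diagnosis mixture for centre {centre!r}")
            if centre not in self.age_model:
                raise ValueError(f"no age model for centre {centre!r}")
        for centre, mix in self.diagnosis_mixture.items():
            vals = np.array(list(mix.values()), dtype=float)
            if np.any(vals < 0) or not np.all(np.isfinite(vals)):
                raise ValueError(f"diagnosis mixture for {centre!r} has invalid weights")
            if abs(vals.sum() - 1.0) > MIXTURE_TOL:
                raise ValueError(
                    f"diagnosis mixture for {centre!r} sums to {vals.sum()}, not 1"
                )
            unknown = set(mix) - set(BETHESDA_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown Bethesda categories: {sorted(unknown)}")
        for diag, p in self.hpv_model.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"hpv_model[{diag!r}] must lie in [0, 1], got {p}")
        if not 0.0 <= self.hpv_missing_rate <= 1.0:
            raise ValueError(f"hpv_missing_rate must lie in [0, 1]")
        if not 0.0 <= self.thinprep_fraction <= 1.0:
            raise ValueError("thinprep_fraction must lie in [0, 1]")


def _slide_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-slide substream: master seed + slide counter."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _sample_age(model: dict, rng: np.random.Generator) -> float:
    mu = float(model["median"])
    q1, q3 = model["iqr"]
    sigma = (float(q3) - float(q1)) / 1.349
    lo, hi = model.get("bounds", AGE_BOUNDS)
    for _ in range(1000):
        age = rng.normal(mu, sigma)
        if lo <= age <= hi:
            return float(age)
    return float(np.clip(mu, lo, hi))


def simulate_cmd_vector(
    true_class: str,
    noise: CmdNoiseModel,
    rng: np.random.Generator,
    taxonomy: tuple[str, ...] = TAXONOMY_11,
) -> dict[str, float]:
    """Draw one CMD vector for a cell of ``true_class``.

    Every entry is an independent Beta draw in [0, 1]; under the default
    noise the expected true-class entry strictly exceeds every off-class
    expectation.  In the noiseless limit (infinite concentration) the true
    class gets 1 and everything else 0.
    """
    if true_class not in taxonomy:
        raise ValueError(f"unknown class {true_class!r} for this taxonomy")
    values: dict[str, float] = {}
    for cls in taxonomy:
        mu = noise.mean_for(true_class, cls)
        if not math.isfinite(noise.concentration):
            values[cls] = 1.0 if cls == true_class else 0.0
        else:
            values[cls] = float(
                rng.beta(mu * noise.concentration, (1.0 - mu) * noise.concentration)
            )
    return values


def _cmd_matrix(
    true_classes: np.ndarray,
    noise: CmdNoiseModel,
    rng: np.random.Generator,
    taxonomy: tuple[str, ...],
) -> np.ndarray:
    """Vectorised CMD draws for a slide: (n_cells, n_classes) array."""
    n = true_classes.size
    k = len(taxonomy)
    index = {c: i for i, c in enumerate(taxonomy)}
    ti = np.array([index[c] for c in true_classes])
    if not math.isfinite(noise.concentration):
        out = np.zeros((n, k))
        out[np.arange(n), ti] = 1.0
        return out
    mu = np.full((n, k), noise.off_mean)
    for (true_c, other_c), m in noise.confusion.items():
        if true_c in index and other_c in index:
            mu[ti == index[true_c], index[other_c]] = m
    mu[np.arange(n), ti] = noise.true_mean
    conc = noise.concentration
    return rng.beta(mu * conc, (1.0 - mu) * conc)


def _simulate_slide(
    config: SimConfig, centre: str, index: int, slide_id: str
) -> tuple[dict, pd.DataFrame]:
    rng = _slide_rng(config.seed, index)
    mix = config.diagnosis_mixture[centre]
    cats = list(mix)
    diagnosis = rng.choice(cats, p=np.array([mix[c] for c in cats]))
    if rng.random() < config.hpv_missing_rate:
        hpv = "missing"
    else:
        hpv = "positive" if rng.random() < config.hpv_model.get(diagnosis, 0.0) else "negative"
    age = _sample_age(config.age_model[centre], rng)
    prep = "ThinPrep" if rng.random() < config.thinprep_fraction else "SurePath"

    n_base = config.cellularity.sample(rng)
    base_classes = tuple(
        c for c in config.taxonomy if c not in (LSIL, HSIL, ADENOCARCINOMA)
    )
    weights = config.composition.weights(age, base_classes)
    base = rng.choice(len(base_classes), size=n_base, p=weights)
    true_classes = [np.array(base_classes, dtype=object)[base]]
    for cls in (LSIL, HSIL, ADENOCARCINOMA):
        if cls in config.taxonomy:
            n_abn = config.abnormal_burden.sample(diagnosis, cls, hpv, rng)
            if n_abn:
                true_classes.append(np.full(n_abn, cls, dtype=object))
    true = np.concatenate(true_classes)
    rng.shuffle(true)
    n_cells = true.size

    cmd = _cmd_matrix(true, config.cmd_noise, rng, config.taxonomy)
    cells = pd.DataFrame(
        {
            "slide_id": slide_id,
            "cell_id": [f"{slide_id}_c{i:06d}" for i in range(n_cells)],
            "x": rng.uniform(0, 4480, n_cells),
            "y": rng.uniform(0, 4504, n_cells),
            "z": rng.integers(0, 40, n_cells),
            "true_class": true,
        }
    )
    for j, cls in enumerate(config.taxonomy):
        cells[f"cmd_{cls}"] = cmd[:, j]
    slide = {
        "slide_id": slide_id,
        "centre": centre,
        "prep": prep,
        "diagnosis": str(diagnosis),
        "age": round(age, 1),
        "hpv": hpv,
        "n_cells": n_cells,
    }
    return slide, cells


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: (slides table, cells table).

    Slides carry centre / prep / diagnosis / age / HPV metadata (class counts
    are added downstream by gating); cells carry positions, the simulated
    true class and one ``cmd_<class>`` column per taxonomy entry.  Output is
    a pure function of the config, including its master seed.
    """
    slides: list[dict] = []
    cell_frames: list[pd.DataFrame] = []
    index = 0
    for centre in config.centres:
        for _ in range(config.n_slides[centre]):
            slide_id = f"{centre}{index:05d}"
            slide, cells = _simulate_slide(config, centre, index, slide_id)
            slides.append(slide)
            cell_frames.append(cells)
            index += 1
    slide_cols = ["slide_id", "centre", "prep", "diagnosis", "age", "hpv", "n_cells"]
    if not slides:
        cmd_cols = [f"cmd_{c}" for c in config.taxonomy]
        return (
            pd.DataFrame(columns=slide_cols),
            pd.DataFrame(
                columns=["slide_id", "cell_id", "x", "y", "z", "true_class", *cmd_cols]
            ),
        )
    return (
        pd.DataFrame(slides, columns=slide_cols),
        pd.concat(cell_frames, ignore_index=True),
    )
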