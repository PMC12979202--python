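# cmdcyto

Slide-level triage of cervical liquid-based cytology from per-cell AI
confidence vectors.

Modern autonomous cytology systems image a whole slide in 3D, detect every
nucleus, and run a classifier that emits, for each cell, one sigmoid
confidence value per morphological class — leukocytes,
superficial/intermediate squamous cells, parabasal cells, squamous
metaplasia, glandular cells, miscellaneous clusters, navicular cells, LSIL,
HSIL, adenocarcinoma, and irrelevant objects.  Treated like
cluster-of-differentiation markers in flow cytometry, these **CMD vectors**
let a whole slide be analysed as a cell population: cells are gated into
classes, per-class counts are aggregated per slide, and the counts become
quantitative biomarkers for slide-level endpoints such as *LSIL+* (low-grade
or worse) and *HSIL+* (high-grade or worse).

`cmdcyto` implements that analysis end to end, for researchers evaluating
count-based cytology triage:

* **Hierarchical gating** — each cell is labelled by a fixed rule order:
  irrelevant gate → leukocyte gate → lesion gates (LSIL / HSIL /
  adenocarcinoma, default per-cell probability threshold 0.80) → argmax over
  the remaining normal classes.
* **Slide endpoints** — LSIL+ (negatives NILM, positives LSIL/ASC-H/HSIL/SCC,
  ASC-US excluded; score = LSIL + HSIL counts, or LSIL alone) and HSIL+
  (negatives NILM/ASC-US/LSIL, positives HSIL/SCC, ASC-H excluded; score =
  HSIL count), plus HPV positivity as a reference standard.
* **Statistics** — one-sided Mann–Whitney tests (HPV⁺ > HPV⁻, abnormal >
  NILM), Cliff's δ = P(Y > X) − P(Y < X), Benjamini–Hochberg q-values per
  analysis family, empirical ROC/AUC with stratified-bootstrap percentile
  bands (2,000 resamples on a uniform FPR grid), Wilson intervals for human
  operating points, matched-specificity ΔTPR / matched-sensitivity ΔFPR
  bootstrap tests, LOWESS age trends with bootstrap bands, per-cell
  threshold sweeps (0.60–0.99).
* **Z-stack extraction** — grouping of per-layer nucleus detections into 3D
  instances (single-linkage, lateral tolerance + layer gap), best-focus layer
  selection (variance of Laplacian, Tenengrad optional), 224×224
  nucleus-centred crops with reflection padding.
* **Synthetic cohorts** — a multi-centre cohort generator with log-normal
  cellularity (10³–10⁵ cells/slide), age-conditional epithelial composition
  (superficial/intermediate decline after 50, navicular peak in the early
  20s), negative-binomial lesion burdens conditional on diagnosis and HPV,
  and independent Beta CMD noise with configurable confusion between
  look-alike classes (navicular ↔ LSIL).  Every downstream stage is testable
  against known ground truth, with no data download.

## Worked example

```python
from cmdcyto import (SimConfig, CellularityModel, GateConfig, LSIL_PLUS, HSIL_PLUS,
                     simulate_cohort, attach_counts, endpoint_roc,
                     mann_whitney_one_sided)

config = SimConfig(
    n_slides={"C": 60, "K": 60},
    cellularity=CellularityModel(median=2000, sigma_log=0.8),
    seed=7,
)
slides, cells = simulate_cohort(config)
cells, slides = attach_counts(cells, slides, GateConfig())
print(f"{len(slides)} slides, {len(cells)} cells")

for spec in (LSIL_PLUS, HSIL_PLUS):
    print(f"{spec.name} AUC = {endpoint_roc(slides, spec).auc:.3f}")

avail = slides[slides.hpv.isin(["positive", "negative"])]
neg = avail.loc[avail.hpv == "negative", "count_lsil"]
pos = avail.loc[avail.hpv == "positive", "count_lsil"]
res = mann_whitney_one_sided(neg, pos)
print(f"HPV+ vs HPV- LSIL counts: delta = {res.delta:.2f}, one-sided p = {res.p:.2g}")
```

prints

```
120 slides, 356518 cells
LSIL+ AUC = 0.992
HSIL+ AUC = 0.974
HPV+ vs HPV- LSIL counts: delta = 0.80, one-sided p = 8.3e-12
```

The AUCs say that on this simulated two-centre cohort the gated LSIL+HSIL
(resp. HSIL) counts rank abnormal slides almost perfectly above normal ones;
the positive Cliff's δ says an HPV-positive slide carries more AI-detected
LSIL cells than an HPV-negative one in 90% of cross pairs, mirroring the
biological expectation that HPV drives the abnormal-cell burden.

A `cmdcyto` command-line tool exposes the same stages
(`simulate`, `gate`, `score`, `stats`, `sweep`, `compare`, `report`, `run`);
`cmdcyto run --out results --seed 1` performs the whole chain and writes
tidy CSVs plus a JSON manifest that makes the run byte-reproducible.

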