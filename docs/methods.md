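# Methods

This note documents the models, conventions and numerical choices behind
`cmdcyto`, in the order data flows through the pipeline.

## CMD vectors and hierarchical gating

Each cell carries a vector of independent per-class confidences in [0, 1]
(sigmoid outputs, deliberately *not* constrained to sum to one: a cell can
be confidently "LSIL-like" and moderately "navicular-like" at once).  Labels
are assigned by a strict hierarchy modelled on flow-cytometry gating:

1. irrelevant-object gate (debris, defocus) — threshold default **0.5**;
2. leukocyte gate — threshold default **0.5**;
3. lesion gates for LSIL, HSIL and adenocarcinoma — threshold default
   **0.80** each.  A cell crossing several lesion gates takes the crossed
   class with the highest confidence; exact ties resolve by severity
   (adenocarcinoma > HSIL > LSIL);
4. otherwise the argmax over the remaining normal classes
   (superficial/intermediate, parabasal, metaplastic, glandular,
   miscellaneous, and navicular in the 11-class taxonomy).

All gates use the ≥ convention, so a threshold of 0 labels everything at
that stage.  The irrelevant/leukocyte defaults of 0.5 are our choice — the
source analysis publishes those gates only graphically — and are
configurable; the adenocarcinoma gate defaults to the same 0.80 as
LSIL/HSIL.  Per-slide class counts are exact aggregations of the labels, so
counts always sum to the number of cells (asserted at run time).

Design choice: the published gating uses a 2D scatter gate on the
(irrelevant, leukocyte) plane; whether that region is axis-aligned is not
stated.  We implement axis-aligned thresholds, which reproduce the described
rule order exactly and keep the gate a one-parameter-per-class object.

## Slide endpoints and scores

* **LSIL+**: negatives NILM; positives LSIL, ASC-H, HSIL, SCC; ASC-US
  excluded.  Default predictor: LSIL + HSIL counts; an `lsil_only` variant
  is selectable because both predictors appear in published practice and
  neither is canonical.
* **HSIL+**: negatives NILM, ASC-US, LSIL; positives HSIL, SCC; ASC-H
  excluded.  Predictor: HSIL count.
* All-samples variants fold the excluded category into the negatives, so
  both the exclusion-based and the everything-included analyses are
  reachable.
* **HPV endpoint**: the HPV test result is the label; slides with a missing
  result are excluded; the same count scores act as predictors.

Positivity curves report, per Bethesda category and integer cutoff *c*, the
fraction of slides with count > *c*; non-increase in *c* is asserted on all
outputs.  The threshold sweep re-gates every cell with all lesion gates set
to each value of a grid (default 0.60 to 0.99 in steps of 0.01 — the grid
endpoints are fixed, the step is our choice) and recomputes the endpoint
AUC with a stratified-bootstrap CI.

## Statistics

* **Mann–Whitney**: `U_ref` counts reference wins with ties as ½.  The
  p-value is one-sided for the pre-specified alternative (comparator >
  reference).  Exact enumeration is used when `n_ref·n_comp ≤ 400` and the
  pooled sample is tie-free; otherwise the tie-corrected normal
  approximation with continuity correction.  Count data essentially always
  carry ties, so real comparisons use the corrected approximation; the two
  agree within 0.01 at n = 15 per group (tested).
* **Cliff's δ** is the pairwise dominance statistic
  δ = [#(comp > ref) − #(comp < ref)]/(n₁n₂) = 1 − 2·U_ref/(n₁n₂),
  positive when the comparator tends larger.  It is computed via midranks,
  which equals pairwise counting exactly, and satisfies AUC = (δ + 1)/2.
* **Multiplicity**: Benjamini–Hochberg step-up q-values within each analysis
  family (one family = one comparison set per figure/table, e.g. "HPV effect
  on LSIL counts across centres").
* **ROC**: score ≥ t ⇒ predicted positive; ties contribute ½, so AUC is the
  two-sample rank statistic.  Bootstrap bands resample positives and
  negatives separately (stratified) with 2,000 resamples by default,
  interpolate each resample's curve linearly onto a uniform 1,001-node FPR
  grid, and take pointwise 2.5/97.5 percentiles.  Percentile (not BCa)
  intervals throughout.  The percentile interval of the resampled AUCs is
  reported alongside the band.
* **Operating points**: sensitivity/specificity of a binary triage rule
  (ASC-US+ or LSIL+ calls against the HPV reference) with closed-form 95%
  Wilson intervals.
* **Matched comparison**: ΔTPR at the human specificity (read off the
  interpolated curve) or ΔFPR at the human sensitivity (inverse
  interpolation; if the curve never reaches the human sensitivity, ΔFPR is
  computed against FPR = 1 and flagged as extrapolated).  The bootstrap
  jointly resamples slides, re-deriving both the curve and the human point
  in each resample; a fixed-human-point variant is available because the
  published procedure does not fully specify which quantity is re-estimated.
  Two-sided p = 2 × the smaller tail probability of the bootstrap Δ
  distribution, capped at 1.
* **Age trends**: LOWESS (statsmodels) on log counts with slides at zero
  count excluded per class, percentile band over 100 bootstrap resamples,
  back-transformed to the count scale.

All resampling is a pure function of (data, parameters, seed).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it is
the test bed for every stage, and its defaults define the simulated study
conditions.

* **Cohort layout**: four centres (C, T, K, J) with default slide counts
  318/222/385/199 and centre-specific diagnosis mixtures (the screening
  centre K mostly NILM, the cancer-specialty centre C enriched for
  abnormals).  The mixtures are our choice; only the cohort sizes and the
  qualitative centre roles are documented facts.
* **Ages**: truncated normals per centre matched to the reported medians and
  IQRs — C 49 (41–59), T 42 (35–53), K 40 (30–48), J 42 (34–55) — with
  σ = IQR/1.349, truncated to [18, 90].
* **Cellularity**: log-normal with median 10⁴ and σ_log = 1.15, spanning the
  documented two-orders-of-magnitude range (central 95% ≈ 10³–10⁵ cells);
  only the spread is documented, the distributional family is our choice.
* **Composition**: age-conditional mixture over the non-lesion classes — a
  logistic decline of the superficial/intermediate share after age 50
  (redistributed to parabasal/metaplastic), and a Gaussian navicular bump
  centred at 22 years (width 6), mirroring the documented qualitative
  trends.  Magnitudes are free parameters with the defaults stated in
  `CompositionModel`.
* **HPV**: P(HPV+ | diagnosis) rises with severity (0.25 for NILM to 0.95
  for SCC); 25% of slides lack a result, mirroring the restricted-subset
  analyses.  Illustrative values.
* **Abnormal burden**: negative-binomial counts per lesion class conditional
  on (diagnosis, HPV+ multiplier); the real burden distributions are
  published only as violin plots, so means and the dispersion (r = 0.7) are
  illustrative defaults, documented in `AbnormalBurdenModel`.
* **CMD noise**: independent Beta(μk, (1−μ)k) per class with concentration
  k = 25, true-class mean 0.92, off-class mean 0.04, and explicit confusion
  means for morphologically adjacent pairs (navicular→LSIL 0.25,
  LSIL→navicular 0.15, LSIL↔HSIL 0.12).  k → ∞ is the noiseless limit used
  by recovery tests.  No noise law is published; independence plus Beta
  marginals is the simplest model with sigmoid semantics.
* **Seeding**: one master seed; slide *i* uses the substream
  `SeedSequence(seed, spawn_key=(i,))`, so any slide subset is reproducible
  independently of cohort size and outputs are byte-identical across runs.

What the generator does **not** emulate: spatial correlation of cells on a
slide, within-slide heterogeneity of CMD noise, correlated classifier errors
(e.g. stain-dependent drift), inter-centre scanner differences, and any
coupling between cellularity and diagnosis.  Passing tests therefore
demonstrate the correctness of the analysis machinery under the assumed
statistical structure, not the clinical performance of any classifier on
real slides.

## Z-stack extraction

Detections are grouped by single-linkage connectivity: two detections link
when their lateral centre distance is ≤ a tolerance (default half the mean
box diagonal) and their layer indices differ by ≤ max-gap + 1 (default gap
0, i.e. adjacent layers).  Instances are connected components; the
representative centre is the score-weighted member mean.  The published
procedure names no thresholds or metric, so these defaults are declared, not
inferred.  Focus scoring defaults to variance of Laplacian (Tenengrad via
`metric="tenengrad"`); both are offset-invariant and fall strictly under
Gaussian blur.  Ties in layer selection resolve toward the z-range midpoint,
then the lower index.  Crops use 0-based (x = column, y = row) coordinates,
map the centre pixel to output index (size//2, size//2), and fill beyond
the border by mirror reflection (excluding the edge pixel), which avoids the
flat borders that constant padding would inject into focus scores.

## Problem sizes and runtime choices

Simulation-heavy checks run on scaled cohorts chosen as the package's test
conditions: planted-effect recovery uses 400 slides with ~2,000 cells each
(the planted burden separation, 10× between HPV strata, is what the check
targets — cellularity only adds runtime); bootstrap-coverage replication
uses 200 replicate slide-level cohorts of 400 scores with 500 resamples;
sweep-stability cohorts use 120 slides at ~800 cells.  The acceptance script
simulates a quarter-scale four-centre cohort (80/55/96/50 slides, median
3,000 cells) and runs the full protocol on it.  Expected values for the
planted checks come from numerical integration over the planted
negative-binomial laws, with the exact two-sample U-statistic variance
(Hoeffding decomposition) supplying the Monte-Carlo tolerance.

## Known limitations

* The generator's burden and mixture defaults are illustrative; no attempt
  is made to fit them to any deposited dataset.
* UMAP embedding and plot rendering are out of scope: the gated cell matrix
  and tidy CSV tables are the contract, and can be fed to external tools.
* The exact Mann–Whitney path is limited to small tie-free samples; large
  tied count data always use the corrected normal approximation.
* Image stacks are handled as in-memory arrays generated programmatically;
  no slide-scanner file formats are read.
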