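# Methods

`cfcin` models a multi-analyte liquid-biopsy workflow for metastatic
colorectal cancer: chromosomal-instability (CIN) subtyping from low-coverage
whole-genome sequencing (LC-WGS) of plasma cell-free DNA, nucleosome
footprint scoring from the same reads, targeted methylation scoring with
tumor-content normalization, and survival analysis relating all three
read-outs to treatment outcome. Because the corresponding patient data are
controlled-access, the package ships a synthetic cohort generator with full
ground truth; every quantitative claim in the test suite and in
`scripts/acceptance.py` is a property of the methods exercised on that
generator or a closed-form/worked-example computation.

## Copy-number model

A plasma sample is a two-component mixture of tumor and non-tumor DNA. For
a genomic bin with integer tumor copy number `CN` and tumor fraction
`tf ∈ [0, 1]`, the expected depth ratio relative to diploid is

    r(tf, CN) = (2 (1 − tf) + tf · CN) / 2.

**Binning and normalization.** Read counts are tallied in fixed 500 kb bins
(0-based, half-open; bin size is configurable — the trial data this mirrors
were sequenced at 0.1–0.5×, a regime where 500 kb binning is standard). A
reference panel of healthy plasma samples provides a per-bin median
(location) and MAD (scale) of depth-normalized counts; bins with zero
median, or MAD above 5× the median MAD, are blacklisted. A sample is
depth-normalized, divided by the panel location, and — because total-count
normalization is inflated by net genomic gain — recentered so that the
median unmasked bin sits at ratio 1 (the median bin is assumed diploid;
this holds whenever less than half the genome is altered). The recentering
also makes the unit contract exact: doubling one bin's depth yields a log2
ratio of exactly 1 there and 0 elsewhere. Sex chromosomes are not treated
specially by the generator; on real data they should be excluded from the
panel.

**Segmentation.** Recursive segmentation with the two-sample t-like
statistic of circular binary segmentation: within a segment, every interior
interval [i, j) is scored against the rest of the segment (plain
prefix/suffix cuts are the i=0 / j=m special cases); the best interval is
accepted when its statistic exceeds 5.0 and every resulting part keeps at
least 5 unmasked bins, and the up-to-three parts are recursed on. The
interior-interval form is essential: a single prefix/suffix cut provably
cannot isolate a short focal event embedded in a long segment (its best-cut
statistic stays far below any reasonable threshold), which collapses dense
CIN-high profiles into averaged segments and biases the tumor-fraction fit
roughly twofold low. No permutation p-values or pruning are used; the
statistic threshold doubles as the stopping rule.

**Tumor fraction.** A grid search over tf ∈ {0.01, …, 1.00} (step 0.01):
for each candidate tf every segment is assigned the copy number in
{0, 1, 2, 3, 4} minimizing the squared log2 deviation from `log2 r(tf, CN)`
(the ratio floored at 0.01 to keep the log finite), and the bin-weighted
total error is minimized over tf. Near-ties (relative 1e-9) resolve to the
smallest tf, a deliberate guard against purity/ploidy aliasing: a profile
containing only CN3 gains and CN1 losses at tf is reproduced exactly by
CN4/CN0 at tf/2. For this reason the synthetic CIN-high archetypes always
contain at least one CN4 amplification and one CN0 deletion, which break
the alias; real profiles usually contain enough state diversity to do the
same. Profiles with no segment beyond ±0.02 return tf = 0.

## CIN classification

102 peak regions (43 amplifications, 59 deletions) summarize a profile into
a feature vector of bin-length-weighted mean segment log2 ratios. The real
peak coordinates and cluster centroids come from a tissue-trained
classifier that is not re-derived here; the classifier is therefore
parameterized by a peak BED file and a centroid table, and the synthetic
generator supplies self-consistent ones.

**Scaling.** Before classification a profile is rescaled to
tumor-equivalent copy numbers in linear CN space:
`CN_obs = 2·2^L`, `CN_tumor = 2 + (CN_obs − 2)/tf`, `L' = log2(CN_tumor/2)`
with tf floored at 0.03 (noise-amplification cap) and the CN argument
floored at 0.1. Scaling preserves signs, is the identity at tf = 1, and
inverts exactly under re-dilution away from the clip region. For cohorts
without matched tissue, the mean plasma:tissue tumor-fraction ratio of a
paired cohort substitutes for the per-sample tf.

**Assignment.** Genome-altered fraction (unmasked bins in segments with
|mean| > 0.1) below 0.05 forces cluster 1 (CIN-low) regardless of centroid
geometry; otherwise the cluster with the highest Pearson correlation to its
centroid wins (ties toward the lower index; zero-variance features fall
back to cluster 1 with a warning). Correlation is scale-free, which makes
the call robust to residual tumor-fraction miscalibration. Clusters 2 and 3
together form CIN-high; binary accuracy counts crossings in both
directions. Plasma/tissue concordance is a 3×3 confusion matrix with
match rate (trace/n) and binary CIN-high accuracy.

## Nucleosome footprints

Fragment starts are assigned the signed distance to the nearest nucleosome
center (ties toward the upstream center), histogrammed in 10 bp bins over
±300 bp. Healthy cfDNA yields the M-shape (modes near ±73 bp, dip at the
dyad); tumor-derived fragments are relatively enriched at the center. A
sample profile `s` is scored by linear projection onto the healthy→tumor
axis,

    score = ⟨s − h, m − h⟩ / ⟨m − h, m − h⟩,

which is exactly 0 at the healthy reference `h`, exactly 1 at the tumor
reference `m`, linear in mixture weight, and invariant to adding a constant
to all bins. Scores outside [0, 1] are flagged, never truncated. Reference
profiles are plain (un-renormalized) means of the group profiles; since
each profile sums to 1, the mean does too.

## Methylation

Target regions are designed to be unmethylated in healthy plasma (mean beta
< 0.03) and hypermethylated in tumor. Region betas are pooled-count ratios
meth/(meth+unmeth); zero-coverage cells are missing. Sample QC requires
bisulfite conversion ≥ 95% and mean region coverage ≥ 10×.

Observed betas are the mixture `(1 − tf)·β_healthy + tf·β_tumor`;
tumor-content normalization inverts it,
`β_tumor = clip((β_obs − (1 − tf)·β_healthy)/tf, 0, 1)`, with the same
0.03 tf floor. We normalize betas (not scores); the inversion is exact on
noiseless mixtures but amplifies assay noise by 1/tf, which matters below
tf ≈ 0.1 (see Limitations).

The methylation score is the tumor-class probability of a 500-tree random
forest (sqrt features per split, fixed seed) trained on pre-treatment vs
healthy betas; training samples are scored out-of-bag so no sample is
scored by trees that saw it. Missing regions are imputed with the healthy
panel mean (refused above 50% missing). The pre-to-on-treatment delta is
split at the cohort median — recomputed per cohort, not hard-coded to any
particular dataset's value — into "Large decrease" (below the median) and
"Small decrease" groups.

## Survival and statistics

All estimators are implemented in the package and cross-checked in tests
against independent oracles (enumeration, grid search, lifelines/scipy/
sklearn): Kaplan-Meier product-limit curves (median = earliest time with
S ≤ 0.5); Cox proportional hazards by Newton-Raphson with step halving,
Breslow tie handling (a declared choice; the data are continuous so ties
are rare), Wald CIs, and explicit diagnostics on monotone likelihood — no
silent estimates; Mann-Whitney U with the exact null distribution (DP over
the classic recurrence) for min(n) ≤ 8 without ties and the tie-corrected
normal approximation otherwise; Spearman correlation with average ranks and
the t approximation; ROC AUC in the rank formulation with ties counting ½;
a two-feature logistic combination with leave-one-out probabilities (small
ridge, flagged under perfect separation); and the binomial cohort-sizing
pair `n_min = ⌈log(1−c)/log(1−p)⌉`, `confidence(n) = 1 − (1−p)^n`.
Covariates follow the clinical-table conventions: age dichotomized at 65,
gender as a male indicator, TNM stage ordered with a missing-level
indicator; reference levels are cluster 1 and "Large decrease". Tests are
two-sided with no multiplicity correction.

## Synthetic cohort

Defaults are the study conditions: 74 patients, cluster prevalences
(0.1, 0.45, 0.45), tissue tumor fractions uniform on [0.1, 0.5] with
cluster-1 fractions shrunk by 0.4 (CIN-low tumors shed less ctDNA, matching
the reported cluster-wise tumor-fraction differences), plasma:tissue ratio
0.6, survival in days. The genome is scaled down to 3000 × 500 kb bins on 4
chromosomes with 3×10⁶ reads/sample (~1000 reads/bin) — chosen to preserve
per-bin counting statistics of 500 kb LC-WGS binning at a tractable problem
size. Counts are negative binomial (size 2000, per-bin CV ≈ 4% after GC
bias, which is shared with the panel and cancels under normalization;
dispersion → ∞ gives Poisson). Copy-number events are 12-bin (~6 Mb)
windows carrying a central 4-bin peak; each patient drops each altered
event with probability 0.1 (inter-patient heterogeneity). Cluster-3
nucleosome mixture weights are bimodal (half the patients shrunk to 0.35 of
their tumor fraction) to reproduce the reported heterogeneous cluster-3
footprint. Methylation couples to biology, not just tumor content:
cluster-1 tumor components draw region betas from U(0.15, 0.45) vs
U(0.5, 0.9) for CIN-high (mirroring the reported cluster-wise baseline
score differences and the MSI rationale), responders (p = 0.5) shift tumor
betas down by 0.15 on treatment, and the on-treatment tumor fraction
declines by a factor U(0.4, 0.9) drawn independently of response. Survival
is exponential with hazard multipliers 0.35 for CIN-high and 0.5 for
below-median methylation deltas over a 1/320 d⁻¹ baseline; censoring is a
Bernoulli(rate) uniform truncation so rates 0 and 1 behave exactly. All
draws descend from one seed, bit-for-bit reproducibly.

What the generator does **not** emulate: read-level sequences, GC-bias
inference, allele-specific signal, subclonality, batch effects, fragment
lengths, CpG-level methylation structure. Passing tests therefore show the
pipeline's estimators are correct and well-calibrated under the stated
mixture models — not that the biological effect sizes on real cohorts will
match.

## Known limitations

* The tumor-fraction grid fit is aliased for profiles whose aberrant
  segments all sit in {CN1, CN3}; the smallest-tf tie-break then halves the
  estimate. State-diverse profiles are immune; near-diploid samples remain
  the hard case, as with any purity estimator at this coverage.
* Score-delta analyses retain a residual dependence on tumor-content
  change: mixture deconvolution divides assay noise by tf and the forest
  probability saturates near 1, so added noise can only pull scores down,
  more strongly at lower tumor fraction. On the default cohort this yields
  a rank correlation of about −0.2 to −0.3 between the score delta and the
  tf change even though the beta-level inversion is exact — quantified
  honestly by `scripts/acceptance.py` and flagged by a failing test; at the
  ~40-patient scale of the motivating study the effect is below detection.
* The Cox implementation handles the covariate scales used here; it is not
  a general replacement for a production survival library (no stratified
  baselines, no time-varying effects, no robust variance).
* The CLI report pipeline reads the plasma/on-treatment tumor fractions for
  methylation normalization from the provided tables; off-target-read tf
  estimation is out of scope.
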