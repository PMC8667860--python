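# Methods

## Data model

A protein of length L is represented by its PSI-BLAST position-specific
scoring matrix: an L × 20 matrix of integer log-odds `p_{i,j}`
(dimensionless; positive values mean position i tolerates substitution by
amino acid j). The package fixes the native PSI-BLAST column order
`A R N D C Q E G H I L K M F P S T V W Y` as canonical and all feature
indices refer to it. Only the log-odds block of the ASCII dialect is
modelled; the weighted-percentage block and the information-content columns
are ignored on read and zero-filled on write, so write→parse is the
identity on the log-odds block. Parsed entries must be integers with
|value| ≤ 32 — anything larger is treated as a parse error rather than
biology. Rows labelled `X` (unknown residue) are kept: their scores are
defined, they count toward L in every 1/L normalisation, but they
contribute to no residue group in PSSM-COMPOSITION.

## Feature descriptors

All extractors are pure functions of the matrix and residue string and
operate on the raw integer log-odds by default. An optional element-wise
sigmoid `1/(1+e^{-x})` is available (`sigmoid=True`) for users who prefer
bounded inputs; it is off by default because the defining formulas operate
on `p_{i,j}` directly.

* **AAC-PSSM** (20-d): `x_j = (1/L) Σ_i p_{i,j}` — the evolutionary
  amino-acid composition. Invariant under row duplication.
* **DPC-PSSM** (400-d): `y_{i,j} = (1/(L−1)) Σ_k p_{k,i} p_{k+1,j}`,
  flattened row-major over (i, j). Requires L ≥ 2.
* **AADP-PSSM** (420-d): concatenation of the two, names prefixed
  `AAC:`/`DPC:`.
* **PSSM-COMPOSITION** (400-d): `c_{a,j} = (1/L) Σ_{i: res_i=a} p_{i,j}`,
  the 20 × 20 matrix flattened row-major (rows = residue type) and min-max
  scaled to [−1, 1] over the 400 entries: `v' = 2(v−min)/(max−min) − 1`,
  with all-equal inputs mapping to 0. The scaling is per sample —
  dataset-level scaling would leak test statistics into training. Min-max
  is the simplest map achieving the stated range; the scaled vector attains
  both endpoints whenever the entries are not all equal.
* **RPSSM** (110-d): columns are first reduced to a 10-letter alphabet.
  The default grouping `{FYW} {ML} {IV} {ATS} {NH} {QED} {RK} {C} {G} {P}`
  follows the classical 10-letter reduced alphabets built from substitution
  clusters; it is a constructor argument, not a constant. Reduction takes
  the **mean** of grouped columns (a sum would inflate multi-member
  groups; configurable). The descriptor is then 10 per-column population
  variances `D_s = (1/L) Σ_i (p̃_{i,s} − mean_i p̃_{i,s})²` followed by 100
  dipeptide terms `D_{s,t} = (1/(L−1)) Σ_i (p̃_{i,s} − p̃_{i+1,t})²/2`,
  (s, t) row-major. The dipeptide term uses the **difference** form — it
  measures how much consecutive positions disagree between reduced letters
  s and t, and is zero on a constant matrix, which the squared-sum variant
  is not; the sum form remains available (`difference=False`) for
  comparison with descriptor variants that define it that way. All 110
  values are non-negative by construction.
* **Fusion**: fixed block order AADP | COMPOSITION | RPSSM
  (420 + 400 + 110 = 930), independent of argument order. Feature names
  (`DPC:A>R`, `COMP:C|W`, `RPSSM:D[2,7]`) make the flattening auditable.

## MRMD feature selection

Relevance of feature i is `maxMR_i = |PCC(f_i, C)|` with the sample Pearson
correlation; a zero-variance feature has relevance 0 by convention rather
than NaN. Distance is the mean over the other M−1 features of three
pairwise measures — Euclidean distance, cosine similarity, Tanimoto
coefficient — computed exactly (O(M²N) via the Gram matrix; exact up to
M = 2,000, far above the 930 used here). Because ED is unbounded while
COS/TC lie in [−1, 1], the per-feature mean EDs are min-max normalised to
[0, 1] before averaging into `maxMD_i = (ED'_i + COS_i + TC_i)/3`;
otherwise the mean is dominated by ED's scale. The normalisation can be
disabled. Note `maxMD` is not guaranteed non-negative in pathological
cases (mean cosine similarity can be negative); it is validated against a
brute-force reference rather than clamped.

The combined score is `2(w·maxMR + (1−w)·maxMD)` with w = 0.5 by default,
i.e. the equally weighted sum — the original MRMD formulation. Ties break
by original feature index for stability. An alternative aggregation builds
a dominance graph (edge j→i whenever i outranks j under any of the four
constituent criteria) and ranks by PageRank with damping 0.85; both modes
are deterministic, and the graph construction is one documented
interpretation of "PageRank over the rankings" — the simple combined score
is the default.

Subset selection adds features one at a time in rank order and scores each
prefix by stratified k-fold (default 10) cross-validated accuracy with a
library-default forest (100 trees, unlimited depth, √M features per
split — the heavy 800-tree configuration is reserved for the final model);
`best_k` is the smallest prefix attaining the maximal mean accuracy.
Stratified folds are used because class proportions must survive the
split; folds are shuffled by the caller's seed, so the curve is
reproducible.

## Classifier and evaluation

The final model is a scikit-learn random forest with 800 trees, maximum
depth 50 and **all** features considered at each split, single-threaded
for determinism. (Configurations with unlimited depth are one flag away;
depth 50 is the default as the more specific of the two published
statements about tree size.) Prediction scores are the fraction of trees
voting positive; the label threshold is fixed at 0.5, with the full ROC
sweep always available.

Metrics follow the standard definitions: ACC = (TP+TN)/total,
SN = TP/(TP+FN), SP = TN/(TN+FP) (all ×100), and MCC with the usual
product-of-marginals denominator, returning 0 (flagged
`mcc_degenerate`) when any factor vanishes. ROC points come from a
descending-threshold sweep with tie grouping and the AUC from the
trapezoid rule, which equals the Mann-Whitney concordance probability with
ties half-weighted — the test suite asserts this against an O(n²) pairwise
oracle. Cross-validation pools out-of-fold predictions into a single
confusion matrix (a well-defined single report), and also retains per-fold
accuracies (mean ± sd in the JSON form).

## Synthetic data

The generator emulates the *structure* of PSI-BLAST profiles, not
DNA-binding biology: residues uniform over the 20 letters, length uniform
in a range (default 50–200, typical of globular domains), scores drawn
from a normal distribution (sd 3), rounded and clipped to the default
band −8..12 that matches the empirical spread of real log-odds profiles.
Positive-class samples receive a mean shift (`effect`, default 0) on a
fixed four-column subset (A, R, N, D), which makes the corresponding
AAC-PSSM features informative by construction and gives feature-ranking
tests a known ground truth; `effect=0` makes the classes exchangeable.
Everything derives from one `numpy` Generator seed, so datasets are
byte-identical across runs.

What passing tests on this generator do show: the pipeline recovers a
planted column-mean signal essentially perfectly (pooled 10-fold CV
accuracy ≥ 95% at effect 6 with 100+100 samples), ranks the planted
features in the top decile, and reports chance-level AUC on exchangeable
classes. What they do not show: performance on real proteins, where class
signal is distributed, correlated with phylogeny, and far weaker —
benchmark-level accuracy claims require the real curated datasets and a
full PSI-BLAST profile run, both outside this package's scope.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic datasets of
100+100 samples (lengths 50–200) for signal-recovery checks and a
200-tree, √M-features forest for cross-validation at that stage — the
selection-stage forest configuration, chosen so a full run completes in
well under a minute while leaving the planted-signal margins enormous
(observed CV accuracy 100% against the 95% bound). Oracle-agreement
checks use 200 random profiles/tables per computation at tolerance 1e-10.
Degenerate inputs are defined rather than left to NaN: Pearson of a
constant vector is 0, COS/TC of a zero vector are 0, MCC with a zero
factor is 0 (flagged), min-max scaling of a constant block maps to 0.
Ranking ties break by feature index; `best_k` ties break toward the
smaller subset.

## Known limitations

* Consumes pre-computed ASCII PSSMs only; no PSI-BLAST orchestration, no
  other profile formats.
* Binary labels only; no multiclass support.
* The PageRank aggregation graph is one interpretation among several
  possible; results with it are labelled accordingly in the ranking
  metadata.
* The incremental selection curve is O(M) forest fits; for the full 930
  features budget minutes, or truncate with `max_k`.
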