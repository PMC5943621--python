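# Methods

`kmersig` identifies *group-specific* sequences between two groups of shotgun
metagenomic samples — case and control — using long canonical k-mers as
features, without reference genomes, read alignment, or metagenome-wide
assembly.  This note records the model, the procedure, the synthetic
community the package tests itself against, and the numerical and design
choices a maintainer would want to know about.

## The feature model

For sample *j*, let f°ᵢ(j) be the number of occurrences of canonical k-mer
*i* across all reads of the sample (a k-mer and its reverse complement are
one object, stored as the lexicographic minimum of the pair; the canonical
space has (4ᵏ + 4^(k/2))/2 classes for even k and 4ᵏ/2 for odd k).  The
**numerical feature** is the within-sample relative frequency
fᵢ(j) = f°ᵢ(j) / Σᵢ f°ᵢ(j), which corrects for sequencing depth.  The
**logical feature** is its presence indicator, 1 iff fᵢ(j) > 0.

k-mers occurring only once in a sample are discarded at count time
(`min_count = 2`): at k ≈ 30–40 singletons are dominated by sequencing
errors and make presence features unstable.  The normalization denominator
is therefore the post-singleton-removal total; this is a constant-factor
approximation of the all-k-mer total, and since every feature within a
sample is scaled identically it does not affect presence, rank statistics,
or any downstream selection.

The per-sample vectors from the training samples are merged into a sparse
m × N matrix (rows in lexicographic k-mer order).  A row is dropped as
**highly sparse** when the k-mer is absent in *more than* a fraction
`sparsity` (default 0.8) of the control samples *and* of the case samples.
The strict inequality is evaluated in exact rational arithmetic
(`Fraction(str(sparsity))`) so ties such as 8 > 0.8·10 are never decided by
floating-point rounding.  Column normalization is not recomputed after row
filtering.

## Feature selection

Selection uses training samples only.  Two tracks:

**Logical track.**  Each k-mer's presence pattern is itself a classifier:
either presence predicts case, or presence predicts control.  Its score is
the ASS — the average of sensitivity and specificity — maximized over the
two orientations, so ASS ∈ [0.5, 1] and the score is symmetric under
relabeling.  K-mers with ASS ≥ θ₁ (default 0.8) are group-specific.  A
Pearson χ² test on the 2×2 presence-by-group table (1 df, no continuity
correction; degenerate tables give p = 1) is offered as an alternative
ranking; it cuts the ranked list at the same size as the ASS cut.  The two
rankings are strongly concordant (the acceptance suite measures top-400
overlap on a 10,000-feature simulated matrix).

**Numerical track.**  Among rows not selected logically, the two-sided
Wilcoxon rank-sum test keeps rows with p ≤ θ₂ (default 0.01; the relaxed
preset uses 0.05).  When both group sizes are ≤ 10 and the row is tie-free,
the exact U null distribution is used (computed once per group-size pair by
the standard counting recurrence and cached); otherwise the normal
approximation with tie correction and continuity correction.  Each survivor
is then fitted with a one-covariate logistic regression (intercept +
frequency) by vectorized Newton iterations; a row that fails to converge —
complete separation — is refitted with a small ridge penalty (1e-4, slope
only), so perfectly separating rows return ASS = 1 rather than erroring.
The predictor calls case when the fitted probability ≥ 0.5, its ASS is
computed in-sample on the training samples, and rows with ASS ≥ θ₃
(default 0.8) are selected.

Within each track the output is sorted by descending training ASS with ties
broken lexicographically by k-mer, making selection fully deterministic.

## Multi-feature prediction

Selected features are often redundant (adjacent k-mers from one locus share
a presence pattern).  A greedy pass in descending-ASS order keeps a feature
iff its |Pearson correlation| with every already-kept feature is ≤
`pcc_max` (default 0.75); of a correlated pair the higher-ASS member
survives — a deterministic refinement of discarding one member at random.
Zero-variance rows are defined to correlate 0 with everything.  An optional
cap (`max_decorrelation_candidates`, default 5000) bounds the quadratic
pass at very large selections.

Survivors are ranked by classic bagged-forest permutation importance: each
of `n_trees` (default 500) decision trees is fitted on a bootstrap sample,
and the mean decrease in out-of-bag accuracy when one feature is permuted
among the OOB rows is averaged over trees.  This OOB-permutation form is
implemented in the package (scikit-learn's `permutation_importance` is not
OOB-based); the trees themselves and the final random-forest classifier
over the top `top_n` features (default 10; 15 suits smaller-cohort
settings) come from scikit-learn.  AUC is the Mann-Whitney statistic
normalized by n_case·n_control with half credit for ties.

The cross-validation harness runs `runs` independent repetitions (default
20) of stratified `folds`-fold CV (default 10).  Matrix construction, the
sparsity filter, both selection tracks, decorrelation, importance ranking
and forest training all see only the fold's training samples; held-out
columns are projected onto the selected rows afterwards (a k-mer absent
from a projected sample is 0).  Fold ROC curves are vertically averaged on
a 101-point FPR grid per run; the aggregate is the mean over runs with a
t-based 95% CI.  All stochastic steps expand one pipeline seed through a
counter-based `SeedSequence` scheme, so a rerun with the same seed is
byte-identical.

## Assembly of group-specific sequences

Selected k-mers of a track are assembled into longer marker sequences with
an exact-overlap unitig assembler: nodes are canonical k-mers, edges are
exact (k−1)-base overlaps considered in both orientations, and maximal
unambiguous paths are emitted.  Branching nodes terminate contigs — no
path-resolution heuristics, hence no chimeras — and every window of every
contig is by construction an input k-mer.  Selected k-mers are exact,
error-filtered sequences, so mismatch-tolerant overlap alignment (as in
general-purpose assemblers built for reads) adds nothing here; note also
that such assemblers' default minimum-overlap settings cannot join k-mers
at these lengths at all.  Contigs shorter than `min_contig_len` (default
200 bp) are discarded.  Output is deterministic: traversal starts from
lexicographically sorted k-mers, each contig is reported in canonical
orientation (min of sequence and reverse complement), sorted by descending
length then sequence.

## The synthetic community

The simulator generates the study conditions every end-to-end test runs
under.  A community of eleven genomes mirrors a human-gut-like design:

* eight **background** genomes with identical central relative abundances
  in both groups (7, 16, 10, 10, 10, 8, 6, 6%);
* one **shared-common** strain at 18% in both groups;
* one **case-only** strain (6% in cases, absent from controls) built by
  copying the shared-common strain and replacing 10 blocks totalling
  1 − `shared_fraction` (default 13%) of its length with novel uniform
  DNA — the replaced blocks are the exact case-specific truth regions;
* one **differential** genome at 9% in controls whose case-group value is
  solved in closed form so the normalized control:case ratio equals the
  configured fold change exactly (3× by default, giving 3% in cases).

Per-sample abundances add half-normal noise |N(0, σ)| with σ equal to each
genome's central abundance, then renormalize to a valid composition
(renormalization is required for the draws to be relative abundances at
all; absent genomes stay exactly 0).  Reads (fixed length, default 100 bp)
pick a genome with probability proportional to abundance × genome length —
abundances are cell proportions, so longer genomes contribute
proportionally more reads — with uniform start, uniform strand, and
optional i.i.d. substitution errors (0 by default).

The default scale is 15+15 samples, 50 kb genomes and 200,000 reads per
sample, i.e. ≈ 24× depth for the rarest genome, with k = 31; leakage and
CV checks use a further-scaled community (3 kb genomes, 10,000 reads,
10+10 samples, ≈ 20× depth) so repeated per-fold selection stays fast.
These sizes were chosen so that every canonical k-mer of the case-specific
regions is observed in every case sample with overwhelming probability
(the uncovered-window probability at effective depth ~17× is e⁻¹⁷ per
position), which is exactly the regime the logical track targets.

What the simulation does *not* emulate: sequencer error profiles and
quality scores, paired-end inserts, GC bias, real inter-genome homology
(backgrounds are i.i.d. uniform DNA, so cross-genome k-mer collisions are
essentially absent at k = 31), strain mixtures beyond the single
shared/case-only pair, and compositional batch effects.  Passing tests
therefore demonstrate the machinery — counting, selection, assembly,
no-leakage CV — under clean, fully-known truth; they do not establish
robustness to error-rich or highly homologous real data.

## Evaluation against truth

A selected k-mer *matches* a truth category when it (or its reverse
complement) occurs fully inside one of the category's regions (strict
containment; an "any overlap" mode exists).  Precision is the matched
fraction of the selection; recall is the fraction of category-region
positions covered by at least one occurrence of any selected k-mer.  For
the logical track, precision is reported at strain level — against the
whole case-only genome — because a selected k-mer straddling a
replaced-block boundary is genuinely case-specific sequence even though it
is not contained in a single block; recall is measured on the replaced
blocks proper.  For the numerical track, precision is measured against the
union of the differential genome and the common (shared) regions — both
are differentially abundant between groups, the former by design and the
latter because cases carry two copies of the shared sequence — and recall
against the differential genome.

Contig coverage is exact-substring pseudo-alignment: a read (or its
reverse complement) fully contained in a contig adds 1 to the positions it
spans; depth is normalized by (reads/10⁶) and displayed as log(1+x), with
controls above cases in the exported matrix.  Simulated reads are
error-free by default, so alignment-with-mismatches would change nothing
here.

## Numerical and design notes

* **Orientation of the single-logical predictor**: both orientations are
  evaluated and the max is kept, making ASS label-symmetric.
* **Logistic ASS** is in-sample on the training set; the probability
  cutoff is fixed at 0.5.
* **χ² without continuity correction**; degenerate 2×2 tables give p = 1.
* **No multiple-testing correction** on Wilcoxon p-values: selection is
  validated by held-out prediction, not by FDR claims.
* **Counting** runs on a 2-bit rolling encoder (one uint64 per window,
  k ≤ 32, compiled with numba; windows containing non-ACGT characters are
  skipped, not substituted — matching standard k-mer counters and
  inventing no sequence) with a pure-Python fallback for longer k.
  Results are independent of read batching/partitioning; a property test
  asserts equality with a brute-force oracle.
* **Paired-end files** are treated as extra reads of the same sample.
* **Config** holds every threshold exactly once; presets `strict`
  (θ₁ = θ₃ = 0.8, θ₂ = 0.01) and `relaxed` (θ₁ = θ₃ = 0.75, θ₂ = 0.05)
  cover simple and complex phenotype-microbiome associations.  k defaults
  to 40 with a documented validity band of 30–40 (long enough to be
  genome-specific, short enough for read-length and depth constraints);
  the bundled simulations use k = 31 so codes fit one machine word.
* **Count caching** is content-addressed (path, size, mtime, k,
  min_count); rerunning a count stage with unchanged inputs is a no-op.

## Known limitations

* The numerical track inherits compositionality: a genuinely differential
  genome shifts every other frequency in the opposite direction, so very
  deep designs can select weak "shadow" features from unchanged genomes.
  The decorrelation pass removes most of these (they are correlated with
  the primary signal), but no compositional transform (e.g. CLR) is
  applied — by design, matching the plain-frequency feature definition.
* In-sample logistic ASS on very small training folds (≤ 6 per group) can
  reach 1.0 by chance; thresholds were tuned for cohort-scale designs.
* The assembler emits unitigs only; repeats within the selected k-mer set
  fragment contigs rather than risk chimeras.
* Exact-match evaluation and pseudo-alignment assume error-free selected
  k-mers and simulated reads; with `err_rate > 0` coverage is
  underestimated.
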