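# Methods

## Setting

Two species are profiled on species-specific microarray platforms, each
producing a probesets × samples matrix of RMA-style log2 intensities over
a large, heterogeneous compendium of tissues, conditions and labs.  The
analysis asks whether orthologous genes keep their global expression
behavior across species: do samples cluster by tissue rather than
species, do orthologs keep their transcriptome-wide co-expression
neighborhoods (corCor), and do the most- and least-variable genes of a
tissue coincide through orthology (tissue-specific and housekeeping
programs)?

Everything upstream of the expression matrix — CEL parsing, RMA
summarization, QC-metric computation, ortholog retrieval — is out of
scope; the package consumes matrices, annotation tables, an ortholog
table, probe sequences and a QC metrics table.

## Array QC

An array passes iff all six metrics fall in their acceptance windows.
All bounds are inclusive except the RNA-degradation slope, which is a
strict one-sided `< 1.7`; the remaining ranges are read inclusively
("20 to 150" taken literally), and every bound is configurable.  The report
lists every violated criterion per array, and pass ∪ fail partitions the
input exactly.

## Probeset pairing

Probes (25-mers) of every candidate probeset of gene A are aligned
against those of its ortholog's probesets.  Scoring is the legacy
nucleotide-BLAST default: match +1, mismatch −3, affine gaps costing
5 + 2k for length k.  A hit is reported only if the two probes share an
exact 7-mer on the given strands (the word-seeding requirement of a
word size 7 search); otherwise the score is 0 even when the full dynamic
program would be positive.  The implementation delegates the dynamic
program to Biopython's `PairwiseAligner`; the test suite checks it
against an independent hand-rolled Gotoh DP on a thousand random probe
pairs.

Per probeset combination, probe matches are reduced to a one-to-one set
*greedily* by descending score (ties by probe id) — "best one-to-one
match" read as common practice rather than optimal assignment; a
Hungarian-assignment mode exists behind `optimal_assignment=True` for
sensitivity analysis.  The combination with the most retained matches
wins; ties break by total score, then lexicographic probeset ids.  Gene
pairs with no scoring combination are flagged unpairable and excluded
downstream.  The ortholog table must be one-to-one (duplicated gene ids
are rejected rather than silently reduced).

Strand handling: probes are aligned as given.  Platform probes are
strand-consistent, so no reverse-complement search is done by default.

## Normalization and merging

`x' = (x − median) / MAD` row-wise (by probeset) or column-wise (by
sample).  The MAD is unscaled — no 1.4826 consistency factor — because
the procedure is a rank-robust standardization, not a normal-σ estimate;
even-length medians are the mean of the central order statistics.
Vectors with MAD = 0 are set to zero and flagged (dropping them would
break row alignment across species).  A `scale_tag` on the matrix makes
re-normalization an error instead of a silent double transform.  Merging
concatenates sample columns of paired probesets bit-for-bit; rows are
keyed `probeset_a|probeset_b`.

Tissue balancing (removal of categories dominated by one species, e.g.
mammary gland or hematopoietic samples) is an annotation-driven column
filter: an explicit drop-list by default, with an optional cross-species
count-ratio rule — this kind of sample-balance curation is inherently
manual, so the drop-list is the honest default.

## Global structure

PCA treats samples as observations: the merged matrix is transposed,
variables are mean-centered and not rescaled (`prcomp` defaults), and
variance fractions are relative to total variance.  Loading signs are
fixed (largest-magnitude entry positive) so results are reproducible.
Tissue-versus-species clustering is usually judged visually from
scatter plots; the package quantifies it with silhouette scores on the first k
score dimensions (Euclidean; groups with < 2 samples excluded).  The
expected phenomenology, which the tests assert on synthetic data: under
by-probeset normalization tissues dominate (per-probeset species offsets
are removed within species), under by-sample normalization the
platform/species split owns the first component.

The tissue×species structure is a matrix of mean pairwise Pearson
correlations between all (species, tissue) sample groups; within-group
entries exclude self-pairs (a sample's correlation with itself would
inflate diagonals).  The matrix rows are clustered with Euclidean
distance and complete linkage (the defaults of the usual heatmap
tooling), giving the side-by-side same-tissue cross-species leaves when
conservation is present.

## corCor

Inner stage: Spearman (average ranks for ties), each gene against the
n−1 other paired genes on its own platform, profiles ordered identically
under the pairing.  Outer stage: Pearson between the two profiles
(Spearman available via flag); the choice is genuinely open, and Pearson
matches the integrative-correlation tradition the statistic comes from.  Constant expression rows get
zeroed correlations and a flag; a zero-variance profile yields NaN
("undefined"), never 0.  Exceedance counts use strict `>`.

The all-pairs computation rank-transforms each matrix once and uses
standardized matrix products — O(n²s) overall — so thousands of pairs
are desk-scale.

Null model: each row's values shuffled independently across samples
(destroys gene–gene structure, preserves per-gene marginals); a global
pooled shuffle is also available, since matrix randomization admits both
readings.  Under the null, corCor has sd ≈ 1/√(n−1), so with
n ≥ 1000 pairs an exceedance threshold of 0.1 sits beyond 3σ and under
1% of pairs cross it — the test suite checks exactly this.

## Variance windows and list overlap

Per tissue and species, genes are ranked by sample variance (ddof 1) over
that tissue's samples, by default on by-probeset-normalized values (the
scale the merged pipeline works on); ties break by gene id.  Windows are
non-overlapping consecutive blocks from the most variable end; the
remainder (n mod window) is dropped from windowed plots but kept in
top-fraction lists, where "top 10%" means ⌈0.1·n⌉ genes.  Shared
fractions are computed in both directions; with a one-to-one pairing
over a common universe they are identical, which the code asserts.  The
randomized baseline draws independent uniform rankings per species;
its expected shared fraction is window/n (≈ 9.7% for 600 of 6,180,
i.e. the ~10% negative control).

The overlap of two conserved-gene lists (sizes K and n) from a common
universe of N genes with observed overlap k is tested with the exact
hypergeometric upper tail P(X ≥ k) — "at least k overlaps" semantics —
accumulated in log space (log-gamma binomials + logsumexp) so p-values
of 1e−8 and below are exact to printed precision.  The universe size is
an explicit parameter: in cross-study comparisons it is the intersection
of the two studies' gene sets, not either study's full complement.

## Synthetic data generator

The generator emits everything the pipeline consumes, with ground truth:

- **Universe** — n one-to-one ortholog pairs; each gene has one probeset
  per species (a configurable fraction get two, to exercise the pairing
  choice).  The orthologous probeset pair carries species-B probes that
  are species-A probes with i.i.d. substitutions at `probe_divergence`
  (no indels, keeping the Hamming-based truth exact); alternative
  probesets are unrelated random sequences, as alternative probesets
  target different transcript regions.  The recorded true pair is
  recomputed from the emitted sequences as the minimum-divergence
  combination.
- **Expression** — log2-scale signal
  `x = μ_g + specific + batch + species_offset + ε` with μ_g ~ N(8, 1)
  shared across species.  A tissue-specific gene is shifted in its home
  tissue by `effect_size · N(1, activation_cv)` per sample in both
  species: the mean shift is `effect_size` (default 2 log2 units), and
  the activation spread (default cv 1.5) makes planted genes the most
  variable within their own tissue, emulating compendia that mix
  conditions under which the gene is or is not induced.  Housekeeping
  genes draw residuals at `noise_sd/2` (a quarter of baseline variance).
  Samples group into experiments of five with N(0, batch_sd) offsets per
  50-gene block (lab effects); species B gets a per-probeset
  N(0, species_shift_sd) offset (residual platform difference, the
  source of the species split under by-sample normalization).
- **QC table** — exactly `round(fail_fraction·n)` arrays violate one to
  three metric ranges; the rest sit strictly inside all of them.

Defaults: 300 genes, 13 tissue categories, 10 samples/tissue/species,
10 specific genes per tissue, 30 housekeeping, noise 1.0, batch 0.5,
species shift 1.0, 11 probes of 25 nt per probeset, 5% probe divergence.
All randomness flows from one seeded generator per call; identical
(design, seed) reproduce byte-identical artifacts.

What the generator does *not* emulate: probe-level intensities and RMA
itself, probe GC/affinity biases, correlated (non-block) batch
structure, many-to-many orthology, tissue-composition gradients, and
dataset sizes in the thousands of arrays.  Passing tests therefore
demonstrate correctness and recoverability of the *methods* under a
known conserved-signal model at desk scale — not the published
compendium-scale effect sizes (e.g. specific exceedance counts or the
42%/27% shared fractions), which depend on the real data.

## Problem sizes and numerics

The statistical tests run at 300 genes × 6 tissues × 10 samples per
tissue per species (the pipeline example scale), with 20 planted
specific genes per tissue so that, as in real tissue compendia,
tissue-specific programs make up the bulk of the most-variable genes;
pairing-recovery tests use 50-gene universes over 5 seeds; the corCor
null check uses 1,000 pairs × 102 samples per species.  Normalized-axis
medians are checked to 1e−12; PCA against an eigensolve to 1e−8; corCor
against a nested-loop oracle to 1e−10; the hypergeometric tail against
exact integer arithmetic to 1e−12 for every universe N ≤ 25.

Known limitations: the greedy one-to-one probe matching is order-exact
but not globally optimal (the assignment mode is); silhouette is one of
several possible co-clustering statistics; the tissue-balancing rule is
a stand-in for a manual curation step; corCor within single homogeneous
tissues is expected to be weak (platform and lab effects dominate), and
the package makes no claim there.
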