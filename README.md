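# xspecies

Cross-species comparison of global gene-expression patterns from
species-specific microarray platforms — the kind of analysis that asks
whether human and mouse orthologs occupy similar positions in their
species' transcriptomes, using large heterogeneous sample compendia rather
than matched experiments.

The package is aimed at computational biologists who want the full
analysis chain as reusable, tested components:

1. **Array QC** (`xspecies.qc`) — filter arrays on precomputed quality
   metrics (AvgBg 20–150, PP 25–65%, RNAdeg < 1.7, sfs 0.1–2.5,
   nuse 0.97–1.05, rle ±0.15).
2. **Ortholog probeset pairing** (`xspecies.pairing`) — for each
   orthologous gene pair, align every probe of every candidate probeset
   across species (Smith–Waterman, match +1 / mismatch −3, affine gaps
   5 + 2k, a shared exact 7-mer required to seed), reduce to one-to-one
   top probe matches, and pick the probeset combination with the most
   matches.
3. **Normalization and merging** (`xspecies.normalize`) — robust
   centering/scaling by probeset or by sample,
   `x' = (x − median) / MAD`, then merging the two species' matrices on
   the probeset pairing.
4. **Global structure** (`xspecies.global_patterns`) — PCA of the merged
   matrix (samples as observations), silhouette summaries of
   tissue-versus-species clustering, the tissue×species mean-Pearson
   correlation matrix, and its complete-linkage dendrogram.
5. **corCor** (`xspecies.corcor`) — for an ortholog pair (A, A′), the
   correlation of correlation coefficients: Spearman-correlate each gene
   with all n−1 other paired genes on its own platform, then correlate the
   two profiles, `corCor = cor(v(A), v(A′))`. Includes a shuffled-matrix
   null with threshold-exceedance counts.
6. **Variance-window sharing** (`xspecies.varshare`) — rank genes by
   within-tissue variance per species, count orthologs shared between
   corresponding windows (tissue-specific programs at the variable end,
   housekeeping at the stable end), against a randomized-ranking baseline
   (expected sharing ≈ window/n). Plus the exact hypergeometric upper-tail
   test `P(X ≥ k)` for the overlap of two gene lists from a common
   universe.
7. **Synthetic data** (`xspecies.synthgen`) — a generator that emulates
   the whole setting (diverged 25-mer probes, planted conserved
   tissue-specific and housekeeping programs, batch effects, a
   species/platform shift) with recorded ground truth, so every stage is
   testable without downloads.
8. **Pipeline** (`xspecies.pipeline` / the `xspecies` CLI) — YAML-driven
   orchestration with a checksummed run manifest.

## Worked example

```python
import numpy as np
from xspecies.synthgen import SynthDesign, generate_universe, generate_expression
from xspecies.pairing import build_pairing_map
from xspecies import normalize as nm
from xspecies.global_patterns import pca, cluster_separation
from xspecies.corcor import corcor_all, count_exceeding
from xspecies.varshare import hypergeom_overlap_test

design = SynthDesign(
    n_genes=120, tissues=("nervous_system", "muscle_heart", "liver"),
    samples_per_tissue_per_species=8, n_specific_per_tissue=15,
    n_housekeeping=12, probe_divergence=0.05, seed=7,
)
universe = generate_universe(design)
pairing, unpairable = build_pairing_map(
    universe.ortholog_table, universe.probesets_a, universe.probesets_b
)

m_a, m_b, annot_a, annot_b = generate_expression(design, universe.truth)
na = nm.normalize_by_probeset(m_a).matrix
nb = nm.normalize_by_probeset(m_b).matrix
merged = nm.merge_matrices(na, nb, pairing, annot_a, annot_b)

result = pca(merged, n_components=3)
_, sil_tissue = cluster_separation(result.scores, merged.annotation, "tissue", k=3)
_, sil_species = cluster_separation(result.scores, merged.annotation, "species", k=3)
cc = corcor_all(na, nb, pairing)
count, _ = count_exceeding(cc, 0.1)
t = hypergeom_overlap_test(1344, 51, 79, 13)
```

prints (via the obvious `print` statements):

```
paired 120 of 120 ortholog pairs (0 unpairable)
merged matrix: 120 probeset pairs x 48 samples
variance fractions (PC1-3): [0.116 0.077 0.068]
silhouette by tissue: 0.329, by species: 0.010
mean corCor 0.060; 44 of 120 pairs exceed 0.1
overlap test: P(X >= 13) = 2.9e-06
```

Reading the numbers: probe alignment recovered a probeset pair for every
ortholog at 5% sequence divergence.  After by-probeset normalization the
samples cluster by tissue, not by species (silhouette 0.33 vs 0.01) — the
planted tissue programs are conserved, and per-probeset normalization has
removed the platform offset.  corCor is shifted well above zero (a null of
this size has sd ≈ 1/√119 ≈ 0.09 around 0), showing that orthologs keep
their co-expression neighborhoods across the two synthetic species.  The
overlap test shows the chance of 13 shared genes between lists of 51 and
79 drawn from a 1,344-gene universe is ~3 in a million.

The same chain runs from the shell:

```sh
xspecies run --config run.yaml --outdir out/   # stage-by-stage outputs + manifest.json
xspecies overlaptest --universe 1344 --k1 51 --k2 79 --overlap 13
```

## Layout

```
src/xspecies/      library modules (synthgen, qc, pairing, normalize,
                   global_patterns, corcor, varshare, pipeline, cli)
tests/             pytest suite with independent oracles
docs/methods.md    model and design notes
scripts/           acceptance script
```
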