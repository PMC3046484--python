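"""Synthetic two-species expression datasets with known ground truth.

The generator emulates the structure of a two-platform microarray compendium:
a set of one-to-one orthologous gene pairs, each measured by one or more
probesets of short (25-mer) probes whose sequences have diverged between the
species; per-sample log2 intensities with planted tissue-specific and
housekeeping signatures shared by both species; additive experiment-batch
effects; and a per-probeset species/platform offset that systematically
displaces one species' profiles.  A :class:`GroundTruth` records every
planted feature so downstream stages can be scored against it.

Nothing at the raw-probe-intensity level is simulated: matrices are emitted
directly on the log2 scale that RMA-style summarization would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xspecies.containers import ExpressionMatrix
from xspecies.qc import DEFAULT_THRESHOLDS, QC_METRICS

_BASES = np.array(list("ACGT"))

#: Thirteen generalized tissue categories well represented in both species.
DEFAULT_TISSUES = (
    "nervous_system",
    "muscle_heart",
    "liver",
    "cell_line",
    "immune_system",
    "reproductive_system",
    "bone",
    "endocrine",
    "skin",
    "gastrointestinal",
    "adipose",
    "kidney",
    "lung",
)


@dataclass(frozen=True)
class SynthDesign:
    """Parameters of a synthetic two-species study.

    Parameters
    ----------
    n_genes:
        Number of orthologous gene pairs.
    tissues:
        Tissue-category names shared by both species.
    samples_per_tissue_per_species:
        Samples generated per tissue in each species.
    n_specific_per_tissue:
        Planted tissue-specific genes per tissue (conserved in both species).
    n_housekeeping:
        Planted low-variance genes.
    effect_size:
        Mean log2 up-shift of a tissue-specific gene in its home tissue.
    noise_sd:
        Residual per-sample standard deviation (log2 units).
    batch_sd:
        Standard deviation of additive per-experiment, per-gene-block offsets.
    species_shift_sd:
        Standard deviation of the per-probeset offset applied to species B,
        emulating residual platform differences.
    probe_len, probes_per_probeset:
        Probe geometry (25-mers, 11 probes per probeset, Affymetrix-like).
    probe_divergence:
        Per-base substitution probability between orthologous probes.
    multi_probeset_fraction:
        Fraction of genes measured by two probesets per species, exercising
        the probeset-pairing choice.
    activation_cv:
        Per-sample spread of the tissue-specific activation (the shift for a
        specific gene in its tissue is ``effect_size * N(1, activation_cv)``),
        giving planted genes elevated within-tissue variance.
    seed:
        Root seed; every generator call derives its own stream from it.
    """

    n_genes: int = 300
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    samples_per_tissue_per_species: int = 10
    n_specific_per_tissue: int = 10
    n_housekeeping: int = 30
    effect_size: float = 2.0
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    species_shift_sd: float = 1.0
    probe_len: int = 25
    probes_per_probeset: int = 11
    probe_divergence: float = 0.05
    multi_probeset_fraction: float = 0.2
    activation_cv: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "samples_per_tissue_per_species": self.samples_per_tissue_per_species,
            "n_specific_per_tissue": self.n_specific_per_tissue,
            "n_housekeeping": self.n_housekeeping,
            "probe_len": self.probe_len,
            "probes_per_probeset": self.probes_per_probeset,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not self.tissues:
            raise ValueError("tissues must be non-empty")
        planted = self.n_specific_per_tissue * len(self.tissues) + self.n_housekeeping
        if planted > self.n_genes:
            raise ValueError(
                "n_specific_per_tissue x |tissues| + n_housekeeping "
                f"({planted}) exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.probe_divergence <= 1.0:
            raise ValueError(
                f"probe_divergence must be in [0, 1], got {self.probe_divergence}"
            )
        if not 0.0 <= self.multi_probeset_fraction <= 1.0:
            raise ValueError("multi_probeset_fraction must be in [0, 1]")


@dataclass
class ProbesetRecord:
    probeset_id: str
    gene_id: str
    probes: list[str]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic universe.

    ``specific_genes`` / ``housekeeping_genes`` / ``ortholog_map`` are keyed
    by species-A gene ids; ``probeset_gene_a`` / ``_b`` map every emitted
    probeset to its gene so expression can be laid out per probeset row.
    """

    specific_genes: dict[str, set[str]]
    housekeeping_genes: set[str]
    ortholog_map: list[tuple[str, str]]
    true_probeset_pairs: dict[tuple[str, str], tuple[str, str]]
    probeset_gene_a: dict[str, str]
    probeset_gene_b: dict[str, str]
    design: SynthDesign = field(repr=False)


@dataclass
class SynthUniverse:
    """Ortholog table, per-species probe records and the ground truth."""

    ortholog_table: pd.DataFrame
    probesets_a: dict[str, ProbesetRecord]
    probesets_b: dict[str, ProbesetRecord]
    truth: GroundTruth


def _random_probe(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``.

    A substitution always changes the base (drawn from the three others), so
    the realized Hamming divergence equals the number of hits.
    """
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    for i in np.nonzero(hits)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def probeset_divergence(rec_a: ProbesetRecord, rec_b: ProbesetRecord) -> float:
    """Mean per-base Hamming divergence between index-matched probes."""
    if len(rec_a.probes) != len(rec_b.probes):
        raise ValueError("probe counts differ")
    total = mismatches = 0
    for pa, pb in zip(rec_a.probes, rec_b.probes):
        if len(pa) != len(pb):
            raise ValueError("probe lengths differ")
        total += len(pa)
        mismatches += sum(x != y for x, y in zip(pa, pb))
    return mismatches / total


def generate_universe(design: SynthDesign) -> SynthUniverse:
    """Create the gene/probeset universe for a design.

    Every gene gets at least one probeset per species; a
    ``multi_probeset_fraction`` of genes get two per species.  The first
    species-B probeset carries species-A probes mutated at
    ``probe_divergence``; all other probesets are unrelated random
    sequences, so exactly one low-divergence combination exists per gene
    and the intended pairing is the minimum-divergence one.
    ``true_probeset_pairs`` is recomputed from the emitted sequences by
    direct Hamming count, not assumed from the construction.
    """
    rng = np.random.default_rng([design.seed, 1])
    n = design.n_genes
    genes_a = [f"gA{i:05d}" for i in range(n)]
    genes_b = [f"gB{i:05d}" for i in range(n)]

    n_multi = int(round(design.multi_probeset_fraction * n))
    multi = set(rng.choice(n, size=n_multi, replace=False).tolist()) if n_multi else set()

    probesets_a: dict[str, ProbesetRecord] = {}
    probesets_b: dict[str, ProbesetRecord] = {}
    true_pairs: dict[tuple[str, str], tuple[str, str]] = {}
    for i in range(n):
        k = 2 if i in multi else 1
        recs_a, recs_b = [], []
        for j in range(k):
            probes_a = [
                _random_probe(rng, design.probe_len)
                for _ in range(design.probes_per_probeset)
            ]
            if j == 0:
                # the orthologous probeset pair: diverged copies
                probes_b = [_mutate(rng, p, design.probe_divergence) for p in probes_a]
            else:
                # alternative probesets target other transcript regions, so
                # their sequences are unrelated across species
                probes_b = [
                    _random_probe(rng, design.probe_len)
                    for _ in range(design.probes_per_probeset)
                ]
            recs_a.append(ProbesetRecord(f"pA{i:05d}.{j}", genes_a[i], probes_a))
            recs_b.append(ProbesetRecord(f"pB{i:05d}.{j}", genes_b[i], probes_b))
        for rec in recs_a:
            probesets_a[rec.probeset_id] = rec
        for rec in recs_b:
            probesets_b[rec.probeset_id] = rec
        best = min(
            (
                (probeset_divergence(ra, rb), ra.probeset_id, rb.probeset_id)
                for ra in recs_a
                for rb in recs_b
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        true_pairs[(genes_a[i], genes_b[i])] = (best[1], best[2])

    # plant tissue-specific and housekeeping genes on a random disjoint subset
    order = rng.permutation(n)
    specific: dict[str, set[str]] = {}
    pos = 0
    for t in design.tissues:
        specific[t] = {genes_a[order[pos + j]] for j in range(design.n_specific_per_tissue)}
        pos += design.n_specific_per_tissue
    housekeeping = {genes_a[order[pos + j]] for j in range(design.n_housekeeping)}

    truth = GroundTruth(
        specific_genes=specific,
        housekeeping_genes=housekeeping,
        ortholog_map=list(zip(genes_a, genes_b)),
        true_probeset_pairs=true_pairs,
        probeset_gene_a={p: r.gene_id for p, r in probesets_a.items()},
        probeset_gene_b={p: r.gene_id for p, r in probesets_b.items()},
        design=design,
    )
    ortholog_table = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    return SynthUniverse(ortholog_table, probesets_a, probesets_b, truth)


def generate_expression(
    design: SynthDesign, truth: GroundTruth
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Emit per-species expression matrices and sample annotations.

    The signal model, entirely on the log2 scale::

        x = mu_g + specific(g, tissue, sample) + batch(experiment, block)
            + species_offset(probeset) [species B only] + eps

    Baseline means ``mu_g ~ N(8, 1)`` are shared by both species.  A
    tissue-specific gene is shifted in its home tissue by
    ``effect_size * N(1, activation_cv)`` per sample — the mean shift equals
    ``effect_size`` while the activation spread makes planted genes the most
    variable within their own tissue, in both species (conserved signal).
    Housekeeping genes draw their residual at ``noise_sd / 2`` (variance a
    quarter of baseline); all other genes at ``noise_sd``.  Samples within a
    tissue are grouped into experiments of five, each with an additive
    ``N(0, batch_sd)`` offset per 50-gene block.

    Returns ``(matrix_a, matrix_b, annot_a, annot_b)``.
    """
    if truth.design != design:
        raise ValueError("GroundTruth was generated under a different design")
    rng = np.random.default_rng([design.seed, 2])
    n = design.n_genes
    tissues = list(design.tissues)
    spt = design.samples_per_tissue_per_species
    genes_a = [ga for ga, _ in truth.ortholog_map]
    gene_index = {g: i for i, g in enumerate(genes_a)}

    mu = rng.normal(8.0, 1.0, size=n)
    noise_scale = np.full(n, design.noise_sd)
    for g in truth.housekeeping_genes:
        noise_scale[gene_index[g]] = design.noise_sd / 2.0
    spec_tissue = np.full(n, -1)
    for ti, t in enumerate(tissues):
        for g in truth.specific_genes[t]:
            spec_tissue[gene_index[g]] = ti

    block = np.arange(n) // 50  # gene blocks for batch effects
    n_blocks = int(block.max()) + 1

    results = {}
    for species, tag in (("A", "A"), ("B", "B")):
        sample_ids, tissue_names, exp_ids = [], [], []
        tissue_idx = []
        for ti, t in enumerate(tissues):
            for k in range(spt):
                sample_ids.append(f"s{tag}_{t}_{k:03d}")
                tissue_names.append(t)
                tissue_idx.append(ti)
                exp_ids.append(f"E{tag}_{t}_{k // 5}")
        n_samples = len(sample_ids)
        tissue_idx = np.array(tissue_idx)

        experiments = sorted(set(exp_ids))
        exp_pos = {e: i for i, e in enumerate(experiments)}
        exp_idx = np.array([exp_pos[e] for e in exp_ids])
        batch = rng.normal(0.0, design.batch_sd, size=(len(experiments), n_blocks))

        signal = np.tile(mu[:, None], (1, n_samples))
        home = spec_tissue[:, None] == tissue_idx[None, :]
        activation = rng.normal(1.0, design.activation_cv, size=(n, n_samples))
        signal = signal + np.where(home, design.effect_size * activation, 0.0)
        signal = signal + batch[exp_idx][:, block].T

        probeset_gene = truth.probeset_gene_a if species == "A" else truth.probeset_gene_b
        probeset_ids = sorted(probeset_gene)
        if species == "A":
            row_gene = np.array([gene_index[probeset_gene[p]] for p in probeset_ids])
        else:
            gene_b_to_a = {gb: ga for ga, gb in truth.ortholog_map}
            row_gene = np.array(
                [gene_index[gene_b_to_a[probeset_gene[p]]] for p in probeset_ids]
            )
        values = signal[row_gene]
        if species == "B":
            offsets = rng.normal(0.0, design.species_shift_sd, size=len(probeset_ids))
            values = values + offsets[:, None]
        noise = rng.normal(0.0, 1.0, size=values.shape) * noise_scale[row_gene][:, None]
        values = values + noise

        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=probeset_ids, columns=sample_ids)
        )
        annot = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species": species,
                "tissue": tissue_names,
                "experiment": exp_ids,
            }
        )
        results[species] = (matrix, annot)

    return results["A"][0], results["B"][0], results["A"][1], results["B"][1]


def generate_qc_table(
    n_arrays: int, fail_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit a per-array QC metrics table with known pass/fail labels.

    Passing arrays draw every metric strictly inside the default acceptance
    ranges (5% margin from each bound); failing arrays violate one to three
    randomly chosen metrics.  Exactly ``round(fail_fraction * n_arrays)``
    arrays fail.  Returns ``(metrics, labels)`` where labels are
    ``"pass"``/``"fail"`` indexed like the metrics table.
    """
    if n_arrays <= 0:
        raise ValueError("n_arrays must be positive")
    if not 0.0 <= fail_fraction <= 1.0:
        raise ValueError("fail_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    n_fail = int(round(fail_fraction * n_arrays))
    fail_set = set(rng.choice(n_arrays, size=n_fail, replace=False).tolist())

    ranges = DEFAULT_THRESHOLDS.as_ranges()
    rows, labels = [], []
    for i in range(n_arrays):
        row = {"array_id": f"array{i:04d}"}
        # start strictly inside every range
        for metric in QC_METRICS:
            lo, hi = ranges[metric]
            lo_eff = lo if lo is not None else hi - 2.0
            hi_eff = hi if hi is not None else lo + 2.0
            margin = 0.05 * (hi_eff - lo_eff)
            row[metric] = rng.uniform(lo_eff + margin, hi_eff - margin)
        if i in fail_set:
            k = rng.integers(1, 4)
            bad = rng.choice(len(QC_METRICS), size=k, replace=False)
            for m in bad:
                metric = QC_METRICS[m]
                lo, hi = ranges[metric]
                width = (hi - lo) if lo is not None and hi is not None else 1.0
                if lo is not None and (hi is None or rng.random() < 0.5):
                    row[metric] = lo - rng.uniform(0.05, 0.5) * width
                else:
                    row[metric] = hi + rng.uniform(0.05, 0.5) * width
            labels.append("fail")
        else:
            labels.append("pass")
        rows.append(row)
    metrics = pd.DataFrame(rows)
    return metrics, pd.Series(labels, index=metrics.index, name="label")
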