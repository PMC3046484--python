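"""Cross-species probeset pairing by probe-sequence local alignment.

For each orthologous gene pair, every probe of every species-A probeset is
aligned against every probe of the candidate species-B probesets using
gapped local alignment (match +1, mismatch −3, affine gaps with existence 5
and extension 2 — legacy blastn defaults — and a required shared exact
7-mer word mirroring ``-W 7``).  Probe matches are reduced to a one-to-one
set greedily by descending score, and the probeset combination with the
most retained probe–probe top matches represents the ortholog pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align

_VALID = set("ACGTN")


@dataclass(frozen=True)
class AlignmentParams:
    """Local-alignment scoring scheme and seeding requirement.

    A gap of length k costs ``gap_open_penalty + k * gap_extend_penalty``.
    ``low_complexity_filter`` is accepted for interface completeness but no
    filtering is implemented (probes are short and pre-selected).
    ``optimal_assignment`` switches the one-to-one reduction from greedy to
    a maximum-total-score assignment, for sensitivity analysis.
    """

    word_size: int = 7
    gap_open_penalty: float = 5.0
    gap_extend_penalty: float = 2.0
    match_reward: float = 1.0
    mismatch_penalty: float = 3.0
    low_complexity_filter: bool = False
    optimal_assignment: bool = False

    def __post_init__(self) -> None:
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if self.gap_open_penalty <= 0 or self.gap_extend_penalty <= 0:
            raise ValueError("gap penalties must be positive")
        if self.mismatch_penalty <= 0:
            raise ValueError("mismatch_penalty must be positive (subtracted)")


@dataclass(frozen=True)
class ProbeMatch:
    probe_a: str
    probe_b: str
    score: float


@dataclass
class ProbesetPairChoice:
    """Chosen probeset pair for one ortholog gene pair, with audit counts."""

    gene_a: str
    gene_b: str
    probeset_a: str | None
    probeset_b: str | None
    n_top_matches: int
    total_score: float
    candidates: pd.DataFrame  # per-combination match counts and scores

    @property
    def pairable(self) -> bool:
        return self.probeset_a is not None


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_reward
    aligner.mismatch_score = -params.mismatch_penalty
    # first residue of a gap costs open+extend (NCBI convention)
    aligner.open_gap_score = -(params.gap_open_penalty + params.gap_extend_penalty)
    aligner.extend_gap_score = -params.gap_extend_penalty
    return aligner


def _validate_seq(seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")


def _shares_word(seq_a: str, seq_b: str, w: int) -> bool:
    # words containing N are ambiguous and never seed
    words = {
        seq_a[i : i + w]
        for i in range(len(seq_a) - w + 1)
        if "N" not in seq_a[i : i + w]
    }
    return any(
        seq_b[i : i + w] in words
        for i in range(len(seq_b) - w + 1)
        if "N" not in seq_b[i : i + w]
    )


def align_probes(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Best local-alignment score between two probes, 0 without a seed.

    The score is the maximum Smith–Waterman score under the scheme in
    ``params``, reported only when the sequences share at least one exact
    ``word_size``-mer on the given strands; otherwise 0, even if a positive
    alignment exists.
    """
    _validate_seq(seq_a)
    _validate_seq(seq_b)
    if not seq_a or not seq_b:
        return 0.0
    if len(seq_a) < params.word_size or len(seq_b) < params.word_size:
        return 0.0
    if not _shares_word(seq_a, seq_b, params.word_size):
        return 0.0
    return float(_aligner(params).score(seq_a, seq_b))


def best_one_to_one_matches(
    probes_a: list[tuple[str, str]],
    probes_b: list[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
) -> list[ProbeMatch]:
    """Reduce all pairwise probe alignments to one-to-one top matches.

    Probes are ``(probe_id, sequence)`` pairs.  Greedy reduction: repeatedly
    retain the highest-scoring pair among unmatched probes with score > 0;
    ties broken by (probe_a id, probe_b id) lexicographically.  With
    ``params.optimal_assignment`` the retained set instead maximizes total
    score (Hungarian assignment restricted to positive scores).
    """
    if not probes_a or not probes_b:
        raise ValueError("probe lists must be non-empty")
    scored = []
    score_mat = np.zeros((len(probes_a), len(probes_b)))
    for i, (id_a, seq_a) in enumerate(probes_a):
        for j, (id_b, seq_b) in enumerate(probes_b):
            s = align_probes(seq_a, seq_b, params)
            score_mat[i, j] = s
            if s > 0:
                scored.append((s, id_a, id_b, i, j))

    if params.optimal_assignment:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-score_mat)
        matches = [
            ProbeMatch(probes_a[i][0], probes_b[j][0], float(score_mat[i, j]))
            for i, j in zip(rows, cols)
            if score_mat[i, j] > 0
        ]
        return sorted(matches, key=lambda m: (-m.score, m.probe_a, m.probe_b))

    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for s, id_a, id_b, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(ProbeMatch(id_a, id_b, float(s)))
    return matches


def _probe_list(record) -> list[tuple[str, str]]:
    return [
        (f"{record.probeset_id}|{idx}", seq) for idx, seq in enumerate(record.probes)
    ]


def pair_probesets(
    gene_pair: tuple[str, str],
    probesets_a,
    probesets_b,
    params: AlignmentParams = AlignmentParams(),
) -> ProbesetPairChoice:
    """Choose the probeset combination with the most probe–probe top matches.

    ``probesets_a`` / ``probesets_b`` are lists of records with
    ``probeset_id`` and ``probes`` attributes.  Ties on match count are
    broken by larger total score, then by lexicographic probeset ids.  A
    gene pair with no combination scoring a single match is returned
    unpairable (``probeset_a is None``).
    """
    if not probesets_a or not probesets_b:
        raise ValueError("each side needs at least one probeset")
    rows = []
    for ra in probesets_a:
        for rb in probesets_b:
            matches = best_one_to_one_matches(_probe_list(ra), _probe_list(rb), params)
            rows.append(
                {
                    "probeset_a": ra.probeset_id,
                    "probeset_b": rb.probeset_id,
                    "n_top_matches": len(matches),
                    "total_score": float(sum(m.score for m in matches)),
                }
            )
    candidates = pd.DataFrame(rows)
    best = candidates.sort_values(
        by=["n_top_matches", "total_score", "probeset_a", "probeset_b"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).iloc[0]
    if best["n_top_matches"] == 0:
        return ProbesetPairChoice(
            gene_pair[0], gene_pair[1], None, None, 0, 0.0, candidates
        )
    return ProbesetPairChoice(
        gene_pair[0],
        gene_pair[1],
        best["probeset_a"],
        best["probeset_b"],
        int(best["n_top_matches"]),
        float(best["total_score"]),
        candidates,
    )


PAIRING_COLUMNS = [
    "gene_a", "gene_b", "probeset_a", "probeset_b", "n_top_matches", "total_score",
]


def build_pairing_map(
    ortholog_table: pd.DataFrame,
    probesets_a: dict,
    probesets_b: dict,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair probesets for every gene pair of a one-to-one ortholog table.

    ``probesets_a`` / ``probesets_b`` map probeset id to a record with
    ``gene_id`` and ``probes``.  Returns ``(pairing, unpairable)`` where
    ``pairing`` has one row per pairable gene pair (in ortholog-table order)
    and ``unpairable`` lists excluded pairs with a reason.  Duplicate gene
    ids in the ortholog table are rejected: a one-to-one input is required.
    """
    for col in ("gene_a", "gene_b"):
        if col not in ortholog_table.columns:
            raise ValueError(f"ortholog table missing column {col!r}")
        if ortholog_table[col].duplicated().any():
            dup = ortholog_table.loc[ortholog_table[col].duplicated(), col].iloc[0]
            raise ValueError(
                f"duplicate gene id {dup!r} in ortholog table; one-to-one input required"
            )

    by_gene_a: dict[str, list] = {}
    for rec in probesets_a.values():
        by_gene_a.setdefault(rec.gene_id, []).append(rec)
    by_gene_b: dict[str, list] = {}
    for rec in probesets_b.values():
        by_gene_b.setdefault(rec.gene_id, []).append(rec)

    paired_rows, unpaired_rows = [], []
    for _, row in ortholog_table.iterrows():
        ga, gb = row["gene_a"], row["gene_b"]
        recs_a = sorted(by_gene_a.get(ga, []), key=lambda r: r.probeset_id)
        recs_b = sorted(by_gene_b.get(gb, []), key=lambda r: r.probeset_id)
        if not recs_a or not recs_b:
            side = "a" if not recs_a else "b"
            unpaired_rows.append(
                {"gene_a": ga, "gene_b": gb, "reason": f"no probesets for species {side}"}
            )
            continue
        choice = pair_probesets((ga, gb), recs_a, recs_b, params)
        if not choice.pairable:
            unpaired_rows.append(
                {"gene_a": ga, "gene_b": gb, "reason": "no probe match in any combination"}
            )
            continue
        paired_rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "probeset_a": choice.probeset_a,
                "probeset_b": choice.probeset_b,
                "n_top_matches": choice.n_top_matches,
                "total_score": choice.total_score,
            }
        )
    pairing = pd.DataFrame(paired_rows, columns=PAIRING_COLUMNS)
    unpairable = pd.DataFrame(unpaired_rows, columns=["gene_a", "gene_b", "reason"])
    return pairing, unpairable
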