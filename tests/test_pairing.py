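"""Probe alignment and probeset-pairing selection."""

import numpy as np
import pandas as pd
import pytest

from xspecies.pairing import (
    AlignmentParams,
    align_probes,
    best_one_to_one_matches,
    build_pairing_map,
    pair_probesets,
)
from xspecies.synthgen import (
    ProbesetRecord,
    SynthDesign,
    generate_universe,
)

BASES = np.array(list("ACGT"))


def random_mer(rng, n=25):
    return "".join(rng.choice(BASES, n))


def mutate(rng, seq, k):
    arr = list(seq)
    for pos in rng.choice(len(arr), size=k, replace=False):
        arr[pos] = rng.choice(BASES[BASES != arr[pos]])
    return "".join(arr)


class TestAlignProbes:
    def test_identical_probes_score_full_length(self):
        seq = "ACGTACGTACGTACGTACGTACGTA"
        assert align_probes(seq, seq) == 25.0

    def test_no_shared_word_scores_zero(self):
        # differ at every 4th base: longest exact run is 3 < word_size 7
        a = "ACGTACGTACGTACGTACGTACGTA"
        b = "".join(
            c if i % 4 else ("C" if c != "C" else "G") for i, c in enumerate(a)
        )
        assert align_probes(a, b) == 0.0

    def test_central_substitution_prefers_mismatch_over_split(self):
        rng = np.random.default_rng(5)
        a = random_mer(rng)
        b = mutate(rng, a[:12] + a[12] + a[13:], 0)  # copy
        b = b[:12] + ("A" if a[12] != "A" else "C") + b[13:]
        # full-length alignment: 24 matches - 1 mismatch = 21, beats the
        # best clean 12-mer segment (12)
        assert align_probes(a, b) == 21.0

    def test_empty_sequence_scores_zero(self):
        assert align_probes("", "ACGTACG") == 0.0

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            align_probes("ACGTXCG", "ACGTACG")

    def test_agrees_with_exhaustive_dp_when_seeded(self, sw_oracle, rng):
        hits = 0
        for trial in range(300):
            a = random_mer(rng)
            b = mutate(rng, a, rng.integers(0, 8)) if trial % 3 else random_mer(rng)
            words_a = {a[i : i + 7] for i in range(19)}
            if not any(b[i : i + 7] in words_a for i in range(19)):
                continue
            hits += 1
            assert align_probes(a, b) == sw_oracle(a, b)
        assert hits > 100  # the comparison actually exercised seeded pairs

    def test_score_never_increases_under_mutation_ladder(self, rng):
        # each step breaks one further matching position (distinct sites),
        # so every alignment's score weakly decreases
        for _ in range(20):
            a = random_mer(rng)
            positions = rng.permutation(25)[:10]
            b, prev = list(a), align_probes(a, a)
            for pos in positions:
                b[pos] = rng.choice(BASES[BASES != a[pos]])
                s = align_probes(a, "".join(b))
                assert s <= prev
                prev = s


class TestOneToOneMatching:
    def test_identical_probe_lists_fully_matched(self):
        probes = [(f"p{i}", "ACGTACGTACGTACGTACGTACGTA") for i in range(3)]
        matches = best_one_to_one_matches(probes, probes)
        assert len(matches) == 3
        assert all(m.score == 25.0 for m in matches)

    def test_all_zero_scores_give_empty_matching(self):
        a = [("a0", "AAAAAAAAAAAAAAAAAAAAAAAAA")]
        b = [("b0", "CGCGCGCGCGCGCGCGCGCGCGCGC")]
        assert best_one_to_one_matches(a, b) == []

    def test_greedy_conflict_resolution_matches_hand_simulation(self, monkeypatch):
        """a1 is the best partner for both b1 and b2; greedy gives b1 to a1
        (higher score first), then b2 must take a2."""
        import xspecies.pairing as pairing_mod

        scores = {
            ("a1", "b1"): 20.0, ("a1", "b2"): 18.0, ("a1", "b3"): 0.0,
            ("a2", "b1"): 15.0, ("a2", "b2"): 14.0, ("a2", "b3"): 0.0,
            ("a3", "b1"): 0.0, ("a3", "b2"): 0.0, ("a3", "b3"): 9.0,
        }
        monkeypatch.setattr(
            pairing_mod, "align_probes", lambda sa, sb, p=None: scores[(sa, sb)]
        )
        probes_a = [(i, i) for i in ("a1", "a2", "a3")]
        probes_b = [(i, i) for i in ("b1", "b2", "b3")]
        matches = best_one_to_one_matches(probes_a, probes_b)
        got = {(m.probe_a, m.probe_b): m.score for m in matches}
        assert got == {("a1", "b1"): 20.0, ("a2", "b2"): 14.0, ("a3", "b3"): 9.0}

    def test_empty_probe_list_rejected(self):
        with pytest.raises(ValueError):
            best_one_to_one_matches([], [("b0", "ACGTACG")])


class TestPairProbesets:
    def test_single_candidate_chosen(self, rng):
        probes = [random_mer(rng) for _ in range(4)]
        ra = ProbesetRecord("pa", "ga", probes)
        rb = ProbesetRecord("pb", "gb", [mutate(rng, p, 1) for p in probes])
        choice = pair_probesets(("ga", "gb"), [ra], [rb])
        assert (choice.probeset_a, choice.probeset_b) == ("pa", "pb")
        assert choice.n_top_matches == 4

    def test_tie_on_matches_broken_by_total_score(self, rng):
        shared = [random_mer(rng) for _ in range(3)]
        ra = ProbesetRecord("pa", "ga", shared)
        # both candidates match all 3 probes, but pb_far carries mutations
        rb_near = ProbesetRecord("pb_near", "gb", list(shared))
        rb_far = ProbesetRecord("pb_far", "gb", [mutate(rng, p, 2) for p in shared])
        choice = pair_probesets(("ga", "gb"), [ra], [rb_far, rb_near])
        near = pair_probesets(("ga", "gb"), [ra], [rb_near])
        far = pair_probesets(("ga", "gb"), [ra], [rb_far])
        assert near.n_top_matches == far.n_top_matches == 3
        assert near.total_score > far.total_score
        assert choice.probeset_b == "pb_near"

    def test_unmatchable_pair_flagged(self):
        ra = ProbesetRecord("pa", "ga", ["A" * 25])
        rb = ProbesetRecord("pb", "gb", ["C" * 25])
        choice = pair_probesets(("ga", "gb"), [ra], [rb])
        assert not choice.pairable


class TestBuildPairingMap:
    def universe(self, **kw):
        defaults = dict(
            n_genes=50,
            tissues=("t1", "t2"),
            samples_per_tissue_per_species=3,
            n_specific_per_tissue=2,
            n_housekeeping=2,
            multi_probeset_fraction=0.2,
            seed=1,
        )
        defaults.update(kw)
        return generate_universe(SynthDesign(**defaults))

    def test_empty_ortholog_table_gives_empty_pairing(self):
        u = self.universe()
        empty = pd.DataFrame({"gene_a": [], "gene_b": []})
        pairing, unpairable = build_pairing_map(empty, u.probesets_a, u.probesets_b)
        assert pairing.empty and unpairable.empty

    def test_zero_divergence_recovers_all_truth_pairs(self):
        u = self.universe(probe_divergence=0.0)
        pairing, unpairable = build_pairing_map(
            u.ortholog_table, u.probesets_a, u.probesets_b
        )
        assert unpairable.empty and len(pairing) == 50
        for _, r in pairing.iterrows():
            assert u.truth.true_probeset_pairs[(r.gene_a, r.gene_b)] == (
                r.probeset_a,
                r.probeset_b,
            )

    def test_gene_without_probes_is_flagged(self):
        u = self.universe(probe_divergence=0.0)
        gb_drop = u.ortholog_table["gene_b"].iloc[0]
        probesets_b = {
            pid: rec for pid, rec in u.probesets_b.items() if rec.gene_id != gb_drop
        }
        pairing, unpairable = build_pairing_map(
            u.ortholog_table, u.probesets_a, probesets_b
        )
        assert len(pairing) == 49
        assert list(unpairable["gene_b"]) == [gb_drop]

    def test_duplicate_gene_ids_rejected(self):
        u = self.universe()
        dup = pd.concat([u.ortholog_table, u.ortholog_table.iloc[[0]]])
        with pytest.raises(ValueError, match="one-to-one"):
            build_pairing_map(dup, u.probesets_a, u.probesets_b)

    def test_symmetric_at_zero_divergence(self):
        u = self.universe(probe_divergence=0.0, n_genes=20, multi_probeset_fraction=0.3)
        fwd, _ = build_pairing_map(u.ortholog_table, u.probesets_a, u.probesets_b)
        swapped = u.ortholog_table.rename(
            columns={"gene_a": "gene_b", "gene_b": "gene_a"}
        )
        rev, _ = build_pairing_map(swapped, u.probesets_b, u.probesets_a)
        fwd_pairs = set(zip(fwd["probeset_a"], fwd["probeset_b"]))
        rev_pairs = set(zip(rev["probeset_b"], rev["probeset_a"]))
        assert fwd_pairs == rev_pairs


@pytest.mark.parametrize("seed", range(1, 6))
def test_truth_recovery_at_five_percent_divergence(seed):
    """>= 95% of ground-truth probeset pairs recovered at 5% divergence."""
    u = generate_universe(
        SynthDesign(
            n_genes=50,
            tissues=("t1", "t2"),
            samples_per_tissue_per_species=3,
            n_specific_per_tissue=2,
            n_housekeeping=2,
            probe_divergence=0.05,
            multi_probeset_fraction=0.2,
            seed=seed,
        )
    )
    pairing, unpairable = build_pairing_map(
        u.ortholog_table, u.probesets_a, u.probesets_b
    )
    hits = sum(
        u.truth.true_probeset_pairs[(r.gene_a, r.gene_b)]
        == (r.probeset_a, r.probeset_b)
        for _, r in pairing.iterrows()
    )
    assert hits / len(u.ortholog_table) >= 0.95
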