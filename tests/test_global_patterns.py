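"""PCA, silhouette separation, tissue correlations, hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_bundle
from xspecies import normalize as nm
from xspecies.containers import ExpressionMatrix, MergedMatrix
from xspecies.global_patterns import (
    TissueCorrelationMatrix,
    cluster_separation,
    hierarchical_cluster,
    pca,
    tissue_correlation_matrix,
)


def em(values, tag="by_probeset"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"p{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        tag,
    )


class TestPCA:
    def test_rank_one_data_concentrates_variance(self, rng):
        pattern = rng.normal(size=6)
        weights = rng.normal(size=8)
        m = em(np.outer(pattern, weights))  # samples proportional to one pattern
        result = pca(m, n_components=5)
        assert result.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one_when_all_kept(self, rng):
        m = em(rng.normal(size=(20, 10)))
        result = pca(m)  # all min(dims) components
        assert result.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(result.variance_fractions) <= 1e-12).all()

    def test_matches_covariance_eigensolve(self, rng):
        """Scores/loadings reproduce centered data; eigenvalues agree."""
        m = em(rng.normal(size=(20, 10)))
        result = pca(m)
        x = m.values().T
        xc = x - x.mean(axis=0)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        np.testing.assert_allclose(recon, xc, atol=1e-8)
        eigvals = np.linalg.eigvalsh(np.cov(xc, rowvar=False))[::-1]
        fractions = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            result.variance_fractions, fractions[: len(result.variance_fractions)],
            atol=1e-8,
        )

    def test_loadings_orthonormal(self, rng):
        m = em(rng.normal(size=(15, 8)))
        result = pca(m, n_components=5)
        l = result.loadings.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(5), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        m = em(rng.normal(size=(12, 7)))
        result = pca(m, n_components=4)
        l = result.loadings.to_numpy()
        for j in range(4):
            assert l[np.argmax(np.abs(l[:, j])), j] > 0

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            pca(em(rng.normal(size=(5, 4))), n_components=6)


class TestClusterSeparation:
    def scores_frame(self, x):
        return pd.DataFrame(
            x, index=[f"s{i}" for i in range(len(x))],
            columns=[f"PC{j + 1}" for j in range(x.shape[1])],
        )

    def annot_frame(self, labels):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(labels))],
                "species": "A",
                "tissue": labels,
                "experiment": "e",
            }
        )

    def test_separated_blobs_score_high(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(10, 0.1, (10, 3))])
        labels = ["g1"] * 10 + ["g2"] * 10
        _, overall = cluster_separation(
            self.scores_frame(x), self.annot_frame(labels), "tissue", k=3
        )
        assert overall > 0.9

    def test_permuted_labels_score_near_zero(self, rng):
        x = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(3, 1, (15, 3))])
        labels = np.array(["g1"] * 15 + ["g2"] * 15)
        vals = []
        for _ in range(20):
            perm = rng.permutation(labels)
            _, overall = cluster_separation(
                self.scores_frame(x), self.annot_frame(perm), "tissue", k=3
            )
            vals.append(overall)
        assert abs(np.mean(vals)) < 0.05

    def test_small_groups_excluded_with_warning(self, rng):
        x = rng.normal(size=(5, 3))
        labels = ["g1", "g1", "g2", "g2", "lone"]
        with pytest.warns(UserWarning, match="lone"):
            per_group, _ = cluster_separation(
                self.scores_frame(x), self.annot_frame(labels), "tissue", k=2
            )
        assert "lone" not in per_group


class TestTissueCorrelation:
    def merged_from(self, values, groups):
        m = em(values)
        annotation = pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "species": [g.split(":")[0] for g in groups],
                "tissue": [g.split(":")[1] for g in groups],
                "experiment": "e",
            }
        )
        return MergedMatrix(m, annotation)

    def test_copy_groups_obey_copy_symmetry(self, rng):
        """A group and its exact copy: every cross pair either duplicates a
        within pair or is a self-copy (correlation 1), so the cross mean is
        1/n + (n-1)/n * within (within-group means exclude self-pairs)."""
        n = 3
        block = rng.normal(size=(30, n))
        merged = self.merged_from(
            np.hstack([block, block]), ["A:t"] * n + ["B:t"] * n
        )
        tcm = tissue_correlation_matrix(merged)
        within = tcm.values.loc["A:t", "A:t"]
        cross = tcm.values.loc["A:t", "B:t"]
        assert cross == pytest.approx(1 / n + (n - 1) / n * within, abs=1e-12)
        assert tcm.values.loc["B:t", "B:t"] == pytest.approx(within, abs=1e-12)

    def test_uncorrelated_groups_near_zero(self, rng):
        n_rows = 2000
        values = rng.normal(size=(n_rows, 8))
        merged = self.merged_from(values, ["A:x"] * 4 + ["B:y"] * 4)
        tcm = tissue_correlation_matrix(merged)
        assert abs(tcm.values.loc["A:x", "B:y"]) < 3 / np.sqrt(n_rows)

    def test_matches_brute_force_pairwise_loop(self, rng):
        values = rng.normal(size=(10, 12))
        groups = ["A:t1"] * 4 + ["A:t2"] * 4 + ["B:t1"] * 4
        merged = self.merged_from(values, groups)
        tcm = tissue_correlation_matrix(merged)
        labels = np.array(groups)
        for g in tcm.groups:
            for h in tcm.groups:
                cols_g = np.nonzero(labels == g)[0]
                cols_h = np.nonzero(labels == h)[0]
                cors = [
                    np.corrcoef(values[:, i], values[:, j])[0, 1]
                    for i in cols_g
                    for j in cols_h
                    if not (g == h and i == j)
                ]
                assert tcm.values.loc[g, h] == pytest.approx(np.mean(cors), abs=1e-12)

    def test_requires_by_probeset_scale(self, rng):
        merged = self.merged_from(rng.normal(size=(5, 4)), ["A:t"] * 2 + ["B:t"] * 2)
        merged.matrix.scale_tag = "by_sample"
        with pytest.raises(ValueError, match="by_probeset"):
            tissue_correlation_matrix(merged)


class TestHierarchicalCluster:
    def tcm(self, values, groups):
        return TissueCorrelationMatrix(
            groups=groups, values=pd.DataFrame(values, index=groups, columns=groups)
        )

    def test_two_groups_single_join(self):
        c = self.tcm([[1.0, 0.2], [0.2, 1.0]], ["g1", "g2"])
        order, z = hierarchical_cluster(c)
        assert order == ["g1", "g2"]
        assert z.shape == (1, 4)

    def test_identical_rows_join_first_at_zero_distance(self):
        values = np.array(
            [[1.0, 0.5, 0.1], [1.0, 0.5, 0.1], [0.0, 0.9, 0.4]]
        )
        c = self.tcm(values, ["g1", "g2", "g3"])
        _, z = hierarchical_cluster(c)
        assert set(z[0, :2].astype(int)) == {0, 1}
        assert z[0, 2] == 0.0

    def test_matches_hand_simulated_complete_linkage(self):
        # rows on a line at 0, 1, 3, 7: complete linkage joins (0,1) at 1,
        # then {0,1} with 3 at max(3,2)=3, then with 7 at max(7,6,4)=7
        groups = list("abcd")
        values = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [3.0, 0.0], [7.0, 0.0]], index=groups
        )
        c = TissueCorrelationMatrix(groups=groups, values=values)
        _, z = hierarchical_cluster(c)
        np.testing.assert_allclose(z[:, 2], [1.0, 3.0, 7.0])


@pytest.mark.parametrize("seed", range(1, 6))
def test_same_tissue_cross_species_correlation_elevated(seed):
    """Same-tissue human/mouse-style groups correlate above background.

    For >= 90% of tissues, the cross-species same-tissue entry exceeds the
    mean cross-species off-tissue entry of that tissue's row.
    """
    b = make_bundle(seed=seed)
    na = nm.normalize_by_probeset(b["matrix_a"]).matrix
    nb = nm.normalize_by_probeset(b["matrix_b"]).matrix
    merged = nm.merge_matrices(na, nb, b["pairing"], b["annot_a"], b["annot_b"])
    tcm = tissue_correlation_matrix(merged)
    tissues = b["design"].tissues
    wins = 0
    for t in tissues:
        same = tcm.values.loc[f"A:{t}", f"B:{t}"]
        off = [tcm.values.loc[f"A:{t}", f"B:{u}"] for u in tissues if u != t]
        wins += same > np.mean(off)
    assert wins / len(tissues) >= 0.9


@pytest.mark.parametrize("seed", range(1, 6))
def test_same_tissue_groups_cluster_as_siblings(seed):
    """Dendrogram places the two species' same-tissue groups side by side
    for >= 75% of tissues."""
    from scipy.cluster.hierarchy import fcluster

    b = make_bundle(seed=seed)
    na = nm.normalize_by_probeset(b["matrix_a"]).matrix
    nb = nm.normalize_by_probeset(b["matrix_b"]).matrix
    merged = nm.merge_matrices(na, nb, b["pairing"], b["annot_a"], b["annot_b"])
    tcm = tissue_correlation_matrix(merged)
    order, z = hierarchical_cluster(tcm)
    pos = {g: i for i, g in enumerate(order)}
    siblings = sum(
        abs(pos[f"A:{t}"] - pos[f"B:{t}"]) == 1 for t in b["design"].tissues
    )
    assert siblings / len(b["design"].tissues) >= 0.75
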