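"""Shared fixtures: small synthetic bundles and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xspecies import normalize as nm
from xspecies.synthgen import SynthDesign, generate_expression, generate_universe


def smith_waterman_affine(
    a: str, b: str, match=1.0, mismatch=3.0, gap_open=5.0, gap_extend=2.0
) -> float:
    """Exhaustive Gotoh local-alignment DP (no seeding); test oracle only.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - (gap_open + gap_extend), e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - (gap_open + gap_extend), f[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else -mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


@pytest.fixture(scope="session")
def sw_oracle():
    return smith_waterman_affine


def truth_pairing_frame(truth) -> pd.DataFrame:
    """Pairing table built from the generator's ground truth."""
    rows = [
        {"gene_a": ga, "gene_b": gb, "probeset_a": pa, "probeset_b": pb}
        for (ga, gb), (pa, pb) in truth.true_probeset_pairs.items()
    ]
    return pd.DataFrame(rows)


def make_bundle(seed: int, **overrides) -> dict:
    """Generate a compact two-species dataset with truth-based pairing.

    Defaults: 300 genes, 6 tissues, 10 samples per tissue per species, a
    planted tissue-specific program of 20 genes per tissue (so, as in real
    tissue compendia, tissue-specific genes make up the bulk of the most
    variable ones) — enough structure for the statistical invariants while
    staying fast.
    """
    defaults = dict(
        n_genes=300,
        tissues=(
            "nervous_system", "muscle_heart", "liver",
            "cell_line", "immune_system", "skin",
        ),
        samples_per_tissue_per_species=10,
        n_specific_per_tissue=20,
        n_housekeeping=30,
        seed=seed,
    )
    defaults.update(overrides)
    design = SynthDesign(**defaults)
    universe = generate_universe(design)
    m_a, m_b, annot_a, annot_b = generate_expression(design, universe.truth)
    return {
        "design": design,
        "universe": universe,
        "truth": universe.truth,
        "matrix_a": m_a,
        "matrix_b": m_b,
        "annot_a": annot_a,
        "annot_b": annot_b,
        "pairing": truth_pairing_frame(universe.truth),
    }


@pytest.fixture(scope="session")
def bundle1() -> dict:
    return make_bundle(seed=1)


@pytest.fixture(scope="session")
def merged_by_probeset(bundle1):
    na = nm.normalize_by_probeset(bundle1["matrix_a"]).matrix
    nb = nm.normalize_by_probeset(bundle1["matrix_b"]).matrix
    return nm.merge_matrices(
        na, nb, bundle1["pairing"], bundle1["annot_a"], bundle1["annot_b"]
    )


@pytest.fixture(scope="session")
def merged_by_sample(bundle1):
    na = nm.normalize_by_sample(bundle1["matrix_a"]).matrix
    nb = nm.normalize_by_sample(bundle1["matrix_b"]).matrix
    return nm.merge_matrices(
        na, nb, bundle1["pairing"], bundle1["annot_a"], bundle1["annot_b"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
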