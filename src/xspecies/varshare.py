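"""Variance-ranked ortholog sharing and gene-list overlap testing.

Within one tissue and one species, genes are sorted by expression variance.
Sliding down both species' rankings in non-overlapping windows (600 genes
in the full-compendium setting), the fraction of each window's genes whose
ortholog lands in the other species' corresponding window measures how
strongly tissue-specific (most-variable) and housekeeping (least-variable)
programs are shared.  A randomized baseline gives the chance level
(≈ window_size / n_genes), and the exact hypergeometric upper tail tests
the overlap of two conserved-gene lists drawn from a common universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from xspecies.containers import ExpressionMatrix


@dataclass(frozen=True)
class WindowConfig:
    """Windowing of a variance-ranked gene list.

    ``window_size`` genes per consecutive non-overlapping block, most
    variable first; the remainder (n mod window_size) is dropped from the
    windowed analysis.  ``top_fraction`` controls conserved-list extraction
    (the "top 10% most variable" lists).
    """

    window_size: int = 600
    top_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")


def gene_variance_ranking(
    m: ExpressionMatrix, annotation: pd.DataFrame, tissue: str
) -> pd.DataFrame:
    """Rank rows by descending expression variance within one tissue.

    Sample variance (denominator n−1) over the tissue's sample columns;
    ties broken by row id.  Returns a DataFrame with columns
    ``probeset_id`` and ``variance`` in rank order.
    """
    samples = annotation.loc[annotation["tissue"] == tissue, "sample_id"]
    samples = [s for s in samples if s in set(m.sample_ids)]
    if not samples:
        raise ValueError(f"tissue {tissue!r} absent from annotation/matrix")
    if len(samples) < 3:
        raise ValueError(f"tissue {tissue!r} has fewer than 3 samples")
    sub = m.data.loc[:, samples]
    var = sub.var(axis=1, ddof=1)
    out = (
        pd.DataFrame({"probeset_id": var.index, "variance": var.to_numpy()})
        .sort_values(by=["variance", "probeset_id"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return out


@dataclass
class WindowSharingResult:
    """Per-window shared-ortholog fractions for one tissue comparison."""

    windows: pd.DataFrame  # window, frac_a_in_b, frac_b_in_a, mean_frac
    n_genes: int
    window_size: int


def _window_index(ranked_ids: list[str], window_size: int) -> dict[str, int]:
    n_windows = len(ranked_ids) // window_size
    return {
        g: pos // window_size
        for pos, g in enumerate(ranked_ids[: n_windows * window_size])
    }


def window_shared_fraction(
    ranked_a: pd.DataFrame,
    ranked_b: pd.DataFrame,
    pairing: pd.DataFrame,
    config: WindowConfig = WindowConfig(),
) -> WindowSharingResult:
    """Fraction of each variance window shared through orthology.

    ``ranked_a`` / ``ranked_b`` come from :func:`gene_variance_ranking` on
    the two species (same paired universe).  For window w of species A, the
    fraction is the share of its genes whose ortholog falls in window w of
    species B; computed in both directions.  With a one-to-one pairing over
    a common universe the directions coincide (asserted).
    """
    ids_a = list(ranked_a["probeset_id"])
    ids_b = list(ranked_b["probeset_id"])
    a_to_b = dict(zip(pairing["probeset_a"], pairing["probeset_b"]))
    b_to_a = dict(zip(pairing["probeset_b"], pairing["probeset_a"]))
    if set(ids_a) != set(a_to_b) or set(ids_b) != set(b_to_a):
        raise ValueError("ranked lists must cover exactly the paired universe")
    n = len(ids_a)
    if config.window_size > n:
        raise ValueError(f"window_size {config.window_size} exceeds n_genes {n}")

    win_a = _window_index(ids_a, config.window_size)
    win_b = _window_index(ids_b, config.window_size)
    n_windows = n // config.window_size

    rows = []
    for w in range(n_windows):
        genes_a = [g for g, ww in win_a.items() if ww == w]
        frac_ab = (
            sum(1 for g in genes_a if win_b.get(a_to_b[g]) == w) / config.window_size
        )
        genes_b = [g for g, ww in win_b.items() if ww == w]
        frac_ba = (
            sum(1 for g in genes_b if win_a.get(b_to_a[g]) == w) / config.window_size
        )
        assert frac_ab == frac_ba, "directions must agree for one-to-one pairing"
        rows.append(
            {
                "window": w,
                "frac_a_in_b": frac_ab,
                "frac_b_in_a": frac_ba,
                "mean_frac": (frac_ab + frac_ba) / 2.0,
            }
        )
    return WindowSharingResult(
        windows=pd.DataFrame(rows), n_genes=n, window_size=config.window_size
    )


def randomized_baseline(
    n_genes: int,
    config: WindowConfig = WindowConfig(),
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Chance-level window sharing under independent random rankings.

    Each replicate draws an independent uniform random ranking per species
    and computes per-window shared fractions; the expected fraction is
    ``window_size / n_genes``.  Returns per-window mean and sd across
    replicates plus the replicate-level grand mean in ``attrs``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if config.window_size > n_genes:
        raise ValueError("window_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    n_windows = n_genes // config.window_size
    used = n_windows * config.window_size
    fracs = np.empty((n_reps, n_windows))
    for rep in range(n_reps):
        wa = np.empty(n_genes, dtype=np.int64)
        wb = np.empty(n_genes, dtype=np.int64)
        wa[rng.permutation(n_genes)] = np.arange(n_genes)
        wb[rng.permutation(n_genes)] = np.arange(n_genes)
        wa = np.where(wa < used, wa // config.window_size, -1)
        wb = np.where(wb < used, wb // config.window_size, -2)
        same = wa == wb
        for w in range(n_windows):
            fracs[rep, w] = (same & (wa == w)).sum() / config.window_size
    out = pd.DataFrame(
        {
            "window": np.arange(n_windows),
            "mean_frac": fracs.mean(axis=0),
            "sd_frac": fracs.std(axis=0, ddof=1) if n_reps > 1 else np.nan,
        }
    )
    out.attrs["grand_mean"] = float(fracs.mean())
    out.attrs["n_reps"] = n_reps
    return out


def top_conserved_list(
    ranked_a: pd.DataFrame,
    ranked_b: pd.DataFrame,
    pairing: pd.DataFrame,
    top_fraction: float = 0.1,
) -> pd.DataFrame:
    """Orthologs in the top variance fraction of both species' rankings.

    The top list is the first ``ceil(top_fraction * n)`` genes of each
    ranking; the intersection is returned ordered by mean rank (then by
    species-A probeset id).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    ids_a = list(ranked_a["probeset_id"])
    ids_b = list(ranked_b["probeset_id"])
    k = int(np.ceil(top_fraction * len(ids_a)))
    a_to_b = dict(zip(pairing["probeset_a"], pairing["probeset_b"]))
    rank_a = {g: i for i, g in enumerate(ids_a)}
    rank_b = {g: i for i, g in enumerate(ids_b)}
    top_b = set(ids_b[:k])
    rows = []
    for g in ids_a[:k]:
        partner = a_to_b.get(g)
        if partner in top_b:
            rows.append(
                {
                    "probeset_a": g,
                    "probeset_b": partner,
                    "rank_a": rank_a[g],
                    "rank_b": rank_b[partner],
                    "mean_rank": (rank_a[g] + rank_b[partner]) / 2.0,
                }
            )
    out = pd.DataFrame(
        rows, columns=["probeset_a", "probeset_b", "rank_a", "rank_b", "mean_rank"]
    )
    return out.sort_values(
        by=["mean_rank", "probeset_a"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class OverlapTest:
    """Exact hypergeometric upper-tail overlap test.

    For two lists of sizes K and n drawn from a universe of N genes with
    observed overlap k, ``p_value = P(X >= k)`` with
    X ~ Hypergeometric(N, K, n).
    """

    N: int
    K: int
    n: int
    k: int
    p_value: float


def hypergeom_overlap_test(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Upper-tail hypergeometric probability of a list overlap.

    The tail P(X >= k) = sum_{i=k}^{min(K, n)} C(K,i) C(N−K,n−i) / C(N,n)
    is accumulated in log space (log-gamma binomials + logsumexp) for
    numerical stability at small p-values.
    """
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("list sizes must satisfy 0 <= K, n <= N")
    if k < 0 or k > min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K, n)={min(K, n)}]")
    i = np.arange(k, min(K, n) + 1)
    # only terms with n - i <= N - K are feasible
    i = i[(n - i) <= (N - K)]
    if len(i) == 0:
        raise ValueError("no feasible overlap terms (inconsistent N, K, n, k)")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_terms = log_comb(K, i) + log_comb(N - K, n - i) - log_comb(N, n)
    p = float(np.exp(logsumexp(log_terms)))
    return OverlapTest(N=N, K=K, n=n, k=k, p_value=min(p, 1.0))
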