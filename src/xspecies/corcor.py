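"""Correlation of correlation coefficients (corCor) across species.

For an ortholog pair (A, A'): rank every gene's expression within its own
platform, correlate gene A with each of the other n−1 paired genes on its
chip (Spearman) to get the profile v(A); build v(A') the same way on the
other platform, ordered identically under the pairing; corCor is the
correlation between v(A) and v(A').  High |corCor| means the gene occupies
a similar position in both species' co-expression networks, independent of
sample composition; negative values indicate inverted co-expression.

The all-pairs stage is computed by rank-transforming each matrix once and
taking standardized matrix products, so a ~6,000-pair compendium stays
desk-scale (O(n^2 s) total work).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from xspecies.containers import ExpressionMatrix


@dataclass
class CorCorResult:
    """Per-ortholog-pair corCor values plus run metadata.

    ``values`` has one row per pairing row with a ``corcor`` column;
    undefined values (zero-variance profile vectors) are NaN and listed in
    ``undefined``.
    """

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def corcor(self) -> pd.Series:
        return self.values["corcor"]

    @property
    def undefined(self) -> list[int]:
        return list(np.nonzero(self.values["corcor"].isna().to_numpy())[0])


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks; returns (ranks, constant_row_mask)."""
    ranks = rankdata(values, axis=1)
    constant = values.std(axis=1) == 0
    return ranks, constant


def _row_corr_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman correlations between rows.

    Constant rows are flagged and their correlations set to 0.
    """
    ranks, constant = _rank_rows(values)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((z**2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    z = z / safe[:, None]
    corr = z @ z.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, constant


def correlation_profile(m: ExpressionMatrix, row: str | int) -> np.ndarray:
    """Spearman correlations of one probeset with every other row.

    Rows must already be restricted to (and ordered by) the pairing.  The
    self-entry is excluded, so the profile has length n−1.  A constant row
    yields an all-zero profile (flagged at the matrix level in
    :func:`corcor_all`).
    """
    if m.shape[1] < 3:
        raise ValueError("Spearman profiles need at least 3 samples")
    i = row if isinstance(row, int) else m.probeset_ids.index(row)
    corr, _ = _row_corr_matrix(m.values())
    return np.delete(corr[i], i)


def corcor_all(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    pairing: pd.DataFrame,
    outer: str = "pearson",
) -> CorCorResult:
    """corCor for every ortholog probeset pair.

    Both matrices are restricted to the pairing's probesets and aligned in
    pairing order, so entry i of each profile refers to the same ortholog
    pair on both sides.  The outer correlation between the two profiles is
    Pearson by default (``outer="spearman"`` ranks the profiles first).  A
    pair whose profile has zero variance on either side gets NaN, not 0.
    """
    if outer not in ("pearson", "spearman"):
        raise ValueError(f"unknown outer correlation {outer!r}")
    a = m_a.data.loc[pairing["probeset_a"]].to_numpy(dtype=float)
    b = m_b.data.loc[pairing["probeset_b"]].to_numpy(dtype=float)
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("Spearman profiles need at least 3 samples per species")
    n = a.shape[0]
    corr_a, _ = _row_corr_matrix(a)
    corr_b, _ = _row_corr_matrix(b)

    # profiles: rows of the correlation matrices minus the self entry
    mask = ~np.eye(n, dtype=bool)
    va = corr_a[mask].reshape(n, n - 1)
    vb = corr_b[mask].reshape(n, n - 1)
    if outer == "spearman":
        va = rankdata(va, axis=1)
        vb = rankdata(vb, axis=1)
    va = va - va.mean(axis=1, keepdims=True)
    vb = vb - vb.mean(axis=1, keepdims=True)
    na = np.sqrt((va**2).sum(axis=1))
    nb = np.sqrt((vb**2).sum(axis=1))
    defined = (na > 0) & (nb > 0)
    denom = np.where(defined, na * nb, 1.0)
    cc = (va * vb).sum(axis=1) / denom
    cc = np.clip(cc, -1.0, 1.0)
    cc[~defined] = np.nan

    values = pairing.reset_index(drop=True).copy()
    values["corcor"] = cc
    return CorCorResult(
        values=values,
        metadata={
            "n_pairs": n,
            "samples_a": a.shape[1],
            "samples_b": b.shape[1],
            "outer": outer,
        },
    )


@dataclass
class CorCorNull:
    """Randomized-null corCor distributions and threshold exceedances."""

    replicates: list[np.ndarray]
    exceedance: pd.DataFrame  # columns: rep, threshold, count, fraction
    metadata: dict


def _randomize(
    values: np.ndarray, rng: np.random.Generator, mode: str
) -> np.ndarray:
    if mode == "shuffle_within_row":
        return rng.permuted(values, axis=1)
    if mode == "shuffle_global":
        flat = values.ravel().copy()
        rng.shuffle(flat)
        return flat.reshape(values.shape)
    raise ValueError(f"unknown randomization mode {mode!r}")


def corcor_null(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    pairing: pd.DataFrame,
    n_reps: int = 1,
    seed: int = 0,
    mode: str = "shuffle_within_row",
    thresholds: tuple[float, ...] = (0.05, 0.1),
    outer: str = "pearson",
) -> CorCorNull:
    """Negative-control corCor distribution under randomized matrices.

    Each replicate randomizes both matrices (default: every row's values
    shuffled independently across samples, destroying gene–gene structure
    while preserving per-gene marginals; ``shuffle_global`` pools all
    values) and recomputes corCor for every pair.  Exceedance counts use
    strict ``>`` at each threshold.  Deterministic under ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    reps, rows = [], []
    for rep in range(n_reps):
        ra = ExpressionMatrix(
            pd.DataFrame(
                _randomize(m_a.values(), rng, mode),
                index=m_a.data.index,
                columns=m_a.data.columns,
            )
        )
        rb = ExpressionMatrix(
            pd.DataFrame(
                _randomize(m_b.values(), rng, mode),
                index=m_b.data.index,
                columns=m_b.data.columns,
            )
        )
        cc = corcor_all(ra, rb, pairing, outer=outer).corcor.to_numpy()
        reps.append(cc)
        defined = cc[~np.isnan(cc)]
        for t in thresholds:
            count = int((defined > t).sum())
            rows.append(
                {
                    "rep": rep,
                    "threshold": t,
                    "count": count,
                    "fraction": count / len(defined) if len(defined) else np.nan,
                }
            )
    return CorCorNull(
        replicates=reps,
        exceedance=pd.DataFrame(rows),
        metadata={"seed": seed, "mode": mode, "n_reps": n_reps, "outer": outer},
    )


def count_exceeding(result: CorCorResult, threshold: float) -> tuple[int, int]:
    """Number of pairs with corCor strictly above ``threshold``.

    Undefined (NaN) values are excluded; returns ``(count, n_undefined)``.
    """
    cc = result.corcor.to_numpy()
    nan = np.isnan(cc)
    return int((cc[~nan] > threshold).sum()), int(nan.sum())
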