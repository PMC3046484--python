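"""Global expression structure: PCA, cluster separation, tissue correlations.

Samples are the observations: the merged probeset-pair x sample matrix is
transposed, mean-centered per variable (no rescaling, matching R's
``prcomp`` defaults) and decomposed.  Cluster quality on the top components
is quantified by silhouette scores.  The tissue x species structure is
summarized as a matrix of mean pairwise Pearson correlations between
sample groups, hierarchically clustered with Euclidean distance and
complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from xspecies.containers import ExpressionMatrix, MergedMatrix


@dataclass
class PCAResult:
    """Sample scores, variable loadings and per-component variance shares."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # probeset pairs x components
    variance_fractions: np.ndarray


@dataclass
class TissueCorrelationMatrix:
    """Mean Pearson correlations between (species, tissue) sample groups."""

    groups: list[str]
    values: pd.DataFrame  # groups x groups
    order: list[str] | None = None  # dendrogram leaf order, once clustered


def _as_matrix(m) -> ExpressionMatrix:
    return m.matrix if isinstance(m, MergedMatrix) else m


def pca(m, n_components: int | None = None) -> PCAResult:
    """PCA with samples as observations and mean-centered variables.

    Components are ordered by decreasing variance; ``variance_fractions``
    are proportions of the *total* variance, so they sum to 1 only when all
    ``min(n_samples, n_rows)`` components are kept.  Sign convention: the
    largest-magnitude entry of each loading vector is positive.
    """
    mat = _as_matrix(m)
    n_rows, n_samples = mat.shape
    if n_rows < 2 or n_samples < 2:
        raise ValueError("PCA needs at least 2 rows and 2 samples")
    max_comp = min(n_samples, n_rows)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(dims)={max_comp}"
        )
    x = mat.values().T  # samples x variables
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # variables x components

    # deterministic sign: largest-|.| loading entry positive per component
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=mat.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=mat.probeset_ids, columns=comp_names),
        variance_fractions=model.explained_variance_ratio_.copy(),
    )


def cluster_separation(
    scores: pd.DataFrame,
    annotation: pd.DataFrame,
    label_column: str = "tissue",
    k: int = 3,
) -> tuple[dict[str, float], float]:
    """Silhouette of annotated groups on the first ``k`` score dimensions.

    Groups with fewer than 2 samples are excluded with a warning.  Returns
    ``(per_group_mean, overall_mean)`` using Euclidean distances.
    """
    labels = (
        annotation.set_index("sample_id")[label_column].reindex(scores.index)
    )
    if labels.isna().any():
        missing = list(scores.index[labels.isna()])[:3]
        raise ValueError(f"samples without annotation: {missing}")
    counts = labels.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warn(f"excluding groups with <2 samples: {small}")
    keep = ~labels.isin(small)
    labels = labels[keep]
    if labels.nunique() < 2:
        raise ValueError("need at least two groups with >=2 samples")
    x = scores.loc[keep.index[keep]].iloc[:, :k].to_numpy()
    sil = silhouette_samples(x, labels.to_numpy())
    per_group = {
        g: float(sil[labels.to_numpy() == g].mean()) for g in sorted(labels.unique())
    }
    return per_group, float(sil.mean())


def tissue_correlation_matrix(
    merged: MergedMatrix, annotation: pd.DataFrame | None = None
) -> TissueCorrelationMatrix:
    """Mean pairwise Pearson correlation between (species, tissue) groups.

    Entry (g, h) averages the correlation (across probeset pairs) of every
    sample column in g with every column in h; within-group entries average
    over distinct column pairs only, excluding each sample with itself.
    Requires a by-probeset-normalized merged matrix.  Groups with no
    samples are dropped with a warning; singleton groups yield NaN on the
    diagonal.
    """
    if merged.matrix.scale_tag != "by_probeset":
        raise ValueError("tissue correlations require by_probeset normalization")
    annot = annotation if annotation is not None else merged.annotation
    labels = (
        annot.set_index("sample_id")
        .reindex(merged.matrix.sample_ids)
        .apply(lambda r: f"{r['species']}:{r['tissue']}", axis=1)
    )
    groups = sorted(labels.dropna().unique())
    col_corr = np.corrcoef(merged.matrix.values(), rowvar=False)
    idx = {g: np.nonzero((labels == g).to_numpy())[0] for g in groups}
    empty = [g for g in groups if len(idx[g]) == 0]
    if empty:
        warn(f"dropping empty groups: {empty}")
        groups = [g for g in groups if g not in empty]

    out = np.empty((len(groups), len(groups)))
    for i, g in enumerate(groups):
        for j, h in enumerate(groups):
            sub = col_corr[np.ix_(idx[g], idx[h])]
            if i == j:
                n = len(idx[g])
                if n < 2:
                    out[i, j] = np.nan
                else:
                    mask = ~np.eye(n, dtype=bool)
                    out[i, j] = sub[mask].mean()
            else:
                out[i, j] = sub.mean()
    values = pd.DataFrame(out, index=groups, columns=groups)
    return TissueCorrelationMatrix(groups=groups, values=values)


def hierarchical_cluster(
    c: TissueCorrelationMatrix,
) -> tuple[list[str], np.ndarray]:
    """Complete-linkage clustering of correlation-matrix rows.

    Euclidean distance between rows, complete linkage (the defaults of the
    usual heatmap tooling).  NaN diagonal entries (singleton groups) are
    replaced by 1.0 for distance purposes.  Returns ``(leaf_order,
    linkage_matrix)`` and records the order on ``c``.
    """
    vals = c.values.to_numpy(dtype=float).copy()
    d = np.where(np.isnan(vals), 1.0, vals)
    z = linkage(d, method="complete", metric="euclidean")
    order = [c.groups[i] for i in leaves_list(z)]
    c.order = order
    return order, z
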