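"""Median/MAD centering and scaling, tissue balancing, and matrix merging.

Normalization is robust and axis-wise: subtract the median and divide by
the (unscaled) median absolute deviation, either row-by-row (by probeset,
making intensities comparable across platforms) or column-by-column (by
sample).  Vectors with MAD = 0 are set to zeros and flagged rather than
dropped, preserving row alignment across species.  Two identically
normalized per-species matrices are merged on an ortholog probeset pairing
by concatenating sample columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from xspecies.containers import ExpressionMatrix, MergedMatrix, check_annotation


@dataclass
class NormalizationResult:
    matrix: ExpressionMatrix
    mad_zero: list[str]  # probeset or sample ids whose MAD was zero


def _median_mad_normalize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize rows of ``values``; returns (normalized, mad_zero_mask)."""
    med = np.median(values, axis=1, keepdims=True)
    centered = values - med
    mad = np.median(np.abs(centered), axis=1, keepdims=True)
    zero = (mad == 0).ravel()
    safe = np.where(mad == 0, 1.0, mad)
    out = centered / safe
    out[zero, :] = 0.0
    return out, zero


def normalize_by_probeset(m: ExpressionMatrix) -> NormalizationResult:
    """Center each row on median zero and scale by its MAD.

    Requires a ``raw`` matrix (re-normalization is rejected).  Rows whose
    MAD is zero are zeroed and listed in ``mad_zero``.  The MAD carries no
    consistency factor: the scale is exactly median(|x − median(x)|).
    """
    if m.scale_tag != "raw":
        raise ValueError(
            f"normalize_by_probeset requires a raw matrix, got {m.scale_tag!r}"
        )
    out, zero = _median_mad_normalize(m.values())
    flagged = [pid for pid, z in zip(m.probeset_ids, zero) if z]
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return NormalizationResult(ExpressionMatrix(data, "by_probeset"), flagged)


def normalize_by_sample(m: ExpressionMatrix) -> NormalizationResult:
    """Column-wise analogue of :func:`normalize_by_probeset`."""
    if m.scale_tag != "raw":
        raise ValueError(
            f"normalize_by_sample requires a raw matrix, got {m.scale_tag!r}"
        )
    out, zero = _median_mad_normalize(m.values().T)
    flagged = [sid for sid, z in zip(m.sample_ids, zero) if z]
    data = pd.DataFrame(out.T, index=m.data.index, columns=m.data.columns)
    return NormalizationResult(ExpressionMatrix(data, "by_sample"), flagged)


def merge_matrices(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    pairing: pd.DataFrame,
    annot_a: pd.DataFrame,
    annot_b: pd.DataFrame,
) -> MergedMatrix:
    """Merge two normalized per-species matrices on a probeset pairing.

    Rows follow pairing order, keyed ``probeset_a|probeset_b``; columns are
    the species-A samples followed by the species-B samples.  Values are
    copied bit-for-bit — no renormalization happens here.
    """
    if m_a.scale_tag != m_b.scale_tag:
        raise ValueError(
            "scale_tag mismatch: normalize both sides identically before merging "
            f"(got {m_a.scale_tag!r} vs {m_b.scale_tag!r})"
        )
    if m_a.scale_tag not in ("by_probeset", "by_sample"):
        raise ValueError("merge requires normalized matrices (by_probeset or by_sample)")
    check_annotation(annot_a)
    check_annotation(annot_b)

    for col, m, side in (("probeset_a", m_a, "A"), ("probeset_b", m_b, "B")):
        missing = set(pairing[col]) - set(m.data.index)
        if missing:
            raise ValueError(
                f"probeset {sorted(missing)[0]!r} from pairing not in species-{side} matrix"
            )

    rows_a = m_a.data.loc[pairing["probeset_a"]].to_numpy()
    rows_b = m_b.data.loc[pairing["probeset_b"]].to_numpy()
    keys = [
        f"{pa}|{pb}" for pa, pb in zip(pairing["probeset_a"], pairing["probeset_b"])
    ]
    values = np.hstack([rows_a, rows_b])
    columns = list(m_a.data.columns) + list(m_b.data.columns)
    data = pd.DataFrame(values, index=keys, columns=columns)
    merged = ExpressionMatrix(data, m_a.scale_tag)
    annotation = pd.concat([annot_a, annot_b], ignore_index=True)
    return MergedMatrix(merged, annotation)


def apply_tissue_drop_list(
    m: ExpressionMatrix,
    annotation: pd.DataFrame,
    drop_tissues: list[str] | None = None,
    max_species_ratio: float | None = None,
    other_annotation: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove samples of tissue categories dominated by one species.

    The default mechanism is an explicit ``drop_tissues`` list (the study
    removed e.g. mammary-gland and hematopoietic samples this way).
    Alternatively, with ``max_species_ratio`` and the other species'
    annotation, any tissue whose sample-count ratio between species exceeds
    the threshold (or is present in only one species) is dropped.
    """
    check_annotation(annotation)
    drop = set(drop_tissues or [])
    if max_species_ratio is not None:
        if other_annotation is None:
            raise ValueError("max_species_ratio requires other_annotation")
        counts_here = annotation["tissue"].value_counts()
        counts_other = other_annotation["tissue"].value_counts()
        for tissue in set(counts_here.index) | set(counts_other.index):
            a = counts_here.get(tissue, 0)
            b = counts_other.get(tissue, 0)
            if a == 0 or b == 0 or max(a, b) / min(a, b) > max_species_ratio:
                drop.add(tissue)
    keep = annotation.loc[~annotation["tissue"].isin(drop)]
    kept_matrix = ExpressionMatrix(
        m.data.loc[:, list(keep["sample_id"])], m.scale_tag
    )
    return kept_matrix, keep.reset_index(drop=True)
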