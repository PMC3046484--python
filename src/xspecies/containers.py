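"""Core in-memory containers shared by all pipeline stages.

An :class:`ExpressionMatrix` is a probeset x sample table of RMA-like log2
intensities, carried as a pandas DataFrame plus a ``scale_tag`` that records
which normalization (if any) has been applied.  Downstream stages refuse
matrices on the wrong scale rather than silently renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALE_TAGS = ("raw", "by_probeset", "by_sample")

ANNOTATION_COLUMNS = ["sample_id", "species", "tissue", "experiment"]


@dataclass
class ExpressionMatrix:
    """Probeset x sample expression matrix with a normalization tag.

    Parameters
    ----------
    data:
        DataFrame indexed by probeset id with sample ids as columns.
    scale_tag:
        One of ``raw``, ``by_probeset``, ``by_sample``.
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate probeset id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "probeset_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scale_tag: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probeset_id")
        return cls(df.astype(float), scale_tag=scale_tag)


@dataclass
class MergedMatrix:
    """Two-species matrix merged on ortholog probeset pairs.

    Rows are keyed ``probeset_a|probeset_b``; columns are the species-A
    samples followed by the species-B samples.  ``annotation`` covers every
    column (sample_id, species, tissue, experiment).
    """

    matrix: ExpressionMatrix
    annotation: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        annotated = set(self.annotation["sample_id"])
        cols = set(self.matrix.sample_ids)
        if annotated != cols:
            raise ValueError("annotation sample ids do not match matrix columns")


def check_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample annotation table and return it.

    Requires the four canonical columns and unique sample ids.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if annotation["sample_id"].duplicated().any():
        dup = annotation.loc[annotation["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in annotation: {dup!r}")
    return annotation


def read_annotation(path) -> pd.DataFrame:
    return check_annotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annotation: pd.DataFrame, path) -> None:
    check_annotation(annotation).to_csv(path, sep="\t", index=False)
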