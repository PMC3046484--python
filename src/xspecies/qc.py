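"""Array-level quality filtering on precomputed QC metrics.

Arrays are kept only if all six metrics fall inside their acceptance ranges:
average background (AvgBg), percent-present calls (PP), RNA degradation
slope (RNAdeg), scale factors (sfs), and the probe-level-model summaries
normalized unscaled standard error (nuse) and relative log expression (rle).
Computing these metrics from raw CEL files is out of scope; this module
consumes a metrics table.

All bounds are inclusive except RNAdeg, which is a strict upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

QC_METRICS = ("AvgBg", "PP", "RNAdeg", "sfs", "nuse", "rle")


@dataclass(frozen=True)
class QCThresholds:
    """Acceptance ranges for the six array QC metrics.

    Defaults: AvgBg 20–150; PP 25–65 (percent); RNAdeg < 1.7 (strict);
    sfs 0.1–2.5; nuse 0.97–1.05; rle −0.15–0.15.
    """

    avgbg_range: tuple[float, float] = (20.0, 150.0)
    pp_range: tuple[float, float] = (25.0, 65.0)
    rnadeg_max: float = 1.7
    sfs_range: tuple[float, float] = (0.1, 2.5)
    nuse_range: tuple[float, float] = (0.97, 1.05)
    rle_range: tuple[float, float] = (-0.15, 0.15)

    def __post_init__(self) -> None:
        for name in ("avgbg_range", "pp_range", "sfs_range", "nuse_range", "rle_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(f"{name} bounds must be finite")
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if not math.isfinite(self.rnadeg_max):
            raise ValueError("rnadeg_max must be finite")

    def as_ranges(self) -> dict[str, tuple[float | None, float | None]]:
        """Map metric name to (lower, upper); RNAdeg has no lower bound."""
        return {
            "AvgBg": self.avgbg_range,
            "PP": self.pp_range,
            "RNAdeg": (None, self.rnadeg_max),
            "sfs": self.sfs_range,
            "nuse": self.nuse_range,
            "rle": self.rle_range,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        known = {
            "avgbg_range", "pp_range", "rnadeg_max",
            "sfs_range", "nuse_range", "rle_range",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        kwargs = {
            k: (tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in d.items()
        }
        return cls(**kwargs)


DEFAULT_THRESHOLDS = QCThresholds()


def _violations(row: pd.Series, thresholds: QCThresholds) -> list[str]:
    bad = []
    ranges = thresholds.as_ranges()
    for metric in QC_METRICS:
        lo, hi = ranges[metric]
        v = row[metric]
        if metric == "RNAdeg":
            # the degradation slope bound is strict: 1.7 itself fails
            if v >= hi:
                bad.append(f"RNAdeg>={hi}")
        else:
            if v < lo:
                bad.append(f"{metric}<{lo}")
            elif v > hi:
                bad.append(f"{metric}>{hi}")
    return bad


def filter_arrays(
    metrics: pd.DataFrame, thresholds: QCThresholds = DEFAULT_THRESHOLDS
) -> tuple[list[str], pd.DataFrame]:
    """Partition arrays into a pass list and a per-criterion failure report.

    Parameters
    ----------
    metrics:
        Table with columns ``array_id`` plus the six QC metrics; all metric
        cells must be numeric and present.
    thresholds:
        Acceptance ranges.

    Returns
    -------
    (pass_ids, report) where ``report`` has one row per failing array with a
    comma-separated ``failed_criteria`` column listing *every* violated
    criterion.
    """
    if "array_id" not in metrics.columns:
        raise ValueError("metrics table missing column 'array_id'")
    missing = [c for c in QC_METRICS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    for metric in QC_METRICS:
        col = pd.to_numeric(metrics[metric], errors="coerce")
        if col.isna().any():
            bad_id = metrics.loc[col.isna(), "array_id"].iloc[0]
            raise ValueError(
                f"non-numeric or missing {metric} value for array {bad_id!r}"
            )
    metrics = metrics.assign(**{m: pd.to_numeric(metrics[m]) for m in QC_METRICS})

    passed: list[str] = []
    failed_rows = []
    for _, row in metrics.iterrows():
        bad = _violations(row, thresholds)
        if bad:
            failed_rows.append(
                {"array_id": row["array_id"], "failed_criteria": ",".join(bad)}
            )
        else:
            passed.append(row["array_id"])
    report = pd.DataFrame(failed_rows, columns=["array_id", "failed_criteria"])
    return passed, report
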