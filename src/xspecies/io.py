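"""Readers/writers for the pipeline's plain-text interchange formats.

Expression TSV: first column ``probeset_id``, remaining columns sample ids.
Annotation TSV: ``sample_id``, ``species``, ``tissue``, ``experiment``.
Ortholog TSV: ``gene_a``, ``gene_b``.  Probe FASTA headers:
``>{probeset_id}|{probe_index}|{gene_id}``.  QC TSV: ``array_id`` plus the
six metric columns.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from xspecies.qc import QC_METRICS
from xspecies.synthgen import ProbesetRecord


def write_probe_fasta(probesets: dict[str, ProbesetRecord], path) -> None:
    records = []
    for probeset_id in sorted(probesets):
        rec = probesets[probeset_id]
        for idx, seq in enumerate(rec.probes):
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=f"{rec.probeset_id}|{idx}|{rec.gene_id}",
                    description="",
                )
            )
    SeqIO.write(records, path, "fasta")


def read_probe_fasta(path) -> dict[str, ProbesetRecord]:
    """Parse probe FASTA back into per-probeset records.

    Probes are restored in probe-index order regardless of file order.
    """
    staged: dict[str, dict] = {}
    for rec in SeqIO.parse(path, "fasta"):
        try:
            probeset_id, idx, gene_id = rec.id.split("|")
        except ValueError as exc:
            raise ValueError(
                f"malformed probe FASTA header {rec.id!r}; "
                "expected probeset_id|probe_index|gene_id"
            ) from exc
        entry = staged.setdefault(probeset_id, {"gene": gene_id, "probes": {}})
        if entry["gene"] != gene_id:
            raise ValueError(f"conflicting gene ids for probeset {probeset_id!r}")
        entry["probes"][int(idx)] = str(rec.seq).upper()
    return {
        pid: ProbesetRecord(
            pid, entry["gene"], [entry["probes"][i] for i in sorted(entry["probes"])]
        )
        for pid, entry in staged.items()
    }


def read_ortholog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValueError(f"ortholog table missing column {col!r}")
    return df


def write_ortholog_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pairing_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str,
                                            "probeset_a": str, "probeset_b": str})
    needed = ["gene_a", "gene_b", "probeset_a", "probeset_b"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"pairing table missing columns: {missing}")
    return df


def write_pairing_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_qc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("array_id", *QC_METRICS) if c not in df.columns]
    if missing:
        raise ValueError(f"QC table missing columns: {missing}")
    return df


def write_qc_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
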