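"""FASTQ / TSV plumbing shared by the simulator and the pipeline."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import BarcodeSpec, ReadRecord

__all__ = ["write_fastq", "read_fastq", "read_barcode_table", "write_barcode_table"]

_QUALITY = 40  # constant Phred quality: the generator models no base errors


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    """Write 4-line FASTQ (Phred+33, constant quality 'I'); returns count."""
    records = (
        SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description="",
            letter_annotations={"phred_quality": [_QUALITY] * len(r.sequence)},
        )
        for r in reads
    )
    return SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[ReadRecord]:
    return [ReadRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]


def read_barcode_table(path) -> list[BarcodeSpec]:
    """Read a ``sample<TAB>barcode`` table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"], dtype=str)
    return [BarcodeSpec(row["sample"], row.barcode) for _, row in df.iterrows()]


def write_barcode_table(barcodes: Iterable[BarcodeSpec], path) -> None:
    with open(path, "w") as handle:
        for spec in barcodes:
            handle.write(f"{spec.sample_name}\t{spec.barcode}\n")
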