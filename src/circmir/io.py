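"""File-format helpers: FASTQ/FASTA via Biopython, TSV via pandas.

FASTQ reading is gzip-transparent.  Synthetic reads are written with
Sanger-encoded dummy qualities.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import DemuxResult, ReadRecord

__all__ = ["read_fastq", "write_fastq", "write_insert_fastas", "write_tally"]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> list[ReadRecord]:
    with _open_text(path) as fh:
        return [
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                quality="".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                ),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        qual = r.quality or "I" * len(r.sequence)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_insert_fastas(
    results: Iterable[DemuxResult], out_dir, prefix: str = "inserts"
) -> dict[str, Path]:
    """One FASTA of kept inserts per barcode id; returns barcode -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_barcode: dict[str, list[DemuxResult]] = {}
    for res in results:
        if res.status == "kept":
            by_barcode.setdefault(res.assignment, []).append(res)
    paths = {}
    for barcode, items in sorted(by_barcode.items()):
        path = out_dir / f"{prefix}.{barcode}.fasta"
        with open(path, "w") as fh:
            for res in items:
                fh.write(f">{res.read_id}\n{res.insert}\n")
        paths[barcode] = path
    return paths


def write_tally(tally: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tcount\n")
        for cls, count in tally.items():
            fh.write(f"{cls}\t{count}\n")
        fh.write(f"total\t{sum(tally.values())}\n")
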