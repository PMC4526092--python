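"""Barcode decoding and insert extraction.

Reads carry a six-nucleotide barcode at the 5' end followed by the small-RNA
insert and, optionally, a 3' adaptor.  Decoding allows one mismatch in the
barcode region but requires the match to be unique: a tag within Hamming
distance 1 of two different barcodes is ambiguous and discarded.  An ``N``
base mismatches everything, including another ``N``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "ReadRecord",
    "BarcodeTable",
    "DemuxResult",
    "AMBIGUOUS",
    "UNMATCHED",
    "BARCODE_LENGTH",
    "hamming_distance",
    "assign_barcode",
    "extract_insert",
    "demultiplex",
    "FILTER_CLASSES",
]

BARCODE_LENGTH = 6

#: sentinel assignments
AMBIGUOUS = "ambiguous"
UNMATCHED = "unmatched"

FILTER_CLASSES = (
    "kept",
    "no_insert",
    "low_quality",
    "ambiguous_barcode",
    "unmatched_barcode",
)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read in base space."""

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: sequence must be nonempty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


class BarcodeTable:
    """Mapping of barcode id -> six-nucleotide tag sequence."""

    def __init__(self, barcodes: dict[str, str]):
        if not barcodes:
            raise ValueError("barcode table must not be empty")
        for bid, seq in barcodes.items():
            if len(seq) != BARCODE_LENGTH:
                raise ValueError(f"barcode {bid!r} has length {len(seq)}, expected 6")
        seqs = list(barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcode sequences must be pairwise distinct")
        self.barcodes = dict(barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)

    def items(self):
        return self.barcodes.items()

    def __getitem__(self, bid: str) -> str:
        return self.barcodes[bid]

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTable":
        """Two-column TSV (id, sequence); a header line 'id\\tsequence' is
        tolerated."""
        barcodes: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                bid, seq = line.split("\t")[:2]
                if bid.lower() in ("id", "barcode_id") and seq.lower() == "sequence":
                    continue
                barcodes[bid] = seq.upper()
        return cls(barcodes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsequence\n")
            for bid, seq in self.barcodes.items():
                fh.write(f"{bid}\t{seq}\n")


def hamming_distance(a: str, b: str) -> int:
    """Positional mismatch count; ``N`` mismatches every base (even ``N``)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def assign_barcode(tag: str, table: BarcodeTable) -> str:
    """Decode a six-base tag against the barcode table.

    Returns the unique barcode id at Hamming distance <= 1, the sentinel
    :data:`AMBIGUOUS` if two or more barcodes are within distance 1, or
    :data:`UNMATCHED` if none is.
    """
    if len(tag) != BARCODE_LENGTH:
        raise ValueError(f"tag length {len(tag)} != {BARCODE_LENGTH}")
    near = [bid for bid, seq in table.items() if hamming_distance(tag, seq) <= 1]
    if not near:
        return UNMATCHED
    if len(near) > 1:
        return AMBIGUOUS
    return near[0]


def extract_insert(
    read: ReadRecord,
    adaptor: Optional[str],
    barcode_len: int = BARCODE_LENGTH,
    min_len: int = 1,
) -> Optional[str]:
    """Extract the insert between the barcode region and the 3' adaptor.

    The insert ends at the leftmost exact adaptor occurrence after the
    barcode; a read without any adaptor occurrence keeps its full
    post-barcode sequence.  Returns ``None`` (no insert) when the adaptor
    starts immediately after the barcode or the insert is shorter than
    ``min_len``.
    """
    if adaptor is not None and not adaptor:
        raise ValueError("adaptor must be nonempty (or None to disable trimming)")
    region = read.sequence[barcode_len:]
    if adaptor is not None:
        pos = region.find(adaptor)
        if pos != -1:
            region = region[:pos]
    if len(region) < min_len:
        return None
    return region


@dataclass(frozen=True)
class DemuxResult:
    read_id: str
    assignment: str  # barcode id, AMBIGUOUS, or UNMATCHED
    insert: Optional[str]
    status: str  # one of FILTER_CLASSES


def _mean_phred(quality: str) -> float:
    return sum(ord(c) - 33 for c in quality) / len(quality)


def demultiplex(
    reads: Iterable[ReadRecord],
    table: BarcodeTable,
    adaptor: Optional[str] = None,
    min_len: int = 15,
    max_len: int = 35,
    min_mean_quality: Optional[float] = None,
) -> tuple[list[DemuxResult], dict[str, int]]:
    """Assign every read to exactly one filter class.

    Kept reads are uniquely barcode-decoded and carry an insert whose length
    lies in ``[min_len, max_len]``.  Inserts outside that window count as
    ``no_insert``.  Quality filtering (mean Phred below ``min_mean_quality``)
    is off by default.  The per-class tally always sums to the number of
    input reads.
    """
    results: list[DemuxResult] = []
    tally: Counter[str] = Counter({c: 0 for c in FILTER_CLASSES})
    for read in reads:
        if len(read.sequence) < BARCODE_LENGTH:
            res = DemuxResult(read.id, UNMATCHED, None, "unmatched_barcode")
            results.append(res)
            tally[res.status] += 1
            continue
        assignment = assign_barcode(read.sequence[:BARCODE_LENGTH], table)
        if assignment == UNMATCHED:
            status = "unmatched_barcode"
            insert = None
        elif assignment == AMBIGUOUS:
            status = "ambiguous_barcode"
            insert = None
        elif (
            min_mean_quality is not None
            and read.quality is not None
            and _mean_phred(read.quality) < min_mean_quality
        ):
            status = "low_quality"
            insert = None
        else:
            insert = extract_insert(read, adaptor, min_len=1)
            if insert is None or not (min_len <= len(insert) <= max_len):
                status = "no_insert"
                insert = None
            else:
                status = "kept"
        results.append(DemuxResult(read.id, assignment, insert, status))
        tally[status] += 1
    return results, dict(tally)
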