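"""Expression profiles: reliability filtering, counts-per-million
normalization, and abundance / exclusive-detection sets.

The reliable expression profile keeps features with raw count strictly
greater than 10 and is then normalized against a total of 1,000,000, i.e.
each feature's value is its share of the post-filter library scaled to CPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet

import pandas as pd

__all__ = [
    "CountTable",
    "NormalizedTable",
    "filter_reliable",
    "normalize_cpm",
    "abundant_set",
    "exclusive_features",
]


@dataclass
class CountTable:
    """Raw per-feature read counts for one library."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative counts: {bad}")

    @property
    def size(self) -> int:
        """Library size N = sum of stored counts."""
        return int(sum(self.counts.values()))

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, feature: str, default: int = 0) -> int:
        return self.counts.get(feature, default)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"feature": list(self.counts), "count": list(self.counts.values())}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, library_id: str = "") -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            library_id=library_id or str(path),
            counts=dict(zip(df["feature"].astype(str), df["count"].astype(int))),
        )


@dataclass
class NormalizedTable:
    """Counts-per-million profile; values sum to 1e6 when derived from a
    full (undropped) count table."""

    library_id: str
    cpm: dict[str, float] = field(default_factory=dict)

    def get(self, feature: str, default: float = 0.0) -> float:
        return self.cpm.get(feature, default)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"feature": list(self.cpm), "cpm": list(self.cpm.values())})
        df.to_csv(path, sep="\t", index=False)


def filter_reliable(table: CountTable, min_count: int = 10) -> CountTable:
    """Keep features with count strictly greater than ``min_count``.

    The boundary is exclusive: a feature at exactly ``min_count`` is
    dropped.  The library size of the result is recomputed over the
    retained features.
    """
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    return CountTable(
        library_id=table.library_id,
        counts={k: v for k, v in table.counts.items() if v > min_count},
    )


def normalize_cpm(table: CountTable) -> NormalizedTable:
    """Scale each count to counts-per-million of the library total."""
    n = table.size
    if n <= 0:
        raise ValueError(f"library {table.library_id!r} has zero total count")
    return NormalizedTable(
        library_id=table.library_id,
        cpm={k: v / n * 1_000_000 for k, v in table.counts.items()},
    )


def abundant_set(
    table: CountTable, min_count: int = 20, strict: bool = True
) -> frozenset[str]:
    """Features whose *raw* count exceeds the abundance threshold.

    ``strict=True`` uses count > threshold (the default reading);
    ``strict=False`` uses count >= threshold, exposed because both
    conventions circulate.
    """
    if strict:
        return frozenset(k for k, v in table.counts.items() if v > min_count)
    return frozenset(k for k, v in table.counts.items() if v >= min_count)


def exclusive_features(
    set_a: AbstractSet[str], set_b: AbstractSet[str]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition two detection sets into (only_a, only_b, shared)."""
    a, b = frozenset(set_a), frozenset(set_b)
    return a - b, b - a, a & b
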