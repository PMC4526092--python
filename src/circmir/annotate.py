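"""Small-RNA category annotation of sequenced inserts.

Inserts surviving demultiplexing are classified against a category-labelled
reference set (miRNA / miRNA* / tRNA / rRNA / snRNA / snoRNA).  Non-miRNA
categories are filtered *first*: an insert matching both a tRNA and a miRNA
reference is counted as tRNA, mirroring the filter-then-count order of
small-RNA pipelines.  Per-feature read counts are produced for miRNA and
miRNA* species only; known tRNA-fragment decoys (features annotated as
miRNAs but actually deriving from tRNA) can be struck from count tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "RefRecord",
    "ReferenceSet",
    "AnnotationSummary",
    "classify_insert",
    "annotate_library",
    "apply_fragment_exclusion",
    "CATEGORY_PRIORITY",
]

#: Filtering cascade: non-coding housekeeping RNAs take precedence over
#: miRNA/miRNA* so that reads deriving from abundant structural RNAs are
#: never counted toward miRNA expression.  miRNA and miRNA* share the final
#: tier.
CATEGORY_PRIORITY: tuple[tuple[str, ...], ...] = (
    ("rRNA",),
    ("tRNA",),
    ("snRNA",),
    ("snoRNA",),
    ("miRNA", "miRNA*"),
)

VALID_CATEGORIES = frozenset(c for tier in CATEGORY_PRIORITY for c in tier)


@dataclass(frozen=True)
class RefRecord:
    """One reference sequence with its RNA category label."""

    name: str
    sequence: str
    category: str
    excluded_as_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference name must be nonempty")
        if not self.sequence:
            raise ValueError(f"reference {self.name!r} has an empty sequence")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for {self.name!r}; "
                f"expected one of {sorted(VALID_CATEGORIES)}"
            )
        if self.category == "miRNA*" and not self.name.endswith("*"):
            raise ValueError(f"star-strand reference {self.name!r} must end with '*'")


class ReferenceSet:
    """Category-labelled small-RNA references with unique names."""

    def __init__(self, records: Iterable[RefRecord]):
        self.records: list[RefRecord] = list(records)
        if not self.records:
            raise ValueError("reference set must not be empty")
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate reference names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_category(self, *categories: str) -> list[RefRecord]:
        want = set(categories)
        return [r for r in self.records if r.category in want]

    @property
    def excluded_names(self) -> frozenset[str]:
        return frozenset(r.name for r in self.records if r.excluded_as_fragment)

    # FASTA round trip; header convention "name|category|flags"
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                flag = "fragment" if r.excluded_as_fragment else "-"
                fh.write(f">{r.name}|{r.category}|{flag}\n{r.sequence}\n")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        from Bio import SeqIO

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description or rec.id
            parts = header.split("|")
            if len(parts) < 2:
                raise ValueError(f"malformed reference header {header!r}")
            name, category = parts[0], parts[1]
            flag = parts[2] if len(parts) > 2 else "-"
            records.append(
                RefRecord(
                    name=name,
                    sequence=str(rec.seq).upper(),
                    category=category,
                    excluded_as_fragment=(flag == "fragment"),
                )
            )
        return cls(records)


def _matches(insert: str, ref_seq: str, mismatches: int) -> bool:
    """Containment match: the shorter sequence occurs in the longer with at
    most ``mismatches`` substitutions at some offset (no indels)."""
    if mismatches == 0:
        return insert in ref_seq or ref_seq in insert
    short, long_ = (insert, ref_seq) if len(insert) <= len(ref_seq) else (ref_seq, insert)
    ls, ll = len(short), len(long_)
    for off in range(ll - ls + 1):
        d = 0
        window = long_[off : off + ls]
        for a, b in zip(short, window):
            if a != b:
                d += 1
                if d > mismatches:
                    break
        else:
            return True
    return False


def _candidates(insert: str, refs: ReferenceSet, mismatches: int) -> list[RefRecord]:
    """All references in the *highest-priority* matching tier, name-sorted."""
    for tier in CATEGORY_PRIORITY:
        hits = [
            r
            for r in refs.records
            if r.category in tier and _matches(insert, r.sequence, mismatches)
        ]
        if hits:
            return sorted(hits, key=lambda r: r.name)
    return []


def classify_insert(
    insert: str, refs: ReferenceSet, mismatches: int = 0
) -> tuple[Optional[str], Optional[str]]:
    """Classify one insert.

    Returns ``(category, feature_name)``; the feature name is reported only
    for miRNA/miRNA* hits.  Unannotated inserts return ``(None, None)``.
    Within-category ties are broken by the lexicographically smallest
    feature name.
    """
    if not insert:
        raise ValueError("insert must be nonempty")
    if len(refs) == 0:  # pragma: no cover - ReferenceSet forbids this
        raise ValueError("empty reference set")
    hits = _candidates(insert, refs, mismatches)
    if not hits:
        return None, None
    best = hits[0]
    if best.category in ("miRNA", "miRNA*"):
        return best.category, best.name
    return best.category, None


@dataclass
class AnnotationSummary:
    """Per-library annotation tallies: the species-composition and
    length-distribution summaries plus raw per-miRNA counts."""

    library_id: str
    category_counts: dict[str, int] = field(default_factory=dict)
    unannotated: int = 0
    length_counts: dict[int, int] = field(default_factory=dict)
    feature_counts: dict[str, int] = field(default_factory=dict)
    ambiguous_within_category: int = 0

    @property
    def total(self) -> int:
        return sum(self.category_counts.values()) + self.unannotated

    @property
    def percentages(self) -> dict[str, float]:
        """Category percentages over all inserts (including unannotated);
        sums to 100 up to rounding."""
        n = self.total
        if n == 0:
            return {}
        out = {c: 100.0 * v / n for c, v in self.category_counts.items()}
        out["unannotated"] = 100.0 * self.unannotated / n
        return out

    def mirna_star_split(self) -> tuple[int, int]:
        """(#distinct miRNA features, #distinct miRNA* features) detected."""
        stars = sum(1 for f in self.feature_counts if f.endswith("*"))
        return len(self.feature_counts) - stars, stars


def annotate_library(
    inserts: Sequence[str],
    refs: ReferenceSet,
    mismatches: int = 0,
    library_id: str = "",
) -> AnnotationSummary:
    """Annotate a library of inserts and tally composition.

    Classification is memoised over distinct insert sequences, which keeps
    the naive containment scan fast on deep libraries (small-RNA libraries
    have many identical reads).
    """
    if len(inserts) == 0:
        raise ValueError("insert collection must be nonempty")
    summary = AnnotationSummary(library_id=library_id)
    cat_counts: Counter[str] = Counter()
    len_counts: Counter[int] = Counter()
    feat_counts: Counter[str] = Counter()
    cache: dict[str, tuple[Optional[str], Optional[str], bool]] = {}
    for ins in inserts:
        hit = cache.get(ins)
        if hit is None:
            cands = _candidates(ins, refs, mismatches)
            if not cands:
                hit = (None, None, False)
            else:
                best = cands[0]
                ambiguous = len(cands) > 1
                if best.category in ("miRNA", "miRNA*"):
                    hit = (best.category, best.name, ambiguous)
                else:
                    hit = (best.category, None, ambiguous)
            cache[ins] = hit
        category, feature, ambiguous = hit
        len_counts[len(ins)] += 1
        if category is None:
            summary.unannotated += 1
            continue
        cat_counts[category] += 1
        if ambiguous:
            summary.ambiguous_within_category += 1
        if feature is not None:
            feat_counts[feature] += 1
    summary.category_counts = dict(cat_counts)
    summary.length_counts = dict(sorted(len_counts.items()))
    summary.feature_counts = dict(feat_counts)
    return summary


def apply_fragment_exclusion(
    counts: Mapping[str, int], refs: ReferenceSet
) -> dict[str, int]:
    """Drop features annotated as fragments of other RNA classes (e.g. a
    'miRNA' that is in fact a tRNA cleavage product) from a count table."""
    excluded = refs.excluded_names
    return {k: v for k, v in counts.items() if k not in excluded}
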