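"""Synthetic serum/plasma small-RNA data with known ground truth.

The generator emulates the statistical structure of a pooled two-library
circulating-miRNA sequencing experiment: base-space reads laid out as
barcode(6 nt) + insert (+ optional 3' adaptor in "raw mode"), insert
lengths peaked at 22 nt, library compositions that differ between fluids
(plasma dominated by miRNA, serum by tRNA), and per-feature counts drawn
as Poisson with configurable truly-differential features and
serum-exclusive features.  All randomness flows from a single integer
seed, so identical configurations reproduce outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import RefRecord, ReferenceSet
from .demux import BARCODE_LENGTH, ReadRecord
from .quantify import CountTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_references",
    "simulate_reads",
    "simulate_counts",
    "simulate_qpcr",
    "simulate_target_map",
    "simulate_term_map",
]

BASES = np.array(list("ACGT"))

#: Default library compositions: the serum pool is tRNA-dominated (~75%)
#: with ~21% miRNA, while plasma is miRNA-dominated (~52%).
DEFAULT_CATEGORY_FRACTIONS: dict[str, dict[str, float]] = {
    "serum": {"miRNA": 0.2102, "tRNA": 0.7461, "rRNA": 0.02, "snRNA": 0.01, "snoRNA": 0.0137},
    "plasma": {"miRNA": 0.5204, "tRNA": 0.36, "rRNA": 0.05, "snRNA": 0.03, "snoRNA": 0.0396},
}

#: Insert lengths peaked at the canonical 22-nt Dicer product.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {20: 0.05, 21: 0.20, 22: 0.50, 23: 0.15, 24: 0.10}

#: Typical reference lengths per non-miRNA category.
_CATEGORY_REF_LENGTH = {"tRNA": 75, "rRNA": 120, "snRNA": 95, "snoRNA": 80}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic serum/plasma experiment.

    ``n_reads`` defaults to 1e5 per library (full-scale 2.9M plasma /
    6.9M serum runs are reachable by overriding it).  ``min_cpm``
    guarantees every feature at least that base abundance (in CPM of the
    plasma profile), which is useful when tests require every feature to
    clear detection thresholds.
    """

    seed: int = 0
    n_reads: Mapping[str, int] = field(
        default_factory=lambda: {"serum": 100_000, "plasma": 100_000}
    )
    category_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORY_FRACTIONS.items()}
    )
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    n_mirnas: int = 200
    star_fraction: float = 0.15
    de_fraction: float = 0.10
    de_fold_change: float = 4.0
    de_down_fraction: float = 0.25
    true_fold_changes: Optional[Mapping[str, float]] = None
    serum_exclusive_fraction: float = 0.05
    barcodes: Mapping[str, str] = field(
        default_factory=lambda: {"serum": "AAGGCC", "plasma": "CCTTAA"}
    )
    error_rate: float = 0.0
    overdispersion: float = 0.0
    abundance_sigma: float = 1.0
    min_cpm: float = 0.0
    n_per_other_category: int = 5
    adaptor: str = "CGCCTTGGCCGTACAGCAG"
    with_adaptor: bool = False
    decoy_fragment: bool = True
    qpcr_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for lib, n in self.n_reads.items():
            if n <= 0:
                raise ValueError(f"n_reads[{lib!r}] must be positive")
        for lib, fracs in self.category_fractions.items():
            if not fracs:
                raise ValueError(f"category fractions for {lib!r} must be nonempty")
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category fractions for {lib!r} sum to {total}, not 1")
            if any(not (0 <= f <= 1) for f in fracs.values()):
                raise ValueError(f"category fractions for {lib!r} must lie in [0, 1]")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length distribution sums to {total}, not 1")
        for frac in (
            self.star_fraction,
            self.de_fraction,
            self.de_down_fraction,
            self.serum_exclusive_fraction,
        ):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if not (0 <= self.error_rate <= 1):
            raise ValueError("error rate must lie in [0, 1]")
        if self.de_fold_change <= 0:
            raise ValueError("fold changes must be positive")
        if self.true_fold_changes is not None and any(
            fc <= 0 for fc in self.true_fold_changes.values()
        ):
            raise ValueError("fold changes must be positive")
        seqs = list(self.barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcodes must be pairwise distinct")
        if any(len(s) != BARCODE_LENGTH for s in seqs):
            raise ValueError("barcodes must be 6 nt")

    @property
    def libraries(self) -> list[str]:
        return list(self.n_reads)

    def categories(self) -> list[str]:
        cats: dict[str, None] = {}
        for fracs in self.category_fractions.values():
            for c in fracs:
                cats.setdefault(c, None)
        return list(cats)


@dataclass
class SimTruth:
    """Ground truth channel for testing downstream stages."""

    #: per-library per-feature true sampling proportions (each sums to 1)
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    #: per-feature configured fold change (serum relative to plasma)
    fold_changes: dict[str, float] = field(default_factory=dict)
    #: per-feature label: up | down | ns | serum_only
    de_labels: dict[str, str] = field(default_factory=dict)
    #: per-read origin (read_id, library, barcode_id, category, feature, insert)
    reads: Optional[pd.DataFrame] = None

    def de_features(self) -> frozenset[str]:
        return frozenset(f for f, l in self.de_labels.items() if l in ("up", "down"))

    def serum_exclusive(self) -> frozenset[str]:
        return frozenset(f for f, l in self.de_labels.items() if l == "serum_only")

    def null_features(self) -> frozenset[str]:
        return frozenset(f for f, l in self.de_labels.items() if l == "ns")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng([int(config.seed), stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mirna_names(config: SimConfig) -> tuple[list[str], int]:
    n_star = round(config.star_fraction * config.n_mirnas)
    names = []
    for i in range(config.n_mirnas):
        base = f"mir-{i + 1:04d}"
        names.append(base + "*" if i < n_star else base)
    return names, n_star


def simulate_references(config: SimConfig) -> ReferenceSet:
    """Generate a category-labelled reference set.

    ``round(star_fraction * n_mirnas)`` miRNA entries are star strands
    (names suffixed "*"); each non-miRNA category in the configuration gets
    ``n_per_other_category`` entries of a category-typical length.  When
    ``decoy_fragment`` is set, one extra miRNA-labelled entry is flagged as
    a known tRNA fragment so the downstream exclusion path is exercised.
    """
    if config.n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    categories = config.categories()
    if not categories:
        raise ValueError("category list must be nonempty")
    rng = _rng(config, 1)
    records: list[RefRecord] = []
    seen: set[str] = set()
    names, _ = _mirna_names(config)
    if "miRNA" in categories:
        for name in names:
            length = int(rng.integers(22, 25))
            while True:
                seq = _random_seq(rng, length)
                if seq not in seen:
                    break
            seen.add(seq)
            category = "miRNA*" if name.endswith("*") else "miRNA"
            records.append(RefRecord(name=name, sequence=seq, category=category))
        if config.decoy_fragment:
            records.append(
                RefRecord(
                    name="mir-frag-0001",
                    sequence=_random_seq(rng, 22),
                    category="miRNA",
                    excluded_as_fragment=True,
                )
            )
    for cat in categories:
        if cat in ("miRNA", "miRNA*"):
            continue
        length = _CATEGORY_REF_LENGTH.get(cat, 80)
        for i in range(config.n_per_other_category):
            records.append(
                RefRecord(
                    name=f"{cat.lower()}-{i + 1:03d}",
                    sequence=_random_seq(rng, length),
                    category=cat,
                )
            )
    return ReferenceSet(records)


def _feature_weights(
    rng: np.random.Generator, n: int, sigma: float
) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=sigma, size=n)


def _floor_proportions(p: np.ndarray, floor: float) -> np.ndarray:
    """Water-fill the distribution so every positive entry is >= floor."""
    p = p.copy()
    positive = p > 0
    if floor * positive.sum() > 1:
        raise ValueError("min_cpm floor infeasible for this many features")
    for _ in range(100):
        low = positive & (p < floor)
        if not low.any():
            break
        p[low] = floor
        high = positive & ~low
        residual = 1.0 - floor * low.sum()
        p[high] *= residual / p[high].sum()
    return p


@dataclass
class _MirnaProfile:
    """Per-miRNA truth profile shared by the read and count generators."""

    names: list[str]
    plasma_p: np.ndarray  # within-miRNA-profile proportions, sums to 1
    serum_p: np.ndarray
    fold_changes: dict[str, float]
    labels: dict[str, str]


def _build_mirna_profile(config: SimConfig, rng: np.random.Generator) -> _MirnaProfile:
    names, _ = _mirna_names(config)
    n = len(names)
    idx = rng.permutation(n)
    n_excl = round(config.serum_exclusive_fraction * n)
    n_de = round(config.de_fraction * n)
    exclusive = {names[i] for i in idx[:n_excl]}
    de_names = [names[i] for i in idx[n_excl : n_excl + n_de]]
    n_down = round(config.de_down_fraction * n_de)

    fold_changes = {name: 1.0 for name in names}
    for rank, name in enumerate(de_names):
        up = rank >= n_down
        fold_changes[name] = (
            config.de_fold_change if up else 1.0 / config.de_fold_change
        )
    if config.true_fold_changes:
        unknown = set(config.true_fold_changes) - set(names)
        if unknown:
            raise ValueError(f"fold changes for unknown features: {sorted(unknown)}")
        fold_changes.update(config.true_fold_changes)

    w = _feature_weights(rng, n, config.abundance_sigma)
    base = w / w.sum()
    if config.min_cpm > 0:
        base = _floor_proportions(base, config.min_cpm / 1e6)
    excl_mask = np.array([name in exclusive for name in names])
    plasma_p = np.where(excl_mask, 0.0, base)
    plasma_p = plasma_p / plasma_p.sum()
    fc = np.array([fold_changes[name] for name in names])
    serum_p = base * fc
    serum_p = serum_p / serum_p.sum()

    labels = {}
    for name in names:
        if name in exclusive:
            labels[name] = "serum_only"
        elif fold_changes[name] > 1:
            labels[name] = "up"
        elif fold_changes[name] < 1:
            labels[name] = "down"
        else:
            labels[name] = "ns"
    return _MirnaProfile(names, plasma_p, serum_p, fold_changes, labels)


def simulate_reads(
    config: SimConfig, refs: ReferenceSet
) -> tuple[list[ReadRecord], SimTruth]:
    """Emit synthetic reads for every configured library.

    Each read samples a category by the library's composition, a feature
    within the category, an insert length from the configured length
    distribution (capped at the reference length), and a uniformly placed
    reference substring of that length.  miRNA feature abundances follow
    the same differential profile as :func:`simulate_counts` (configured
    fold changes and serum-exclusive features); non-miRNA categories use
    fluid-independent abundance weights.  Per-base substitution errors are
    applied to the full read at ``error_rate``.  The truth table records
    every read's origin.
    """
    if len(refs) == 0:
        raise ValueError("reference set must be nonempty")
    rng = _rng(config, 2)
    lengths = np.array(sorted(config.length_distribution))
    length_p = np.array([config.length_distribution[l] for l in lengths], dtype=float)
    length_p = length_p / length_p.sum()
    max_ref_len = max(len(r.sequence) for r in refs.records)
    if lengths.min() > max_ref_len:
        raise ValueError("every requested insert length exceeds all reference lengths")

    profile = _build_mirna_profile(config, rng)
    by_cat: dict[str, list[RefRecord]] = {}
    for r in refs.records:
        cat = "miRNA" if r.category in ("miRNA", "miRNA*") else r.category
        by_cat.setdefault(cat, []).append(r)
    shared_weights = {
        cat: _feature_weights(rng, len(recs), config.abundance_sigma)
        for cat, recs in by_cat.items()
        if cat != "miRNA"
    }

    def mirna_weights(lib: str) -> np.ndarray:
        # weights aligned to by_cat["miRNA"] record order; decoy fragments
        # get a fixed fluid-independent weight so exclusion is exercised
        p = dict(
            zip(profile.names, profile.serum_p if lib == "serum" else profile.plasma_p)
        )
        decoy_w = 1.0 / max(len(profile.names), 1)
        w = np.array([p.get(r.name, decoy_w) for r in by_cat["miRNA"]])
        return w

    reads: list[ReadRecord] = []
    truth_rows: list[tuple] = []
    for lib in config.libraries:
        barcode = config.barcodes[lib]
        fracs = config.category_fractions[lib]
        cats = [c for c in fracs if c in by_cat]
        cat_p = np.array([fracs[c] for c in cats], dtype=float)
        if cat_p.sum() <= 0:
            raise ValueError(f"no reference coverage for library {lib!r}")
        cat_p = cat_p / cat_p.sum()
        n = config.n_reads[lib]
        cat_draw = rng.choice(len(cats), size=n, p=cat_p)
        len_draw = lengths[rng.choice(len(lengths), size=n, p=length_p)]
        feat_draw = np.zeros(n, dtype=np.int64)
        for ci, cat in enumerate(cats):
            mask = cat_draw == ci
            count = int(mask.sum())
            if count == 0:
                continue
            w = mirna_weights(lib) if cat == "miRNA" else shared_weights[cat]
            feat_draw[mask] = rng.choice(len(by_cat[cat]), size=count, p=w / w.sum())
        for i in range(n):
            cat = cats[cat_draw[i]]
            recs = by_cat[cat]
            ref = recs[int(feat_draw[i])]
            insert_len = int(min(len_draw[i], len(ref.sequence)))
            start = int(rng.integers(0, len(ref.sequence) - insert_len + 1))
            insert = ref.sequence[start : start + insert_len]
            seq = barcode + insert
            if config.with_adaptor:
                seq += config.adaptor
            if config.error_rate > 0:
                seq = _apply_errors(rng, seq, config.error_rate)
            read_id = f"{lib}_{i + 1:07d}"
            reads.append(ReadRecord(id=read_id, sequence=seq, quality="I" * len(seq)))
            truth_rows.append((read_id, lib, lib, ref.category, ref.name, insert))
    truth = SimTruth(
        proportions={
            "serum": dict(zip(profile.names, profile.serum_p)),
            "plasma": dict(zip(profile.names, profile.plasma_p)),
        },
        fold_changes=profile.fold_changes,
        de_labels=profile.labels,
        reads=pd.DataFrame(
            truth_rows,
            columns=["read_id", "library", "barcode_id", "category", "feature", "insert"],
        ),
    )
    return reads, truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    for idx in np.flatnonzero(hit):
        alternatives = [b for b in "ACGT" if b != arr[idx]]
        arr[idx] = alternatives[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_counts(
    config: SimConfig,
) -> tuple[CountTable, CountTable, SimTruth]:
    """Draw per-miRNA Poisson count tables for serum and plasma.

    Plasma proportions come from lognormal abundance weights (optionally
    floored at ``min_cpm``); serum proportions are plasma proportions times
    the configured fold change, renormalized.  Serum-exclusive features
    have plasma proportion exactly zero.  ``overdispersion`` > 0 mixes the
    Poisson mean with a Gamma multiplier of unit mean and the given
    variance, for robustness probing; it defaults off, matching the Poisson
    null of the differential test.
    """
    rng = _rng(config, 3)
    profile = _build_mirna_profile(config, rng)
    n = len(profile.names)

    depth = {lib: config.n_reads[lib] for lib in ("serum", "plasma")}
    for lib, d in depth.items():
        if d <= 0:
            raise ValueError(f"depth for {lib} must be positive")

    def draw(p: np.ndarray, d: int) -> np.ndarray:
        mean = p * d
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            mean = mean * rng.gamma(shape, 1.0 / shape, size=n)
        return rng.poisson(mean)

    serum_counts = draw(profile.serum_p, depth["serum"])
    plasma_counts = draw(profile.plasma_p, depth["plasma"])

    truth = SimTruth(
        proportions={
            "serum": dict(zip(profile.names, profile.serum_p)),
            "plasma": dict(zip(profile.names, profile.plasma_p)),
        },
        fold_changes=profile.fold_changes,
        de_labels=profile.labels,
    )
    serum = CountTable(
        "serum", dict(zip(profile.names, (int(c) for c in serum_counts)))
    )
    plasma = CountTable(
        "plasma", dict(zip(profile.names, (int(c) for c in plasma_counts)))
    )
    return serum, plasma, truth


def simulate_qpcr(
    fold_changes: Mapping[str, float],
    config: SimConfig,
    noise_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Emit a triplicate Ct table whose noise-free ddCt encodes the given
    true serum/plasma fold changes.

    Output columns: fluid, miRNA, rep1..rep3, with U6 reference rows per
    fluid.  The plasma-side Ct baseline is fixed; the serum-side miRNA Ct
    is shifted by -log2(fold change) so that 2^(-ddCt) recovers the truth
    exactly at zero noise.  Gaussian replicate noise uses ``noise_sd``
    (default: the config's ``qpcr_noise_sd``).
    """
    if not fold_changes:
        raise ValueError("fold-change mapping must be nonempty")
    if any(fc <= 0 for fc in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    sd = config.qpcr_noise_sd if noise_sd is None else noise_sd
    rng = _rng(config, 4)
    u6_ct = 20.0
    base_ct = 28.0
    rows = []

    def triplicate(center: float) -> list[float]:
        if sd == 0:
            return [center, center, center]
        return list(center + rng.normal(0.0, sd, size=3))

    for fluid in ("serum", "plasma"):
        rows.append([fluid, REFERENCE] + triplicate(u6_ct))
    for mirna in fold_changes:
        rows.append(["plasma", mirna] + triplicate(base_ct))
        rows.append(["serum", mirna] + triplicate(base_ct - math.log2(fold_changes[mirna])))
    return pd.DataFrame(rows, columns=["fluid", "miRNA", "rep1", "rep2", "rep3"])


REFERENCE = "U6"


def simulate_target_map(
    mirnas: Sequence[str],
    n_genes: int = 500,
    targets_per_mirna: int = 40,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random miRNA -> target-gene map over a synthetic gene universe
    g0001..gN; overlapping target sets guarantee genes hit by >= 2 miRNAs."""
    rng = np.random.default_rng([seed, 5])
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    return {
        m: set(rng.choice(genes, size=min(targets_per_mirna, n_genes), replace=False))
        for m in mirnas
    }


def simulate_term_map(
    genes: Sequence[str],
    enriched_genes: Sequence[str],
    n_terms: int = 20,
    term_size: int = 30,
    namespace: str = "GO-process",
    seed: int = 0,
):
    """Random term map over ``genes`` plus one term ("term-0001") seeded
    from ``enriched_genes`` so an enrichment signal exists by construction."""
    from .enrichment import Term, TermMap

    rng = np.random.default_rng([seed, 6])
    genes = list(genes)
    terms = []
    seedset = list(dict.fromkeys(enriched_genes))[:term_size]
    pad = [g for g in genes if g not in seedset]
    take = min(max(term_size - len(seedset), 0), len(pad))
    if take:
        seedset = seedset + list(rng.choice(pad, size=take, replace=False))
    if seedset:
        terms.append(
            Term(id="term-0001", name="seeded enriched term", namespace=namespace,
                 genes=frozenset(seedset))
        )
    for i in range(1, n_terms):
        size = min(term_size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        terms.append(
            Term(
                id=f"term-{i + 1:04d}",
                name=f"random term {i + 1}",
                namespace=namespace,
                genes=frozenset(members),
            )
        )
    return TermMap(terms)
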