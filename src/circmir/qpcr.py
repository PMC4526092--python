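"""Relative quantification by RT-qPCR and cross-platform validation.

Triplicate Ct values are averaged, normalized to the U6 snRNA reference
within each fluid (dCt = Ct_miRNA - Ct_U6), and compared between fluids
(ddCt = dCt_serum - dCt_plasma; fold change = E^(-ddCt) with amplification
efficiency E = 2 by default).  Agreement with sequencing is summarised by
the Pearson correlation of log2 fold changes across the shared miRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "QpcrResult",
    "MeanCt",
    "mean_ct",
    "ddct_fold_change",
    "analyze_ct_table",
    "read_ct_table",
    "PlatformCorrelation",
    "correlate_platforms",
]

REFERENCE_NAME = "U6"


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one miRNA in one fluid."""

    fluid: str  # "serum" | "plasma"
    mirna: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.fluid not in ("serum", "plasma"):
            raise ValueError(f"fluid must be serum or plasma, got {self.fluid!r}")
        finite = [c for c in self.ct_values if math.isfinite(c)]
        if any(not (0 < c <= 45) for c in finite):
            raise ValueError(f"{self.mirna}/{self.fluid}: Ct values must lie in (0, 45]")


class MeanCt(NamedTuple):
    value: float
    n_used: int
    incomplete: bool  # True when fewer than 3 finite replicates were used


def mean_ct(replicates: Sequence[float]) -> MeanCt:
    """Arithmetic mean of the finite replicate Ct values.

    Missing replicates (NaN) are tolerated down to a single value, with the
    ``incomplete`` flag raised; no finite replicate is a hard error.
    """
    finite = [c for c in replicates if math.isfinite(c)]
    if not finite:
        raise ValueError("no finite Ct replicate")
    return MeanCt(sum(finite) / len(finite), len(finite), len(finite) < 3)


@dataclass(frozen=True)
class QpcrResult:
    mirna: str
    dct_serum: float
    dct_plasma: float
    ddct: float
    fold_change: float

    @property
    def log2_fold_change(self) -> float:
        return math.log2(self.fold_change)


def ddct_fold_change(
    ct_mirna_serum: float,
    ct_u6_serum: float,
    ct_mirna_plasma: float,
    ct_u6_plasma: float,
    efficiency: float = 2.0,
    mirna: str = "",
) -> QpcrResult:
    """Serum-vs-plasma fold change from four mean Ct values.

    dCt = Ct_miRNA - Ct_U6 per fluid; ddCt = dCt_serum - dCt_plasma; the
    fold change is efficiency^(-ddCt), with efficiency 2 corresponding to
    perfect doubling per cycle.
    """
    for v in (ct_mirna_serum, ct_u6_serum, ct_mirna_plasma, ct_u6_plasma):
        if not math.isfinite(v):
            raise ValueError("all mean Ct values must be finite")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    dct_s = ct_mirna_serum - ct_u6_serum
    dct_p = ct_mirna_plasma - ct_u6_plasma
    ddct = dct_s - dct_p
    return QpcrResult(
        mirna=mirna,
        dct_serum=dct_s,
        dct_plasma=dct_p,
        ddct=ddct,
        fold_change=efficiency ** (-ddct),
    )


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns fluid, miRNA, rep1, rep2, rep3; U6 reference rows
    are identified by miRNA name 'U6'."""
    df = pd.read_csv(path, sep="\t")
    required = {"fluid", "miRNA", "rep1", "rep2", "rep3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def analyze_ct_table(
    ct: pd.DataFrame, efficiency: float = 2.0
) -> list[QpcrResult]:
    """Compute per-miRNA ddCt fold changes from a tidy Ct table."""
    rep_cols = ["rep1", "rep2", "rep3"]

    def fluid_means(fluid: str) -> dict[str, MeanCt]:
        sub = ct[ct["fluid"] == fluid]
        return {
            row["miRNA"]: mean_ct([float(row[c]) for c in rep_cols])
            for _, row in sub.iterrows()
        }

    serum, plasma = fluid_means("serum"), fluid_means("plasma")
    for fluid, means in (("serum", serum), ("plasma", plasma)):
        if REFERENCE_NAME not in means:
            raise ValueError(f"no {REFERENCE_NAME} reference rows for {fluid}")
    mirnas = sorted((set(serum) & set(plasma)) - {REFERENCE_NAME})
    return [
        ddct_fold_change(
            serum[m].value,
            serum[REFERENCE_NAME].value,
            plasma[m].value,
            plasma[REFERENCE_NAME].value,
            efficiency=efficiency,
            mirna=m,
        )
        for m in mirnas
    ]


class PlatformCorrelation(NamedTuple):
    r: float
    n: int
    defined: bool


def correlate_platforms(
    seq_log2fc: Mapping[str, float], qpcr_log2fc: Mapping[str, float]
) -> PlatformCorrelation:
    """Pearson correlation of sequencing vs qPCR log2 fold changes over the
    shared miRNA names.  Zero variance on either side (or fewer than three
    shared miRNAs) yields an undefined result flagged ``defined=False``.
    """
    shared = sorted(set(seq_log2fc) & set(qpcr_log2fc))
    if len(shared) < 3:
        return PlatformCorrelation(math.nan, len(shared), False)
    a = [seq_log2fc[m] for m in shared]
    b = [qpcr_log2fc[m] for m in shared]
    if len(set(a)) == 1 or len(set(b)) == 1:
        return PlatformCorrelation(math.nan, len(shared), False)
    r = float(stats.pearsonr(a, b).statistic)
    return PlatformCorrelation(r, len(shared), True)
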