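"""Differential expression between two pooled count libraries.

The null model treats each feature's counts in the two libraries as
independent Poisson draws with a common underlying concentration.
Conditioning on the total t = x + y, the serum count x is
Binomial(t, N1/(N1+N2)), which yields an exact two-sided test (the
conditional binomial test for comparing two Poisson rates); an
Audic-Claverie-style posterior-predictive variant is provided as an
alternative.  Calls combine the exact P-value with a fold-change threshold
on CPM (up: FC > f and p < alpha; down: FC < 1/f and p < alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .quantify import CountTable, filter_reliable, normalize_cpm

__all__ = [
    "DEResult",
    "ClusterResult",
    "log2_fold_change",
    "poisson_exact_pvalue",
    "poisson_exact_pvalues",
    "audic_claverie_pvalue",
    "call_differential",
    "hierarchical_cluster",
    "cluster_matrix",
    "to_newick",
]


def log2_fold_change(
    cpm_serum: float, cpm_plasma: float, pseudocount: float = 0.5
) -> float:
    """log2 ratio of the two normalized values.

    When both values are positive the ratio is taken directly; when exactly
    one side is zero a continuity pseudocount (default half a CPM) is added
    to both sides; when both are zero the fold change is undefined and NaN
    is returned.
    """
    if cpm_serum < 0 or cpm_plasma < 0:
        raise ValueError("CPM values must be nonnegative")
    if cpm_serum == 0 and cpm_plasma == 0:
        return math.nan
    if cpm_serum > 0 and cpm_plasma > 0:
        return math.log2(cpm_serum / cpm_plasma)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive when a value is zero")
    return math.log2((cpm_serum + pseudocount) / (cpm_plasma + pseudocount))


def poisson_exact_pvalue(x: int, n1: float, y: int, n2: float) -> float:
    """Exact two-sided P-value for equality of two Poisson rates.

    Conditioned on t = x + y, x ~ Binomial(t, n1/(n1+n2)) under the null;
    the two-sided P doubles the smaller tail and is capped at 1.  The
    degenerate x = y = 0 case carries no evidence and returns 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    t = x + y
    if t == 0:
        return 1.0
    p0 = n1 / (n1 + n2)
    lower = stats.binom.cdf(x, t, p0)
    upper = stats.binom.sf(x - 1, t, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def poisson_exact_pvalues(
    x: np.ndarray, n1: float, y: np.ndarray, n2: float
) -> np.ndarray:
    """Vectorised :func:`poisson_exact_pvalue` over aligned count arrays."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    t = x + y
    p0 = n1 / (n1 + n2)
    with np.errstate(invalid="ignore"):
        lower = stats.binom.cdf(x, t, p0)
        upper = stats.binom.sf(x - 1, t, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(t == 0, 1.0, p)


def audic_claverie_pvalue(x: int, n1: float, y: int, n2: float) -> float:
    """Audic-Claverie-style two-sided P-value.

    Given x tags in library 1, the posterior-predictive distribution of the
    library-2 count is negative binomial with r = x + 1 successes and
    success probability n1/(n1+n2); the two-sided P doubles the smaller
    tail at the observed y.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p0 = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p0)
    upper = stats.nbinom.sf(y - 1, x + 1, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class DEResult:
    """Per-feature differential-expression record (serum vs plasma)."""

    feature: str
    x: int  # raw serum count
    y: int  # raw plasma count
    n1: int  # serum library size (post-filter)
    n2: int  # plasma library size (post-filter)
    cpm_serum: float
    cpm_plasma: float
    log2fc: float
    p_value: float
    call: str  # up | down | ns
    exclusive: str  # serum_only | plasma_only | shared

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "x": self.x,
            "y": self.y,
            "cpm_serum": self.cpm_serum,
            "cpm_plasma": self.cpm_plasma,
            "log2fc": self.log2fc,
            "p_value": self.p_value,
            "call": self.call,
            "exclusive": self.exclusive,
        }


def call_differential(
    serum: CountTable,
    plasma: CountTable,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.001,
    pseudocount: float = 0.5,
    min_count: int = 10,
    apply_reliability_filter: bool = True,
    bh_correct: bool = False,
) -> list[DEResult]:
    """Call differential features between the serum and plasma libraries.

    Both tables first pass the count > ``min_count`` reliability filter
    (disable with ``apply_reliability_filter=False`` if already filtered);
    CPM is computed over each post-filter profile.  The feature universe is
    the union of the two filtered tables, a feature absent from one side
    carrying count 0 there.  Features detected on only one side are flagged
    exclusive and not called; shared features are called up/down/ns against
    the fold-change and P-value thresholds.  ``bh_correct`` applies
    Benjamini-Hochberg across shared features before thresholding (off by
    default: raw thresholds).
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if apply_reliability_filter:
        serum = filter_reliable(serum, min_count)
        plasma = filter_reliable(plasma, min_count)
    features = sorted(set(serum.counts) | set(plasma.counts))
    if not features:
        return []
    n1, n2 = serum.size, plasma.size
    cpm_s = normalize_cpm(serum) if n1 > 0 else NormalizedTableEmpty(serum.library_id)
    cpm_p = normalize_cpm(plasma) if n2 > 0 else NormalizedTableEmpty(plasma.library_id)
    x = np.array([serum.get(f) for f in features], dtype=np.int64)
    y = np.array([plasma.get(f) for f in features], dtype=np.int64)
    pvals = poisson_exact_pvalues(x, max(n1, 1), y, max(n2, 1))
    shared = (x > 0) & (y > 0)
    if bh_correct and shared.any():
        from statsmodels.stats.multitest import multipletests

        adj = pvals.copy()
        adj[shared] = multipletests(pvals[shared], method="fdr_bh")[1]
        pvals = adj
    results: list[DEResult] = []
    for i, f in enumerate(features):
        cs, cp = cpm_s.get(f, 0.0), cpm_p.get(f, 0.0)
        lfc = log2_fold_change(cs, cp, pseudocount)
        if x[i] > 0 and y[i] == 0:
            exclusive = "serum_only"
        elif x[i] == 0 and y[i] > 0:
            exclusive = "plasma_only"
        else:
            exclusive = "shared"
        call = "ns"
        if exclusive == "shared" and pvals[i] < p_threshold:
            fc = cs / cp if cp > 0 else math.inf
            if fc > fc_threshold:
                call = "up"
            elif fc < 1.0 / fc_threshold:
                call = "down"
        results.append(
            DEResult(
                feature=f,
                x=int(x[i]),
                y=int(y[i]),
                n1=n1,
                n2=n2,
                cpm_serum=cs,
                cpm_plasma=cp,
                log2fc=lfc,
                p_value=float(pvals[i]),
                call=call,
                exclusive=exclusive,
            )
        )
    return results


class NormalizedTableEmpty:
    def __init__(self, library_id: str):
        self.library_id = library_id
        self.cpm: dict[str, float] = {}

    def get(self, feature: str, default: float = 0.0) -> float:
        return default


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


@dataclass
class ClusterResult:
    """Agglomerative clustering of the log2 expression matrix."""

    features: list[str]
    leaf_order: list[str]
    linkage: np.ndarray
    matrix: pd.DataFrame


def cluster_matrix(
    results: Sequence[DEResult], called_only: bool = True
) -> pd.DataFrame:
    """Feature x library matrix of log2(CPM + 1) for clustering."""
    rows = [r for r in results if (r.call != "ns" if called_only else True)]
    return pd.DataFrame(
        {
            "serum": [math.log2(r.cpm_serum + 1) for r in rows],
            "plasma": [math.log2(r.cpm_plasma + 1) for r in rows],
        },
        index=[r.feature for r in rows],
    )


def hierarchical_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage agglomerative clustering on Euclidean distances.

    Deterministic given the input row order (SciPy's tie-breaking is by
    index).  Requires at least two features.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires at least 2 features")
    z = hierarchy.linkage(matrix.to_numpy(), method="average", metric="euclidean")
    order = hierarchy.leaves_list(z)
    features = list(matrix.index)
    return ClusterResult(
        features=features,
        leaf_order=[features[i] for i in order],
        linkage=z,
        matrix=matrix,
    )


def to_newick(result: ClusterResult) -> str:
    """Render the merge tree as a Newick string with merge heights as
    branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.features[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
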