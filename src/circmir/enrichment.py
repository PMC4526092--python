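"""Hypergeometric term enrichment of predicted miRNA target genes.

Target genes hit by at least two differential miRNAs form the query set;
each annotation term (GO biological-process or KEGG pathway stand-ins,
supplied as GMT files) is tested for over-representation with the
hypergeometric upper tail, corrected across tested terms by
Benjamini-Hochberg.  A term is reported significant when its corrected P
is below alpha and it contains at least ``min_hits`` query genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

__all__ = [
    "Term",
    "TermMap",
    "read_target_map",
    "write_target_map",
    "select_target_genes",
    "hypergeometric_tail",
    "EnrichmentResult",
    "enrich",
]


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    namespace: str  # "GO-process" or "KEGG" (free-form accepted)
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.id!r} has an empty gene set")


class TermMap:
    """Term-to-gene annotation with per-namespace gene universes."""

    def __init__(self, terms: Iterable[Term]):
        self.terms: list[Term] = list(terms)
        ids = [t.id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("term ids must be unique")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def namespaces(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.namespace, None)
        return list(seen)

    def universe(self, namespace: Optional[str] = None) -> frozenset[str]:
        """All genes annotated in the namespace (or in any namespace)."""
        genes: set[str] = set()
        for t in self.terms:
            if namespace is None or t.namespace == namespace:
                genes |= t.genes
        return frozenset(genes)

    @classmethod
    def from_gmt(cls, path, namespace: str = "GO-process") -> "TermMap":
        """GMT: term id, description, then tab-separated gene symbols."""
        terms = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms.append(
                    Term(
                        id=parts[0],
                        name=parts[1],
                        namespace=namespace,
                        genes=frozenset(g for g in parts[2:] if g),
                    )
                )
        return cls(terms)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.terms:
                genes = "\t".join(sorted(t.genes))
                fh.write(f"{t.id}\t{t.name}\t{genes}\n")


def read_target_map(path) -> dict[str, set[str]]:
    """Two-column TSV (miRNA, gene) -> mapping miRNA -> target gene set."""
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mirna, gene = line.split("\t")[:2]
            if mirna.lower() in ("mirna", "mir") and gene.lower() == "gene":
                continue
            targets.setdefault(mirna, set()).add(gene)
    return targets


def write_target_map(targets: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\n")
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def select_target_genes(
    targets: Mapping[str, set[str]],
    de_mirnas: Iterable[str],
    min_mirnas: int = 2,
) -> frozenset[str]:
    """Genes targeted by at least ``min_mirnas`` of the given miRNAs."""
    if min_mirnas < 1:
        raise ValueError("min_mirnas must be >= 1")
    hits: dict[str, int] = {}
    for mirna in set(de_mirnas):
        for gene in targets.get(mirna, ()):
            hits[gene] = hits.get(gene, 0) + 1
    return frozenset(g for g, c in hits.items() if c >= min_mirnas)


def hypergeometric_tail(k: int, big_k: int, n: int, big_m: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(M, K, n).

    M is the universe size, K the number of annotated (term) genes, n the
    query size, k the observed overlap.
    """
    if not (0 <= k <= min(big_k, n)):
        raise ValueError(f"k={k} outside [0, min(K={big_k}, n={n})]")
    if big_k > big_m or n > big_m:
        raise ValueError("K and n must not exceed the universe size M")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, big_m, big_k, n))


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    namespace: str
    k: int  # query genes hitting the term
    hit_genes: tuple[str, ...]
    term_size: int  # K, within-universe term size
    query_size: int  # n, within-universe query size
    universe_size: int  # M
    p_value: float
    p_corrected: float
    significant: bool


def _adjust(pvals: Sequence[float], method: str) -> list[float]:
    if not pvals:
        return []
    if method == "none":
        return list(pvals)
    from statsmodels.stats.multitest import multipletests

    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return list(multipletests(list(pvals), method=key)[1])


def enrich(
    query: Iterable[str],
    terms: TermMap,
    min_hits: int = 2,
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query gene set.

    Universes are per namespace (all genes annotated to any term of that
    namespace); query genes outside a namespace's universe are dropped for
    that namespace's tests.  Multiple-testing correction runs over terms
    with at least one hit; zero-hit terms are reported with p = 1 and are
    excluded from the correction denominator.  Results are sorted by raw P
    ascending (ties by term id).
    """
    if correction not in ("bh", "bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    query = frozenset(query)
    results: list[EnrichmentResult] = []
    for namespace in terms.namespaces():
        universe = terms.universe(namespace)
        ns_query = query & universe
        n, m = len(ns_query), len(universe)
        ns_results: list[EnrichmentResult] = []
        for term in terms:
            if term.namespace != namespace:
                continue
            term_genes = term.genes & universe
            hits = tuple(sorted(ns_query & term_genes))
            k = len(hits)
            p = hypergeometric_tail(k, len(term_genes), n, m) if n > 0 else 1.0
            ns_results.append(
                EnrichmentResult(
                    term_id=term.id,
                    name=term.name,
                    namespace=namespace,
                    k=k,
                    hit_genes=hits,
                    term_size=len(term_genes),
                    query_size=n,
                    universe_size=m,
                    p_value=p,
                    p_corrected=1.0,
                    significant=False,
                )
            )
        tested = [r for r in ns_results if r.k >= 1]
        adjusted = _adjust([r.p_value for r in tested], correction)
        for r, padj in zip(tested, adjusted):
            r.p_corrected = float(padj)
        for r in ns_results:
            r.significant = r.p_corrected < alpha and r.k >= min_hits
        results.extend(ns_results)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "namespace": r.namespace,
                "p_value": r.p_value,
                "p_corrected": r.p_corrected,
                "hit_count": r.k,
                "hit_genes": ",".join(r.hit_genes),
                "significant": r.significant,
            }
            for r in results
        ]
    )
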