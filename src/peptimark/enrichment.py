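"""GO biological-process enrichment with kappa-score functional grouping.

Query proteins (marker parents plus mapped proteases) are tested per term by
a two-sided hypergeometric test (minimum-likelihood definition) against an
annotation universe; p-values receive the Holm (Bonferroni step-down)
correction. Significant terms are grouped functionally: two terms are linked
when the Cohen's kappa of their gene-membership vectors reaches the kappa
threshold (default 0.45), and connected components of that graph form the
functional groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "AnnotationTable",
    "hypergeom_two_sided",
    "holm_adjust",
    "kappa_score",
    "cluster_terms",
    "go_enrichment",
]


@dataclass
class AnnotationTable:
    """term_id -> annotated identifiers, plus the background universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.terms.values(), set()) - self.universe
        if stray:
            raise ValidationError(
                f"annotated identifiers missing from universe: {sorted(stray)[:5]} ..."
            )

    @classmethod
    def from_tsv(cls, path: str | Path, universe: Iterable[str] | None = None
                 ) -> "AnnotationTable":
        """Read a two-column (term_id, gene_id) TSV; universe defaults to all
        annotated identifiers."""
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["term_id", "gene_id"], comment="#")
        terms: dict[str, set[str]] = {}
        for t, g in zip(df["term_id"], df["gene_id"]):
            terms.setdefault(t, set()).add(g)
        uni = set(df["gene_id"]) if universe is None else set(universe)
        return cls(terms, uni)


def hypergeom_two_sided(k: int, K: int, n: int, N: int,
                        method: str = "min-likelihood") -> float:
    """Two-sided hypergeometric p.

    With ``k`` query hits in a term of size ``K``, a query of size ``n`` and
    a universe of size ``N``. The default ``"min-likelihood"`` definition
    sums the probabilities of every outcome whose point probability does not
    exceed P(X = k); ``"double"`` doubles the smaller one-sided tail. Both
    are capped at 1 and detect enrichment as well as depletion.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if method == "double":
        lower = stats.hypergeom.cdf(k, N, K, n)
        upper = stats.hypergeom.sf(k - 1, N, K, n)
        return float(min(2 * min(lower, upper), 1.0))
    if method != "min-likelihood":
        raise ValidationError(f"unknown method {method!r}")
    lo = max(0, n + K - N)
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    p_k = stats.hypergeom.pmf(k, N, K, n)
    # tolerance guards against float noise when excluding outcomes "above" P(X=k)
    p = pmf[pmf <= p_k * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm (Bonferroni step-down) adjusted p-values, original order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def kappa_score(u: Sequence[int], v: Sequence[int]) -> float:
    """Cohen's kappa between two binary membership vectors.

    kappa = (p_o - p_e) / (1 - p_e); defined as 1 when chance agreement is
    total (both vectors constant and identical).
    """
    u = np.asarray(u, int).ravel()
    v = np.asarray(v, int).ravel()
    if u.size != v.size:
        raise ValidationError("vectors must have equal length")
    if u.size == 0:
        raise ValidationError("vectors must be non-empty")
    p_o = float((u == v).mean())
    pu, pv = u.mean(), v.mean()
    p_e = pu * pv + (1 - pu) * (1 - pv)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def cluster_terms(
    results: pd.DataFrame,
    annotation: AnnotationTable,
    threshold: float = 0.45,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group significant terms into kappa functional groups.

    Terms with ``p_adj <= alpha`` enter a graph with an edge wherever the
    kappa of their gene-membership vectors (over the universe) is >= the
    threshold; connected components get consecutive ``group_id`` values
    (singletons allowed). Non-significant terms receive group_id -1.
    """
    out = results.copy()
    out["group_id"] = -1
    sig = out.index[out["p_adj"] <= alpha]
    universe = sorted(annotation.universe)
    vectors = {
        t: np.fromiter((g in annotation.terms.get(t, set()) for g in universe),
                       dtype=int, count=len(universe))
        for t in sig
    }
    g = nx.Graph()
    g.add_nodes_from(sig)
    terms = list(sig)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            if kappa_score(vectors[a], vectors[b]) >= threshold:
                g.add_edge(a, b)
    for gid, comp in enumerate(nx.connected_components(g)):
        for t in comp:
            out.loc[t, "group_id"] = gid
    return out


def go_enrichment(
    query: Iterable[str],
    annotation: AnnotationTable,
    alpha: float = 0.05,
    kappa_threshold: float = 0.45,
) -> pd.DataFrame:
    """Term enrichment of a query set with Holm correction and kappa groups.

    Returns a DataFrame indexed by term_id with columns k, K, n, N, p, p_adj
    and group_id, sorted by adjusted p.
    """
    query_set = set(query) & annotation.universe
    n, N = len(query_set), len(annotation.universe)
    if n == 0:
        raise ValidationError("query has no identifiers in the universe")
    rows = {}
    for term, genes in annotation.terms.items():
        K = len(genes)
        k = len(query_set & genes)
        rows[term] = {"k": k, "K": K, "n": n, "N": N,
                      "p": hypergeom_two_sided(k, K, n, N)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "term_id"
    df["p_adj"] = holm_adjust(df["p"])
    df = cluster_terms(df, annotation, threshold=kappa_threshold, alpha=alpha)
    return df.sort_values(["p_adj", "p"])
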