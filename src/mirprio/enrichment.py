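"""Hypergeometric gene-set enrichment with Bonferroni or BH-FDR correction.

For a query of n genes drawn from a background of N, a concept with K
members overlapping the query in k genes is scored with the upper-tail
hypergeometric probability P(X >= k).  Multiple-testing correction is
applied *within* each annotation category — concepts are ranked within
categories, and pooling would let large categories swamp small ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationCorpus, GeneList

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_pvalue", "adjust", "enrich"]

#: floor applied to p-values before taking reciprocals downstream
P_FLOOR = 1e-300

ADJUST_METHODS = ("bonferroni", "fdr_bh")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the concept size, n the query size and k
    the observed overlap.  Returns exactly 1.0 for k = 0.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"K={K}, n={n} must lie in [0, N={N}]")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, 0.0))


def adjust(p_values: Iterable[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment of raw p-values.

    ``bonferroni``: min(1, p*m).  ``fdr_bh``: Benjamini–Hochberg step-up
    with enforced monotonicity.  Output preserves input order and length.
    """
    if method not in ADJUST_METHODS:
        raise ValueError(f"method must be one of {ADJUST_METHODS}")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method=method)[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-concept enrichment records.

    ``table`` columns: category, concept_id, name, k, K, n, N, p_raw,
    p_adj, significant, members_hit (frozenset).  Only concepts with
    k >= 1 are recorded; correction is nonetheless computed over *all*
    size-eligible concepts of the category (absent overlap means p = 1).
    Rows are sorted by p_raw ascending within each category.
    """

    table: pd.DataFrame
    method: str
    alpha_sig: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def category_records(self, category: str) -> pd.DataFrame:
        return self.table[self.table["category"] == category]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["members_hit"] = df["members_hit"].map(lambda s: ";".join(sorted(s)))
        df.to_csv(path, sep="\t", index=False)


def enrich(
    gene_list: GeneList,
    corpus: AnnotationCorpus,
    method: str = "bonferroni",
    alpha_sig: float = 0.05,
    background: Optional[frozenset[str]] = None,
    min_K: int = 2,
    max_K: int = 2000,
) -> EnrichmentResult:
    """Enrich a gene list against every category of the corpus.

    The background defaults, per category, to the union of that
    category's concept members; pass an explicit set to override.  Query
    genes outside the background are dropped with a warning; an empty
    intersection is an error.
    """
    if method not in ADJUST_METHODS:
        raise ValueError(f"method must be one of {ADJUST_METHODS}")
    query_all = gene_list.as_set
    if not query_all & corpus.background:
        raise ValueError("gene list has no overlap with the corpus background")
    dropped = query_all - corpus.background
    if dropped:
        logger.warning(
            "%d query genes outside the corpus background dropped", len(dropped)
        )

    records: list[dict] = []
    for category in sorted(corpus.categories):
        bg = background if background is not None else corpus.category_background(category)
        query = query_all & bg
        n = len(query)
        N = len(bg)
        tested: list[tuple[str, int, frozenset[str], float]] = []
        for cid in sorted(corpus.categories[category]):
            concept = corpus.categories[category][cid]
            members = concept.members & bg
            K = len(members)
            if not (min_K <= K <= max_K):
                continue
            hit = frozenset(members & query)
            p = hypergeom_pvalue(len(hit), K, n, N)
            tested.append((cid, K, hit, p))
        if not tested:
            continue
        p_adj = adjust([t[3] for t in tested], method=method)
        for (cid, K, hit, p), pa in zip(tested, p_adj):
            if not hit:
                continue
            concept = corpus.categories[category][cid]
            records.append(
                {
                    "category": category,
                    "concept_id": cid,
                    "name": concept.name,
                    "k": len(hit),
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_raw": max(p, P_FLOOR),
                    "p_adj": float(pa),
                    "significant": bool(pa <= alpha_sig),
                    "members_hit": hit,
                }
            )
    columns = [
        "category", "concept_id", "name", "k", "K", "n", "N",
        "p_raw", "p_adj", "significant", "members_hit",
    ]
    df = pd.DataFrame(records, columns=columns)
    if len(df):
        df = df.sort_values(
            ["category", "p_raw", "concept_id"], kind="mergesort"
        ).reset_index(drop=True)
    return EnrichmentResult(table=df, method=method, alpha_sig=alpha_sig)


def hypergeom_pvalue_exact(k: int, K: int, n: int, N: int) -> float:
    """Closed-form upper tail via exact binomial coefficients.

    Sum_{j>=k} C(K,j) C(N-K, n-j) / C(N,n) computed in exact integer
    arithmetic; useful as a slow cross-check for tiny problems.
    """
    if k == 0:
        return 1.0
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total
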