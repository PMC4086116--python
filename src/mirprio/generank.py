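"""Gene scoring and ranking.

Three signals feed a gene's final score:

* **Reciprocal-p category scores** — within one annotation category a
  gene's significance is the sum of 1/p over the significant concepts
  containing it, so genes tied to many strong concepts score high.

* **Cross-category propagation** — category scores are diffused over the
  bipartite gene–concept graph (restricted to significant concepts,
  concept influence weighted by 1/p) until they converge, letting
  evidence in one category reinforce related genes in another.  The
  operator is mass-conserving: the combined score vector sums to one at
  every iteration.

* **Interactome scores** — when a training set defines the biological
  context, HITS-with-priors is run on the protein–protein interaction
  graph with the training genes as the root set; the authority vector
  (teleporting back to the root with probability beta) scores each gene
  by its centrality to the context.  Edges are treated as bidirectional.

The annotation-derived and interactome-derived scores are fused by a
weighted sum of max-rescaled components, and genes are ranked by the
fused score (ties broken by identifier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, P_FLOOR
from .io import GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "HitsPriorConfig",
    "PropagationInfo",
    "GeneScoreTable",
    "category_scores",
    "propagate",
    "hits_with_priors",
    "fuse_and_rank",
]


@dataclass(frozen=True)
class PropagationConfig:
    tol: float = 1e-8
    max_iter: int = 1000
    damping: float = 0.85

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or not (0.0 <= self.damping <= 1.0):
            raise ValueError("invalid PropagationConfig")


@dataclass(frozen=True)
class HitsPriorConfig:
    beta: float = 0.5
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid HitsPriorConfig")


@dataclass
class PropagationInfo:
    converged: bool
    n_iter: int
    masses: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class GeneScoreTable:
    """Ranked per-gene scores.

    ``table`` is indexed by gene with columns ``score_<category>``...,
    ``combined``, ``interactome`` (NaN when no training set), ``final``
    and ``rank`` (1 = best; ranks are a permutation of 1..n).
    """

    table: pd.DataFrame
    converged: bool = True

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes_by_rank(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def final_score(self, gene: str) -> float:
        if gene not in self.table.index:
            return 0.0
        return float(self.table.at[gene, "final"])

    def to_tsv(self, path) -> None:
        df = self.table.reset_index(names="gene").sort_values("rank")
        df.to_csv(path, sep="\t", index=False)


def category_scores(
    enrichment: EnrichmentResult,
    genes: GeneList,
    use_adjusted: bool = False,
) -> dict[str, dict[str, float]]:
    """Per-gene, per-category reciprocal-p scores.

    score(g, c) = sum over significant concepts t of category c with
    g among the concept's hit members of 1/p(t).  Nominal (raw) p-values
    are used by default; p is floored at ``P_FLOOR`` so reciprocals stay
    finite.  Genes hitting no significant concept score 0.
    """
    pcol = "p_adj" if use_adjusted else "p_raw"
    scores: dict[str, dict[str, float]] = {
        g: {c: 0.0 for c in enrichment.table["category"].unique()} for g in genes
    }
    gene_set = genes.as_set
    for row in enrichment.significant.itertuples():
        r = 1.0 / max(getattr(row, pcol), P_FLOOR)
        for g in row.members_hit & gene_set:
            scores[g][row.category] += r
    return scores


def _concept_structure(
    enrichment: EnrichmentResult, genes: Sequence[str]
) -> dict[str, list[tuple[float, np.ndarray]]]:
    """Significant-concept incidence per category.

    Returns {category: [(weight, member-index-array), ...]} where weights
    are reciprocal raw p-values normalized to sum one within the category.
    """
    gidx = {g: i for i, g in enumerate(genes)}
    structure: dict[str, list[tuple[float, np.ndarray]]] = {}
    sig = enrichment.significant
    for category in sorted(sig["category"].unique()):
        rows = sig[sig["category"] == category]
        weights = 1.0 / np.maximum(rows["p_raw"].to_numpy(float), P_FLOOR)
        weights = weights / weights.sum()
        entries = []
        for w, hit in zip(weights, rows["members_hit"]):
            idx = np.array(sorted(gidx[g] for g in hit if g in gidx), dtype=int)
            if idx.size:
                entries.append((float(w), idx))
        if entries:
            structure[category] = entries
    return structure


def propagate(
    cat_scores: Mapping[str, Mapping[str, float]],
    enrichment: EnrichmentResult,
    genes: GeneList,
    config: PropagationConfig = PropagationConfig(),
) -> tuple[dict[str, float], PropagationInfo]:
    """Diffuse category scores across categories until convergence.

    One iteration, starting from the current combined vector x (sums
    to 1):

    1. each significant concept t of category c gets the mean combined
       score of its member genes, scaled by the concept's within-category
       weight (1/p normalized over the category's significant concepts);
    2. a gene's per-category signal is the sum of its concepts' scores,
       and its cross-category signal m(g) the mean over categories;
    3. x <- damping * m + (1 - damping) * x0, renormalized to sum 1,
       where x0 is the initial cross-category mean of the normalized
       category score vectors.

    Iteration stops when the largest per-gene change drops below
    ``config.tol`` or after ``config.max_iter`` iterations (returned
    un-converged with a warning, never an exception).
    """
    gene_ids = list(genes)
    n = len(gene_ids)
    cats_nonzero = [
        c for c in sorted({c for g in cat_scores.values() for c in g})
        if sum(cat_scores[g].get(c, 0.0) for g in gene_ids) > 0
    ]
    if not cats_nonzero:
        # a normal outcome for weakly enriched test lists, not an error
        logger.info("no category carries a nonzero score; combined scores are zero")
        return {g: 0.0 for g in gene_ids}, PropagationInfo(converged=True, n_iter=0)

    per_cat = np.zeros((len(cats_nonzero), n))
    for ci, c in enumerate(cats_nonzero):
        v = np.array([cat_scores[g].get(c, 0.0) for g in gene_ids], float)
        per_cat[ci] = v / v.sum()
    x0 = per_cat.mean(axis=0)
    x0 = x0 / x0.sum()

    structure = _concept_structure(enrichment, gene_ids)
    cats = [c for c in cats_nonzero if c in structure]
    if not cats:
        return dict(zip(gene_ids, x0)), PropagationInfo(converged=True, n_iter=0, masses=[1.0])

    d = config.damping
    x = x0.copy()
    info = PropagationInfo(converged=False, n_iter=0, masses=[float(x.sum())])
    for it in range(1, config.max_iter + 1):
        m = np.zeros(n)
        for c in cats:
            for w, idx in structure[c]:
                m[idx] += w * x[idx].mean()
        m /= len(cats)
        y = d * m + (1.0 - d) * x0
        total = y.sum()
        if total <= 0:  # degenerate: damping=1 with signal-free concepts
            y = x0.copy()
            total = y.sum()
        y = y / total
        delta = float(np.max(np.abs(y - x)))
        x = y
        info.n_iter = it
        info.masses.append(float(x.sum()))
        if delta < config.tol:
            info.converged = True
            break
    if not info.converged:
        logger.warning("propagation did not converge in %d iterations", config.max_iter)
    return dict(zip(gene_ids, x)), info


def hits_with_priors(
    ppi_edges: Iterable[tuple[str, str]],
    root: GeneList | Iterable[str],
    config: HitsPriorConfig = HitsPriorConfig(),
) -> dict[str, float]:
    """HITS with priors on an undirected interaction graph.

    The prior is uniform over the root (training) genes present in the
    graph; every step teleports back to it with the back probability
    beta.  With A the (symmetric) adjacency matrix and ``norm`` the
    L1 normalization:

        a <- (1 - beta) * norm(A^T h) + beta * prior
        h <- (1 - beta) * norm(A a)   + beta * prior

    Returns the authority vector: a probability distribution over graph
    nodes (sums to 1).  Genes absent from the graph score 0 implicitly.
    """
    from scipy.sparse import csr_matrix

    root_set = root.as_set if isinstance(root, GeneList) else frozenset(root)
    nodes: set[str] = set()
    edge_list: list[tuple[str, str]] = []
    for u, v in ppi_edges:
        if u == v:
            continue
        nodes.update((u, v))
        edge_list.append((u, v))
    if not nodes:
        raise ValueError("empty interaction graph")
    order = sorted(nodes)
    idx = {g: i for i, g in enumerate(order)}
    n = len(order)
    rows, cols = [], []
    for u, v in edge_list:
        rows.extend((idx[u], idx[v]))
        cols.extend((idx[v], idx[u]))
    A = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = np.minimum(A.data, 1.0)  # collapse parallel edges

    in_root = np.array([g in root_set for g in order])
    if not in_root.any():
        raise ValueError("no root (training) gene is present in the graph")
    prior = in_root / in_root.sum()

    def l1(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        return v / s if s > 0 else v

    beta = config.beta
    h = prior.copy()
    a = prior.copy()
    for _ in range(config.max_iter):
        a_new = (1.0 - beta) * l1(A.T @ h) + beta * prior
        h = (1.0 - beta) * l1(A @ a_new) + beta * prior
        delta = float(np.max(np.abs(a_new - a)))
        a = a_new
        if delta < config.tol:
            break
    else:
        logger.warning("HITS-with-priors did not converge in %d iterations", config.max_iter)
    return dict(zip(order, a))


def _rescale(v: np.ndarray) -> np.ndarray:
    m = v.max() if len(v) else 0.0
    return v / m if m > 0 else v


def fuse_and_rank(
    combined: Mapping[str, float],
    interactome: Optional[Mapping[str, float]] = None,
    weight: float = 0.5,
    cat_scores: Optional[Mapping[str, Mapping[str, float]]] = None,
    converged: bool = True,
) -> GeneScoreTable:
    """Fuse annotation and interactome scores and assign ranks.

    final = combined when no interactome signal is present, else
    ``weight * rescale(combined) + (1 - weight) * rescale(interactome)``
    with each component divided by its maximum.  Ranks are by final score
    descending, gene identifier ascending on ties.
    """
    if not (0.0 <= weight <= 1.0):
        raise ValueError("fusion weight must lie in [0, 1]")
    genes = sorted(combined)
    comb = np.array([combined[g] for g in genes], float)
    data: dict[str, np.ndarray | list] = {}
    if cat_scores is not None:
        categories = sorted({c for g in cat_scores.values() for c in g})
        for c in categories:
            data[f"score_{c}"] = [cat_scores.get(g, {}).get(c, 0.0) for g in genes]
    data["combined"] = comb
    if interactome is None:
        data["interactome"] = np.full(len(genes), np.nan)
        final = comb
    else:
        inter = np.array([interactome.get(g, 0.0) for g in genes], float)
        data["interactome"] = inter
        final = weight * _rescale(comb) + (1.0 - weight) * _rescale(inter)
    data["final"] = final
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    ordered = df.sort_values(["final", "gene"], ascending=[False, True], kind="mergesort")
    df["rank"] = pd.Series(range(1, len(genes) + 1), index=ordered.index)
    return GeneScoreTable(table=df, converged=converged)
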