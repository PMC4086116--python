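"""End-to-end orchestration: compendium → enrichment → gene ranking →
(interactome) → miR ranking → (expression integration).

:func:`prioritize` is the in-memory core used by the CLI and by the
validation harness; :func:`run_pipeline` adds file IO around it and
writes a reproducible output bundle (TSVs, GML network, JSON manifest
with the exact config and seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .compendium import InteractionCompendium, targets_of
from .enrichment import EnrichmentResult, enrich
from .expression import rerank_with_expression
from .generank import (
    GeneScoreTable,
    HitsPriorConfig,
    PropagationConfig,
    category_scores,
    fuse_and_rank,
    hits_with_priors,
    propagate,
)
from .io import ExpressionTable, GeneList, write_network_gml
from .mirrank import DEFAULT_ALPHA, MiRScoreTable, score_mirs_eq1, score_mirs_eq2

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "prioritize", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """Method parameters shared by every stage."""

    alpha: float = DEFAULT_ALPHA
    correction: str = "bonferroni"
    alpha_sig: float = 0.05
    fusion_weight: float = 0.5
    use_adjusted_p: bool = False
    min_K: int = 2
    max_K: int = 2000
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    hits: HitsPriorConfig = field(default_factory=HitsPriorConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    enrichment: EnrichmentResult
    gene_table: GeneScoreTable
    mir_table: Optional[MiRScoreTable]
    train_table: Optional[GeneScoreTable] = None
    gene_expression_table: Optional[object] = None
    mir_expression_table: Optional[object] = None


def score_gene_list(
    genes: GeneList,
    corpus,
    params: PipelineParams,
    interactome: Optional[dict[str, float]] = None,
) -> tuple[EnrichmentResult, GeneScoreTable]:
    """Enrich one gene list and build its ranked score table."""
    enr = enrich(
        genes,
        corpus,
        method=params.correction,
        alpha_sig=params.alpha_sig,
        min_K=params.min_K,
        max_K=params.max_K,
    )
    cat = category_scores(enr, genes, use_adjusted=params.use_adjusted_p)
    combined, info = propagate(cat, enr, genes, config=params.propagation)
    table = fuse_and_rank(
        combined,
        interactome=interactome,
        weight=params.fusion_weight,
        cat_scores=cat,
        converged=info.converged,
    )
    return enr, table


def prioritize(
    test_genes: GeneList,
    mirs: Sequence[str],
    corpus,
    compendium: InteractionCompendium,
    params: PipelineParams = PipelineParams(),
    training: Optional[GeneList] = None,
    ppi_edges: Optional[Sequence[tuple[str, str]]] = None,
    gene_expression: Optional[ExpressionTable] = None,
    mir_expression: Optional[ExpressionTable] = None,
) -> PipelineResult:
    """Run the full prioritization for one test set of genes and miRs.

    Without a training set, miRs are scored training-free; with one, the
    training genes are scored through the same annotation pipeline, the
    interactome stage (when a PPI edge list is given) roots the
    HITS-with-priors walk at the training set, and miRs are scored in the
    training-dependent mode.
    """
    interactome = None
    train_table = None
    if training is not None:
        if ppi_edges:
            full = hits_with_priors(ppi_edges, training, config=params.hits)
            interactome = {g: full.get(g, 0.0) for g in test_genes}
        _, train_table = score_gene_list(training, corpus, params)

    enr, gene_table = score_gene_list(test_genes, corpus, params, interactome=interactome)

    mir_table = None
    if mirs:
        if training is not None:
            mir_table = score_mirs_eq2(
                list(mirs), gene_table, train_table, compendium, alpha=params.alpha
            )
        else:
            mir_table = score_mirs_eq1(
                list(mirs), gene_table, compendium, alpha=params.alpha
            )

    result = PipelineResult(
        enrichment=enr, gene_table=gene_table, mir_table=mir_table, train_table=train_table
    )
    if gene_expression is not None:
        scores = {g: gene_table.final_score(g) for g in gene_table.table.index}
        result.gene_expression_table = rerank_with_expression(scores, gene_expression)
    if mir_expression is not None and mir_table is not None:
        scores = dict(zip(mir_table.table["mir"], mir_table.table["sig"]))
        result.mir_expression_table = rerank_with_expression(scores, mir_expression)
    return result


def _network_export(
    result: PipelineResult, compendium: InteractionCompendium, path: Path
) -> None:
    """Tripartite concept–mRNA–miR network with scores as node attributes."""
    nodes: list[dict] = []
    edges: list[dict] = []
    gene_ids = set(result.gene_table.table.index)
    for row in result.enrichment.significant.itertuples():
        cid = f"concept:{row.concept_id}"
        nodes.append({"id": cid, "type": "concept", "score": 1.0 / row.p_raw})
        for g in sorted(row.members_hit & gene_ids):
            edges.append({"src": cid, "dst": f"gene:{g}", "kind": "annotation"})
    for g in result.gene_table.table.index:
        nodes.append(
            {"id": f"gene:{g}", "type": "mRNA", "score": result.gene_table.final_score(g)}
        )
    if result.mir_table is not None:
        for row in result.mir_table.table.itertuples():
            nodes.append({"id": f"mir:{row.mir}", "type": "miR", "score": row.sig})
            for g in sorted(targets_of(compendium, row.mir, restrict_to=gene_ids)):
                edges.append({"src": f"mir:{row.mir}", "dst": f"gene:{g}", "kind": "regulation"})
    write_network_gml(nodes, edges, path)


def run_pipeline(
    out_dir: str | Path,
    test_genes: GeneList,
    mirs: Sequence[str],
    corpus,
    compendium: InteractionCompendium,
    params: PipelineParams = PipelineParams(),
    training: Optional[GeneList] = None,
    ppi_edges: Optional[Sequence[tuple[str, str]]] = None,
    gene_expression: Optional[ExpressionTable] = None,
    mir_expression: Optional[ExpressionTable] = None,
    seed: int = 0,
) -> PipelineResult:
    """Run :func:`prioritize` and write the output bundle.

    The bundle (gene/miR/enrichment TSVs, GML network, JSON manifest) is
    deterministic: identical inputs, config and seed give byte-identical
    files.  On any stage failure partial outputs are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = prioritize(
            test_genes, mirs, corpus, compendium, params,
            training=training, ppi_edges=ppi_edges,
            gene_expression=gene_expression, mir_expression=mir_expression,
        )
        result.gene_table.to_tsv(out / "genes.tsv")
        result.enrichment.to_tsv(out / "enrichment.tsv")
        if result.mir_table is not None:
            result.mir_table.to_tsv(out / "mirs.tsv")
        if result.train_table is not None:
            result.train_table.to_tsv(out / "training_genes.tsv")
        if result.gene_expression_table is not None:
            result.gene_expression_table.reset_index().to_csv(
                out / "genes_expression.tsv", sep="\t", index=False
            )
        if result.mir_expression_table is not None:
            result.mir_expression_table.reset_index().to_csv(
                out / "mirs_expression.tsv", sep="\t", index=False
            )
        _network_export(result, compendium, out / "network.gml")
        manifest = {
            "mirprio_version": __version__,
            "seed": seed,
            "params": params.to_dict(),
            "test_genes": list(test_genes),
            "mirs": sorted(mirs),
            "training": list(training) if training is not None else None,
            "n_interactions": len(compendium),
            "converged": result.gene_table.converged,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return result
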