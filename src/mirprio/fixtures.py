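"""Synthetic corpora, compendia, PPI graphs and expression tables with planted signal.

The generator emulates the inputs the ranking pipeline consumes, at desk
scale, with a tunable planted signal:

* a **signal module** — a coherent set of genes that behaves like a real
  functional module: it is densely co-annotated (a handful of "signal"
  concepts per category draw most of their members from the module) and
  densely interconnected in the synthetic PPI graph;
* **planted miRs** whose targets are drawn from the signal module with
  probability ``signal_strength`` (decoy miRs target uniformly), so at
  strength 0 planted and decoy miRs are statistically identical — the
  null fixture — while at strength 1 every planted target lies inside
  the module;
* an expression table giving signal genes elevated expression level and
  fold change with Gaussian noise.

All randomness flows from one master seed through documented substreams
(corpus=0, compendium=1, expression=2, ppi=3), so every artifact is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compendium import InteractionCompendium, SourceTable, union_compendium
from .io import AnnotationCorpus, Concept, ExpressionTable, GeneList

__all__ = [
    "FixtureSpec",
    "PlantedTruth",
    "FixtureBundle",
    "make_corpus",
    "make_compendium",
    "make_expression",
    "make_ppi",
    "make_bundle",
]

_SUBSTREAMS = {"corpus": 0, "compendium": 1, "expression": 2, "ppi": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults define the standard evaluation fixture: 200 genes, four
    core annotation categories of 30 concepts each, 20 miRs with one
    planted at signal strength 0.8.
    """

    n_genes: int = 200
    categories: tuple[str, ...] = ("GO_BP", "MousePhenotype", "Pathway", "Coexpression")
    n_concepts_per_category: int = 30
    concept_size_range: tuple[int, int] = (5, 15)
    n_mirs: int = 20
    targets_per_mir: int = 25
    planted_mir_count: int = 1
    signal_strength: float = 0.8
    signal_module_size: int = 30
    n_signal_concepts_per_category: int = 4
    signal_concept_purity: float = 0.85
    expression_noise_sd: float = 0.5
    ppi_within_signal_p: float = 0.35
    ppi_background_p: float = 0.02
    rng_seed: int = 42

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_concepts_per_category, self.n_mirs,
            self.targets_per_mir, self.planted_mir_count, self.signal_module_size,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        lo, hi = self.concept_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("invalid concept_size_range")
        if self.planted_mir_count > self.n_mirs:
            raise ValueError("more planted miRs than miRs")
        if self.signal_module_size > self.n_genes:
            raise ValueError("signal module larger than the gene universe")

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.rng_seed, _SUBSTREAMS[component]])
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Manifest of what was planted, for evaluation."""

    planted_mirs: tuple[str, ...]
    signal_module: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class FixtureBundle:
    spec: FixtureSpec
    corpus: AnnotationCorpus
    compendium: InteractionCompendium
    truth: PlantedTruth
    ppi_edges: tuple[tuple[str, str], ...]
    expression: ExpressionTable

    @property
    def genes(self) -> list[str]:
        return sorted(self.corpus.background)

    @property
    def training(self) -> GeneList:
        return GeneList(genes=self.truth.signal_module, label="training")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _mir_names(n: int) -> list[str]:
    return [f"mir-{i:03d}" for i in range(1, n + 1)]


def signal_module(spec: FixtureSpec) -> tuple[str, ...]:
    """The planted functional module (deterministic under the seed)."""
    rng = spec.rng("corpus")
    genes = _gene_names(spec.n_genes)
    return tuple(
        sorted(str(g) for g in rng.choice(genes, size=spec.signal_module_size, replace=False))
    )


def make_corpus(spec: FixtureSpec) -> AnnotationCorpus:
    """Synthetic annotation corpus with a coherently annotated signal module.

    The first ``n_signal_concepts_per_category`` concepts of each
    category draw ``signal_concept_purity`` of their members from the
    signal module; all other concepts sample uniformly.  Every gene is
    guaranteed at least one annotation, so the background equals the
    full gene universe.
    """
    rng = spec.rng("corpus")
    genes = _gene_names(spec.n_genes)
    module = sorted(
        str(g) for g in rng.choice(genes, size=spec.signal_module_size, replace=False)
    )
    non_module = [g for g in genes if g not in set(module)]
    lo, hi = spec.concept_size_range

    categories: dict[str, dict[str, Concept]] = {}
    covered: set[str] = set()
    for cat in spec.categories:
        concepts: dict[str, Concept] = {}
        for j in range(1, spec.n_concepts_per_category + 1):
            cid = f"{cat}:C{j:03d}"
            size = int(rng.integers(lo, hi + 1))
            if j <= spec.n_signal_concepts_per_category:
                n_sig = min(round(spec.signal_concept_purity * size), len(module))
                members = {str(g) for g in rng.choice(module, size=n_sig, replace=False)}
                n_rest = min(size - n_sig, len(non_module))
                if n_rest > 0:
                    members |= {str(g) for g in rng.choice(non_module, size=n_rest, replace=False)}
            else:
                members = {str(g) for g in rng.choice(genes, size=min(size, len(genes)), replace=False)}
            concepts[cid] = Concept(cid, f"{cat} synthetic concept {j}", frozenset(members))
            covered |= members
        categories[cat] = concepts

    # guarantee full coverage so the background is the whole universe
    uncovered = sorted(set(genes) - covered)
    if uncovered:
        cat = spec.categories[-1]
        filler_id = f"{cat}:C{spec.n_concepts_per_category + 1:03d}"
        extra = [str(g) for g in rng.choice(genes, size=max(0, 2 - len(uncovered)), replace=False)]
        members = frozenset(uncovered) | frozenset(extra)
        categories[cat] = dict(categories[cat])
        categories[cat][filler_id] = Concept(
            filler_id, f"{cat} synthetic filler", members
        )
    return AnnotationCorpus(categories=categories, background=frozenset(genes))


def make_compendium(
    spec: FixtureSpec, corpus: AnnotationCorpus
) -> tuple[InteractionCompendium, PlantedTruth]:
    """Synthetic miR→gene compendium with planted target bias.

    Planted miRs draw round(signal_strength * targets_per_mir) targets
    from the signal module (capped at the module size) and the remainder
    uniformly from the not-yet-chosen genes, so at strength 0 a planted
    miR is distributed exactly like a decoy; decoy miRs draw uniformly
    from all genes.
    """
    rng = spec.rng("compendium")
    genes = sorted(corpus.background)
    module = list(signal_module(spec))
    non_module = [g for g in genes if g not in set(module)]
    mirs = _mir_names(spec.n_mirs)
    planted = sorted(str(m) for m in rng.choice(mirs, size=spec.planted_mir_count, replace=False))

    pairs: set[tuple[str, str]] = set()
    planted_pairs: set[tuple[str, str]] = set()
    for mir in mirs:
        if mir in planted:
            n_sig = min(round(spec.signal_strength * spec.targets_per_mir), len(module))
            targets = {str(g) for g in rng.choice(module, size=n_sig, replace=False)}
            remaining = [g for g in genes if g not in targets]
            n_rest = min(spec.targets_per_mir - n_sig, len(remaining))
            if n_rest > 0:
                targets |= {str(g) for g in rng.choice(remaining, size=n_rest, replace=False)}
        else:
            targets = {
                str(g)
                for g in rng.choice(genes, size=min(spec.targets_per_mir, len(genes)), replace=False)
            }
        for g in targets:
            pairs.add((mir, g))
            if mir in planted:
                planted_pairs.add((mir, g))

    compendium = union_compendium(
        [SourceTable(name="synthetic_predictions", pairs=frozenset(pairs))]
    )
    truth = PlantedTruth(
        planted_mirs=tuple(planted),
        signal_module=tuple(module),
        pairs=frozenset(planted_pairs),
    )
    return compendium, truth


def make_expression(
    spec: FixtureSpec, signal_genes: Sequence[str], all_genes: Optional[Sequence[str]] = None
) -> ExpressionTable:
    """Two-level expression table: elevated signal genes plus Gaussian noise.

    Baseline expression mean 2.0, signal mean 8.0; baseline fold change
    1x, signal 4x (noise multiplies the ratio by 2^N(0, sd)).  With
    ``expression_noise_sd`` = 0 the table is exactly two-level.
    """
    rng = spec.rng("expression")
    genes = list(all_genes) if all_genes is not None else _gene_names(spec.n_genes)
    sig = set(signal_genes)
    sd = spec.expression_noise_sd
    base_expr, sig_expr = 2.0, 8.0
    rows = []
    for g in genes:
        mean = sig_expr if g in sig else base_expr
        expr = max(0.0, mean + rng.normal(0.0, sd))
        fold = (4.0 if g in sig else 1.0) * 2.0 ** rng.normal(0.0, sd)
        rows.append({"id": g, "expression_level": expr, "fold_change": fold})
    df = pd.DataFrame(rows).set_index("id").sort_index()
    return ExpressionTable(rows=df)


def make_ppi(spec: FixtureSpec, corpus: AnnotationCorpus) -> tuple[tuple[str, str], ...]:
    """Synthetic PPI edge list: dense within the signal module, sparse elsewhere."""
    rng = spec.rng("ppi")
    genes = sorted(corpus.background)
    module = set(signal_module(spec))
    edges: list[tuple[str, str]] = []
    for i, u in enumerate(genes):
        for v in genes[i + 1:]:
            p = spec.ppi_within_signal_p if (u in module and v in module) else spec.ppi_background_p
            if rng.random() < p:
                edges.append((u, v))
    return tuple(edges)


def make_bundle(spec: FixtureSpec = FixtureSpec()) -> FixtureBundle:
    """Generate the full synthetic world for one spec."""
    corpus = make_corpus(spec)
    compendium, truth = make_compendium(spec, corpus)
    ppi = make_ppi(spec, corpus)
    expression = make_expression(spec, truth.signal_module)
    return FixtureBundle(
        spec=spec, corpus=corpus, compendium=compendium,
        truth=truth, ppi_edges=ppi, expression=expression,
    )


# ---------------------------------------------------------------------------
# on-disk round-trip helpers: fixtures write the same formats the readers read

def write_corpus_gmt(corpus: AnnotationCorpus, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cat in sorted(corpus.categories):
        p = out / f"{cat}.gmt"
        lines = []
        for cid in sorted(corpus.categories[cat]):
            c = corpus.categories[cat][cid]
            lines.append("\t".join([c.concept_id, c.name] + sorted(c.members)))
        p.write_text("\n".join(lines) + "\n")
        paths[cat] = p
    return paths


def write_gene_list(genes: Sequence[str], path: str | Path) -> Path:
    p = Path(path)
    p.write_text("\n".join(genes) + "\n")
    return p


def write_expression_tsv(expression: ExpressionTable, path: str | Path) -> Path:
    p = Path(path)
    df = expression.rows.reset_index()
    df = df.rename(
        columns={"id": "Gene", "expression_level": "Expression level", "fold_change": "Fold change"}
    )
    df.to_csv(p, sep="\t", index=False)
    return p


def write_ppi_tsv(edges: Sequence[tuple[str, str]], path: str | Path) -> Path:
    p = Path(path)
    with open(p, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    return p
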