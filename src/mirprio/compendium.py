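"""miR→mRNA interaction compendium: the union of prediction/validation sources.

Target-prediction algorithms overlap poorly, so candidate interactions are
the *union* of all sources, each pair keeping the provenance of every
source that contributed it.  An interaction is flagged validated when any
contributing source is experimental (e.g. a curated-validation database);
validation status is metadata only and carries no extra weight downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import GeneList, IdMap, normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "SourceTable",
    "InteractionCompendium",
    "normalize_mir",
    "load_source",
    "union_compendium",
    "targets_of",
]


def normalize_mir(mir: str, strip_species_prefix: bool = False) -> str:
    """Canonicalize a miR identifier: lowercase, trimmed.

    ``strip_species_prefix`` drops a leading ``xxx-`` species code
    (``hsa-miR-9`` → ``mir-9``).  Arms (-5p/-3p) are never collapsed:
    they are distinct regulators.
    """
    m = mir.strip().lower()
    if strip_species_prefix and m.count("-") >= 2:
        head, rest = m.split("-", 1)
        if len(head) == 3 and head.isalpha() and head not in ("mir", "let"):
            m = rest
    return m


@dataclass(frozen=True)
class Interaction:
    mir: str
    gene: str
    sources: frozenset[str]
    validated: bool

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("interaction with empty source set")


@dataclass(frozen=True)
class SourceTable:
    """One prediction/validation source: a named set of (mir, gene) pairs."""

    name: str
    pairs: frozenset[tuple[str, str]]
    experimental: bool = False


@dataclass
class InteractionCompendium:
    """Union of all sources, queryable by miR and by gene."""

    interactions: dict[tuple[str, str], Interaction]
    source_registry: dict[str, bool]
    _by_mir: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _by_gene: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for inter in self.interactions.values():
            unknown = inter.sources - set(self.source_registry)
            if unknown:
                raise ValueError(f"unregistered sources {sorted(unknown)}")
            self._by_mir.setdefault(inter.mir, set()).add(inter.gene)
            self._by_gene.setdefault(inter.gene, set()).add(inter.mir)

    def __len__(self) -> int:
        return len(self.interactions)

    @property
    def mirs(self) -> frozenset[str]:
        return frozenset(self._by_mir)

    def genes_of(self, mir: str) -> frozenset[str]:
        return frozenset(self._by_mir.get(mir, set()))

    def mirs_of(self, gene: str) -> frozenset[str]:
        return frozenset(self._by_gene.get(gene, set()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mir": i.mir,
                "gene": i.gene,
                "sources": ";".join(sorted(i.sources)),
                "validated": i.validated,
            }
            for i in self.interactions.values()
        ]
        df = pd.DataFrame(rows, columns=["mir", "gene", "sources", "validated"])
        return df.sort_values(["mir", "gene"], kind="mergesort").reset_index(drop=True)


def load_source(
    path: str | Path,
    source_name: str,
    experimental: bool = False,
    mir_col: str = "mir",
    gene_col: str = "gene",
    id_map: Optional[IdMap] = None,
    strip_species_prefix: bool = False,
) -> SourceTable:
    """Load one source's TSV of miR–gene pairs, normalized and deduplicated."""
    id_map = id_map or IdMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (mir_col, gene_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing configured column {col!r}")
    pairs: set[tuple[str, str]] = set()
    for mir, gene in zip(df[mir_col], df[gene_col]):
        if pd.isna(mir) or pd.isna(gene):
            continue
        g = id_map.resolve(str(gene))
        if g is None:
            continue
        pairs.add((normalize_mir(str(mir), strip_species_prefix), g))
    if not pairs:
        logger.warning("source %s (%s) contributed no pairs", source_name, path)
    return SourceTable(name=source_name, pairs=frozenset(pairs), experimental=experimental)


def union_compendium(sources: Sequence[SourceTable]) -> InteractionCompendium:
    """Union the sources into a compendium with per-pair provenance.

    Order-independent: any permutation of ``sources`` yields an identical
    compendium.  ``validated`` is the OR of the experimental flags over
    contributing sources.
    """
    if not sources:
        raise ValueError("at least one source required")
    registry = {s.name: s.experimental for s in sorted(sources, key=lambda s: s.name)}
    if len(registry) != len(sources):
        raise ValueError("duplicate source names")
    acc: dict[tuple[str, str], set[str]] = {}
    for s in sources:
        for pair in s.pairs:
            acc.setdefault(pair, set()).add(s.name)
    interactions = {
        (mir, gene): Interaction(
            mir=mir,
            gene=gene,
            sources=frozenset(names),
            validated=any(registry[n] for n in names),
        )
        for (mir, gene), names in acc.items()
    }
    return InteractionCompendium(interactions=interactions, source_registry=registry)


def compendium_from_pairs(
    pairs: Iterable[tuple[str, str]],
    source_name: str = "pairs",
    experimental: bool = False,
) -> InteractionCompendium:
    """Convenience constructor from bare (mir, gene) pairs (one source)."""
    src = SourceTable(
        name=source_name,
        pairs=frozenset((normalize_mir(m), normalize_gene_id(g)) for m, g in pairs),
        experimental=experimental,
    )
    return union_compendium([src])


def targets_of(
    compendium: InteractionCompendium,
    mir: str,
    restrict_to: Optional[GeneList | Iterable[str]] = None,
) -> frozenset[str]:
    """Target genes of a miR, optionally intersected with a gene list.

    An unknown miR yields the empty set rather than an error.
    """
    targets = compendium.genes_of(normalize_mir(mir))
    if restrict_to is not None:
        allowed = restrict_to.as_set if isinstance(restrict_to, GeneList) else frozenset(restrict_to)
        targets = targets & allowed
    return targets


def write_compendium_tsv(compendium: InteractionCompendium, path: str | Path) -> None:
    compendium.to_frame().to_csv(path, sep="\t", index=False)


def read_compendium_tsv(path: str | Path) -> InteractionCompendium:
    """Read a compendium persisted by :func:`write_compendium_tsv`.

    Experimental flags are reconstructed from the validated column: a
    source is experimental if every interaction citing it is validated.
    """
    df = pd.read_csv(path, sep="\t")
    per_source_validated: dict[str, list[bool]] = {}
    acc: dict[tuple[str, str], tuple[set[str], bool]] = {}
    for _, row in df.iterrows():
        names = set(str(row["sources"]).split(";"))
        validated = bool(row["validated"])
        acc[(row["mir"], row["gene"])] = (names, validated)
        for n in names:
            per_source_validated.setdefault(n, []).append(validated)
    registry = {n: all(v) for n, v in per_source_validated.items()}
    interactions = {
        pair: Interaction(mir=pair[0], gene=pair[1], sources=frozenset(names), validated=val)
        for pair, (names, val) in acc.items()
    }
    return InteractionCompendium(interactions=interactions, source_registry=registry)
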