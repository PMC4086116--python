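"""Readers and writers for the external file formats, plus gene-identifier resolution.

All gene identifiers are resolved into a single internal namespace of
uppercase HGNC-style symbols.  Numeric identifiers (Entrez) are mapped
through a user-supplied two-column mapping table; a symbol with no mapping
entry is kept as its own canonical form.  Keeping one namespace avoids
double counting when the same gene arrives once as a symbol and once as an
Entrez ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IdMap",
    "GeneList",
    "ExpressionTable",
    "Concept",
    "AnnotationCorpus",
    "normalize_gene_id",
    "read_id_map",
    "read_gene_list",
    "read_gmt",
    "read_expression_table",
    "write_network_gml",
    "read_network_gml",
    "write_tsv",
]

#: default category vocabulary for annotation corpora
DEFAULT_CATEGORIES = (
    "GO_BP",
    "MousePhenotype",
    "Pathway",
    "Coexpression",
    "TFBS",
    "Disease",
)


def normalize_gene_id(token: str) -> str:
    """Canonicalize a raw identifier token: strip whitespace, uppercase.

    Idempotent: ``normalize_gene_id(normalize_gene_id(x)) == normalize_gene_id(x)``.
    """
    return token.strip().upper()


@dataclass(frozen=True)
class IdMap:
    """Alias → canonical-symbol mapping (e.g. Entrez ID → HGNC symbol).

    Tokens absent from the map resolve to their normalized form unless they
    are purely numeric, in which case they are unresolvable (a bare Entrez
    ID without a mapping cannot be trusted to name a gene).
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def resolve(self, token: str) -> Optional[str]:
        t = normalize_gene_id(token)
        if not t:
            return None
        if t in self.mapping:
            return normalize_gene_id(self.mapping[t])
        if t.isdigit():
            return None
        return t


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of resolved gene identifiers."""

    genes: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("GeneList contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)

    @property
    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class ExpressionTable:
    """Per-entity expression level and/or fold change.

    ``rows`` is indexed by entity id with (optional) columns
    ``expression_level`` and ``fold_change``; at least one is present.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        cols = set(self.rows.columns)
        if not cols & {"expression_level", "fold_change"}:
            raise ValueError(
                "ExpressionTable needs an 'expression_level' or 'fold_change' column"
            )

    def get(self, entity: str, column: str) -> Optional[float]:
        if column not in self.rows.columns or entity not in self.rows.index:
            return None
        v = self.rows.at[entity, column]
        return None if pd.isna(v) else float(v)


@dataclass(frozen=True)
class Concept:
    """A named gene set (GO term, pathway, phenotype, coexpression module...)."""

    concept_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class AnnotationCorpus:
    """Concept → gene memberships partitioned into named categories."""

    categories: Mapping[str, Mapping[str, Concept]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for cat, concepts in self.categories.items():
            for c in concepts.values():
                if not c.members:
                    raise ValueError(f"concept {c.concept_id} in {cat} has no members")
                if not c.members <= self.background:
                    raise ValueError(
                        f"concept {c.concept_id} has members outside the background"
                    )

    def category_background(self, category: str) -> frozenset[str]:
        """Union of all member genes of one category."""
        out: set[str] = set()
        for c in self.categories[category].values():
            out |= c.members
        return frozenset(out)

    def restrict(self, categories: Sequence[str]) -> "AnnotationCorpus":
        """Corpus limited to a subset of category names (for ablation runs)."""
        unknown = set(categories) - set(self.categories)
        if unknown:
            raise KeyError(f"unknown categories: {sorted(unknown)}")
        if not categories:
            raise ValueError("category subset is empty")
        return AnnotationCorpus(
            categories={c: self.categories[c] for c in categories},
            background=self.background,
        )


def read_id_map(path: str | Path) -> IdMap:
    """Two-column TSV ``alias<TAB>canonical`` (no header)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"id map line needs two columns: {line!r}")
        mapping[normalize_gene_id(parts[0])] = normalize_gene_id(parts[1])
    return IdMap(mapping)


def read_gene_list(
    path: str | Path,
    id_map: Optional[IdMap] = None,
    label: str = "",
    max_unresolved_fraction: float = 0.5,
) -> GeneList:
    """Read a plain-text gene list (one identifier per line, ``#`` comments).

    Unresolvable identifiers are collected and logged; the read only fails
    when more than ``max_unresolved_fraction`` of the lines are
    unresolvable, which usually signals a wrong-species or wrong-format
    input rather than a few stale symbols.
    """
    id_map = id_map or IdMap()
    tokens = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not tokens:
        raise ValueError("empty gene list")
    resolved: list[str] = []
    unresolved: list[str] = []
    seen: set[str] = set()
    duplicates = 0
    for tok in tokens:
        g = id_map.resolve(tok)
        if g is None:
            unresolved.append(tok)
        elif g in seen:
            duplicates += 1
        else:
            seen.add(g)
            resolved.append(g)
    if unresolved:
        logger.warning(
            "%d/%d identifiers unresolvable in %s (e.g. %s)",
            len(unresolved), len(tokens), path, unresolved[:5],
        )
    if len(unresolved) > max_unresolved_fraction * len(tokens):
        raise ValueError(
            f"{len(unresolved)} of {len(tokens)} identifiers unresolvable "
            f"(> {max_unresolved_fraction:.0%})"
        )
    if duplicates:
        logger.warning("%d duplicate identifiers dropped from %s", duplicates, path)
    if not resolved:
        raise ValueError("no resolvable identifiers in gene list")
    return GeneList(genes=tuple(resolved), label=label or Path(path).stem)


def read_gmt(path: str | Path, id_map: Optional[IdMap] = None) -> dict[str, Concept]:
    """Read one GMT file (one annotation category).

    Each line: ``concept-id<TAB>concept-name<TAB>gene...``.  Concepts with
    no member genes are dropped with a warning; a line with fewer than two
    fields, or a repeated concept id, is an error.
    """
    id_map = id_map or IdMap()
    concepts: dict[str, Concept] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (<2 fields)")
        cid, name = parts[0].strip(), parts[1].strip()
        if cid in concepts:
            raise ValueError(f"{path}:{lineno}: duplicate concept {cid!r}")
        members = frozenset(
            g for g in (id_map.resolve(t) for t in parts[2:] if t.strip()) if g
        )
        if not members:
            logger.warning("%s:%d: concept %s has no members, dropped", path, lineno, cid)
            continue
        concepts[cid] = Concept(concept_id=cid, name=name, members=members)
    return concepts


def corpus_from_gmt_files(
    files: Mapping[str, str | Path],
    id_map: Optional[IdMap] = None,
    background: Optional[Iterable[str]] = None,
) -> AnnotationCorpus:
    """Assemble an :class:`AnnotationCorpus` from ``{category: gmt-path}``.

    The background defaults to the union of all members across categories.
    """
    categories = {cat: read_gmt(p, id_map) for cat, p in files.items()}
    if background is None:
        bg: set[str] = set()
        for concepts in categories.values():
            for c in concepts.values():
                bg |= c.members
        background = bg
    return AnnotationCorpus(categories=categories, background=frozenset(background))


_EXPR_COLUMN_ALIASES = {
    "expression level": "expression_level",
    "expression_level": "expression_level",
    "fold change": "fold_change",
    "fold_change": "fold_change",
}


def read_expression_table(
    path: str | Path, id_map: Optional[IdMap] = None
) -> ExpressionTable:
    """Read a TSV expression table.

    The first column holds identifiers; value columns are matched
    case-insensitively against ``Expression level`` and ``Fold change``.
    Duplicate identifiers keep the row with the largest \\|fold change\\|
    (largest expression level when no fold-change column exists).
    """
    id_map = id_map or IdMap()
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    rename = {
        c: _EXPR_COLUMN_ALIASES[c.strip().lower()]
        for c in df.columns[1:]
        if c.strip().lower() in _EXPR_COLUMN_ALIASES
    }
    if not rename:
        raise ValueError(
            "expression table needs an 'Expression level' and/or 'Fold change' column"
        )
    df = df.rename(columns=rename)
    keep = [id_col] + sorted(set(rename.values()))
    df = df[keep]
    df["_id"] = [id_map.resolve(t) for t in df[id_col].astype(str)]
    n_unresolved = int(df["_id"].isna().sum())
    if n_unresolved:
        logger.warning("%d unresolvable identifiers dropped from %s", n_unresolved, path)
    df = df.dropna(subset=["_id"])
    if df["_id"].duplicated().any():
        if "fold_change" in df.columns:
            key = df["fold_change"].abs()
        else:
            key = df["expression_level"]
        logger.warning("duplicate identifiers in %s resolved by largest value", path)
        df = df.assign(_key=key).sort_values("_key").drop_duplicates("_id", keep="last")
        df = df.drop(columns="_key")
    rows = df.set_index("_id")[sorted(set(rename.values()))]
    rows.index.name = "id"
    return ExpressionTable(rows=rows.sort_index())


NODE_TYPES = ("miR", "mRNA", "concept", "interaction")


def write_network_gml(
    nodes: Sequence[Mapping], edges: Sequence[Mapping], path: str | Path
) -> None:
    """Write a typed, scored network as Cytoscape-compatible GML.

    ``nodes``: {id, type, score}; ``edges``: {src, dst, kind}.  An edge
    naming an undeclared node is an error.
    """
    ids = {n["id"] for n in nodes}
    g = nx.DiGraph()
    for n in sorted(nodes, key=lambda n: n["id"]):
        if n.get("type") not in NODE_TYPES:
            raise ValueError(f"node {n['id']}: unknown type {n.get('type')!r}")
        g.add_node(n["id"], type=n["type"], score=float(n.get("score", 0.0)))
    for e in sorted(edges, key=lambda e: (e["src"], e["dst"])):
        if e["src"] not in ids or e["dst"] not in ids:
            raise ValueError(f"edge ({e['src']}, {e['dst']}) references unknown node")
        g.add_edge(e["src"], e["dst"], kind=e.get("kind", ""))
    nx.write_gml(g, str(path))


def read_network_gml(path: str | Path) -> nx.DiGraph:
    return nx.read_gml(str(path))


def write_tsv(
    table: pd.DataFrame,
    path: str | Path,
    sort_by: Optional[Sequence[tuple[str, bool]]] = None,
) -> None:
    """Write a TSV with a deterministic row order.

    ``sort_by`` is a list of ``(column, ascending)`` pairs; it defaults to
    score descending with id/gene/mir ascending as tiebreak when those
    columns exist.
    """
    df = table.copy()
    if sort_by is None:
        sort_by = []
        for col, asc in (("score", False), ("final", False), ("sig", False)):
            if col in df.columns:
                sort_by.append((col, asc))
                break
        for col in ("id", "gene", "mir"):
            if col in df.columns:
                sort_by.append((col, True))
                break
    if sort_by:
        cols = [c for c, _ in sort_by]
        asc = [a for _, a in sort_by]
        df = df.sort_values(cols, ascending=asc, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
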