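"""Core domain types: gene sets (PAGs), collections, and ontology hierarchies.

A PAG (Pathway, Annotated gene list, or Gene signature) is a named gene set
with a free-text description.  Collections of PAGs are exchanged in the GMT
format (one tab-separated record per line: id, description, genes...).
Ontology hierarchies are ingested as plain child->parent (is-a) edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "PAG",
    "GeneSetCollection",
    "OntologyDAG",
    "GmtParseError",
    "ValidationError",
    "read_gmt",
    "write_gmt",
    "read_descriptions",
    "write_descriptions",
    "read_ontology_edges",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


class ValidationError(ValueError):
    """Raised when domain invariants are violated (duplicate ids, cycles...)."""


@dataclass(frozen=True)
class PAG:
    """A named gene set.

    Gene identifiers are opaque strings, compared case-sensitively after
    whitespace trimming.  ``genes`` preserves first-occurrence order so that
    serialisation round-trips exactly; duplicates are collapsed.
    """

    id: str
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("PAG id must be non-empty")
        cleaned = _dedup([g.strip() for g in self.genes if g.strip()])
        object.__setattr__(self, "genes", tuple(cleaned))

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _dedup(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it)
    return list(seen)


@dataclass
class GeneSetCollection:
    """An ordered list of PAGs plus the gene universe (background).

    When no explicit background is supplied the universe is exactly the union
    of all member gene sets.
    """

    pags: list[PAG]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pags]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate PAG ids: {sorted(dupes)}")
        union = frozenset().union(*(p.gene_set for p in self.pags)) if self.pags else frozenset()
        if not self.universe:
            self.universe = union
        elif not union <= self.universe:
            raise ValidationError(
                f"universe is missing {len(union - self.universe)} member genes"
            )

    def __len__(self) -> int:
        return len(self.pags)

    def __iter__(self):
        return iter(self.pags)

    def __getitem__(self, pag_id: str) -> PAG:
        for p in self.pags:
            if p.id == pag_id:
                return p
        raise KeyError(pag_id)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pags]

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        """Collection restricted to ``ids`` (order taken from ``ids``)."""
        return GeneSetCollection([self[i] for i in ids], universe=self.universe)

    def descriptions(self) -> dict[str, str]:
        return {p.id: p.description for p in self.pags}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, tab-separated
    ``id<TAB>description<TAB>gene1<TAB>gene2...``.

    Raises :class:`GmtParseError` (naming the line number) on lines with
    fewer than three fields, and :class:`ValidationError` on duplicate ids.
    """
    pags: list[PAG] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid, desc, genes = fields[0].strip(), fields[1], fields[2:]
            pags.append(PAG(id=pid, name=pid, description=desc, genes=tuple(genes)))
    return GeneSetCollection(pags)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in collection:
            fh.write("\t".join([p.id, p.description, *p.genes]) + "\n")


def read_descriptions(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV of id -> free text. Missing text yields ''."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            out[parts[0].strip()] = parts[1] if len(parts) > 1 else ""
    return out


def write_descriptions(descriptions: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, text in descriptions.items():
            fh.write(f"{pid}\t{text}\n")


class OntologyDAG:
    """A directed acyclic graph of ontology terms with child->parent is-a edges."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        if names:
            for node in names:
                g.add_node(node)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise ValidationError(f"ontology edge list contains a cycle: {cycle}")
        self.graph = g  # edges point child -> parent
        self.names = dict(names or {})

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def roots(self) -> list[str]:
        """Nodes with no parent (no outgoing child->parent edge)."""
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return sorted(self.graph.predecessors(term))

    def depth(self, term: str, root: str) -> int | None:
        """Shortest-path distance from ``root`` down to ``term`` along is-a
        edges (None when unreachable).  depth(root, root) == 0."""
        try:
            return nx.shortest_path_length(self.graph, source=term, target=root)
        except nx.NetworkXNoPath:
            return None
        except nx.NodeNotFound:
            return None


def read_ontology_edges(
    path: str | Path, names_path: str | Path | None = None
) -> OntologyDAG:
    """Read a 2-column TSV of child-id, parent-id is-a edges.

    An optional sidecar TSV maps term id -> display name/description.
    Cycles raise :class:`ValidationError`.
    """
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            edges.append((parts[0].strip(), parts[1].strip()))
    names = read_descriptions(names_path) if names_path else None
    return OntologyDAG(edges, names=names)
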