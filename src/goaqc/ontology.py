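"""Ontology DAG handling: loading, validation, traversal, and the merged
specificity graph.

The Gene Ontology is a multi-rooted directed acyclic graph whose terms are
connected by hierarchical ``is_a`` and ``part_of`` relations (child points to
parent).  Both relation types carry specificity information: a child term
describes a strictly narrower concept than any of its parents.  Everything in
this package that reasons about over-specific / over-broad annotation errors
is grounded in the traversal primitives defined here.

Two graph views are provided:

* :class:`OntologyDag` — the typed child→parent DAG as loaded from an edge
  list or a restricted OBO file.
* :class:`SpecificityGraph` — the pre-training view in which ``is_a`` and
  ``part_of`` are merged into a single ``children_of`` edge type and every
  edge is mirrored by an untyped-reverse ``parent_of`` edge, so that a
  hierarchy encoder sees direction but not relation subtype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

RELATION_TYPES = ("is_a", "part_of")

#: edge types of the merged specificity view
CHILDREN_OF = "children_of"
PARENT_OF = "parent_of"

_ID_PATTERN = re.compile(r"^(GO:[0-9]{7}|T:[0-9]+)$")


class OntologyError(ValueError):
    """Structural problem in ontology input (cycle, dangling edge, bad relation)."""


class UnknownTermError(KeyError):
    """Lookup of a term id that is not part of the DAG."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    ``id`` is a CURIE (``GO:0005085`` for real data; fixtures use the relaxed
    ``T:<n>`` form).  ``namespace`` is one of the three GO sub-ontologies.
    """

    id: str
    name: str
    namespace: str = "biological_process"
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _ID_PATTERN.match(self.id):
            raise OntologyError(f"term id {self.id!r} is not a valid CURIE")
        if not self.name:
            raise OntologyError(f"term {self.id} has an empty name")


class OntologyDag:
    """Validated child→parent DAG over :class:`OntologyTerm` nodes.

    Multiple parents (across either relation type) are allowed; the graph is
    rejected if it contains a cycle, a self-loop, an edge endpoint without a
    declared term, or a relation outside ``{is_a, part_of}``.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        edges: Iterable[tuple[str, str, str]],
    ) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id}")
            self.terms[t.id] = t

        # child -> parent digraph; edge data keeps the relation subtype
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.terms)
        self.edges: set[tuple[str, str, str]] = set()
        for child, parent, relation in edges:
            if relation not in RELATION_TYPES:
                raise OntologyError(
                    f"unknown relation {relation!r} on edge ({child}, {parent})"
                )
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyError(
                        f"edge ({child}, {parent}, {relation}) references "
                        f"undeclared term {endpoint!r}"
                    )
            if child == parent:
                raise OntologyError(f"self-loop on {child}")
            self.edges.add((child, parent, relation))
            self._g.add_edge(child, parent, relation=relation)

        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    # -- basic protocol ----------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDag):
            return NotImplemented
        return self.terms == other.terms and self.edges == other.edges

    def name_of(self, term_id: str) -> str:
        return self._term(term_id).name

    def _term(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    # -- traversal ---------------------------------------------------------
    def ancestors(self, term_id: str) -> set[str]:
        """All proper ancestors reachable over any mix of is_a/part_of edges."""
        self._term(term_id)
        return set(nx.descendants(self._g, term_id))  # child->parent orientation

    def descendants(self, term_id: str) -> set[str]:
        self._term(term_id)
        return set(nx.ancestors(self._g, term_id))

    def direct_parents(self, term_id: str) -> set[str]:
        self._term(term_id)
        return set(self._g.successors(term_id))

    def direct_children(self, term_id: str) -> set[str]:
        """Terms with an edge (child, term_id, *); empty set for a leaf."""
        self._term(term_id)
        return set(self._g.predecessors(term_id))

    @property
    def roots(self) -> set[str]:
        """Terms without any parent.

        These correspond to namespace roots (extremely broad concepts such as
        "biological process"); corpus synthesis excludes them from over-broad
        replacement because they carry no usable specificity signal.
        """
        return {t for t in self.terms if not self._g.out_degree(t)}

    def related(self, a: str, b: str) -> bool:
        """True iff a == b or the two terms are in an ancestor/descendant relation."""
        return a == b or b in self.ancestors(a) or a in self.ancestors(b)

    # -- transforms --------------------------------------------------------
    def extract_subgraph(
        self, seed_terms: Iterable[str], closure: str = "children"
    ) -> "OntologyDag":
        """Induced sub-DAG over the seed terms plus their closure.

        ``closure`` is ``"children"`` (direct children of each seed, the
        default), ``"ancestors"``, or ``"both"``.  Only is_a/part_of edges are
        represented in this package, so nothing else can leak in.  An empty
        seed set yields an empty DAG.
        """
        seeds = set(seed_terms)
        for s in seeds:
            self._term(s)
        if closure not in ("children", "ancestors", "both"):
            raise ValueError(f"unknown closure mode {closure!r}")
        keep = set(seeds)
        if closure in ("children", "both"):
            for s in seeds:
                keep |= self.direct_children(s)
        if closure in ("ancestors", "both"):
            for s in seeds:
                keep |= self.ancestors(s)
        sub_edges = [
            (c, p, r) for (c, p, r) in self.edges if c in keep and p in keep
        ]
        return OntologyDag((self.terms[t] for t in sorted(keep)), sub_edges)


@dataclass(frozen=True)
class SpecificityGraph:
    """Merged-edge view used to pre-train the hierarchy encoder.

    Each DAG edge (child, parent, is_a|part_of) becomes one ``children_of``
    edge (child, parent) plus the mirrored ``parent_of`` edge (parent, child).
    The relation subtype is deliberately discarded so the encoder can only
    learn broad/narrow direction, not the subtype label.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, str]] = field(repr=False)

    def typed_edges(self, relation: str) -> set[tuple[str, str]]:
        return {(a, b) for (a, b, r) in self.edges if r == relation}


def build_specificity_graph(dag: OntologyDag) -> SpecificityGraph:
    """Merge is_a/part_of into children_of and mirror every edge as parent_of."""
    edges: set[tuple[str, str, str]] = set()
    for child, parent, _relation in dag.edges:
        edges.add((child, parent, CHILDREN_OF))
        edges.add((parent, child, PARENT_OF))
    return SpecificityGraph(nodes=frozenset(dag.terms), edges=frozenset(edges))


# -- loading ---------------------------------------------------------------

def load_dag(
    edge_records: Sequence[tuple[str, str, str]],
    terms: Sequence[OntologyTerm],
) -> OntologyDag:
    """Validate raw records into an :class:`OntologyDag` (cycle check included)."""
    return OntologyDag(terms, edge_records)


def read_terms_tsv(path) -> list[OntologyTerm]:
    """Read a term table ``id<TAB>name<TAB>namespace`` (comment lines skipped)."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise OntologyError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            terms.append(OntologyTerm(id=parts[0], name=parts[1], namespace=parts[2]))
    return terms


def read_edges_tsv(path) -> list[tuple[str, str, str]]:
    """Read an edge list ``child<TAB>parent<TAB>relation``."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise OntologyError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            edges.append((parts[0], parts[1], parts[2]))
    return edges


def write_dag_tsv(dag: OntologyDag, terms_path, edges_path, header: str = "") -> None:
    with open(terms_path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for t in sorted(dag.terms.values(), key=lambda t: t.id):
            fh.write(f"{t.id}\t{t.name}\t{t.namespace}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for c, p, r in sorted(dag.edges):
            fh.write(f"{c}\t{p}\t{r}\n")


def read_obo(path) -> OntologyDag:
    """Read a restricted OBO file.

    Only ``id``, ``name``, ``namespace``, ``is_a`` and ``relationship:
    part_of`` stanza lines are interpreted; every other tag (definitions,
    xrefs, regulates-style relationships, obsoletion metadata) is ignored.
    """
    import obonet

    g = obonet.read_obo(path, ignore_obsolete=True)
    terms = []
    edges = []
    for node, data in g.nodes(data=True):
        terms.append(
            OntologyTerm(
                id=node,
                name=data.get("name", node),
                namespace=data.get("namespace", "biological_process"),
                synonyms=tuple(data.get("synonym", ())),
            )
        )
    for child, parent, key in g.edges(keys=True):
        if key in RELATION_TYPES:
            edges.append((child, parent, key))
    return OntologyDag(terms, edges)
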