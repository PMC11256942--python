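"""Heterogeneous GOA knowledge graph and its edge-type-classification encoder.

Every annotation record is modeled as an edge between a PMG node (the PMID +
gene pair that identifies one piece of literature evidence for one gene) and
a GO term node.  Consistent records become ``annotate`` edges, inconsistent
records — irrespective of inconsistency type — become ``not_annotate`` edges,
and a gene's existing annotations (background knowledge) contribute further
``annotate`` edges to the same PMG node.  The graph is undirected and
strictly bipartite: edges exist only between PMG and GO nodes.

A three-layer heterogeneous SAGE encoder is pre-trained to classify edge
types from the concatenated 8-dim embeddings of the two endpoints; the
embeddings read off the last convolution layer then summarize co-annotation
structure (genes annotated to the same terms end up close) and are consumed
downstream by the joint classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    EncoderConfig,
    HeteroSageEncoder,
    MlpHead,
    PairClassifierModel,
    TrainingError,
    normalized_adjacency,
    per_id_normal_vector,
    train_pair_classifier,
)

ANNOTATE = "annotate"
NOT_ANNOTATE = "not_annotate"
EDGE_TYPES = (ANNOTATE, NOT_ANNOTATE)


class GraphDataError(ValueError):
    """Conflicting or malformed annotation-graph input."""


@dataclass(frozen=True, order=True)
class PmgKey:
    """Composite evidence key: one PMID paired with one gene id."""

    pmid: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.pmid or not self.gene_id:
            raise GraphDataError("PMG key components must be non-empty")

    @property
    def canonical(self) -> str:
        return f"{self.pmid}_{self.gene_id}"


@dataclass(frozen=True)
class HeteroAnnotationGraph:
    """Bipartite PMG/GO graph with typed (annotate / not_annotate) edges."""

    pmg_nodes: tuple[str, ...]  # canonical PMG strings, sorted
    go_nodes: tuple[str, ...]  # GO CURIEs, sorted
    edges: frozenset[tuple[str, str, str]]  # (pmg_canonical, go_id, edge_type)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lists(self) -> dict[str, list[tuple[int, int]]]:
        """Per edge type: (pmg_index, go_index) pairs, deterministically ordered."""
        pmg_index = {p: i for i, p in enumerate(self.pmg_nodes)}
        go_index = {g: i for i, g in enumerate(self.go_nodes)}
        out: dict[str, list[tuple[int, int]]] = {t: [] for t in EDGE_TYPES}
        for pmg, go, et in sorted(self.edges):
            out[et].append((pmg_index[pmg], go_index[go]))
        return out


def build_annotation_graph(
    instances, include_background: bool = True, include_candidate: bool = True
) -> HeteroAnnotationGraph:
    """Assemble the heterogeneous graph from labeled instances.

    Consistent (CO) instances yield ``annotate`` edges, all inconsistency
    labels yield ``not_annotate`` edges, and each id in an instance's
    ``existing_go_ids`` yields a background ``annotate`` edge with the same
    PMG node.  At most one edge per (PMG, GO) pair: an instance edge takes
    precedence over a background edge; two instances that assert different
    edge types for the same pair are a data error.  ``include_candidate=False``
    drops the instances' own candidate edges (used when encoding held-out
    instances, so the edge under prediction never participates in message
    passing) while keeping the background edges.
    """
    instance_edge: dict[tuple[str, str], str] = {}
    background_pairs: set[tuple[str, str]] = set()
    for inst in instances:
        pmg = PmgKey(inst.pmid, inst.gene_id).canonical
        et = ANNOTATE if inst.label == "CO" else NOT_ANNOTATE
        key = (pmg, inst.go_id)
        if include_candidate:
            if key in instance_edge and instance_edge[key] != et:
                raise GraphDataError(
                    f"conflicting edge types for {pmg} -- {inst.go_id}"
                )
            instance_edge[key] = et
        if include_background:
            for existing in inst.existing_go_ids or ():
                background_pairs.add((pmg, existing))
    edges: set[tuple[str, str, str]] = {
        (pmg, go, et) for (pmg, go), et in instance_edge.items()
    }
    for pmg, go in background_pairs:
        if (pmg, go) not in instance_edge:
            edges.add((pmg, go, ANNOTATE))
    pmg_nodes = tuple(sorted({pmg for pmg, _go, _et in edges}))
    go_nodes = tuple(sorted({go for _pmg, go, _et in edges}))
    return HeteroAnnotationGraph(pmg_nodes, go_nodes, frozenset(edges))


#: message-passing schema of the undirected bipartite graph: each edge type
#: passes messages in both directions.
RELATIONS = [
    (f"{et}__{src}_to_{dst}", src, dst)
    for et in EDGE_TYPES
    for src, dst in (("go", "pmg"), ("pmg", "go"))
]


def graph_adjacency(graph: HeteroAnnotationGraph) -> dict[str, np.ndarray]:
    """Row-normalized aggregation matrices for every relation in the schema."""
    n_pmg, n_go = len(graph.pmg_nodes), len(graph.go_nodes)
    by_type = graph.edge_lists()
    adj: dict[str, np.ndarray] = {}
    for et in EDGE_TYPES:
        pairs = by_type[et]
        adj[f"{et}__go_to_pmg"] = normalized_adjacency(
            n_pmg, n_go, [(g, p) for p, g in pairs]
        )
        adj[f"{et}__pmg_to_go"] = normalized_adjacency(
            n_go, n_pmg, [(p, g) for p, g in pairs]
        )
    return adj


def init_node_features(
    graph: HeteroAnnotationGraph, dim: int = 8, seed: int = 0
) -> dict[str, np.ndarray]:
    """All-ones vectors for PMG nodes; deterministic per-id normals for GO nodes.

    The GO initialization is keyed by (seed, GO id), so the same term gets
    identical initial features in any graph built under the same seed.
    """
    pmg = np.ones((len(graph.pmg_nodes), dim))
    go = np.stack(
        [per_id_normal_vector(seed, go_id, dim) for go_id in graph.go_nodes]
    ) if graph.go_nodes else np.zeros((0, dim))
    return {"pmg": pmg, "go": go}


@dataclass
class NodeEmbeddingTable:
    """Exported node-id -> vector map with a fixed dimension."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.vectors

    def lookup(self, node_id: str) -> np.ndarray | None:
        """Vector for ``node_id``, or ``None`` as an explicit missing signal."""
        return self.vectors.get(node_id)

    def embeddings_for(self, inst) -> tuple[np.ndarray | None, np.ndarray | None]:
        """(PMG vector, GO vector) for one instance; ``None`` where missing."""
        pmg = PmgKey(inst.pmid, inst.gene_id).canonical
        return self.lookup(pmg), self.lookup(inst.go_id)

    def write_tsv(self, path, header: str = "") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"# {header}\n")
            for node_id in sorted(self.vectors):
                vals = "\t".join(f"{v:.10g}" for v in self.vectors[node_id])
                fh.write(f"{node_id}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path) -> "NodeEmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        dim = 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
                dim = len(parts) - 1
        return cls(dim=dim, vectors=vectors)


@dataclass
class HeldOutEmbeddings:
    """Per-instance endpoint embeddings under the leave-candidate-out protocol.

    For every instance, the split's full graph (background annotate edges and
    the other instances' candidate edges) is encoded with that instance's own
    candidate edge removed from message passing, and the embeddings of its
    PMG and GO endpoints are stored.  This keeps the edge under prediction —
    whose type is exactly the label — out of its own features.
    """

    dim: int
    pairs: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def embeddings_for(self, inst) -> tuple[np.ndarray | None, np.ndarray | None]:
        pair = self.pairs.get(inst.key)
        if pair is None:
            return None, None
        return pair


def export_held_out_embeddings(
    model: "PairClassifierModel",
    instances,
    seed: int = 0,
    include_background: bool = True,
) -> HeldOutEmbeddings:
    """Encode each instance on its split graph minus its own candidate edge."""
    graph = build_annotation_graph(
        instances, include_background=include_background, include_candidate=True
    )
    dim = model.encoder.dim
    features = init_node_features(graph, dim, seed)
    pmg_index = {p: i for i, p in enumerate(graph.pmg_nodes)}
    go_index = {g: i for i, g in enumerate(graph.go_nodes)}
    out = HeldOutEmbeddings(dim=dim)
    base_edges = graph.edge_lists()
    n_pmg, n_go = len(graph.pmg_nodes), len(graph.go_nodes)
    for inst in instances:
        pmg = PmgKey(inst.pmid, inst.gene_id).canonical
        pi, gi = pmg_index[pmg], go_index[inst.go_id]
        adj: dict[str, np.ndarray] = {}
        for et in EDGE_TYPES:
            pairs = [(p, g) for p, g in base_edges[et] if (p, g) != (pi, gi)]
            adj[f"{et}__go_to_pmg"] = normalized_adjacency(
                n_pmg, n_go, [(g, p) for p, g in pairs]
            )
            adj[f"{et}__pmg_to_go"] = normalized_adjacency(
                n_go, n_pmg, [(p, g) for p, g in pairs]
            )
        h = model.encoder.forward(features, adj)
        out.pairs[inst.key] = (h["pmg"].data[pi].copy(), h["go"].data[gi].copy())
    return out


def train_edge_classifier(
    graph: HeteroAnnotationGraph,
    features: dict[str, np.ndarray],
    cfg: EncoderConfig | None = None,
) -> tuple[PairClassifierModel, dict[str, list[float]]]:
    """Pre-train the encoder by classifying edges as annotate / not_annotate.

    The head consumes the two concatenated endpoint vectors (2 x node_dim)
    and emits a 2-logit vector; training minimizes cross-entropy over all
    edges, full batch.  Requires at least one edge of each type.
    """
    cfg = cfg or EncoderConfig()
    by_type = graph.edge_lists()
    if any(not by_type[et] for et in EDGE_TYPES):
        raise TrainingError(
            "edge-type classification needs at least one edge of each type"
        )
    rng = np.random.default_rng(cfg.seed)
    encoder = HeteroSageEncoder(RELATIONS, cfg.node_dim, cfg.n_layers, rng)
    head = MlpHead(2 * cfg.node_dim, cfg.hidden_dim, len(EDGE_TYPES), rng)
    iu, iv, labels = [], [], []
    for cls_idx, et in enumerate(EDGE_TYPES):
        for p, g in by_type[et]:
            iu.append(p)
            iv.append(g)
            labels.append(cls_idx)
    metrics = train_pair_classifier(
        encoder,
        head,
        features,
        graph_adjacency(graph),
        ("pmg", "go"),
        np.array(iu),
        np.array(iv),
        np.array(labels),
        cfg,
    )
    model = PairClassifierModel(encoder, head, cfg, EDGE_TYPES)
    return model, metrics


def export_embeddings(
    model: PairClassifierModel,
    graph: HeteroAnnotationGraph,
    features: dict[str, np.ndarray],
) -> NodeEmbeddingTable:
    """Last-layer embeddings for every node, keyed by canonical id.

    Purely a function of features and topology, so it works inductively on
    graphs never seen during training.
    """
    dim = model.encoder.dim
    if any(mat.shape[1] != dim for mat in features.values()):
        raise ValueError("feature dimension does not match the trained encoder")
    h = model.encoder.forward(features, graph_adjacency(graph))
    table = NodeEmbeddingTable(dim=dim)
    for i, pmg in enumerate(graph.pmg_nodes):
        table.vectors[pmg] = h["pmg"].data[i].copy()
    for i, go in enumerate(graph.go_nodes):
        table.vectors[go] = h["go"].data[i].copy()
    return table
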