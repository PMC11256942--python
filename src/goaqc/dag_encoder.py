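"""Hierarchy (specificity) encoder over the merged-edge ontology view.

Over-specific / over-broad annotation errors are errors of *specificity*:
the chosen term sits too deep or too high in the ontology relative to what
the evidence supports.  To give the classifier access to that signal, term
nodes of the merged :class:`~goaqc.ontology.SpecificityGraph` (``children_of``
/ ``parent_of`` edges, relation subtypes discarded) are embedded in 16
dimensions by the same heterogeneous SAGE family used for the annotation
graph.

The pre-training objective is a 3-way ordered-pair classification: given the
embeddings of terms (a, b), predict whether a is a child of b, a parent of
b, or unrelated.  Negative (``no_edge``) pairs are sampled uniformly at a
1:1 ratio per positive and exclude transitive ancestor/descendant pairs,
which are hierarchically related even though no single edge connects them.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

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
from .goa_graph import NodeEmbeddingTable
from .ontology import CHILDREN_OF, PARENT_OF, SpecificityGraph

PAIR_CLASSES = (CHILDREN_OF, PARENT_OF, "no_edge")

#: both merged relations connect term nodes to term nodes
RELATIONS = [
    (CHILDREN_OF, "term", "term"),
    (PARENT_OF, "term", "term"),
]


def _node_order(graph: SpecificityGraph) -> list[str]:
    return sorted(graph.nodes)


def spec_graph_adjacency(graph: SpecificityGraph) -> dict[str, np.ndarray]:
    index = {t: i for i, t in enumerate(_node_order(graph))}
    n = len(index)
    adj = {}
    for rel in (CHILDREN_OF, PARENT_OF):
        pairs = [(index[a], index[b]) for a, b in sorted(graph.typed_edges(rel))]
        adj[rel] = normalized_adjacency(n, n, pairs)
    return adj


def init_term_features(graph: SpecificityGraph, dim: int = 16, seed: int = 0) -> dict[str, np.ndarray]:
    """Deterministic per-term-id standard-normal initial features."""
    order = _node_order(graph)
    if not order:
        return {"term": np.zeros((0, dim))}
    return {
        "term": np.stack([per_id_normal_vector(seed, t, dim) for t in order])
    }


def _sample_training_pairs(
    graph: SpecificityGraph, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive pairs from edges plus 1:1 uniformly sampled no_edge pairs.

    Unrelated means: no edge in either direction and no transitive
    ancestor/descendant path over ``children_of`` edges.
    """
    order = _node_order(graph)
    index = {t: i for i, t in enumerate(order)}
    children_edges = graph.typed_edges(CHILDREN_OF)
    reach = nx.DiGraph()
    reach.add_nodes_from(order)
    reach.add_edges_from(children_edges)
    related: set[tuple[int, int]] = set()
    for t in order:
        for anc in nx.descendants(reach, t):  # t reaches anc => anc is an ancestor
            related.add((index[t], index[anc]))
            related.add((index[anc], index[t]))

    iu, iv, labels = [], [], []
    for cls_idx, rel in enumerate((CHILDREN_OF, PARENT_OF)):
        for a, b in sorted(graph.typed_edges(rel)):
            iu.append(index[a])
            iv.append(index[b])
            labels.append(cls_idx)
    n_pos = len(iu)
    n = len(order)
    no_edge_cls = PAIR_CLASSES.index("no_edge")
    attempts = 0
    drawn = 0
    seen_neg: set[tuple[int, int]] = set()
    while drawn < n_pos and attempts < 200 * max(n_pos, 1):
        attempts += 1
        a, b = int(rng.integers(n)), int(rng.integers(n))
        if a == b or (a, b) in related or (a, b) in seen_neg:
            continue
        seen_neg.add((a, b))
        iu.append(a)
        iv.append(b)
        labels.append(no_edge_cls)
        drawn += 1
    return np.array(iu), np.array(iv), np.array(labels)


def train_dag_encoder(
    spec_graph: SpecificityGraph, cfg: EncoderConfig | None = None
) -> tuple[PairClassifierModel, dict[str, list[float]]]:
    """Pre-train the 16-dim hierarchy encoder by ordered-pair classification."""
    cfg = cfg or EncoderConfig(node_dim=16)
    if not spec_graph.nodes:
        raise TrainingError("empty specificity graph")
    if not spec_graph.typed_edges(CHILDREN_OF) or not spec_graph.typed_edges(PARENT_OF):
        raise TrainingError("both children_of and parent_of edges are required")
    rng = np.random.default_rng(cfg.seed)
    encoder = HeteroSageEncoder(RELATIONS, cfg.node_dim, cfg.n_layers, rng)
    head = MlpHead(2 * cfg.node_dim, cfg.hidden_dim, len(PAIR_CLASSES), rng)
    iu, iv, labels = _sample_training_pairs(spec_graph, rng)
    metrics = train_pair_classifier(
        encoder,
        head,
        init_term_features(spec_graph, cfg.node_dim, cfg.seed),
        spec_graph_adjacency(spec_graph),
        ("term", "term"),
        iu,
        iv,
        labels,
        cfg,
    )
    return PairClassifierModel(encoder, head, cfg, PAIR_CLASSES), metrics


def export_dag_embeddings(
    model: PairClassifierModel, spec_graph: SpecificityGraph
) -> NodeEmbeddingTable:
    """16-dim embeddings for every term in the sub-graph.

    Unseen terms are simply absent from the table; consumers receive the
    explicit missing signal from :meth:`NodeEmbeddingTable.lookup`.
    """
    features = init_term_features(spec_graph, model.encoder.dim, model.cfg.seed)
    h = model.encoder.forward(features, spec_graph_adjacency(spec_graph))
    table = NodeEmbeddingTable(dim=model.encoder.dim)
    for i, term in enumerate(_node_order(spec_graph)):
        table.vectors[term] = h["term"].data[i].copy()
    return table
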