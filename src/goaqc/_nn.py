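"""Shared neural components: heterogeneous SAGE encoder, MLP head, training loop.

The two knowledge encoders in this package (annotation-graph encoder and
hierarchy encoder) share one architecture family: a stack of heterogeneous
graph convolution layers, where each layer

1. runs one GraphSAGE-style sub-layer per edge type (mean over neighbors of
   that type, concatenated with the node's own vector, linearly projected),
2. combines the per-edge-type outputs by summation,
3. applies ReLU, then batch normalization over the nodes of each type.

A one-hidden-layer MLP head over the concatenation of two endpoint
embeddings turns the encoder into an edge/pair classifier.  The encoder is
inductive: it consumes only node feature matrices and (row-normalized)
adjacency, never node identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, parameter, zeros_parameter

_BN_EPS = 1e-5


class TrainingError(RuntimeError):
    """Raised for untrainable inputs (single edge type) or numerical failure."""


@dataclass
class EncoderConfig:
    """Hyper-parameters of a graph knowledge encoder.

    Defaults mirror the reference setup: 8-dim node vectors for the
    annotation graph (the hierarchy encoder overrides ``node_dim=16``),
    three convolution layers, and a small MLP classification head.
    """

    node_dim: int = 8
    n_layers: int = 3
    hidden_dim: int = 16
    epochs: int = 200
    learning_rate: float = 1e-2
    seed: int = 0


#: relation schema entry: (relation_name, src_node_type, dst_node_type)
Relation = tuple[str, str, str]


def normalized_adjacency(
    n_dst: int, n_src: int, edges: list[tuple[int, int]]
) -> np.ndarray:
    """Dense (n_dst x n_src) mean-aggregation matrix from (src, dst) index pairs."""
    a = np.zeros((n_dst, n_src))
    for src, dst in edges:
        a[dst, src] = 1.0
    deg = a.sum(axis=1, keepdims=True)
    deg[deg == 0.0] = 1.0
    return a / deg


class HeteroSageEncoder:
    """Stack of per-edge-type mean-SAGE layers with sum combination, ReLU, BN."""

    def __init__(self, relations: list[Relation], dim: int, n_layers: int,
                 rng: np.random.Generator):
        self.relations = list(relations)
        self.dim = dim
        self.n_layers = n_layers
        node_types = sorted({r[2] for r in relations} | {r[1] for r in relations})
        for nt in node_types:
            if not any(r[2] == nt for r in relations):
                raise ValueError(f"node type {nt!r} receives no messages")
        self._weights: list[dict[str, tuple[Tensor, Tensor]]] = []
        self._bn: list[dict[str, tuple[Tensor, Tensor]]] = []
        for _ in range(n_layers):
            layer_w = {
                rel: (parameter(rng, (2 * dim, dim)), zeros_parameter((dim,)))
                for rel, _src, _dst in relations
            }
            layer_bn = {
                nt: (Tensor(np.ones(dim), requires_grad=True), zeros_parameter((dim,)))
                for nt in node_types
            }
            self._weights.append(layer_w)
            self._bn.append(layer_bn)

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer_w, layer_bn in zip(self._weights, self._bn):
            for w, b in layer_w.values():
                out.extend([w, b])
            for gamma, beta in layer_bn.values():
                out.extend([gamma, beta])
        return out

    def forward(
        self,
        features: dict[str, np.ndarray],
        adjacency: dict[str, np.ndarray],
    ) -> dict[str, Tensor]:
        """Return last-layer node embeddings per node type.

        ``adjacency[rel]`` is the (n_dst x n_src) mean-aggregation matrix for
        that relation; relations absent from ``adjacency`` contribute zero
        messages (their aggregate is an all-zero matrix).
        """
        for nt, mat in features.items():
            if mat.shape[1] != self.dim:
                raise ValueError(
                    f"feature dim {mat.shape[1]} for {nt!r} != encoder dim {self.dim}"
                )
        h: dict[str, Tensor] = {nt: Tensor(mat) for nt, mat in features.items()}
        for layer_w, layer_bn in zip(self._weights, self._bn):
            new_h: dict[str, Tensor] = {}
            for nt in h:
                z: Tensor | None = None
                n_dst = h[nt].shape[0]
                for rel, src, dst in self.relations:
                    if dst != nt:
                        continue
                    a = adjacency.get(rel)
                    if a is None:
                        agg = Tensor(np.zeros((n_dst, self.dim)))
                    else:
                        agg = a @ h[src]
                    w, b = layer_w[rel]
                    part = Tensor.concat_cols([h[nt], agg]) @ w + b
                    z = part if z is None else z + part
                assert z is not None
                z = z.relu()
                gamma, beta = layer_bn[nt]
                mu = z.mean(axis=0, keepdims=True)
                centered = z - mu
                var = (centered * centered).mean(axis=0, keepdims=True)
                zhat = centered * (var + _BN_EPS).pow(-0.5)
                new_h[nt] = zhat * gamma + beta
            h = new_h
        return h


class MlpHead:
    """One-hidden-layer perceptron: in -> hidden (ReLU) -> logits."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator):
        self.w1 = parameter(rng, (in_dim, hidden_dim))
        self.b1 = zeros_parameter((hidden_dim,))
        self.w2 = parameter(rng, (hidden_dim, out_dim))
        self.b2 = zeros_parameter((out_dim,))

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: Tensor) -> Tensor:
        return (x @ self.w1 + self.b1).relu() @ self.w2 + self.b2


@dataclass
class PairClassifierModel:
    """Graph encoder plus pair-classification head, with its config snapshot."""

    encoder: HeteroSageEncoder
    head: MlpHead
    cfg: EncoderConfig
    classes: tuple[str, ...]


def train_pair_classifier(
    encoder: HeteroSageEncoder,
    head: MlpHead,
    features: dict[str, np.ndarray],
    adjacency: dict[str, np.ndarray],
    pair_types: tuple[str, str],
    iu: np.ndarray,
    iv: np.ndarray,
    labels: np.ndarray,
    cfg: EncoderConfig,
) -> dict[str, list[float]]:
    """Full-batch training of encoder+head on labeled node pairs.

    Returns the loss and training-accuracy curves.  Raises
    :class:`TrainingError` on NaN loss, naming the epoch.
    """
    tu, tv = pair_types
    labels = np.asarray(labels, dtype=np.intp)
    opt = Adam(encoder.params + head.params, lr=cfg.learning_rate)
    losses: list[float] = []
    accs: list[float] = []
    for epoch in range(cfg.epochs):
        h = encoder.forward(features, adjacency)
        x = Tensor.concat_cols([h[tu].take_rows(iu), h[tv].take_rows(iv)])
        logits = head.forward(x)
        loss = logits.cross_entropy(labels)
        if not np.isfinite(loss.data):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        accs.append(float((np.argmax(logits.data, axis=1) == labels).mean()))
    return {"loss": losses, "accuracy": accs}


def predict_pairs(
    model: PairClassifierModel,
    features: dict[str, np.ndarray],
    adjacency: dict[str, np.ndarray],
    pair_types: tuple[str, str],
    iu: np.ndarray,
    iv: np.ndarray,
) -> np.ndarray:
    """Argmax class indices for node pairs (ties resolved to the lower index)."""
    h = model.encoder.forward(features, adjacency)
    tu, tv = pair_types
    x = Tensor.concat_cols([h[tu].take_rows(iu), h[tv].take_rows(iv)])
    return np.argmax(model.head.forward(x).data, axis=1)


def per_id_normal_vector(seed: int, node_id: str, dim: int) -> np.ndarray:
    """Deterministic standard-normal vector keyed by (seed, node id).

    The same id receives the same initial features in any graph, which keeps
    pre-training and held-out encoding comparable without the encoder itself
    ever consuming identities.
    """
    import hashlib

    digest = hashlib.blake2b(
        f"{seed}|{node_id}".encode("utf-8"), digest_size=8
    ).digest()
    sub_seed = int.from_bytes(digest, "little") % (2**63)
    return np.random.default_rng(sub_seed).standard_normal(dim)
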