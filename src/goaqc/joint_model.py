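"""Joint graph+text five-class inconsistency classifier.

The classifier consumes one annotation record as a text pair — segment A
carries the annotation under scrutiny (GO term name and gene identifier),
segment B the evidence text (or a GeneRIF statement, or marker-reformulated
evidence, depending on the variant) — and, per variant, concatenates the
pooled text vector with pre-trained knowledge embeddings:

``pooled ‖ goa[PMG] ‖ goa[GO] ‖ dag[GO]``

where ``goa`` is the 8-dim annotation-graph table, ``dag`` the 16-dim
hierarchy table, and only the blocks the variant uses are included.  A
single-hidden-layer MLP head maps the assembled feature vector to five
logits (CO, OS, OB, IM, IG).

The text encoder is an interface.  The bundled implementation is a
deterministic hashed bag-of-words encoder: fast, dependency-free and
reproducible, which makes desk-scale experiments and property tests exact.
A transformer encoder exposing the same ``pool`` contract can be plugged in
without touching anything else.  For the entity-embedding variant, two
learned vectors (inside-span / outside-span) are added to the pooled token
sum, mirroring an additive entity input layer.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._autodiff import Adam, Tensor, parameter, zeros_parameter
from ._nn import MlpHead, per_id_normal_vector
from .goa_graph import NodeEmbeddingTable, PmgKey
from .synthesis import CLASSES, CLASS_INDEX, GoaInstance
from .tagging import EntitySpan, reformulate_entities, tokenize_with_offsets

logger = logging.getLogger(__name__)


class MissingEvidenceError(ValueError):
    """The variant requires an evidence source the instance does not carry."""


@dataclass(frozen=True)
class VariantSpec:
    """One experiment-matrix variant: text handling plus knowledge blocks."""

    name: str
    encoder_id: str = "hashed_bow"
    uses: frozenset[str] = frozenset()  # subset of {dag_table, goa_table, dummy_table}

    @property
    def wants_goa_blocks(self) -> bool:
        return "goa_table" in self.uses or "dummy_table" in self.uses

    @property
    def wants_dag_block(self) -> bool:
        return "dag_table" in self.uses or "dummy_table" in self.uses


VARIANTS: dict[str, VariantSpec] = {
    "text_only": VariantSpec("text_only"),
    "generif": VariantSpec("generif"),
    "entity_embedding": VariantSpec("entity_embedding"),
    "entity_reformulation": VariantSpec("entity_reformulation"),
    "godg": VariantSpec("godg", uses=frozenset({"dag_table"})),
    "exgoa": VariantSpec("exgoa", uses=frozenset({"goa_table"})),
    "godg_exgoa": VariantSpec(
        "godg_exgoa", uses=frozenset({"dag_table", "goa_table"})
    ),
    "dummy": VariantSpec("dummy", uses=frozenset({"dummy_table"})),
}


@dataclass(frozen=True)
class PooledText:
    """Pooled representation of one text pair plus entity-mask token counts."""

    vector: np.ndarray
    dim: int
    n_masked: float = 0.0  # mask-weighted token fractions feeding the
    n_unmasked: float = 0.0  # additive entity embedding layer


class HashedBowEncoder:
    """Deterministic hashed bag-of-words text encoder.

    Tokens are lowercased and hashed into ``dim`` buckets with BLAKE2b (so
    the mapping is stable across processes); the pooled vector is the bucket
    count vector normalized by token count.  Truncation keeps the first
    ``max_tokens`` tokens, dropping the tail of segment B.
    """

    encoder_id = "hashed_bow"

    def __init__(self, dim: int = 32, max_tokens: int = 256):
        self.dim = dim
        self.max_tokens = max_tokens

    def _bucket(self, token: str) -> int:
        digest = hashlib.blake2b(token.lower().encode("utf-8"), digest_size=8)
        return int.from_bytes(digest.digest(), "little") % self.dim

    def pool(
        self,
        segment_a: str,
        segment_b: str,
        mask_spans: Sequence[EntitySpan] | None = None,
    ) -> PooledText:
        tokens_a = [t for t, _s, _e in tokenize_with_offsets(segment_a)]
        tokens_b = tokenize_with_offsets(segment_b)
        budget = max(self.max_tokens - len(tokens_a), 0)
        tokens_b = tokens_b[:budget]
        vec = np.zeros(self.dim)
        for tok in tokens_a:
            vec[self._bucket(tok)] += 1.0
        n_masked = 0
        for tok, start, end in tokens_b:
            vec[self._bucket(tok)] += 1.0
            if mask_spans is not None and any(
                s.overlaps(start, end) for s in mask_spans
            ):
                n_masked += 1
        n_tokens = max(len(tokens_a) + len(tokens_b), 1)
        vec /= n_tokens
        n_unmasked = (len(tokens_a) + len(tokens_b) - n_masked) / n_tokens
        return PooledText(
            vector=vec,
            dim=self.dim,
            n_masked=n_masked / n_tokens,
            n_unmasked=n_unmasked,
        )


def encode_text(
    inst: GoaInstance,
    variant: VariantSpec,
    encoder: HashedBowEncoder,
    term_names: Mapping[str, str] | None = None,
) -> PooledText:
    """Build the variant's text pair for one instance and pool it.

    Segment A is ``"<GO name> ; <gene id>"`` (falling back to the raw CURIE
    when no name table is given); segment B is the evidence text, the
    GeneRIF statement (``generif`` variant; absence is an explicit error),
    or the marker-reformulated evidence (``entity_reformulation``).  The
    ``entity_embedding`` variant additionally reports mask token counts.
    """
    go_name = (term_names or {}).get(inst.go_id, inst.go_id)
    segment_a = f"{go_name} ; {inst.gene_id}"
    if variant.name == "generif":
        if not inst.generif_text:
            raise MissingEvidenceError(
                f"instance {inst.key} has no GeneRIF statement"
            )
        return encoder.pool(segment_a, inst.generif_text)
    if variant.name == "entity_reformulation":
        text = reformulate_entities(inst.evidence_text, inst.entity_spans)
        return encoder.pool(segment_a, text)
    if variant.name == "entity_embedding":
        return encoder.pool(
            segment_a, inst.evidence_text, mask_spans=inst.entity_spans
        )
    return encoder.pool(segment_a, inst.evidence_text)


def make_dummy_embeddings(
    node_ids: Sequence[str], dim: int, seed: int
) -> NodeEmbeddingTable:
    """Structure-free standard-normal embeddings, deterministic per id.

    Used as an independent regularizer baseline: same shapes as the real
    knowledge tables, no information content.
    """
    table = NodeEmbeddingTable(dim=dim)
    for node_id in node_ids:
        table.vectors[node_id] = per_id_normal_vector(seed, f"dummy|{node_id}", dim)
    return table


@dataclass
class FeatureTables:
    """Knowledge tables an instance's feature blocks are looked up in."""

    goa: NodeEmbeddingTable | None = None
    dag: NodeEmbeddingTable | None = None


_warned_missing: set[tuple[str, str]] = set()


def _fill(vec: np.ndarray | None, dim: int, kind: str, node_id: str) -> np.ndarray:
    if vec is None:
        if (kind, node_id) not in _warned_missing:
            _warned_missing.add((kind, node_id))
            logger.warning("no %s embedding for %s; using a zero block", kind, node_id)
        return np.zeros(dim)
    return vec


def assemble_features(
    pooled: PooledText,
    inst: GoaInstance,
    variant: VariantSpec,
    tables: FeatureTables,
) -> np.ndarray:
    """Fixed-order concatenation: pooled ‖ goa[PMG] ‖ goa[GO] ‖ dag[GO].

    Only the blocks the variant uses are appended; a node missing from its
    table contributes a zero block (flagged once per node).  The GOA table
    may be a shared node table or a per-instance held-out view; both expose
    ``embeddings_for(inst)``.
    """
    parts = [pooled.vector]
    if variant.wants_goa_blocks:
        if tables.goa is None:
            raise ValueError(f"variant {variant.name} requires a GOA table")
        pmg_vec, go_vec = tables.goa.embeddings_for(inst)
        pmg = PmgKey(inst.pmid, inst.gene_id).canonical
        parts.append(_fill(pmg_vec, tables.goa.dim, "goa-pmg", pmg))
        parts.append(_fill(go_vec, tables.goa.dim, "goa-go", inst.go_id))
    if variant.wants_dag_block:
        if tables.dag is None:
            raise ValueError(f"variant {variant.name} requires a DAG table")
        parts.append(_fill(tables.dag.lookup(inst.go_id), tables.dag.dim,
                           "dag-go", inst.go_id))
    return np.concatenate(parts)


@dataclass
class ClassifierConfig:
    hidden_dim: int = 64
    epochs: int = 150
    learning_rate: float = 1e-2
    seed: int = 0
    eval_every: int = 5


class InconsistencyModel:
    """Trained five-class head over assembled graph+text features."""

    def __init__(
        self,
        variant: VariantSpec,
        encoder: HashedBowEncoder,
        head: MlpHead,
        entity_vectors: tuple[Tensor, Tensor] | None,
        term_names: Mapping[str, str] | None,
        feature_dim: int,
    ):
        self.variant = variant
        self.encoder = encoder
        self.head = head
        self.entity_vectors = entity_vectors
        self.term_names = term_names
        self.feature_dim = feature_dim

    # -- feature assembly --------------------------------------------------
    def featurize(
        self, instances: Sequence[GoaInstance], tables: FeatureTables
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(fixed feature matrix, masked counts, unmasked counts)."""
        rows, n1, n0 = [], [], []
        for inst in instances:
            pooled = encode_text(inst, self.variant, self.encoder, self.term_names)
            rows.append(assemble_features(pooled, inst, self.variant, tables))
            n1.append(pooled.n_masked)
            n0.append(pooled.n_unmasked)
        return np.stack(rows), np.array(n1), np.array(n0)

    def _logits_tensor(
        self, x: np.ndarray, n1: np.ndarray, n0: np.ndarray
    ) -> Tensor:
        xt = Tensor(x)
        if self.entity_vectors is not None:
            e1, e0 = self.entity_vectors
            d = self.encoder.dim
            contrib = Tensor(n1[:, None]) * e1 + Tensor(n0[:, None]) * e0
            text = Tensor(x[:, :d]) + contrib
            rest = x[:, d:]
            if rest.shape[1]:
                xt = Tensor.concat_cols([text, Tensor(rest)])
            else:
                xt = text
        return self.head.forward(xt)

    def logits(
        self, instances: Sequence[GoaInstance], tables: FeatureTables
    ) -> np.ndarray:
        x, n1, n0 = self.featurize(instances, tables)
        return self._logits_tensor(x, n1, n0).data

    def predict_batch(
        self, instances: Sequence[GoaInstance], tables: FeatureTables
    ) -> list[str]:
        z = self.logits(instances, tables)
        return [CLASSES[i] for i in np.argmax(z, axis=1)]

    def predict(
        self, inst: GoaInstance, tables: FeatureTables
    ) -> tuple[str, np.ndarray]:
        """Argmax label (ties resolved to the lowest class index) plus logits."""
        z = self.logits([inst], tables)[0]
        return CLASSES[int(np.argmax(z))], z


def train_classifier(
    train: Sequence[GoaInstance],
    dev: Sequence[GoaInstance],
    variant: VariantSpec | str,
    cfg: ClassifierConfig | None = None,
    encoder: HashedBowEncoder | None = None,
    term_names: Mapping[str, str] | None = None,
    train_tables: FeatureTables | None = None,
    dev_tables: FeatureTables | None = None,
) -> InconsistencyModel:
    """Cross-entropy training with best-dev-macro-F1 model selection.

    Dev instances are featurized with their own tables (whose graphs withhold
    the candidate edges), so selection follows the held-out protocol.
    """
    from .evaluation import macro_f1  # local import to avoid a module cycle

    if isinstance(variant, str):
        variant = VARIANTS[variant]
    cfg = cfg or ClassifierConfig()
    encoder = encoder or HashedBowEncoder()
    train_tables = train_tables or FeatureTables()
    dev_tables = dev_tables or train_tables
    if not train or not dev:
        raise ValueError("both training and development splits must be non-empty")
    train_labels = np.array([CLASS_INDEX[i.label] for i in train])
    if len(set(train_labels.tolist())) < 2:
        raise ValueError("training split is degenerate: a single class")

    rng = np.random.default_rng(cfg.seed)
    entity_vectors = None
    if variant.name == "entity_embedding":
        entity_vectors = (
            zeros_parameter((encoder.dim,)),
            zeros_parameter((encoder.dim,)),
        )
    # probe feature dimension
    probe = InconsistencyModel(
        variant, encoder, head=None, entity_vectors=entity_vectors,  # type: ignore[arg-type]
        term_names=term_names, feature_dim=0,
    )
    x_train, n1_train, n0_train = probe.featurize(train, train_tables)
    feature_dim = x_train.shape[1]
    head = MlpHead(feature_dim, cfg.hidden_dim, len(CLASSES), rng)
    model = InconsistencyModel(
        variant, encoder, head, entity_vectors, term_names, feature_dim
    )
    x_dev, n1_dev, n0_dev = model.featurize(dev, dev_tables)
    dev_gold = [i.label for i in dev]

    params = list(head.params)
    if entity_vectors is not None:
        params += list(entity_vectors)
    opt = Adam(params, lr=cfg.learning_rate)
    best_f1 = -1.0
    best_state = [p.data.copy() for p in params]
    for epoch in range(cfg.epochs):
        logits = model._logits_tensor(x_train, n1_train, n0_train)
        loss = logits.cross_entropy(train_labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (epoch + 1) % cfg.eval_every == 0 or epoch == cfg.epochs - 1:
            dev_logits = model._logits_tensor(x_dev, n1_dev, n0_dev).data
            dev_pred = [CLASSES[i] for i in np.argmax(dev_logits, axis=1)]
            f1 = macro_f1(dev_gold, dev_pred)
            if f1 > best_f1:
                best_f1 = f1
                best_state = [p.data.copy() for p in params]
    for p, state in zip(params, best_state):
        p.data = state
    return model
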