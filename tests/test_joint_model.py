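"""Text encoding, feature assembly, and the five-class classifier head."""

import numpy as np
import pytest

from goaqc._nn import MlpHead
from goaqc.goa_graph import NodeEmbeddingTable
from goaqc.joint_model import (
    VARIANTS,
    ClassifierConfig,
    FeatureTables,
    HashedBowEncoder,
    InconsistencyModel,
    MissingEvidenceError,
    assemble_features,
    encode_text,
    make_dummy_embeddings,
    train_classifier,
)
from goaqc.synthesis import CLASSES, GoaInstance, Provenance
from goaqc.tagging import EntitySpan


def make_inst(text="RHO-1 binds GTP in cells", label="CO", go="T:1",
              gene="Gene:1", pmid="PMID:1", spans=(), generif=None):
    prov = None if label == "CO" else Provenance(go, gene, "over_specific")
    return GoaInstance(
        go_id=go, gene_id=gene, pmid=pmid, evidence_text=text, label=label,
        entity_spans=tuple(spans), generif_text=generif, provenance=prov,
    )


class TestHashedBowEncoder:
    def test_deterministic_and_discriminative(self):
        enc = HashedBowEncoder(dim=32)
        texts = [
            "alpha binds beta", "alpha binds gamma", "delta represses beta",
            "epsilon localizes to zeta", "alpha binds beta strongly",
        ]
        pools = [enc.pool("T:1 ; Gene:1", t).vector for t in texts]
        again = [enc.pool("T:1 ; Gene:1", t).vector for t in texts]
        for a, b in zip(pools, again):
            assert np.array_equal(a, b)
        for i in range(len(texts)):
            for j in range(i + 1, len(texts)):
                assert not np.array_equal(pools[i], pools[j])

    def test_truncation_drops_segment_b_tail(self):
        enc = HashedBowEncoder(dim=16, max_tokens=5)
        short = enc.pool("a b c", "d e")
        longer = enc.pool("a b c", "d e f g h")
        assert np.array_equal(short.vector, longer.vector)

    def test_entity_mask_counts(self):
        # ClpXP & degradation inside spans, machine outside -> mask (1,1,0)
        enc = HashedBowEncoder(dim=32)
        text = "ClpXP degradation machine"
        spans = [EntitySpan(0, 5, "gene"), EntitySpan(6, 17, "go")]
        segment_a = "T:1 ; Gene:1"
        pooled = enc.pool(segment_a, text, mask_spans=spans)
        from goaqc.tagging import tokenize_with_offsets

        n_tokens = len(tokenize_with_offsets(segment_a)) + 3
        assert pooled.n_masked == pytest.approx(2 / n_tokens)
        assert pooled.n_unmasked == pytest.approx((n_tokens - 2) / n_tokens)


class TestEncodeText:
    def test_generif_missing_is_explicit_error(self):
        inst = make_inst(generif=None)
        with pytest.raises(MissingEvidenceError):
            encode_text(inst, VARIANTS["generif"], HashedBowEncoder())

    def test_generif_substitution_changes_pooling(self):
        enc = HashedBowEncoder()
        inst = make_inst(generif="completely different statement")
        a = encode_text(inst, VARIANTS["text_only"], enc)
        b = encode_text(inst, VARIANTS["generif"], enc)
        assert not np.array_equal(a.vector, b.vector)

    def test_reformulation_adds_markers(self):
        enc = HashedBowEncoder()
        spans = [EntitySpan(0, 5, "gene", "Gene:1")]
        inst = make_inst(spans=spans)
        plain = encode_text(inst, VARIANTS["text_only"], enc)
        marked = encode_text(inst, VARIANTS["entity_reformulation"], enc)
        assert not np.array_equal(plain.vector, marked.vector)

    def test_term_name_reaches_segment_a(self):
        enc = HashedBowEncoder()
        named = encode_text(
            make_inst(), VARIANTS["text_only"], enc, term_names={"T:1": "zunavo"}
        )
        bare = encode_text(make_inst(), VARIANTS["text_only"], enc)
        assert not np.array_equal(named.vector, bare.vector)


class TestDummyEmbeddings:
    def test_deterministic_per_seed(self):
        ids = [f"T:{i}" for i in range(20)]
        a = make_dummy_embeddings(ids, 8, seed=1)
        b = make_dummy_embeddings(ids, 8, seed=1)
        assert all(np.array_equal(a.vectors[i], b.vectors[i]) for i in ids)
        c = make_dummy_embeddings(ids, 8, seed=2)
        assert all(not np.array_equal(a.vectors[i], c.vectors[i]) for i in ids)

    def test_standard_normal_moments(self):
        ids = [f"T:{i}" for i in range(1250)]
        table = make_dummy_embeddings(ids, 8, seed=0)
        draws = np.concatenate([table.vectors[i] for i in ids])
        se = 1.0 / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se
        assert abs(draws.var() - 1.0) < 3 * np.sqrt(2.0 / draws.size)


class TestAssembleFeatures:
    def setup_method(self):
        self.enc = HashedBowEncoder(dim=32)
        self.goa = NodeEmbeddingTable(dim=8)
        self.goa.vectors["PMID:1_Gene:1"] = np.arange(8.0)
        self.goa.vectors["T:1"] = np.arange(8.0) + 10
        self.dag = NodeEmbeddingTable(dim=16)
        self.dag.vectors["T:1"] = np.arange(16.0)

    def test_block_dimensions(self):
        inst = make_inst()
        pooled = encode_text(inst, VARIANTS["text_only"], self.enc)
        tables = FeatureTables(goa=self.goa, dag=self.dag)
        assert assemble_features(
            pooled, inst, VARIANTS["godg_exgoa"], tables
        ).shape == (32 + 8 + 8 + 16,)
        assert assemble_features(
            pooled, inst, VARIANTS["text_only"], FeatureTables()
        ).shape == (32,)
        assert assemble_features(
            pooled, inst, VARIANTS["godg"], FeatureTables(dag=self.dag)
        ).shape == (48,)

    def test_fixed_concatenation_order_and_purity(self):
        inst = make_inst()
        pooled = encode_text(inst, VARIANTS["text_only"], self.enc)
        tables = FeatureTables(goa=self.goa, dag=self.dag)
        x1 = assemble_features(pooled, inst, VARIANTS["godg_exgoa"], tables)
        x2 = assemble_features(pooled, inst, VARIANTS["godg_exgoa"], tables)
        assert np.array_equal(x1, x2)
        assert np.array_equal(x1[32:40], self.goa.vectors["PMID:1_Gene:1"])
        assert np.array_equal(x1[40:48], self.goa.vectors["T:1"])
        assert np.array_equal(x1[48:], self.dag.vectors["T:1"])

    def test_missing_node_zero_block(self):
        inst = make_inst(go="T:404", pmid="PMID:9")
        pooled = encode_text(inst, VARIANTS["text_only"], self.enc)
        x = assemble_features(
            pooled, inst, VARIANTS["exgoa"], FeatureTables(goa=self.goa)
        )
        assert np.array_equal(x[32:48], np.zeros(16))

    def test_table_variant_mismatch_rejected(self):
        inst = make_inst()
        pooled = encode_text(inst, VARIANTS["text_only"], self.enc)
        with pytest.raises(ValueError, match="requires"):
            assemble_features(pooled, inst, VARIANTS["godg"], FeatureTables())


def templated_corpus(n_per_class=12, pmid_base=0):
    """Corpus whose label is a deterministic function of a planted keyword."""
    keyword = {"CO": "supports", "OS": "narrower", "OB": "broader",
               "IM": "tangential", "IG": "misattributed"}
    out = []
    i = pmid_base
    for label in CLASSES:
        for _ in range(n_per_class):
            i += 1
            out.append(
                make_inst(
                    text=f"the evidence {keyword[label]} this annotation",
                    label=label, pmid=f"PMID:{i}",
                )
            )
    return out


class TestTrainClassifier:
    def test_learnable_by_construction_corpus(self):
        train = templated_corpus(12, pmid_base=0)
        dev = templated_corpus(4, pmid_base=100)
        model = train_classifier(
            train, dev, "text_only", ClassifierConfig(seed=0)
        )
        from goaqc.evaluation import macro_f1

        pred = model.predict_batch(dev, FeatureTables())
        assert macro_f1([i.label for i in dev], pred) >= 0.9

    def test_degenerate_single_class_rejected(self):
        single = [make_inst(pmid=f"PMID:{i}") for i in range(4)]
        with pytest.raises(ValueError, match="single class"):
            train_classifier(single, single, "text_only")

    def test_prediction_in_class_set_and_logit_length(self):
        train = templated_corpus(6)
        model = train_classifier(
            train, templated_corpus(2, 200), "text_only",
            ClassifierConfig(epochs=10, seed=0),
        )
        label, logits = model.predict(train[0], FeatureTables())
        assert label in CLASSES and logits.shape == (5,)

    def test_tie_breaks_to_lowest_index(self):
        enc = HashedBowEncoder(dim=8)
        rng = np.random.default_rng(0)
        head = MlpHead(8, 4, 5, rng)
        head.w2.data[:] = 0.0
        head.b2.data[:] = 0.0
        model = InconsistencyModel(
            VARIANTS["text_only"], enc, head, None, None, feature_dim=8
        )
        label, logits = model.predict(make_inst(), FeatureTables())
        assert label == "CO" and np.all(logits == 0.0)

    def test_batch_equals_per_instance(self):
        train = templated_corpus(6)
        dev = templated_corpus(2, 200)
        model = train_classifier(
            train, dev, "text_only", ClassifierConfig(epochs=20, seed=1)
        )
        batch = model.predict_batch(dev, FeatureTables())
        single = [model.predict(i, FeatureTables())[0] for i in dev]
        assert batch == single

    def test_zero_initialized_entity_layer_is_identity(self):
        from goaqc._autodiff import Tensor
        from goaqc.joint_model import VARIANTS

        enc = HashedBowEncoder(dim=16)
        rng = np.random.default_rng(3)
        head = MlpHead(16, 4, 5, rng)
        spans = [EntitySpan(0, 5, "gene", "Gene:1")]
        inst = make_inst(text="RHO-1 binds GTP", spans=spans)
        plain = InconsistencyModel(
            VARIANTS["text_only"], enc, head, None, None, 16
        )
        entity = InconsistencyModel(
            VARIANTS["entity_embedding"], enc, head,
            (Tensor(np.zeros(16), requires_grad=True),
             Tensor(np.zeros(16), requires_grad=True)),
            None, 16,
        )
        assert np.allclose(
            plain.logits([inst], FeatureTables()),
            entity.logits([inst], FeatureTables()),
        )
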