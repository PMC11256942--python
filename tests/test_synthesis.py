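"""Perturbation correctness, corpus balance, fixture-world generation."""

from collections import Counter

import numpy as np
import pytest

from goaqc.io import instance_to_json
from goaqc.synthesis import (
    CLASSES,
    FixtureWorldConfig,
    GoaInstance,
    Provenance,
    SynthesisError,
    generate_fixture_world,
    perturb_incorrect_gene,
    perturb_irrelevant_mention,
    perturb_over_broad,
    perturb_over_specific,
    split_by_pmid,
    synthesize_balanced_corpus,
)
from goaqc.tagging import EntitySpan

from conftest import make_dag


def co_instance(go_id="T:2", gene_id="Gene:1", spans=()):
    return GoaInstance(
        go_id=go_id,
        gene_id=gene_id,
        pmid="PMID:1",
        evidence_text="g1 enables name b. g2 was also seen. name d was ruled out.",
        label="CO",
        entity_spans=tuple(spans),
    )


@pytest.fixture
def behavior_dag():
    # T:3 ("feeding behavior") -> T:2 ("behavior") -> T:1 (root)
    return make_dag([("T:3", "T:2", "is_a"), ("T:2", "T:1", "is_a")])


class TestPerturbations:
    def test_over_specific_picks_direct_child(self, behavior_dag, rng):
        out = perturb_over_specific(co_instance("T:2"), behavior_dag, rng)
        assert out.go_id == "T:3" and out.label == "OS"
        assert out.provenance == Provenance("T:2", "Gene:1", "over_specific")
        assert out.evidence_text == co_instance().evidence_text

    def test_leaf_skips(self, behavior_dag, rng):
        assert perturb_over_specific(co_instance("T:3"), behavior_dag, rng) is None

    def test_over_broad_picks_ancestor_excluding_root(self, behavior_dag, rng):
        out = perturb_over_broad(co_instance("T:3"), behavior_dag, rng)
        assert out.go_id == "T:2" and out.label == "OB"  # root T:1 excluded

    def test_no_nonroot_ancestor_skips(self, behavior_dag, rng):
        assert perturb_over_broad(co_instance("T:2"), behavior_dag, rng) is None

    def test_non_co_input_rejected(self, behavior_dag, rng):
        os_inst = perturb_over_specific(co_instance("T:2"), behavior_dag, rng)
        with pytest.raises(ValueError, match="CO"):
            perturb_over_specific(os_inst, behavior_dag, rng)

    def test_irrelevant_mention_needs_unrelated_mention(self, behavior_dag, rng):
        # mentions: the annotated term and an unrelated term T:4
        dag = make_dag(
            [("T:3", "T:2", "is_a"), ("T:2", "T:1", "is_a"), ("T:4", "T:1", "is_a")]
        )
        spans = [EntitySpan(0, 2, "go", "T:2"), EntitySpan(3, 5, "go", "T:4")]
        out = perturb_irrelevant_mention(co_instance("T:2", spans=spans), dag, rng)
        assert out.go_id == "T:4" and out.label == "IM"
        # related mention only -> skip
        spans2 = [EntitySpan(0, 2, "go", "T:2"), EntitySpan(3, 5, "go", "T:3")]
        assert (
            perturb_irrelevant_mention(co_instance("T:2", spans=spans2), dag, rng)
            is None
        )

    def test_incorrect_gene_requires_comention(self, rng):
        spans = [
            EntitySpan(0, 2, "gene", "Gene:1"),
            EntitySpan(3, 5, "gene", "Gene:2"),
        ]
        out = perturb_incorrect_gene(co_instance(spans=spans), rng)
        assert out.gene_id == "Gene:2" and out.label == "IG"
        assert out.go_id == "T:2"  # term untouched
        single = [EntitySpan(0, 2, "gene", "Gene:1")]
        assert perturb_incorrect_gene(co_instance(spans=single), rng) is None

    def test_sampled_terms_satisfy_relations_on_world(self, small_world, rng):
        dag = small_world.dag
        for inst in small_world.instances[:60]:
            os_out = perturb_over_specific(inst, dag, rng)
            if os_out is not None:
                assert (os_out.go_id, inst.go_id) in {
                    (c, p) for c, p, _ in dag.edges
                }
            ob_out = perturb_over_broad(inst, dag, rng)
            if ob_out is not None:
                assert ob_out.go_id in dag.ancestors(inst.go_id) - dag.roots
            im_out = perturb_irrelevant_mention(inst, dag, rng)
            if im_out is not None:
                mentioned = {
                    s.matched_id for s in inst.entity_spans if s.concept_type == "go"
                }
                assert im_out.go_id in mentioned
                assert not dag.related(im_out.go_id, inst.go_id)
            ig_out = perturb_incorrect_gene(inst, rng)
            if ig_out is not None:
                genes = {
                    s.matched_id for s in inst.entity_spans if s.concept_type == "gene"
                }
                assert ig_out.gene_id in genes and ig_out.gene_id != inst.gene_id


class TestBalancedCorpus:
    @pytest.mark.parametrize("per_class", [1, 7, 20])
    def test_uniform_histogram(self, small_world, per_class):
        corpus = synthesize_balanced_corpus(
            small_world.instances, per_class, small_world.dag, seed=3
        )
        assert len(corpus) == 5 * per_class
        assert Counter(i.label for i in corpus) == {c: per_class for c in CLASSES}
        keys = [i.key for i in corpus]
        assert len(set(keys)) == len(keys)

    def test_zero_per_class(self, small_world):
        assert synthesize_balanced_corpus(small_world.instances, 0, small_world.dag) == []

    def test_deterministic_under_seed(self, small_world):
        a = synthesize_balanced_corpus(small_world.instances, 10, small_world.dag, seed=5)
        b = synthesize_balanced_corpus(small_world.instances, 10, small_world.dag, seed=5)
        assert a == b

    def test_shortfall_names_class_and_gap(self, behavior_dag):
        # only term T:3 is annotatable and it is a leaf -> OS infeasible
        pool = [
            GoaInstance(
                go_id="T:3", gene_id="Gene:1", pmid=f"PMID:{i}",
                evidence_text="text", label="CO",
            )
            for i in range(4)
        ]
        with pytest.raises(SynthesisError, match="OS short by 2"):
            synthesize_balanced_corpus(pool, 2, behavior_dag, seed=0)

    def test_provenance_and_immutability_invariants(self, small_corpus, small_world):
        dag = small_world.dag
        for inst in small_corpus:
            if inst.label == "CO":
                assert inst.provenance is None
                continue
            prov = inst.provenance
            if inst.label == "OS":
                assert prov.original_go_id in dag.direct_parents(inst.go_id)
            if inst.label == "OB":
                assert inst.go_id in dag.ancestors(prov.original_go_id)
            if inst.label == "IG":
                assert inst.gene_id != prov.original_gene_id
                assert inst.go_id == prov.original_go_id
            else:
                assert inst.gene_id == prov.original_gene_id

    def test_background_reattached_for_replaced_gene(self, small_corpus, small_world):
        for inst in small_corpus:
            if inst.label == "IG":
                expected = tuple(
                    t
                    for t in small_world.gene_background[inst.gene_id]
                    if t != inst.go_id
                )
                assert inst.existing_go_ids == expected

    def test_splits_share_no_instance_keys(self, small_splits):
        key_sets = [{i.key for i in split} for split in small_splits]
        pmid_sets = [{i.pmid for i in split} for split in small_splits]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not key_sets[i] & key_sets[j]
                assert not pmid_sets[i] & pmid_sets[j]


class TestFixtureWorld:
    def test_same_seed_identical(self):
        cfg = FixtureWorldConfig(n_terms=80, depth=4, co_layer=2, n_genes=12,
                                 n_gene_families=3, n_instances=30, seed=9)
        w1, w2 = generate_fixture_world(cfg), generate_fixture_world(cfg)
        assert w1.dag == w2.dag
        assert [instance_to_json(a) for a in w1.instances] == [
            instance_to_json(b) for b in w2.instances
        ]
        assert w1.generif == w2.generif

    def test_zero_distractor_gene_rate_blocks_ig(self, rng):
        cfg = FixtureWorldConfig(n_terms=80, depth=4, co_layer=2, n_genes=12,
                                 n_gene_families=3, n_instances=30,
                                 distractor_gene_rate=0.0, seed=2)
        world = generate_fixture_world(cfg)
        for inst in world.instances:
            assert perturb_incorrect_gene(inst, rng) is None

    def test_full_distractor_rates_make_all_classes_eligible(self, small_world, rng):
        dag = small_world.dag
        eligible = 0
        for inst in small_world.instances:
            if all(
                fn is not None
                for fn in (
                    perturb_over_specific(inst, dag, rng),
                    perturb_over_broad(inst, dag, rng),
                    perturb_irrelevant_mention(inst, dag, rng),
                    perturb_incorrect_gene(inst, rng),
                )
            ):
                eligible += 1
        assert eligible / len(small_world.instances) >= 0.95

    def test_infeasible_config_rejected(self):
        with pytest.raises(SynthesisError):
            FixtureWorldConfig(n_terms=3, depth=6)
        with pytest.raises(SynthesisError):
            FixtureWorldConfig(distractor_go_rate=1.5)
        with pytest.raises(SynthesisError):
            FixtureWorldConfig(n_genes=2, n_gene_families=5)

    def test_instances_reference_world_vocabulary(self, small_world):
        dag = small_world.dag
        for inst in small_world.instances[:40]:
            assert inst.go_id in dag
            assert dag.name_of(inst.go_id) in inst.evidence_text
            assert small_world.gene_lexicon[inst.gene_id] in inst.evidence_text
            assert inst.generif_text == small_world.generif[(inst.pmid, inst.gene_id)]
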