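"""End-to-end experiment orchestration.

Glue from fixture world to experiment matrix: synthesize a balanced corpus,
split it on disjoint PMID pools, pre-train the two knowledge encoders,
export per-split embedding tables under the leave-candidate-out protocol
(the encoder is trained on the training+development graph; each instance is
then encoded on its own split's graph — background and other instances'
edges present, its candidate edge withheld), and run the requested variants.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._nn import EncoderConfig
from .dag_encoder import export_dag_embeddings, train_dag_encoder
from .evaluation import MatrixConfig, MatrixReport, run_matrix
from .goa_graph import (
    HeldOutEmbeddings,
    NodeEmbeddingTable,
    PmgKey,
    build_annotation_graph,
    export_held_out_embeddings,
    init_node_features,
    train_edge_classifier,
)
from .joint_model import ClassifierConfig, HashedBowEncoder, make_dummy_embeddings
from .ontology import build_specificity_graph
from .synthesis import (
    FixtureWorld,
    FixtureWorldConfig,
    GoaInstance,
    generate_fixture_world,
    split_by_pmid,
    synthesize_balanced_corpus,
)


@dataclass
class ExperimentContext:
    """Everything produced on the way to a matrix report."""

    world: FixtureWorld
    splits: tuple[list[GoaInstance], list[GoaInstance], list[GoaInstance]]
    goa_tables: dict[str, HeldOutEmbeddings] | None = None
    dag_table: NodeEmbeddingTable | None = None
    goa_metrics: dict[str, list[float]] | None = None
    dag_metrics: dict[str, list[float]] | None = None


def build_goa_tables(
    splits: tuple[list[GoaInstance], list[GoaInstance], list[GoaInstance]],
    cfg: EncoderConfig | None = None,
) -> tuple[dict[str, HeldOutEmbeddings], dict[str, list[float]]]:
    """Pre-train the annotation-graph encoder and export per-split tables.

    The encoder is pre-trained on the training+development graph (candidate
    edges and background included).  Features for every split — training
    included, so feature distributions match — are then exported under the
    leave-candidate-out protocol: each instance is encoded on its own
    split's graph with its candidate edge withheld from message passing.
    """
    cfg = cfg or EncoderConfig()
    train, dev, test = splits
    pretrain_graph = build_annotation_graph(
        list(train) + list(dev), include_background=True, include_candidate=True
    )
    features = init_node_features(pretrain_graph, cfg.node_dim, cfg.seed)
    model, metrics = train_edge_classifier(pretrain_graph, features, cfg)
    tables = {
        name: export_held_out_embeddings(model, insts, seed=cfg.seed)
        for name, insts in (("train", train), ("dev", dev), ("test", test))
    }
    return tables, metrics


def build_dag_table(
    world: FixtureWorld,
    corpus: list[GoaInstance],
    cfg: EncoderConfig | None = None,
) -> tuple[NodeEmbeddingTable, dict[str, list[float]]]:
    """Pre-train the hierarchy encoder on the corpus-anchored sub-DAG."""
    cfg = cfg or EncoderConfig(node_dim=16)
    seeds = {inst.go_id for inst in corpus}
    for inst in corpus:
        seeds.update(inst.existing_go_ids)
    sub = world.dag.extract_subgraph(seeds, closure="children")
    spec_graph = build_specificity_graph(sub)
    model, metrics = train_dag_encoder(spec_graph, cfg)
    return export_dag_embeddings(model, spec_graph), metrics


def dummy_tables_like(
    splits, goa_dim: int = 8, dag_dim: int = 16, seed: int = 0
) -> tuple[dict[str, NodeEmbeddingTable], NodeEmbeddingTable]:
    """Gaussian dummy tables with the same node inventory as the real ones."""
    goa_tables: dict[str, NodeEmbeddingTable] = {}
    all_go: set[str] = set()
    for name, insts in zip(("train", "dev", "test"), splits):
        ids: set[str] = set()
        for inst in insts:
            ids.add(PmgKey(inst.pmid, inst.gene_id).canonical)
            ids.add(inst.go_id)
            ids.update(inst.existing_go_ids)
            all_go.add(inst.go_id)
            all_go.update(inst.existing_go_ids)
        goa_tables[name] = make_dummy_embeddings(sorted(ids), goa_dim, seed)
    dag_table = make_dummy_embeddings(sorted(all_go), dag_dim, seed)
    return goa_tables, dag_table


def run_experiment(
    world_cfg: FixtureWorldConfig,
    per_class: int,
    variant_names: list[str],
    seed: int = 0,
    classifier_cfg: ClassifierConfig | None = None,
    goa_encoder_cfg: EncoderConfig | None = None,
    dag_encoder_cfg: EncoderConfig | None = None,
    encoder: HashedBowEncoder | None = None,
) -> tuple[MatrixReport, ExperimentContext]:
    """Full pipeline: world -> corpus -> splits -> pre-training -> matrix."""
    world = generate_fixture_world(world_cfg)
    corpus = synthesize_balanced_corpus(
        world.instances, per_class, world.dag, seed=seed,
        gene_background=world.gene_background,
    )
    splits = split_by_pmid(corpus, seed=seed)
    ctx = ExperimentContext(world=world, splits=splits)

    needs_goa = any(v in ("exgoa", "godg_exgoa") for v in variant_names)
    needs_dag = any(v in ("godg", "godg_exgoa") for v in variant_names)
    needs_dummy = "dummy" in variant_names
    if needs_goa:
        cfg = goa_encoder_cfg or EncoderConfig(seed=seed)
        ctx.goa_tables, ctx.goa_metrics = build_goa_tables(splits, cfg)
    if needs_dag:
        cfg = dag_encoder_cfg or EncoderConfig(node_dim=16, seed=seed)
        ctx.dag_table, ctx.dag_metrics = build_dag_table(world, corpus, cfg)
    dummy_goa = dummy_dag = None
    if needs_dummy:
        dummy_goa, dummy_dag = dummy_tables_like(splits, seed=seed)

    term_names = {t.id: t.name for t in world.dag.terms.values()}
    matrix_cfg = MatrixConfig(
        encoder=encoder,
        term_names=term_names,
        goa_tables=ctx.goa_tables,
        dag_table=ctx.dag_table,
        dummy_goa_tables=dummy_goa,
        dummy_dag_table=dummy_dag,
        classifier_cfg=classifier_cfg or ClassifierConfig(seed=seed),
        seed=seed,
    )
    report = run_matrix(variant_names, splits, matrix_cfg)
    return report, ctx
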