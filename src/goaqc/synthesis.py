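"""Typed-inconsistency corpus synthesis and synthetic fixture worlds.

Real inconsistency corpora for annotation QA are built by perturbing records
that are known to be consistent.  Starting from a consistent (CO) instance —
a (GO term, gene, PMID, evidence text) triplet — four perturbations plant
one inconsistency each:

* **OS** (over-specific): replace the term with a uniformly sampled *direct
  child*, making the annotation narrower than the evidence supports.
* **OB** (over-broad): replace the term with a uniformly sampled *proper
  ancestor* at any depth (namespace roots excluded), making it too general.
* **IM** (irrelevant GO mention): move the annotation onto a different GO
  term that is mentioned in the evidence text but is hierarchically
  unrelated to the original term.
* **IG** (incorrect gene): reattach the annotation to a different gene that
  is co-mentioned in the evidence.

An instance ineligible for a perturbation (leaf term, no non-root ancestor,
no qualifying mention) yields an explicit skip signal (``None``), never a
silently mislabeled record.  Each synthesized instance keeps provenance of
the original triplet.

The module also generates fully synthetic *fixture worlds* — a layered
random ontology, a gene lexicon grouped into families, templated evidence
texts with distractor mentions, background annotations and GeneRIF-style
sentences — so the entire pipeline runs offline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .ontology import OntologyDag, OntologyTerm
from .tagging import EntitySpan, tag_mentions

CLASSES = ("CO", "OS", "OB", "IM", "IG")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


class SynthesisError(ValueError):
    """Infeasible configuration or corpus-balance shortfall."""


@dataclass(frozen=True)
class Provenance:
    """Original triplet and perturbation that produced a synthetic instance."""

    original_go_id: str
    original_gene_id: str
    perturbation: str


@dataclass(frozen=True)
class GoaInstance:
    """One annotation record with a five-way (in)consistency label."""

    go_id: str
    gene_id: str
    pmid: str
    evidence_text: str
    label: str
    generif_text: str | None = None
    entity_spans: tuple[EntitySpan, ...] = ()
    existing_go_ids: tuple[str, ...] = ()
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "CO" and self.provenance is not None:
            raise ValueError("consistent instances carry no perturbation provenance")
        if self.label != "CO" and self.provenance is None:
            raise ValueError(f"{self.label} instance requires provenance")

    @property
    def key(self) -> str:
        """Instance key in the ``GO_Gene_PMID`` layout."""
        return f"{self.go_id}_{self.gene_id}_{self.pmid}"


def _require_co(inst: GoaInstance) -> None:
    if inst.label != "CO":
        raise ValueError(f"perturbations start from CO instances, got {inst.label}")


def _choice(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


# -- the four perturbations ------------------------------------------------

def perturb_over_specific(
    inst: GoaInstance, dag: OntologyDag, rng: np.random.Generator
) -> GoaInstance | None:
    """Annotate a uniformly sampled direct child instead; leaf terms skip."""
    _require_co(inst)
    children = sorted(dag.direct_children(inst.go_id))
    if not children:
        return None
    return replace(
        inst,
        go_id=_choice(rng, children),
        label="OS",
        provenance=Provenance(inst.go_id, inst.gene_id, "over_specific"),
    )


def perturb_over_broad(
    inst: GoaInstance, dag: OntologyDag, rng: np.random.Generator
) -> GoaInstance | None:
    """Annotate a uniformly sampled proper non-root ancestor (any depth)."""
    _require_co(inst)
    ancestors = sorted(dag.ancestors(inst.go_id) - dag.roots)
    if not ancestors:
        return None
    return replace(
        inst,
        go_id=_choice(rng, ancestors),
        label="OB",
        provenance=Provenance(inst.go_id, inst.gene_id, "over_broad"),
    )


def perturb_irrelevant_mention(
    inst: GoaInstance,
    dag: OntologyDag,
    rng: np.random.Generator,
    go_mention_spans: Sequence[EntitySpan] | None = None,
) -> GoaInstance | None:
    """Annotate a GO term that is mentioned in the evidence but unrelated.

    Eligible replacement terms must be tagged in the evidence text, differ
    from the original, and not be an ancestor or descendant of it (so the IM
    class never collides with OS/OB).
    """
    _require_co(inst)
    spans = inst.entity_spans if go_mention_spans is None else go_mention_spans
    mentioned = {
        s.matched_id
        for s in spans
        if s.concept_type == "go" and s.matched_id and s.matched_id in dag
    }
    eligible = sorted(
        t for t in mentioned if t != inst.go_id and not dag.related(t, inst.go_id)
    )
    if not eligible:
        return None
    return replace(
        inst,
        go_id=_choice(rng, eligible),
        label="IM",
        provenance=Provenance(inst.go_id, inst.gene_id, "irrelevant_mention"),
    )


def perturb_incorrect_gene(
    inst: GoaInstance,
    rng: np.random.Generator,
    gene_mention_spans: Sequence[EntitySpan] | None = None,
) -> GoaInstance | None:
    """Reattach the annotation to a different gene co-mentioned in the evidence."""
    _require_co(inst)
    spans = inst.entity_spans if gene_mention_spans is None else gene_mention_spans
    mentioned = {
        s.matched_id
        for s in spans
        if s.concept_type == "gene" and s.matched_id
    }
    eligible = sorted(g for g in mentioned if g != inst.gene_id)
    if not eligible:
        return None
    return replace(
        inst,
        gene_id=_choice(rng, eligible),
        label="IG",
        provenance=Provenance(inst.go_id, inst.gene_id, "incorrect_gene"),
    )


# -- balanced corpus -------------------------------------------------------

def synthesize_balanced_corpus(
    consistent: Sequence[GoaInstance],
    per_class: int,
    dag: OntologyDag,
    seed: int = 0,
    gene_background: Mapping[str, Sequence[str]] | None = None,
) -> list[GoaInstance]:
    """Exactly ``per_class`` instances per label, 5 x per_class in total.

    CO instances are drawn without replacement from the consistent pool; each
    perturbed class oversamples the eligible pool independently (one use per
    source instance per class), so classes stay mutually exclusive and
    label-pure.  A shortfall raises an error naming the class and the gap.
    Deterministic under a fixed seed.

    When ``gene_background`` maps gene ids to their existing annotations,
    each synthesized instance's ``existing_go_ids`` are re-attached for its
    (possibly replaced) annotated gene, minus the instance's own term —
    mirroring the sourcing order of real pipelines, where background
    retrieval happens per finished instance, keyed by the annotated gene.
    """
    rng = np.random.default_rng(seed)
    pool = list(consistent)
    for inst in pool:
        _require_co(inst)
    if per_class == 0:
        return []
    out: list[GoaInstance] = []
    if len(pool) < per_class:
        raise SynthesisError(
            f"class CO short by {per_class - len(pool)}: pool has {len(pool)} instances"
        )
    for i in rng.permutation(len(pool))[:per_class]:
        out.append(pool[int(i)])

    def attempt(cls: str, inst: GoaInstance) -> GoaInstance | None:
        if cls == "OS":
            out = perturb_over_specific(inst, dag, rng)
        elif cls == "OB":
            out = perturb_over_broad(inst, dag, rng)
        elif cls == "IM":
            out = perturb_irrelevant_mention(inst, dag, rng)
        else:
            out = perturb_incorrect_gene(inst, rng)
        if out is not None and gene_background is not None:
            existing = gene_background.get(out.gene_id, ())
            out = replace(
                out,
                existing_go_ids=tuple(t for t in existing if t != out.go_id),
            )
        return out

    for cls in ("OS", "OB", "IM", "IG"):
        got: list[GoaInstance] = []
        for i in rng.permutation(len(pool)):
            res = attempt(cls, pool[int(i)])
            if res is not None:
                got.append(res)
            if len(got) == per_class:
                break
        if len(got) < per_class:
            raise SynthesisError(
                f"class {cls} short by {per_class - len(got)}: only "
                f"{len(got)} eligible instances"
            )
        out.extend(got)

    keys = [inst.key for inst in out]
    if len(set(keys)) != len(keys):
        raise SynthesisError("duplicate instance keys in synthesized corpus")
    return out


def split_by_pmid(
    instances: Sequence[GoaInstance],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[GoaInstance], list[GoaInstance], list[GoaInstance]]:
    """Train/dev/test partition with disjoint PMID pools."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    pmids = sorted({inst.pmid for inst in instances})
    order = [pmids[int(i)] for i in rng.permutation(len(pmids))]
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_dev = int(round(fractions[1] * n))
    assign: dict[str, int] = {}
    for i, pmid in enumerate(order):
        assign[pmid] = 0 if i < n_train else (1 if i < n_train + n_dev else 2)
    splits: tuple[list[GoaInstance], ...] = ([], [], [])
    for inst in instances:
        splits[assign[inst.pmid]].append(inst)
    return splits


# -- fixture worlds --------------------------------------------------------

@dataclass(frozen=True)
class FixtureWorldConfig:
    """Parameters of a synthetic annotation world.

    The defaults describe a small but structured world: a six-level layered
    ontology of 240 terms, 60 genes in 6 function families (each family tied
    to one branch of the ontology), 600 consistent instances, and distractor
    gene/GO mentions planted in 80% of evidence texts so that IM/IG
    perturbations are feasible for most instances.
    """

    n_terms: int = 240
    max_children: int = 4
    depth: int = 6
    n_genes: int = 60
    n_gene_families: int = 6
    n_instances: int = 600
    distractor_go_rate: float = 0.8
    distractor_gene_rate: float = 0.8
    seed: int = 0
    co_layer: int | None = None  # layer of consistent annotations; default depth//2
    extra_parent_rate: float = 0.15
    n_background: int = 3
    #: population the planted irrelevant-GO mentions are drawn from:
    #: "cluster" — other families' annotated-cluster terms (distractors share
    #: the annotation layer); "cluster_children" — children of other
    #: families' cluster terms (distractors are never annotated-cluster
    #: terms, so an irrelevant mention is structurally distinct from a
    #: wrong-gene annotation in the co-annotation graph)
    distractor_go_source: str = "cluster"

    def __post_init__(self) -> None:
        for name in ("n_terms", "max_children", "depth", "n_genes",
                     "n_gene_families", "n_instances"):
            if getattr(self, name) <= 0:
                raise SynthesisError(f"{name} must be positive")
        for name in ("distractor_go_rate", "distractor_gene_rate", "extra_parent_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SynthesisError(f"{name} must be in [0, 1]")
        if self.depth > self.n_terms:
            raise SynthesisError("depth exceeds the number of terms")
        if self.n_gene_families > self.n_genes:
            raise SynthesisError("more gene families than genes")
        co = self.depth // 2 if self.co_layer is None else self.co_layer
        if not (2 <= co <= self.depth - 2):
            raise SynthesisError(
                f"co_layer {co} must lie in [2, depth-2] so consistent terms "
                "have both children and non-root ancestors"
            )
        if self.distractor_go_source not in ("cluster", "cluster_children"):
            raise SynthesisError(
                f"unknown distractor_go_source {self.distractor_go_source!r}"
            )


@dataclass
class FixtureWorld:
    """A generated world: ontology, genes, consistent instances, GeneRIFs."""

    dag: OntologyDag
    gene_lexicon: dict[str, str]  # gene_id -> symbol
    gene_families: dict[str, int]  # gene_id -> family index
    gene_background: dict[str, tuple[str, ...]]  # gene_id -> existing annotations
    family_pools: list[list[str]]  # family index -> candidate CO term ids
    lexicon: dict[str, tuple[str, str]]  # surface -> (id, concept type)
    instances: list[GoaInstance]
    generif: dict[tuple[str, str], str]  # (pmid, gene_id) -> statement
    cfg: FixtureWorldConfig


_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


def _unique_word(rng: np.random.Generator, used: set[str], n_syllables: int) -> str:
    while True:
        word = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syllables)
        )
        if word not in used:
            used.add(word)
            return word


def _layer_widths(n_terms: int, depth: int) -> list[int]:
    """One root, remaining terms over layers 1..depth-1, doubling per layer."""
    weights = [2.0**i for i in range(1, depth)]
    total = sum(weights)
    rest = n_terms - 1
    widths = [max(1, int(round(rest * w / total))) for w in weights]
    while sum(widths) > rest:
        widths[int(np.argmax(widths))] -= 1
    while sum(widths) < rest:
        widths[int(np.argmax(weights))] += 1
    return [1] + widths


def generate_fixture_world(cfg: FixtureWorldConfig) -> FixtureWorld:
    """Generate a reproducible synthetic annotation world.

    The ontology is layered: every term in layer *i* has a primary parent in
    layer *i-1* assigned by shuffled round-robin (so every internal term has
    at least one child and branches stay balanced) plus, at a configurable
    rate, a secondary parent, making the graph a true multi-parent DAG.
    Genes belong to families; each family is tied to one layer-1 branch, its
    genes carry background annotations drawn from the branch's terms at the
    consistent layer, and its consistent instances annotate terms of that
    same pool.  Evidence texts follow a fixed template with distractor gene
    and GO mentions injected at the configured rates.
    """
    rng = np.random.default_rng(cfg.seed)
    used_words: set[str] = set()
    widths = _layer_widths(cfg.n_terms, cfg.depth)
    co_layer = cfg.depth // 2 if cfg.co_layer is None else cfg.co_layer
    if widths[1] < cfg.n_gene_families:
        raise SynthesisError(
            f"layer 1 has {widths[1]} branches but {cfg.n_gene_families} "
            "gene families were requested"
        )

    # --- ontology ---------------------------------------------------------
    terms: list[OntologyTerm] = []
    edges: list[tuple[str, str, str]] = []
    layers: list[list[str]] = []
    branch_of: dict[str, str] = {}
    counter = 0
    for layer, width in enumerate(widths):
        ids: list[str] = []
        prev = layers[layer - 1] if layer else []
        order = (
            [prev[int(i)] for i in rng.permutation(len(prev))] if prev else []
        )
        for j in range(width):
            counter += 1
            tid = f"T:{counter}"
            name = _unique_word(rng, used_words, 3 + int(rng.integers(2)))
            terms.append(OntologyTerm(id=tid, name=name))
            ids.append(tid)
            if layer:
                primary = order[j % len(order)]
                relation = "is_a" if rng.random() < 0.7 else "part_of"
                edges.append((tid, primary, relation))
                branch_of[tid] = tid if layer == 1 else branch_of[primary]
                if len(prev) > 1 and rng.random() < cfg.extra_parent_rate:
                    others = [p for p in prev if p != primary]
                    secondary = others[int(rng.integers(len(others)))]
                    relation2 = "is_a" if rng.random() < 0.7 else "part_of"
                    edges.append((tid, secondary, relation2))
        layers.append(ids)
    dag = OntologyDag(terms, edges)
    branch_roots = layers[1]

    # --- genes and families ----------------------------------------------
    family_branches = [branch_roots[f] for f in range(cfg.n_gene_families)]
    family_pools: list[list[str]] = []
    for f in range(cfg.n_gene_families):
        pool = [
            t
            for t in layers[co_layer]
            if branch_of[t] == family_branches[f] and dag.direct_children(t)
        ]
        if len(pool) < 2:
            raise SynthesisError(
                f"family {f} has only {len(pool)} candidate terms at layer "
                f"{co_layer}; increase n_terms or reduce n_gene_families"
            )
        family_pools.append(pool)

    gene_lexicon: dict[str, str] = {}
    gene_families: dict[str, int] = {}
    gene_background: dict[str, tuple[str, ...]] = {}
    used_symbols: set[str] = set()
    for g in range(cfg.n_genes):
        gene_id = f"Gene:{800001 + g}"
        symbol = f"{_unique_word(rng, used_symbols, 2)}-{int(rng.integers(1, 100))}"
        family = g % cfg.n_gene_families
        gene_lexicon[gene_id] = symbol
        gene_families[gene_id] = family
        pool = family_pools[family]
        k = min(cfg.n_background, len(pool))
        picks = rng.permutation(len(pool))[:k]
        gene_background[gene_id] = tuple(sorted(pool[int(i)] for i in picks))

    lexicon: dict[str, tuple[str, str]] = {
        symbol: (gene_id, "gene") for gene_id, symbol in gene_lexicon.items()
    }
    for t in terms:
        lexicon[t.name] = (t.id, "go")

    # --- instances --------------------------------------------------------
    gene_ids = sorted(gene_lexicon)
    instances: list[GoaInstance] = []
    generif: dict[tuple[str, str], str] = {}
    for i in range(cfg.n_instances):
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        family = gene_families[gene_id]
        pool = family_pools[family]
        term = pool[int(rng.integers(len(pool)))]
        pmid = f"PMID:{9000001 + i}"
        text = (
            f"{gene_lexicon[gene_id]} enables {dag.name_of(term)} in cultured cells."
        )
        if rng.random() < cfg.distractor_gene_rate:
            other_family_genes = [
                g for g in gene_ids if gene_families[g] != family
            ]
            dgene = other_family_genes[int(rng.integers(len(other_family_genes)))]
            text += (
                f" The related factor {gene_lexicon[dgene]} was detected in the "
                "same assay."
            )
        if rng.random() < cfg.distractor_go_rate:
            if cfg.distractor_go_source == "cluster":
                foreign = [
                    t
                    for f2, pool2 in enumerate(family_pools)
                    if f2 != family
                    for t in pool2
                    if not dag.related(t, term)
                ]
            else:  # children of other families' cluster terms
                foreign = sorted(
                    {
                        c
                        for f2, pool2 in enumerate(family_pools)
                        if f2 != family
                        for t in pool2
                        for c in dag.direct_children(t)
                        if not dag.related(c, term)
                    }
                )
            if foreign:
                dterm = foreign[int(rng.integers(len(foreign)))]
                text += (
                    f" A direct contribution of {dag.name_of(dterm)} was ruled out."
                )
        generif[(pmid, gene_id)] = (
            f"{gene_lexicon[gene_id]} is involved in {dag.name_of(term)}."
        )
        spans = tuple(tag_mentions(text, lexicon))
        instances.append(
            GoaInstance(
                go_id=term,
                gene_id=gene_id,
                pmid=pmid,
                evidence_text=text,
                label="CO",
                generif_text=generif[(pmid, gene_id)],
                entity_spans=spans,
                existing_go_ids=tuple(
                    t for t in gene_background[gene_id] if t != term
                ),
            )
        )
    return FixtureWorld(
        dag=dag,
        gene_lexicon=gene_lexicon,
        gene_families=gene_families,
        gene_background=gene_background,
        family_pools=family_pools,
        lexicon=lexicon,
        instances=instances,
        generif=generif,
        cfg=cfg,
    )
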