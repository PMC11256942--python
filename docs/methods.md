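# Methods

This note documents the models, procedures and design decisions behind
`goaqc`: what each component assumes, which parameters matter, what the
synthetic worlds do and do not emulate, and where the open design choices
were resolved.

## Problem setting

A GOA record is a triplet (GO term, gene, PMID) supported by an evidence
text. The detector performs multi-class single-output classification of
each record into five classes: consistent (CO), over-specific (OS),
over-broad (OB), irrelevant GO mention (IM), incorrect gene (IG). The
classes are treated as mutually exclusive: each synthesized record carries
exactly one planted error (or none). Evaluation is one-vs-all per class —
precision TP/(TP+FP), recall TP/(TP+FN), F1 as harmonic mean — with
unweighted macro averages and the convention 0/0 := 0 (standard, avoids NaN
propagation). On a balanced five-class set, uniform random guessing has
expected per-class P = R = F1 = 1/5 = 0.20; the package provides this floor
both analytically and by Monte-Carlo simulation.

## Corpus synthesis

Perturbations start from consistent instances and an ontology DAG
(`is_a`/`part_of` child→parent edges, validated acyclic, multi-parent):

- **OS** replaces the term with a uniformly sampled *direct child*; leaves
  are skipped.
- **OB** replaces it with a uniformly sampled *proper ancestor at any
  depth*, excluding namespace roots. Uniform sampling over all non-root
  ancestors is a deliberate choice: ancestors at distance > 1 carry greater
  semantic distance, and roots ("process"-like terms) are so broad that they
  degrade into a degenerate class.
- **IM** moves the annotation to a GO term that is tagged in the evidence
  text, differs from the original, and is *not* an ancestor or descendant of
  it. The ancestry exclusion keeps IM disjoint from OS/OB by construction;
  without it, an irrelevant mention that happens to be a child of the true
  term would be an OS instance under another name.
- **IG** reattaches the annotation to a different gene tagged in the
  evidence; single-gene evidence is skipped.

Ineligibility always surfaces as a skip signal. Balance is achieved by
oversampling the eligible consistent pool per class (each source instance is
used at most once per class), so label purity is never traded for
convenience; a shortfall raises an error naming the class and the gap.
Instance keys (`GO_Gene_PMID`) are unique within a corpus, and splits are
built over disjoint PMID pools.

Background annotations (`existing_go_ids`) are *re-attached after*
perturbation when a per-gene background map is supplied: the background of a
record belongs to its annotated gene, so an IG record carries the wrong
gene's annotation profile. This mirrors the sourcing order of real
pipelines (background is retrieved per finished instance from an
annotation database, keyed by the instance's gene) and is what makes
wrong-gene records detectable from co-annotation structure at all.

## Synthetic fixture worlds

`generate_fixture_world` builds a reproducible world from one seed:

- **Ontology**: one root plus `depth−1` layers with roughly doubling widths
  (240 terms over 6 levels by default). Every non-root term receives a
  primary parent in the previous layer by shuffled round-robin — so every
  internal term has at least one child and the layer-1 branches stay
  balanced — plus a secondary parent at rate 0.15, making the graph a true
  multi-parent DAG. Term names are unique pronounceable nonsense words, so
  names carry no morphological specificity cues (real GO names often do:
  "feeding behavior" contains "behavior"; the worlds are deliberately
  harder than reality in this respect).
- **Genes and families**: 60 genes in 6 families, each family tied to one
  layer-1 branch. A family's annotatable terms are its branch's terms at
  the "consistent layer" (`co_layer`, default `depth // 2`) that have
  children — guaranteeing OS and OB are feasible for every consistent
  record. Each gene carries 3 background annotations sampled from its
  family pool.
- **Evidence**: a fixed template — "<gene symbol> enables <term name> …" —
  with a distractor gene from another family and a distractor GO mention
  injected at configured rates (0.8 by default; the diagnostic corpora below
  use 1.0 so that every record co-mentions a second gene and a second term,
  making the distractor pattern itself uninformative). One GeneRIF-style
  sentence per (PMID, gene). Entity spans are produced by the package's own
  dictionary tagger over the world lexicon.
- `distractor_go_source` selects the population of planted irrelevant GO
  mentions: `"cluster"` (default) draws them from other families'
  annotated-cluster terms; `"cluster_children"` draws them from children of
  those terms. The latter matters for diagnosing IG detection: when IM
  distractors are themselves annotated-cluster terms, an IM record (gene of
  family A, term of family B) and an IG record (gene of family B, term of
  family A) are mirror images in the annotation graph, and no co-annotation
  signal can separate them; drawing IM mentions from never-annotated
  children breaks the symmetry.

What the worlds do **not** emulate: lexical variation of concept mentions
(each concept has exactly one surface form), abstract-length documents and
truncation pressure, annotation-frequency skew across terms, noisy or
incomplete background annotations, and any correlation between name
morphology and hierarchy. Passing tests on these worlds therefore
demonstrate that each pipeline stage implements its contract and that the
knowledge-routing claims hold under controlled signal placement — not that
the bundled text encoder approaches production accuracy on real abstracts.

## Background-knowledge encoders

Both encoders share one inductive layer family. A layer runs one
mean-aggregation sub-layer per edge type (mean over that type's neighbors,
concatenated with the node's own vector, linearly projected), sums the
per-type outputs, applies ReLU, then batch normalization per node type.
Three layers are stacked; embeddings are read off the last layer. The
encoder consumes only feature matrices and normalized adjacency — never node
identities — so it transfers to unseen graphs. Batch statistics are always
computed from the graph being encoded, which keeps export deterministic and
permutation-equivariant.

**Annotation-graph encoder.** The heterogeneous GOA graph is bipartite:
PMG nodes (PMID+gene) and GO nodes, with an `annotate` edge per consistent
instance, a `not_annotate` edge per inconsistent instance regardless of
subtype, and `annotate` edges for background annotations. Duplicate
(PMG, GO) pairs merge with instance edges taking precedence; two instances
asserting different types for the same pair are a data error. Node features
are 8-dim: all-ones for PMG nodes, per-id deterministic standard normals for
GO nodes (hash-seeded from the global seed and the term id, so a term's
initial features agree across graphs and runs). Pre-training classifies
edge type from the two concatenated endpoint embeddings through a
one-hidden-layer MLP (16 → hidden → 2 logits), cross-entropy, full batch,
Adam at 1e-2 for 200 epochs (defaults; the optimizer and schedule are our
choices).

**Held-out protocol.** For feature export, every instance is encoded on its
split's graph — background edges and the *other* instances' candidate edges
present — with its *own* candidate edge removed from message passing
(leave-candidate-out). The candidate edge's type is exactly the label, so
letting it participate would leak the answer; the protocol is verified by
asserting embeddings are invariant to the candidate's label flip. Training
instances are exported the same way so that train and evaluation feature
distributions match.

**Hierarchy encoder.** The ontology is reduced to the merged specificity
view: `is_a`/`part_of` collapse to `children_of`, each edge mirrored by an
untyped-reverse `parent_of` edge; the encoder never observes relation
subtypes (asserted on its input schema). Node features are per-id
deterministic normals, dimension 16. Pre-training is our reconstruction of
a hierarchy-encoding objective: 3-way classification of ordered term pairs
as `children_of` / `parent_of` / `no_edge`, with `no_edge` pairs sampled
uniformly at 1:1 per positive and *excluding* transitive
ancestor–descendant pairs (they are hierarchically related even though no
single edge connects them, and labeling them "unrelated" would poison the
signal). This objective is the principal fidelity risk of the package: it
is chosen, not copied, and is recorded here as such. In practice it forces
direction-consistent embeddings (classifying (a,b) as `children_of` pushes
(b,a) toward `parent_of` at ≥ 0.9 consistency on fixtures) and yields
depth-separated embeddings, which is the property the OS/OB classes consume.

The corpus-anchored sub-DAG fed to the hierarchy encoder is extracted by
seeding on the corpus terms (annotated plus background) and closing over
direct children (ancestors optionally, via `closure=`); only
`is_a`/`part_of` edges exist in this package, so no other relation types can
leak in.

## Joint classifier

The text encoder is an interface; the bundled implementation is a hashed
bag-of-words encoder (BLAKE2b token hashing into 32 buckets, counts
normalized by token count, first-256-token truncation dropping the tail of
segment B). It is deterministic across processes and platforms, which makes
desk-scale experiments exactly reproducible; a transformer encoder exposing
the same `pool` contract can be dropped in without changing anything
downstream. Segment A of the input pair is "<GO name> ; <gene id>" — the
classifier must see both elements of the annotation under scrutiny; segment
B is the evidence text, or the GeneRIF statement (its absence under the
`generif` variant is an explicit error, never a silent fallback), or the
marker-reformulated evidence (`[GENE] … [/GENE]`, `[GO] … [/GO]`).

Entity information is injected additively: two learned vectors (inside- and
outside-span), weighted by the fraction of tokens each class covers, are
added to the pooled text vector. Both vectors are zero-initialized, so the
entity variant coincides with the plain encoder at initialization.

Feature assembly is a pure function with fixed order:
`pooled ‖ goa[PMG] ‖ goa[GO] ‖ dag[GO]`, including only the blocks the
variant uses (`godg_exgoa` with the bundled encoder: 32+8+8+16 = 64). A
node missing from its table contributes a zero block and is flagged once;
the alternative (dropping the instance) was rejected to keep evaluation
sets intact. The `dummy` variant substitutes structure-free per-id Gaussian
tables of the same shapes — the regularizer ablation runs through the
identical pipeline.

The head is a single-hidden-layer MLP (hidden 64) to five logits,
cross-entropy, Adam at 1e-2, 150 epochs full batch, model selection by best
development macro-F1 (evaluated every 5 epochs); argmax ties resolve to the
lowest class index for determinism. All defaults live in config objects and
are recorded in artifact headers.

## Numerical choices

- All trainable components run on a small reverse-mode autodiff core over
  numpy (float64, full-batch). Gradients are verified against central
  finite differences in the test suite.
- Batch normalization uses eps = 1e-5; single-node types degenerate to the
  beta offset rather than dividing by zero.
- Mean aggregation over an empty neighborhood is a zero vector.
- Per-id feature initialization hashes `(seed, node id)` with BLAKE2b to a
  sub-seed below 2^63; the same id gets the same vector in any graph.
- Negative-pair sampling in the hierarchy objective retries up to 200×
  the positive count, deduplicating draws.

## Scale of the bundled experiments

The test suite and the acceptance script run desk-scale problem sizes,
chosen as the smallest worlds in which every class signal is cleanly
plantable: 240-term / 6-level ontologies (120-term / 5-level in unit
tests), 60 genes in 6 families, corpora of 80 instances per class split
60/20/20 over disjoint PMIDs, three seeds for the variant comparisons, and
1000 draws per perturbation validity check. The balanced-corpus check runs
at the full 500-per-class evaluation scale (2500 instances). Graph
pre-training uses 200 epochs; the whole acceptance script completes in
minutes on one CPU.

## Known limitations

- The hierarchy pre-training objective is a reconstruction (see above); a
  different objective could change how much depth information the 16-dim
  embeddings carry.
- The hashed bag-of-words encoder ignores word order and syntax entirely;
  CO detection in particular (does the term's mention pattern *support* the
  annotation?) is weak without a contextual encoder, and the absolute
  scores of the bundled experiments should be read only relatively.
- Whether a transformer text encoder should be fine-tuned end-to-end
  jointly with the graph blocks, or frozen with only the head trained, is
  left open by this design; the bundled encoder has no trainable text
  parameters, so the question does not arise at desk scale.
- The annotation-graph signal degrades when term usage is heavily skewed
  (very frequent terms pull embeddings together); the synthetic worlds do
  not model this skew.
- OBO input support covers term id, name, namespace, `is_a` and
  `relationship: part_of` only; richer OBO semantics (intersections,
  obsoletion chains, regulates closures) are out of scope.
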