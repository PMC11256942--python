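# goaqc — typed inconsistency detection for GO annotation

Literature-based Gene Ontology Annotation (GOA) records link a gene product
to a GO term on the strength of a published evidence text. Curated databases
accumulate typed errors in these records: the chosen term can be too narrow
(**over-specific, OS**) or too general (**over-broad, OB**) relative to what
the evidence supports, the annotation can land on a GO term that is merely
*mentioned* in the text (**irrelevant mention, IM**), or on the wrong one of
several genes discussed there (**incorrect gene, IG**). `goaqc` implements
an automatic detector for these error types, framed as five-way
classification of a (GO term, gene, PMID, evidence) triplet into
{CO, OS, OB, IM, IG}, where CO is self-consistency.

The package covers the full experimental loop:

- **Corpus synthesis** — balanced five-class corpora built by perturbing
  consistent records against an ontology DAG: OS samples a direct child of
  the annotated term, OB a proper non-root ancestor, IM an unrelated GO term
  tagged in the evidence, IG a co-mentioned other gene. Every perturbed
  instance records its provenance; ineligible instances yield explicit skip
  signals, never silently mislabeled records. A synthetic *fixture world*
  generator (layered random ontology, gene families, templated evidence with
  planted distractor mentions, background annotations, GeneRIF-style
  statements) makes every stage runnable offline.
- **Background-knowledge encoders** — two pre-trained graph encoders whose
  node embeddings feed the classifier:
  - an *annotation-graph encoder* over the bipartite heterogeneous graph of
    PMG nodes (PMID+gene) and GO nodes, with `annotate` / `not_annotate`
    edges, trained by edge-type classification (8-dim embeddings);
  - a *hierarchy encoder* over the merged specificity view of the ontology
    (`is_a`/`part_of` collapsed to `children_of`, mirrored `parent_of`),
    trained by 3-way ordered-pair classification (16-dim embeddings).

  Both use the same layer family: per-edge-type mean-aggregation
  (GraphSAGE-style) sub-layers, summed across edge types, ReLU, batch
  normalization, stacked three deep — inductive, consuming only features and
  topology.
- **Joint classifier** — a pluggable text encoder pools the input pair
  ("GO name ; gene id" vs. evidence / GeneRIF / marker-reformulated text,
  optionally with an additive entity-mask embedding), and the pooled vector
  is concatenated with the graph blocks `goa[PMG] ‖ goa[GO] ‖ dag[GO]`
  per experiment variant before a one-hidden-layer MLP emits five logits.
- **Evaluation** — one-vs-all precision / recall / F1 per class
  (P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean, 0/0 := 0), macro
  averages, the analytic and Monte-Carlo random-guess baseline (0.20 on a
  balanced five-class setting), and an experiment-matrix runner over the
  variant inventory (`baseline`, `text_only`, `generif`, `entity_embedding`,
  `entity_reformulation`, `godg`, `exgoa`, `godg_exgoa`, `dummy`).

## Worked example

Run the experiment matrix end-to-end on a synthetic world (400 consistent
instances, 40 instances per class after synthesis, disjoint-PMID splits):

```bash
goaqc matrix --variants baseline,text_only,godg --per-class 40 \
      --n-instances 400 --seed 1 --out matrix.tsv
```

```
  variant  CO_F1  OS_F1  OB_F1  IM_F1  IG_F1  macro_F1
 baseline  0.200  0.200  0.200  0.200  0.200     0.200
text_only  0.348  0.286  0.000  0.400  0.308     0.268
     godg  0.267  0.889  0.917  0.609  0.167     0.570
```

(Abbreviated columns; the TSV also carries per-class precision and recall.)
The `baseline` row is the analytic random-guess floor. `text_only` trains the
bundled hashed bag-of-words encoder on the raw text pair: in this world the
term names are opaque symbols, so specificity errors are nearly undecidable
from text and OS/OB hover near chance. `godg` concatenates the 16-dim
hierarchy embeddings of the annotated term: OS/OB F1 jumps to ~0.9 because
the embeddings encode where the term sits in the ontology, which is exactly
the signal those two classes need.

Individual stages (`fixture-world`, `synthesize`, `build-graph`,
`pretrain-goa`, `pretrain-dag`, `train`, `evaluate`) are available as
file-to-file commands; see `goaqc <command> --help`. Every artifact embeds
the seed and a config hash in a header line.

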