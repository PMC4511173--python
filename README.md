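# bteval

Evaluation and knowledge-derivation tooling for event-based biomedical
information extraction:

- **Standoff I/O** (`bteval.standoff`, `bteval.schemas`) — read, write and
  validate tab-separated standoff annotations: text-bound entities with
  discontinuous spans, nested events, ontology normalizations and
  equivalence sets, against either the gene-regulation (GRN) or the
  bacteria-biotope (BB) task schema.
- **Ontology similarity** (`bteval.ontology`) — a minimal OBO 1.2
  loader and Wang semantic similarity (weighted ancestor S-values) with
  configurable per-relation weights.
- **Network inference** (`bteval.inference`, `bteval.network`) — a
  declarative rule engine that rewrites molecular events (binding sites,
  promoters, regulons) into biological interactions, then projects
  `Interaction:<label>` events onto a directed labeled gene network by
  recursively reducing event arguments to their participating genes.
- **Network scoring** (`bteval.network_scoring`) — arc-by-arc graph diff
  producing Slot Error Rate (SER = (S+D+I)/N), recall, precision and F1,
  with *official*, *shape* (labels erased) and *effect* (mechanism arcs
  folded into generic Regulation) modes, and two inversion-folding
  policies.
- **Biotope scoring** (`bteval.bb_scoring`) — sub-task 1 entity
  detection/categorization with graded similarity S = Sc·Se (Wang
  category similarity × segment Jaccard over possibly discontinuous
  spans), optimal one-to-one entity pairing, and SER; sub-tasks 2/3
  event extraction F1 with strict bacterium matching (equivalence sets
  honored), graded biotope boundaries, boundary relaxation and
  intra-sentence restriction.
- **Fixtures** (`bteval.fixtures`) — deterministic generators for
  synthetic ontologies, annotated documents and networks, plus error
  injection with exact, recoverable (S, D, I) ground truth.

## Command line

Everything lives under the `bteval` umbrella (also installed:
`grn-score` and `bb-score` shortcuts):

```bash
# synthetic fixtures
bteval gen-ontology --depth 4 --branching 3 --seed 1 -o onto.obo
bteval gen-bb --seed 1 --n-docs 10 --out corpus/          # writes *.txt/*.a2/ontology.obo
bteval gen-grn --genes 10 --arcs 12 --seed 1 --out ref.net --doc-dir grndocs/
bteval perturb --network ref.net --delete 2 --insert 3 --substitute 1 \
    --seed 5 --out pred.net --truth truth.json

# inference and scoring
bteval grn-infer --in grndocs/ --out inferred.net
bteval grn-score --ref ref.net --pred pred.net --mode official --report json
bteval bb-score --subtask 1 --ref corpus/ --pred predicted/ \
    --onto corpus/ontology.obo --report tsv
bteval bb-score --subtask 2 --ref corpus/ --pred predicted/ \
    --relax-boundaries --intra-sentence
```

`grn-score --ref/--pred` accept an arc-list TSV
(`agent<TAB>label<TAB>target`), a GraphML file, or a directory of
standoff documents (inference is applied first). `bb-score` ref/pred
are directories of `<doc>.txt` + `<doc>.a1/.a2/.ann` files, optionally
with a `sentences.tsv` of gold sentence spans.

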