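# noveltylbd

Literature-based discovery (LBD) over subject–predicate–object (SPO) triples,
with machine-learned filtering of triples down to the ones that express a
paper's *novel contribution* before discovery is run.

## Who this is for

Researchers in biomedical text mining who work with SemMedDB/SemRep-style
predications — dated `(subject CUI, predicate, object CUI)` relations between
UMLS concepts extracted from article abstracts and full texts — and who want
to generate and evaluate candidate hidden knowledge with the classic A–B–C
model without drowning in background-knowledge pairs (connections made
through generic terms like *patient* or *countries*).

## The model

**Open discovery.** Build a directed graph with CUIs as vertices and an edge
i → j whenever some triple has subject i and object j. With binary adjacency
matrix A, the square A² = (s_ij) counts walks of length two, so every ordered
pair with s_ij > 0 but a_ij = 0 is a *candidate hidden knowledge pair*
(CHKP): A and C are unconnected in the literature but linked through at least
one B.

**Triple importance.** A novel contribution is typically stated both in a
paper's abstract and its body. For two triples cui₁₁–rel₁–cui₁₂ and
cui₂₁–rel₂–cui₂₂, similarity is the sum of three cosines — subject vs
subject and object vs object under concept embeddings (cui2vec-style),
predicate vs predicate under word embeddings (GloVe-style) — a value in
[0, 3]. A body triple's importance score is its maximum similarity to any
abstract triple of the same document; scores ≥ 2.5 label it *important*,
≤ 1.5 *not important*, and the gap in between is discarded so the classes
stay well separated. Two classifiers learn these labels:

* a feature network (section, sentence TextRank, CUI hierarchy depths) with
  halving-width ReLU layers, one sigmoid output and per-availability-pattern
  models for missing features;
* a masked-element language model that treats each triple as a three-word
  sentence over a word-level vocabulary, hides one element and predicts it
  from the other two; a binary head over the resulting triple embeddings
  classifies importance and needs no full text at all.

**Timeslicing evaluation.** CHKPs generated from publications dated before a
cutoff D are scored for precision against gold standards drawn from
publications dated ≥ D: all post-cutoff pairs, abstract-only pairs, or only
importance-labelled pairs — the last being the least contaminated by
background knowledge.

Everything is testable without external data: `noveltylbd.synthetic`
generates dated corpora with planted novel triples, hub-structured
background knowledge, planted hidden A→C pairs straddling the cutoff, and
embedding stores whose class subspaces are orthogonal by construction.

## Worked example

Run the full pipeline on a synthetic corpus (16 documents, background noise
enabled, importance by similarity labels):

```sh
noveltylbd run --config example_config.json
```

with `example_config.json` containing

```json
{
  "schema_version": 1,
  "outdir": "lbd_run",
  "seed": 7,
  "cutoff": "2021-01-01",
  "train_window_end": "2021-03-29",
  "hi": 2.5, "lo": 1.5,
  "classifier": "labels",
  "triples_sources": ["all", "important"],
  "gold_variants": ["all_post_triples", "post_abstract_triples", "post_important_triples"],
  "synthetic": {"n_docs": 16, "noise_rate": 0.5, "seed": 7},
  "predications_path": null,
  "concept_embeddings_path": null,
  "predicate_embeddings_path": null,
  "lm": {}
}
```

prints one report per triple source (abridged):

```
{
  "triples_source": "all",
  "total_chkps": 62,
  "precision": {
    "all_post_triples": 0.322581,
    "post_abstract_triples": 0.048387,
    "post_important_triples": 0.048387
  }
}
{
  "triples_source": "important",
  "total_chkps": 3,
  "precision": {
    "all_post_triples": 1.0,
    "post_abstract_triples": 1.0,
    "post_important_triples": 1.0
  }
}
```

Reading: unfiltered discovery over every pre-cutoff triple proposes 62
candidate pairs, most of them chains through shared background concepts, and
only a handful are later confirmed. Restricting discovery to important
triples removes the background edges: exactly the 3 planted hidden (A, C)
pairs remain, every one confirmed by the post-cutoff slice, so precision
reaches 1.0 on all three gold standards — and the gap between the two rows
widens as the gold standard itself excludes background knowledge. The run
directory holds the corpus, the labelled training set, per-source CHKP and
"as yet undiscovered" pair exports, reports (TSV + JSON), a JSON-lines stage
log, and the exact config for bit-identical reruns.

Each stage is also its own subcommand (`simulate`, `convert`, `label`,
`train`, `discover`, `evaluate`) — see `noveltylbd <cmd> --help`.

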