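# Methods

## Problem setting

The package implements A–B–C open discovery over SPO predications and the
machinery to restrict discovery to "important" triples — those expressing a
paper's novel contribution — before candidate pairs are generated. The
pipeline has three parts: (1) the knowledge-graph LBD system, (2) importance
labelling and two trainable importance classifiers, (3) timeslicing
evaluation against gold standards that differ in how much background
knowledge they reward.

## Discovery model

Vertices are concept identifiers (CUIs); a directed, untyped, binary edge
i → j exists when at least one triple has subject i and object j (predicates
are deliberately ignored at graph construction). The graph is held in
networkx; the adjacency matrix is materialised sparse (CSR, int64) in a
sorted, stable vertex order so matrix indices reproduce across runs. Squaring
the sparse matrix gives exact integer counts of length-two walks, and CHKPs
are the ordered pairs (i, j), i ≠ j, with s_ij > 0 and a_ij = 0.

Two boundary conventions needed fixing:

* **Direction.** The defining condition is a zero *in the original adjacency
  matrix*, so a known reverse edge C → A does not suppress the candidate
  (A, C). A `symmetric_suppression` flag inverts this, off by default.
* **Diagonal.** Mutual edges make s_ii > 0, but a self-pair is meaningless
  and is always excluded.

`linking_terms` provides closed discovery: the B-set for a suspected (A, C),
computed as out-neighbours(A) ∩ in-neighbours(C).

## Importance labelling

Two triples are compared by summing three cosine similarities (subjects,
predicates, objects). Concept and predicate vectors come from separate
stores read in word2vec text format; a predicate absent from its store is
composed as the mean of the word vectors of its lower-cased,
underscore-split tokens — a standard bag-of-words composition, chosen
because SemRep predicate names are multi-word but word-embedding releases
key single words.

Cosines can be negative, which would break the stated [0, 3] score range, so
each component is clamped to max(0, cos) by default; an unclamped mode
exists for diagnostics. A body triple's score is its maximum similarity over
the *same document's* abstract triples (never another document's), and the
arg-max abstract triple is retained for explainability. Thresholds default
to hi = 2.5 and lo = 1.5; the open interval between them is a deliberate gap
whose instances are kept (labelled `discarded_gap`) but excluded from
training. Documents with no abstract triples, and pairs with unresolvable
embeddings, are skipped and counted — never silently scored 0, which would
bias the negative class. Class balancing is by random undersampling of the
majority class, seeded.

## Classifiers

**Feature network.** Inputs are a section one-hot plus whichever of
{sentence TextRank, subject CUI depth, object CUI depth} are available;
numeric features are standardised per training pattern. The architecture is
fixed by convention: `depth` hidden ReLU layers of halving widths (default
depth 4, first width 32, floor 1), a single sigmoid output, binary
cross-entropy, default 200 epochs, dropout 0. One model is trained per
feature *availability pattern*; prediction uses the applicable model with
the most features, ties broken by lexicographic pattern id. TextRank uses
the classic parameterisation: undirected sentence graph weighted by token
overlap normalised by the sum of log sentence lengths, damping 0.85,
tolerance 1e-6, at most 100 damped power iterations, scores normalised to
sum to 1. CUI depth is path length from the root of a supplied parent–child
hierarchy (roots at depth 0); concepts outside the hierarchy simply lack the
feature.

**Masked triple LM.** Each triple is a three-word sentence over a word-level
vocabulary (CUIs such as `C0012984` have no meaningful subwords, so no
subword tokenisation). The vocabulary reserves `[PAD] [UNK] [MASK] [CLS]
[SEP]`, then orders observed tokens by descending frequency with
lexicographic tie-break, truncating at `vocab_size` (overflow → `[UNK]`).
Exactly one of the three positions is masked, uniformly at random per
training example — fraction-based masking is meaningless at length 3. The
model sums token and position embeddings, concatenates the three slots, and
feeds `hidden_layers` ReLU layers (tunable, like `vocab_size`) into a
softmax over the vocabulary; embeddings, position vectors and dense weights
train jointly by Adam. A triple's embedding is the concatenation of its
three (token + position) vectors, and a small sigmoid head fine-tuned on the
labelled set yields the binary importance decision at threshold 0.5 (the
threshold is a convention; nothing in the procedure pins it).

All networks run on a small in-package numpy core (`nn.py`) with seeded
initialisation, shuffling and dropout, which keeps two same-seed runs
bit-identical — a property the artifact-level determinism guarantees rely
on. Where an independent check is wanted (e.g. separability of the feature
training blobs), the tests use scikit-learn's logistic regression as the
oracle, never as the implementation.

## Timeslicing evaluation

The timeslice convention is strict: date < D is "pre", date ≥ D is "post"
(the boundary day itself is post). Gold standards project post-cutoff
triples to ordered (subject, object) pairs under three variants: all
sections, abstracts only, and important-labelled only. Precision is
|CHKP ∩ gold| / |CHKP|, with the empty-CHKP case an error rather than zero.
Reports print precision both as a proportion and as a percentage because
"percentage precision" tables are ambiguous between the two. Recall is not
reported by default: emitting all inferable pairs trivially maximises it.
CHKPs found in no gold standard are exported separately as the
still-undiscovered candidates. For nested gold standards a superset gold can
only raise precision, a monotonicity the tests assert.

## Synthetic data: what it emulates, what it does not

The generator's defaults define the study conditions: 40 documents split
evenly around a 2021-01-01 cutoff (pre window from 2020-01-01, post window
to 2021-06-13, dates uniform), 2 novel triples per document, a background
pool of 10 body-only triples, 3 planted hidden chains, embedding dimension
8, noise off. Classifier training data is drawn from the post-cutoff slice
before 2021-03-29 so it cannot overlap the pre-cutoff discovery input.

Construction choices make the planted structure provable rather than merely
likely:

* **Separability by orthogonality.** Background concepts and predicates
  occupy the first half of the embedding dimensions, novel/planted ones the
  second half, so a copied novel triple scores exactly 3 and any
  background-vs-abstract comparison exactly 0. Labels are exact, not tuned
  by margins. A `gap_per_doc` "hard mode" plants body triples that share an
  abstract triple's concepts but carry a background predicate (score 2), to
  exercise the discard logic.
* **Hub-structured background.** Background triples alternate spoke → hub
  and hub → spoke around one generic hub concept (the "patient"-like term),
  which guarantees—for every seed—that unfiltered discovery gains
  background-only two-step pairs that importance filtering removes.
* **Chain isolation.** Each document's novel triples use concept pairs
  unique to that document, and planted chains use disjoint concepts, so the
  pre-cutoff graph's two-step non-edges are exactly the planted (A, C)
  pairs once background is filtered out.

What the generator does *not* model: extraction noise (wrong CUIs,
hallucinated relations), real publication-date dynamics, polysemous
concepts, or embedding stores with partial coverage. Passing the closure
tests therefore shows the pipeline's machinery is correct under its own
assumptions, not that the importance hypothesis holds on real literature —
the latter depends on corpus-scale embeddings and extraction quality that
are inputs here.

## Pipeline and problem sizes

`run_pipeline` executes label → train → predict → discover → evaluate,
persisting the labelled set, per-source CHKP/report/undiscovered exports, a
JSON-lines count log per stage, and the exact config; reruns from a
persisted config are byte-identical. The importance filter is applied to all
distinct pre-cutoff triples (abstract + body), since the LM classifier needs
no full text; the abstract-only source is kept as the unfiltered baseline.
The `classifier: "labels"` mode bypasses the trained model and uses the
similarity labels directly — the right tool when the question is about the
discovery/evaluation machinery rather than classifier generalisation.

Test and acceptance runs use desk-scale sizes chosen to keep the suite quick
while leaving every mechanism exercised: random-graph oracle checks at up to
200 vertices over 100+ seeded graphs; classifier-recovery runs at 250
documents × 4 novel triples (≥500 labelled instances per class, vocabulary
≈ 2,000 tokens, embedding dimension 16). At these sizes the masked LM trains
in seconds; the same code scales linearly in triples per epoch.

## Known limitations

* The feature network and triple LM are small dense models; no attention,
  no layer norm. At three-token inputs this is adequate, but the LM is a
  structural analogue of transformer-based masked modelling, not a
  re-implementation of one.
* Embedding coverage gaps are skipped-and-counted; no back-off embedding is
  learned for out-of-store CUIs.
* Discovery is one-step (length-two walks) and predicate-blind by design;
  multi-step or relation-aware inference is out of scope.
* Thresholds (2.5/1.5) are configuration, taken as given rather than
  re-optimised on a validation set.
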