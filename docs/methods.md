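# Methods

## Problem and approach

`cpimine` extracts chemical–protein interactions (CPIs) from
entity-annotated abstracts in the ChemProt TSV dialect. Candidate
**CPI pairs** are every chemical × gene/protein mention co-occurring in one
sentence; **CPI triplets** extend a pair with one interaction word — a
dictionary term (e.g. *agonist*, *inhibits*) mapped to a CPR relation group.
Pairs inherit their CPR label (1–10) from the gold relation annotations;
unannotated pairs are CPR:10 (no interaction). All triplets of a pair share
the pair's label. The model predicts over the six-class space
{CPR:3, 4, 5, 6, 9, other}: the five evaluated groups (up-regulator,
down-regulator, agonist, antagonist, substrate) plus everything else, and
only evaluated-group predictions are emitted.

## Preprocessing

* **Offset frame.** Entity offsets index `title + separator + body`; the
  separator defaults to a tab (the common ChemProt convention) and is
  configurable, as is a 1-based-offset conversion flag.
* **Sentence segmentation** is rule-based (terminator + whitespace +
  uppercase/digit lookahead, abbreviation blacklist) and deterministic. A
  mention crossing a sentence boundary extends the earlier sentence rather
  than being dropped; repairs are logged and counted.
* **Tokenization** splits leading/trailing punctuation but keeps brackets
  that are balanced within a chunk, so `P2Y(2)` stays one token.
* **Entity masking.** Before parsing, the focal chemical becomes `CHEM`,
  the focal protein `PROT`, and every other tagged entity `CPTk`, where *k*
  is the numeric part of the entity's term id (`T10` → `CPT10`).
  Replacement is span-based: multi-word entities collapse to one token and
  an entity strictly inside a word keeps its surrounding characters
  (`subretinal` with the `retinal` span tagged → `subCPT10`). Masking is
  reversible; tests assert the unmasked text round-trips exactly.

## Dependency graphs

Parsing is behind a `ParserAdapter` contract (token sequence → graph with
one node per token). Two adapters ship: a fixture store (JSON-lines or
CoNLL-U) for pre-computed parses, and a deterministic rule-based parser
that picks a main predicate as root and attaches determiners, adpositional
phrases and noun modifiers with a compact UD-style label set. The rule
parser always returns a tree and exists to satisfy the contract
deterministically; for linguistic fidelity substitute real parses through
the fixture adapter.

Shortest dependency paths (SDPs) are computed on the undirected view of the
graph — standard practice in SDP-based relation extraction; a directed mode
is available. Ties between equal-length paths break by the
lexicographically smallest node sequence, making every downstream feature
bit-reproducible.

**Triple topology (`sp_type`).** The {e1, iw, e2} sub-structure is
classified into eight classes: 0/1/2 when one element lies on the SDP
between the other two (membership tested by the distance identity
d(a,x)+d(x,b)=d(a,b)); otherwise a hub node on shortest paths of all three
pairs indicates a star (3), refined to 5/6/7 when a hub-avoiding path joins
(e1,e2), (iw,e2) or (iw,e1) respectively; no hub means a triangle (4).
Disconnected triples take the sentinel −1, encoded as its own one-hot
column. This predicate-based formalization is this package's contract for
an 8-way shape/order taxonomy that is otherwise ambiguous; tests re-verify
every returned class against an independent exhaustive-path checker.

## Features

Positional features are computed on masked tokens (every entity is exactly
one token). `e1` is the first-occurring focal entity, `e2` the second.

* Counts: sentence length; tokens before e1/e2/iw; entities other than the
  focal pair.
* Windows (default width 3 tokens, configurable): presence of
  `significant*` and of substrate-context stems before e1 / after e2. The
  stem list (`product`, `pathway`, `generat`, `synthe`) is the union of the
  two overlapping exemplar lists the feature definition admits
  (product/production, generate/generated, synthetic/synthesis), matched as
  case-insensitive prefixes.
* Flags: e1/e2 inside brackets (bracket depth at the token); adjacency;
  negation and conjunction words inside the candidate's covered region
  (leftmost to rightmost element, inclusive — for triplets the region
  extends to the interaction word). The shipped negation/conjunction lists
  are small documented closures of common exemplars and are
  user-overridable.
* SDP features: edge counts and word counts of the e1–e2 path (pairs and
  triplets) and of the e1–iw and iw–e2 paths (triplets); one-hot presence
  of each typed dependency per path with the vocabulary frozen at fit time
  (not hard-coded to one parser's inventory); an appositive flag on the
  e1–e2 path (apposition marks coreference, a strong no-interaction
  signal). Disconnected parses take the sentence-length sentinel plus a
  `no_path` flag.
* Triplets additionally carry the dictionary-mapped CPR group of the
  interaction word as a categorical.

Matrices are named-column; at predict time unseen categorical values map to
all-zero one-hots and an unknown non-categorical feature is an error.

## Interaction-word dictionary

A 74-entry seed dictionary of CPR-typical trigger words ships with the
package (`word<TAB>CPR`); users supply larger dictionaries through the same
loader. Matching is case-insensitive exact token match; an optional
suffix-stemming table (s/es/ed/ing) is off by default.

## Three-stage stacked model

* **Stage I** — binary (evaluated group vs not), three families per track
  (random forest, extremely randomized trees, gradient-boosted trees via
  xgboost), pairs and triplets in parallel. Training rows are scored
  strictly out-of-fold over 10 stratified folds; test rows by the average
  of the 10 fold models. Scores are rank-normalized — the empirical rank
  transform (rank−1)/(n−1) with average ranks for ties, a single row
  mapping to 0.5 — and appended as three meta-columns per track. Raw
  probabilities are available behind a flag.
* **Stage II** — six-class, six families per track (the stage-I three plus
  logistic regression, LDA, Gaussian naive Bayes; a config drops to the
  linear/Bayes three). Each family contributes its six out-of-fold class
  scores plus its argmax class (one-hot). When a pair spawned several
  triplets, the triplet with the highest best-evaluated-class score
  (averaged over families) represents it; ties break by earliest
  interaction-word position, then lexicographic word. An alternative
  selection criterion (smallest "other" score) is available.
* **Stage III** — original pair features + both tracks' stage-II blocks
  (pairs with no triplet get a zero block plus an indicator) feed logistic
  regression, random forest, extremely randomized trees and gradient
  boosting; class scores are averaged and the argmax is final. "Other"
  predictions emit no relation.

Fold assignments are retained per stage so leakage is auditable; a
memorizing-learner canary test confirms out-of-fold scores cannot be
memorized. All estimator seeds derive deterministically from one pipeline
seed; fixed seeds give byte-identical prediction files.

Hyper-parameter search (10 random draws, 3-fold CV) and recursive feature
elimination with 3-fold CV are provided per learner per track, scored by
binary F1 (stage I) or micro-F1 over the evaluated classes; both are off by
default because the shipped defaults (100 trees per forest family, depth-4
gradient boosting, C=1 logistic regression) are adequate at package scale.

## Evaluation

Relation identity is abstract-level — (pmid, CPR group, chemical term,
protein term) — so a relation asserted in several sentences counts once.
Micro P/R/F1 pools TP/FP/FN over the five evaluated groups; per-class
metrics derive from a 6×6 confusion matrix whose (other, other) cell is
undefined (non-interacting non-predicted pairs are not enumerable at the
abstract level). Empty gold sets report recall 0 with a warning rather
than NaN.

## Synthetic corpus generator

The generator emits the full three-file dialect plus deterministic fixture
parses, with a versioned template grammar of ~6 sentence templates per CPR
class. Class templates embed exactly one trigger word mapped to their
class; CPR:10 templates embed none, except three distractor templates
where a trigger appears under negation — these give the triplet track
genuine no-interaction candidates, as real corpora do. Entity names are
generated (including multi-word and parenthesized protein names and
sentence-initial capitalization) with exact offsets; every chemical ×
protein pair of an annotated sentence carries the sentence's relation, so
at zero label noise the planted class is recoverable from trigger word +
negation alone (a property test asserts this stump reaches accuracy 1.0).
Label noise flips a pair's class uniformly among the other five groups at
relation-materialization time.

Default conditions: 100 documents × 3 body sentences, class prior
{3: 0.16, 4: 0.20, 5: 0.10, 6: 0.10, 9: 0.14, 10: 0.30} (interaction-bearing
groups ordered as in the real corpus, down-regulators most frequent), label
noise 0. The corpus emulates schema, offsets, triggers and masking
mechanics — not the lexical diversity, cross-sentence relations or
annotation noise of PubMed abstracts. High scores here demonstrate pipeline
correctness and leakage-free stacking, not real-corpus accuracy.

## Problem sizes and numerical choices

Integration tests and the acceptance script train on an 80-document
synthetic split (~280 pairs) and evaluate on a held-out 40-document split,
with 60-tree forests and 40-round boosting — sizes chosen so the full
stacked fit (2 tracks × (3 + 6) families × 10 folds plus 4 final learners)
stays comfortable on one CPU while leaving every stage exercised.
Stratified fold counts fall back to the rarest class's cardinality with a
warning; a class with fewer than 2 rows is an error. Degenerate inputs
(empty relation files, single-token sentences, pairs with no triplet,
disconnected parses) all have defined, tested behavior.

## Known limitations

* The rule parser is a deterministic stand-in with a coarse grammar; SDP
  features are only as good as the parses supplied.
* The seed dictionary is small; recall on real corpora depends on the user
  dictionary supplied.
* Cross-sentence relations are out of reach by construction
  (sentence-bound candidates); they are counted and reported as
  unreachable, not silently dropped.
* Rank normalization of test scores is computed within the scored batch,
  so single-candidate batches receive the neutral score 0.5.
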