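# cpimine

Chemical–protein interaction (CPI) extraction from entity-annotated
abstracts, for text-mining and drug-discovery work on ChemProt-style
corpora (BioCreative VI track 5 format).

Given abstracts with tagged chemical and gene/protein mentions, `cpimine`
builds **CPI pairs** — every chemical × protein co-occurring in one
sentence — and **CPI triplets** — a pair plus one interaction word from a
CPR-mapped dictionary — then classifies each pair into the chemical–protein
relation groups CPR:3 (up-regulator/activator), CPR:4
(down-regulator/inhibitor), CPR:5 (agonist), CPR:6 (antagonist), CPR:9
(substrate) or *other*, and scores predictions with micro-averaged
P/R/F1 over those five groups.

The classifier is a three-stage stacked-generalization model. With
candidate feature vector **x** and the evaluated-group set
E = {3,4,5,6,9}:

* **Stage I** fits three binary base models (random forest, extremely
  randomized trees, gradient-boosted trees) per track (pairs, triplets) to
  P(y ∈ E | x). Training scores are strictly out-of-fold over 10
  stratified folds, rank-normalized to [0,1], and appended as
  meta-features.
* **Stage II** fits six multiclass base models per track (the three above
  plus logistic regression, LDA, naive Bayes) to P(y = c | x, meta). Each
  model's six class scores and argmax are stored; among a pair's triplets
  the one with the highest best-evaluated-class score represents it.
* **Stage III** combines the original pair features with both tracks'
  stage-II outputs into four learners; final prediction is
  argmax_c mean of the four class scores, and *other* emits nothing.

Features combine semantic patterns on the masked token sequence (the focal
chemical becomes `CHEM`, the protein `PROT`, other entities `CPTk`:
positions, windows, negation/conjunction, brackets, adjacency) and
dependency-graph structure (shortest-dependency-path lengths, typed
dependencies one-hot, an 8-way {e1, iw, e2} topology class). Parsers plug
in through an adapter contract; fixture parses (JSON-lines / CoNLL-U) and a
deterministic rule parser ship with the package. See `docs/methods.md`.

## Worked example

Mask a sentence for its (INS37217, P2Y(2) receptor) candidate pair and
match interaction words:

```python
from cpimine import (DocumentRecord, EntityMention, split_sentences,
                     build_pairs, mask_entities, match_interaction_words,
                     load_seed_dictionary)

body = ("P2Y(2) receptor agonist INS37217 enhances functional recovery after "
        "detachment caused by subretinal injection in normal and rds mice.")
doc = DocumentRecord("14507899", "Title.", body)
# mentions carry offsets into doc.full_text (title + tab + body)
...
masked = mask_entities(sentence, mentions, pair)
print(masked.text)
for m in match_interaction_words(masked.tokens, load_seed_dictionary()):
    print(m.token_index, m.word, "-> CPR:%d" % m.entry.mapped_cpr)
```

prints

```
PROT agonist CHEM enhances functional recovery after detachment caused by subCPT10 injection in normal and rds mice.
1 agonist -> CPR:5
3 enhances -> CPR:3
8 caused -> CPR:9
```

The protein and focal chemical are masked to `PROT`/`CHEM`; the tagged
`retinal` span inside "subretinal" becomes `subCPT10` (CPT + term number).
The three dictionary hits spawn three triplets for this pair; at stage II
the best-scoring one (here the *agonist* reading) represents the pair, and
the pipeline emits the relation `14507899  CPR:5  Arg1:T16  Arg2:T15`.

## Command line

```sh
cpimine synth --out data/train --n-docs 100 --seed 0     # synthetic corpus
cpimine train --abstracts data/train/synth_abstracts.tsv \
              --entities data/train/synth_entities.tsv \
              --relations data/train/synth_relations.tsv \
              --out model.joblib --seed 0
cpimine predict --model model.joblib --abstracts ... --entities ... --out preds.tsv
cpimine evaluate --gold data/test/synth_relations.tsv --predictions preds.tsv
```

`evaluate` prints the 6×6 confusion matrix, per-class precision/recall/F1
and the micro scores. The synthetic generator plants a recoverable CPR
signal per sentence (trigger word + pattern), so it exercises every stage
of the pipeline without any external download; real ChemProt splits are
read by the same `read_corpus` loader.

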