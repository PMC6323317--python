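"""Synthetic ChemProt-style corpora with planted CPR structure.

The generator emits the same three-file TSV dialect as the real corpus:
abstracts, entity mentions with character offsets, and relation
annotations.  Each body sentence is drawn from a small versioned template
grammar; a class-c template embeds exactly one interaction word mapped to
CPR group c (CPR:10 templates embed none), so the planted label is
recoverable from the interaction word and sentence pattern.  All chemical x
protein pairs of an annotated sentence carry the sentence's relation, which
keeps the corpus self-consistent: with zero label noise a decision stump on
the interaction-word CPR group reaches accuracy 1.0 on candidate labels.

What this emulates: the corpus schema, entity offset bookkeeping (including
multi-word and parenthesized protein names), class-typical trigger words,
extra masked entities and no-interaction co-occurrences.  What it does not:
the lexical and syntactic diversity of PubMed abstracts, cross-sentence
relations, annotation disagreements and entity-boundary noise — scores on
this corpus bound pipeline correctness, not real-corpus accuracy.

Dependency parses for the fixture adapter come from the deterministic rule
parser applied to every masked candidate variant, serialized in the
JSON-lines fixture format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cpimine import io as cio
from cpimine.candidates import (
    InteractionWordEntry,
    build_candidates,
    load_seed_dictionary,
)
from cpimine.depgraph import FixtureParserAdapter, RuleParser

TEMPLATE_VERSION = 1

#: per-class sentence templates; slots {C} {P} focal pair, {C2}/{P2} an extra
#: co-annotated entity, all placeholders replaced by generated names
TEMPLATES: dict[int, list[str]] = {
    3: [
        "{C} activates {P} in cultured cells.",
        "Treatment with {C} stimulates {P} expression.",
        "{C} markedly enhances {P} activity.",
        "{C} induces {P} and {P2} in the liver.",
        "Low doses of {C} upregulates {P} signaling.",
        "{C} and {C2} potentiates {P} currents.",
    ],
    4: [
        "{C} inhibits {P} in a dose-dependent manner.",
        "{C} potently blocks {P} channels.",
        "Pretreatment with {C} suppresses {P} induction.",
        "{C} attenuates {P} phosphorylation in neurons.",
        "{C} reduces {P} levels after injury.",
        "{C} and {C2} downregulates {P} transcription.",
    ],
    5: [
        "{C} is a potent agonist of {P}.",
        "{C} acts as a selective agonist at {P}.",
        "The novel agonist {C} targets {P} directly.",
        "{C} remains a partial agonist of {P} and {P2}.",
        "As a full agonist of {P}, {C} improved the outcome.",
        "{C}, a selective agonist of {P}, was well tolerated.",
    ],
    6: [
        "{C} is a selective antagonist of {P}.",
        "{C} antagonizes {P} with high affinity.",
        "The antagonist {C} binds {P} tightly.",
        "{C} acts as a competitive antagonist at {P}.",
        "{C} and {C2} antagonizes {P} responses.",
        "{C}, a potent antagonist of {P}, reversed the effect.",
    ],
    9: [
        "{C} is a substrate of {P} in vivo.",
        "{C} was rapidly metabolized by {P}.",
        "{C} is hydrolyzed by {P} in the pathway.",
        "{C} was converted by {P} to an active product.",
        "Accumulation of {C} was caused by {P} deficiency.",
        "{P} produces {C} from dietary precursors.",
    ],
    10: [
        "{C} and {P} were measured in plasma samples.",
        "Levels of {C} did not correlate with {P} abundance.",
        "{C} was administered before {P} assays.",
        "The study compared {C} with {P} across groups.",
        "{C}, {P} and {P2} appeared unrelated in this cohort.",
        "Baseline {C} and {P} varied between patients.",
        # distractor templates: an interaction word appears but is negated,
        # so the triplet track sees no-interaction candidates as real corpora do
        "{C} did not inhibit {P} in any assay.",
        "{C} failed to activate {P} in vivo.",
        "{C} reduced toxicity without affecting {P} function.",
    ],
}

_CHEM_PRE = ["belu", "caro", "dexi", "flo", "gani", "halo", "ibu", "juva",
             "keto", "lori", "meva", "nor", "oxa", "pani", "quar", "rilu"]
_CHEM_STEM = ["statin", "pril", "mab", "zole", "vir", "olol", "micin",
              "parin", "fene", "dipine"]
_PROT_FAM = ["CYP", "MAPK", "AKT", "STAT", "TLR", "GPR", "ABC", "SLC",
             "PDE", "HDAC"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    ``class_prior`` is the per-sentence probability of each planted CPR
    group (must sum to 1); ``label_noise`` flips an annotated pair's class
    uniformly among the other five groups; ``p_extra_entity`` is the chance
    a sentence template with an extra-entity slot is eligible for selection.
    """

    n_documents: int = 100
    sentences_per_document: int = 3
    class_prior: dict[int, float] = field(
        default_factory=lambda: {3: 0.16, 4: 0.20, 5: 0.10, 6: 0.10, 9: 0.14, 10: 0.30}
    )
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_documents < 1 or self.sentences_per_document < 1:
            raise ValueError("corpus must contain at least one document and sentence")
        if set(self.class_prior) != {3, 4, 5, 6, 9, 10}:
            raise ValueError("class prior must cover exactly {3,4,5,6,9,10}")
        if abs(sum(self.class_prior.values()) - 1.0) > 1e-9:
            raise ValueError("class prior must sum to 1")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")


def _chem_name(rng: np.random.Generator) -> str:
    name = rng.choice(_CHEM_PRE) + rng.choice(_CHEM_STEM)
    if rng.random() < 0.3:
        name += f"-{rng.integers(1, 99)}"
    return name


def _prot_name(rng: np.random.Generator) -> str:
    fam = rng.choice(_PROT_FAM)
    num = int(rng.integers(1, 30))
    u = rng.random()
    if u < 0.15:
        return f"P2Y({num}) receptor"
    if u < 0.35:
        return f"{fam}{num} receptor"
    return f"{fam}{num}"


def generate_corpus(cfg: SynthConfig) -> tuple[cio.Corpus, pd.DataFrame]:
    """Generate a corpus and its gold candidate table.

    The table has one row per annotated-sentence chemical x protein pair:
    pmid, sentence template class (planted), final label after noise, and
    the argument term ids.  The relation file lists only non-CPR:10 pairs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.class_prior)
    probs = np.array([cfg.class_prior[c] for c in classes])

    documents: dict[str, cio.DocumentRecord] = {}
    mentions: dict[str, list[cio.EntityMention]] = {}
    relations: list[cio.RelationRecord] = []
    gold_rows: list[dict] = []

    for d in range(cfg.n_documents):
        pmid = str(10_000_000 + d)
        title = f"Profiling chemical modulation of protein targets in cohort {d}."
        body_parts: list[str] = []
        ments: list[cio.EntityMention] = []
        term_counter = 0
        body_pos = len(title) + 1  # full_text = title + "\t" + body

        for _s in range(cfg.sentences_per_document):
            planted = int(rng.choice(classes, p=probs))
            template = TEMPLATES[planted][int(rng.integers(len(TEMPLATES[planted])))]
            fills: dict[str, tuple[str, str]] = {}  # slot -> (surface, etype)
            chems, prots = [], []
            for slot in ("C", "C2", "P", "P2"):
                if "{" + slot + "}" not in template:
                    continue
                if slot.startswith("C"):
                    surface = _chem_name(rng)
                    while any(surface == s for s, _ in fills.values()):
                        surface = _chem_name(rng)
                    fills[slot] = (surface, cio.CHEMICAL)
                else:
                    surface = _prot_name(rng)
                    while any(surface == s for s, _ in fills.values()):
                        surface = _prot_name(rng)
                    gtype = cio.GENE_Y if rng.random() < 0.7 else cio.GENE_N
                    fills[slot] = (surface, gtype)

            # materialize the sentence and record absolute offsets
            sent_text = template
            placeholders = sorted(
                ((sent_text.index("{" + s + "}"), s) for s in fills),
            )
            out, cursor = [], 0
            local_terms: dict[str, cio.EntityMention] = {}
            for _, slot in placeholders:
                ph = "{" + slot + "}"
                at = sent_text.index(ph)
                out.append(sent_text[cursor:at])
                surface, etype = fills[slot]
                if sum(len(x) for x in out) == 0 and surface[0].islower():
                    # sentence-initial entities are capitalized, as in abstracts
                    surface = surface[0].upper() + surface[1:]
                start = body_pos + sum(len(x) for x in out)
                term_counter += 1
                m = cio.EntityMention(pmid, f"T{term_counter}", etype,
                                      start, start + len(surface), surface)
                ments.append(m)
                local_terms[slot] = m
                out.append(surface)
                cursor = at + len(ph)
            out.append(sent_text[cursor:])
            realized = "".join(out)
            body_parts.append(realized)
            body_pos += len(realized) + 1  # sentences joined by one space

            chems = [local_terms[s] for s in ("C", "C2") if s in local_terms]
            prots = [local_terms[s] for s in ("P", "P2") if s in local_terms]
            for cm in chems:
                for pm in prots:
                    label = planted
                    if cfg.label_noise and rng.random() < cfg.label_noise:
                        others = [c for c in classes if c != planted]
                        label = int(others[int(rng.integers(len(others)))])
                    gold_rows.append(
                        {"pmid": pmid, "planted": planted, "label": label,
                         "arg1": cm.term_id, "arg2": pm.term_id}
                    )
                    if label != 10:
                        relations.append(
                            cio.RelationRecord(pmid, label, cm.term_id, pm.term_id,
                                               evaluated=label in cio.EVALUATED_CPR,
                                               label=f"CPR:{label}")
                        )

        documents[pmid] = cio.DocumentRecord(pmid, title, " ".join(body_parts))
        mentions[pmid] = ments

    corpus = cio.Corpus(documents, mentions, relations)
    gold = pd.DataFrame(gold_rows, columns=["pmid", "planted", "label", "arg1", "arg2"])
    return corpus, gold


def generate_parses(
    corpus: cio.Corpus,
    dictionary: list[InteractionWordEntry] | None = None,
    path: str | Path | None = None,
) -> FixtureParserAdapter:
    """Deterministic fixture parses covering every masked candidate variant.

    Runs the rule parser over the masked token sequence of each candidate
    pair and stores the results keyed by token sequence; optionally
    serializes them to the JSON-lines fixture format at *path*.
    """
    dictionary = dictionary if dictionary is not None else load_seed_dictionary()
    parser = RuleParser(verb_lexicon=[e.word for e in dictionary])
    adapter = FixtureParserAdapter()
    candset = build_candidates(corpus, dictionary)
    for idx in range(len(candset.pairs)):
        masked = candset.masked_for(idx)
        adapter.add(parser(masked.tokens))
    if path is not None:
        adapter.write_jsonl(path)
    return adapter
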