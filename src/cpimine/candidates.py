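"""Candidate construction: CPI pairs, CPI triplets, labels and entity masking.

A CPI pair is one chemical mention and one protein mention co-occurring in a
sentence; a CPI triplet adds one interaction word (a dictionary term mapped
to a CPR group) from the same sentence.  Pairs inherit their CPR label from
the gold relation annotations; an unannotated pair is CPR:10 (no
interaction).  Every triplet of a pair shares the pair's label.

Before dependency parsing, the focal chemical is replaced by the single
token ``CHEM``, the focal protein by ``PROT``, and every other tagged entity
by ``CPT<k>`` where *k* is the numeric part of the entity's term identifier
(so term T10 becomes ``CPT10``).  Multi-word entities collapse to one token;
an entity strictly inside a word is replaced in place, preserving its prefix
and suffix (``subretinal`` with the ``retinal`` span tagged becomes
``subCPT10``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from cpimine.io import (
    Corpus,
    EntityMention,
    RelationRecord,
    Sentence,
    Token,
    tokenize,
)

logger = logging.getLogger(__name__)

NO_INTERACTION = 10
EVALUATED_CPR = frozenset({3, 4, 5, 6, 9})

#: default suffix-stemming table for interaction-word matching (off by default)
SUFFIXES = ("ing", "ed", "es", "s")


@dataclass(frozen=True)
class InteractionWordEntry:
    word: str
    mapped_cpr: int


@dataclass(frozen=True)
class InteractionMatch:
    token_index: int
    word: str
    entry: InteractionWordEntry


@dataclass
class CandidatePair:
    sentence: Sentence
    chem: EntityMention
    prot: EntityMention
    label: int = NO_INTERACTION

    @property
    def pmid(self) -> str:
        return self.sentence.pmid

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.pmid, self.chem.term_id, self.prot.term_id)


@dataclass
class CandidateTriplet:
    pair: CandidatePair
    match: InteractionMatch

    @property
    def label(self) -> int:
        return self.pair.label


@dataclass
class MaskedSentence:
    """A sentence with entities masked for parsing, plus the reverse map."""

    tokens: list[str]
    chem_index: int
    prot_index: int
    cpt_indices: dict[int, EntityMention]  # token index -> masked mention
    text: str
    sentence: Sentence
    replacements: list[tuple[int, int, str]] = field(default_factory=list)
    # (start, end, original surface) in masked-text coordinates, sorted

    def unmask_text(self) -> str:
        """Reverse all replacements, recovering the original sentence text."""
        out, cursor = [], 0
        for start, end, surface in self.replacements:
            out.append(self.text[cursor:start])
            out.append(surface)
            cursor = end
        out.append(self.text[cursor:])
        return "".join(out)


# ---------------------------------------------------------------------------
# Dictionary
# ---------------------------------------------------------------------------

def load_dictionary(path: str | Path) -> list[InteractionWordEntry]:
    """Load a two-column TSV (word, CPR id) interaction-word dictionary.

    Words are lowercased and deduplicated; the same word mapped to two
    different CPR groups is an error.
    """
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{ln}: expected 'word<TAB>cpr'")
            word, cpr_s = cols[0].strip().lower(), cols[1].strip()
            cpr = int(cpr_s.removeprefix("CPR:"))
            if not 1 <= cpr <= 10:
                raise ValueError(f"{path}:{ln}: CPR id {cpr} outside 1-10")
            if not word:
                raise ValueError(f"{path}:{ln}: empty word")
            if word in entries and entries[word] != cpr:
                raise ValueError(
                    f"{path}:{ln}: word {word!r} mapped to both CPR:{entries[word]} and CPR:{cpr}"
                )
            entries[word] = cpr
    return [InteractionWordEntry(w, c) for w, c in entries.items()]


def load_seed_dictionary() -> list[InteractionWordEntry]:
    """Load the small bundled dictionary of common interaction words."""
    ref = resources.files("cpimine").joinpath("data/interaction_words.tsv")
    with resources.as_file(ref) as path:
        return load_dictionary(path)


def match_interaction_words(
    tokens: Sequence[str] | Sequence[Token],
    dictionary: Sequence[InteractionWordEntry],
    *,
    stem: bool = False,
) -> list[InteractionMatch]:
    """Find dictionary words among *tokens*, one match per occurrence.

    Matching is case-insensitive exact token match; with ``stem=True`` a
    token also matches after stripping one of the suffixes s/es/ed/ing.
    Matches are ordered by token index.
    """
    index = {e.word: e for e in dictionary}
    matches: list[InteractionMatch] = []
    for i, tok in enumerate(tokens):
        text = tok.text if isinstance(tok, Token) else tok
        low = text.lower()
        entry = index.get(low)
        if entry is None and stem:
            for suf in SUFFIXES:
                if low.endswith(suf) and low[: -len(suf)] in index:
                    entry = index[low[: -len(suf)]]
                    break
        if entry is not None:
            matches.append(InteractionMatch(i, text, entry))
    return matches


# ---------------------------------------------------------------------------
# Pairs, triplets, labels
# ---------------------------------------------------------------------------

def build_pairs(sentence: Sentence, mentions: Sequence[EntityMention]) -> list[CandidatePair]:
    """Cartesian product of chemical x protein mentions within *sentence*.

    Ordered by (chemical offset, protein offset) for determinism.
    """
    in_sent = [m for m in mentions if sentence.contains(m)]
    chems = sorted((m for m in in_sent if m.is_chemical), key=lambda m: (m.start, m.end))
    prots = sorted((m for m in in_sent if m.is_protein), key=lambda m: (m.start, m.end))
    return [CandidatePair(sentence, c, p) for c in chems for p in prots]


def build_triplets(pair: CandidatePair, matches: Sequence[InteractionMatch]) -> list[CandidateTriplet]:
    """One triplet per interaction-word match; all inherit the pair's label."""
    return [CandidateTriplet(pair, m) for m in matches]


def assign_labels(
    pairs: Iterable[CandidatePair], relations: Sequence[RelationRecord]
) -> dict[str, int]:
    """Label each pair with its annotated CPR group, or CPR:10 if unannotated.

    Conflicting annotations for the same (pmid, chem, prot) keep an evaluated
    group over a non-evaluated one, then the lowest CPR id; conflicts are
    logged.  Returns a coverage report: counts of annotations that labeled a
    pair versus those whose arguments never co-occur in one sentence
    (unreachable by a sentence-bound extractor).
    """
    by_key: dict[tuple[str, str, str], list[int]] = {}
    for r in relations:
        by_key.setdefault((r.pmid, r.arg1_term, r.arg2_term), []).append(r.cpr)

    def resolve(cprs: list[int]) -> int:
        ev = sorted(c for c in cprs if c in EVALUATED_CPR)
        return ev[0] if ev else min(cprs)

    used_keys = set()
    for pair in pairs:
        cprs = by_key.get(pair.key)
        if cprs is None:
            pair.label = NO_INTERACTION
            continue
        if len(set(cprs)) > 1:
            logger.warning("conflicting annotations for %s: %s", pair.key, sorted(set(cprs)))
        pair.label = resolve(cprs)
        used_keys.add(pair.key)

    unreachable = sum(1 for k in by_key if k not in used_keys)
    return {
        "annotations": len(by_key),
        "labeled_pairs": len(used_keys),
        "unreachable": unreachable,
    }


# ---------------------------------------------------------------------------
# Entity masking
# ---------------------------------------------------------------------------

def mask_entities(
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    pair: CandidatePair,
) -> MaskedSentence:
    """Replace the focal pair with CHEM/PROT and other entities with CPT<k>.

    Replacement is span-based on the sentence text, so multi-word entities
    become a single token and an entity embedded inside a word keeps its
    surrounding characters (Table-style ``subCPT10``).  *k* is the numeric
    part of the masked entity's term id.
    """
    if _overlaps(pair.chem, pair.prot):
        raise ValueError(
            f"focal mentions overlap: {pair.chem.term_id}/{pair.prot.term_id} in pmid {pair.pmid}"
        )
    focal_ids = {pair.chem.term_id, pair.prot.term_id}
    repls: list[tuple[int, int, str, str, EntityMention]] = [
        (pair.chem.start, pair.chem.end, "CHEM", "chem", pair.chem),
        (pair.prot.start, pair.prot.end, "PROT", "prot", pair.prot),
    ]
    others = sorted(
        (m for m in mentions if sentence.contains(m) and m.term_id not in focal_ids),
        key=lambda m: (m.start, -(m.end - m.start)),
    )
    taken: list[tuple[int, int]] = [(pair.chem.start, pair.chem.end), (pair.prot.start, pair.prot.end)]
    for m in others:
        if any(s < m.end and m.start < e for s, e in taken):
            logger.warning(
                "pmid %s: skipping mention %s overlapping an already-masked span",
                m.pmid, m.term_id,
            )
            continue
        repls.append((m.start, m.end, f"CPT{m.term_number}", "cpt", m))
        taken.append((m.start, m.end))

    repls.sort(key=lambda r: r[0])
    pieces: list[str] = []
    cursor = sentence.start
    new_spans: list[tuple[int, int, str, EntityMention]] = []  # masked-local
    out_len = 0
    replacements: list[tuple[int, int, str]] = []
    text = sentence.text
    for start, end, repl, role, mention in repls:
        pieces.append(text[cursor - sentence.start : start - sentence.start])
        out_len += len(pieces[-1])
        new_spans.append((out_len, out_len + len(repl), role, mention))
        replacements.append((out_len, out_len + len(repl), text[start - sentence.start : end - sentence.start]))
        pieces.append(repl)
        out_len += len(repl)
        cursor = end
    pieces.append(text[cursor - sentence.start :])
    masked_text = "".join(pieces)

    tokens = tokenize(masked_text)
    chem_index = prot_index = -1
    cpt_indices: dict[int, EntityMention] = {}
    for mstart, mend, role, mention in new_spans:
        tok_idx = next(
            (i for i, t in enumerate(tokens) if t.start <= mstart and mend <= t.end), None
        )
        if tok_idx is None:  # replacement split by tokenization; should not happen
            raise RuntimeError(f"masked span [{mstart},{mend}) not covered by one token")
        if role == "chem":
            chem_index = tok_idx
        elif role == "prot":
            prot_index = tok_idx
        else:
            cpt_indices[tok_idx] = mention
    return MaskedSentence(
        tokens=[t.text for t in tokens],
        chem_index=chem_index,
        prot_index=prot_index,
        cpt_indices=cpt_indices,
        text=masked_text,
        sentence=sentence,
        replacements=replacements,
    )


def _overlaps(a: EntityMention, b: EntityMention) -> bool:
    return a.start < b.end and b.start < a.end


def unmask_tokens(masked: MaskedSentence) -> list[str]:
    """Token sequence of the original (unmasked) sentence text."""
    return [t.text for t in tokenize(masked.unmask_text())]


# ---------------------------------------------------------------------------
# Corpus-level candidate construction
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """All candidates of a corpus, with masked sentences and a coverage report."""

    pairs: list[CandidatePair]
    triplets: list[CandidateTriplet]
    triplet_pair_index: list[int]  # row index of each triplet's pair
    masked: dict[int, MaskedSentence]  # pair row index -> MaskedSentence
    coverage: dict[str, int]
    repairs: int

    def masked_for(self, pair_idx: int) -> MaskedSentence:
        return self.masked[pair_idx]


def build_candidates(
    corpus: Corpus,
    dictionary: Sequence[InteractionWordEntry],
    *,
    stem: bool = False,
) -> CandidateSet:
    """Construct all labeled pairs and triplets of a corpus.

    Interaction words are matched on the masked token sequence, whose
    non-entity token positions are identical for every pair of a sentence
    (each entity collapses to exactly one token regardless of role).
    """
    from cpimine.io import sentences_for_document

    pairs: list[CandidatePair] = []
    triplets: list[CandidateTriplet] = []
    triplet_pair_index: list[int] = []
    masked_by_idx: dict[int, MaskedSentence] = {}
    total_repairs = 0
    for pmid in corpus.documents:
        doc = corpus.documents[pmid]
        mentions = corpus.mentions_for(pmid)
        sentences, repairs = sentences_for_document(doc, mentions)
        total_repairs += repairs
        for sent in sentences:
            for pair in build_pairs(sent, mentions):
                idx = len(pairs)
                pairs.append(pair)
                masked = mask_entities(sent, mentions, pair)
                masked_by_idx[idx] = masked
                for m in match_interaction_words(masked.tokens, dictionary, stem=stem):
                    triplets.append(CandidateTriplet(pair, m))
                    triplet_pair_index.append(idx)
    coverage = assign_labels(pairs, corpus.relations)
    return CandidateSet(pairs, triplets, triplet_pair_index, masked_by_idx,
                        coverage, total_repairs)
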