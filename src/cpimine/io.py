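"""ChemProt TSV corpus reader/writer, sentence segmentation and tokenization.

The ChemProt dialect distributes each split as three TSV files:

* abstracts: ``pmid<TAB>title<TAB>body``
* entities:  ``pmid<TAB>Tn<TAB>type<TAB>start<TAB>end<TAB>text`` with
  type one of CHEMICAL, GENE-Y, GENE-N
* relations: ``pmid<TAB>CPR:k<TAB>eval-flag<TAB>label<TAB>Arg1:Tn<TAB>Arg2:Tm``

Entity offsets index into a per-document ``full_text`` built from title and
body.  The official corpus joins them with a tab; the separator is
configurable because other exports use ``"\\n"`` or a single space.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CHEMICAL = "CHEMICAL"
GENE_Y = "GENE-Y"
GENE_N = "GENE-N"
ENTITY_TYPES = frozenset({CHEMICAL, GENE_Y, GENE_N})
PROTEIN_TYPES = frozenset({GENE_Y, GENE_N})

EVALUATED_CPR = (3, 4, 5, 6, 9)


class CorpusFormatError(ValueError):
    """A TSV row violates the ChemProt dialect."""


class CorpusIntegrityError(ValueError):
    """Entity offsets/surfaces disagree with the document text."""


@dataclass(frozen=True)
class DocumentRecord:
    pmid: str
    title: str
    body: str
    separator: str = "\t"

    @property
    def full_text(self) -> str:
        """Offset reference frame for entity mentions: title, separator, body."""
        return self.title + self.separator + self.body


@dataclass(frozen=True)
class EntityMention:
    pmid: str
    term_id: str
    etype: str
    start: int
    end: int
    surface: str

    @property
    def term_number(self) -> int:
        return int(self.term_id[1:])

    @property
    def is_chemical(self) -> bool:
        return self.etype == CHEMICAL

    @property
    def is_protein(self) -> bool:
        return self.etype in PROTEIN_TYPES


@dataclass(frozen=True)
class RelationRecord:
    pmid: str
    cpr: int
    arg1_term: str  # chemical
    arg2_term: str  # gene/protein
    evaluated: bool = True
    label: str = ""


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


@dataclass
class Sentence:
    pmid: str
    index: int
    start: int
    end: int
    text: str
    tokens: list[Token] = field(default_factory=list)

    def contains(self, mention: EntityMention) -> bool:
        return self.start <= mention.start and mention.end <= self.end


@dataclass(frozen=True, order=True)
class PredictionRecord:
    pmid: str
    cpr: int
    arg1_term: str
    arg2_term: str


@dataclass
class Corpus:
    documents: dict[str, DocumentRecord]
    mentions: dict[str, list[EntityMention]]
    relations: list[RelationRecord]

    def mentions_for(self, pmid: str) -> list[EntityMention]:
        return self.mentions.get(pmid, [])


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_PUNCT = set(".,;:!?\"'`%")
_OPENERS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Split *text* into tokens with character spans.

    Whitespace separates chunks; leading/trailing punctuation is peeled into
    separate tokens.  Brackets balanced inside a chunk are kept attached, so
    ``P2Y(2)`` stays one token while ``(SGT)`` becomes three.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, cstart = m.group(), m.start()
        # peel leading punctuation (enclosing brackets always come off)
        while chunk and (chunk[0] in _PUNCT or chunk[0] in _OPENERS):
            tokens.append(Token(chunk[0], offset + cstart, offset + cstart + 1))
            chunk = chunk[1:]
            cstart += 1
        # peel trailing punctuation
        tail: list[Token] = []
        while chunk:
            c = chunk[-1]
            if c in _PUNCT:
                pass
            elif c in _CLOSERS and chunk[:-1].count(_CLOSERS[c]) >= chunk.count(c):
                break  # its opener is inside: keep attached
            elif c in _CLOSERS:
                pass
            else:
                break
            end = cstart + len(chunk)
            tail.append(Token(c, offset + end - 1, offset + end))
            chunk = chunk[:-1]
        if chunk:
            tokens.append(Token(chunk, offset + cstart, offset + cstart + len(chunk)))
        tokens.extend(reversed(tail))
    return tokens


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

#: tokens that commonly end in a period without terminating a sentence
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "et al", "etc", "vs", "cf", "ca", "approx", "fig",
        "figs", "ref", "refs", "no", "nos", "dr", "sp", "spp", "resp",
        "min", "max", "mol", "wt",
    }
)

_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def split_sentences(doc: DocumentRecord, abbreviations: frozenset[str] = ABBREVIATIONS) -> list[Sentence]:
    """Rule-based sentence segmentation of ``doc.full_text``.

    A terminator (``.!?``) followed by whitespace and an uppercase letter or
    digit ends a sentence, unless the word before it is a known abbreviation
    or a single capital initial.  The title/body separator always ends the
    title sentence.  Deterministic; whole text as one sentence is legal.
    """
    text = doc.full_text
    breaks: set[int] = set()
    sep_at = len(doc.title)
    if doc.body:
        breaks.add(sep_at + len(doc.separator))
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        # lookahead: next non-space char must start a sentence-like unit
        rest = text[end:].lstrip()
        if not rest or not (rest[0].isupper() or rest[0].isdigit()):
            continue
        prev = text[: m.start()].rsplit(None, 1)
        last_word = prev[-1] if prev else ""
        last_word = last_word.lstrip("([{\"'")
        if last_word.lower().rstrip(".") in abbreviations:
            continue
        if re.fullmatch(r"[A-Z]", last_word):
            continue  # single-letter initial, e.g. "J. Smith"
        nxt = end
        while nxt < len(text) and text[nxt].isspace():
            nxt += 1
        breaks.add(nxt)
    bounds = sorted(b for b in breaks if 0 < b < len(text))
    sentences: list[Sentence] = []
    prev_b = 0
    for idx, b in enumerate(bounds + [len(text)]):
        raw = text[prev_b:b]
        lstrip = len(raw) - len(raw.lstrip())
        rstrip = len(raw.rstrip())
        if rstrip <= lstrip:
            prev_b = b
            continue
        s, e = prev_b + lstrip, prev_b + rstrip
        sentences.append(
            Sentence(doc.pmid, len(sentences), s, e, text[s:e], tokenize(text[s:e], offset=s))
        )
        prev_b = b
    return sentences


def sentences_for_document(
    doc: DocumentRecord, mentions: Sequence[EntityMention]
) -> tuple[list[Sentence], int]:
    """Segment *doc* and repair boundaries so no mention straddles two sentences.

    When a mention crosses a sentence boundary the earlier sentence is
    extended to cover it (entities are never dropped).  Returns the sentences
    and the number of repairs performed.
    """
    sentences = split_sentences(doc)
    repairs = 0
    i = 0
    while i < len(sentences) - 1:
        sent = sentences[i]
        crossing = [m for m in mentions if m.start < sent.end < m.end]
        if not crossing:
            i += 1
            continue
        repairs += 1
        nxt = sentences.pop(i + 1)
        merged_end = nxt.end
        text = doc.full_text[sent.start : merged_end]
        sentences[i] = Sentence(
            doc.pmid, sent.index, sent.start, merged_end, text,
            tokenize(text, offset=sent.start),
        )
        logger.warning(
            "pmid %s: extended sentence %d to cover mention crossing its boundary",
            doc.pmid, sent.index,
        )
    for j, s in enumerate(sentences):
        s.index = j
    return sentences, repairs


# ---------------------------------------------------------------------------
# Corpus reading / writing
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            yield ln, line.split("\t")


def read_corpus(
    abstract_path: str | Path,
    entity_path: str | Path,
    relation_path: str | Path | None = None,
    *,
    separator: str = "\t",
    one_based: bool = False,
) -> Corpus:
    """Read one ChemProt-style split into a validated :class:`Corpus`.

    Every mention's surface string is checked against the ``full_text``
    slice; relation arguments must resolve to mentions of the same document.
    ``relation_path`` may be omitted (prediction mode).  ``one_based``
    converts inclusive 1-based offsets to the 0-based half-open frame used
    throughout.
    """
    documents: dict[str, DocumentRecord] = {}
    for ln, cols in _read_tsv(abstract_path):
        if len(cols) < 2:
            raise CorpusFormatError(f"{abstract_path}:{ln}: expected pmid/title/body")
        pmid, title = cols[0], cols[1]
        body = cols[2] if len(cols) > 2 else ""
        if not pmid:
            raise CorpusFormatError(f"{abstract_path}:{ln}: empty pmid")
        documents[pmid] = DocumentRecord(pmid, title, body, separator=separator)

    mentions: dict[str, list[EntityMention]] = {p: [] for p in documents}
    term_index: dict[tuple[str, str], EntityMention] = {}
    for ln, cols in _read_tsv(entity_path):
        if len(cols) != 6:
            raise CorpusFormatError(f"{entity_path}:{ln}: expected 6 columns, got {len(cols)}")
        pmid, term, etype, start_s, end_s, surface = cols
        if etype not in ENTITY_TYPES:
            raise CorpusFormatError(f"{entity_path}:{ln}: unknown entity type {etype!r}")
        if pmid not in documents:
            raise CorpusFormatError(f"{entity_path}:{ln}: unknown pmid {pmid}")
        start, end = int(start_s), int(end_s)
        if one_based:
            start -= 1
        full = documents[pmid].full_text
        if not (0 <= start < end <= len(full)):
            raise CorpusIntegrityError(
                f"pmid {pmid} term {term}: offsets [{start},{end}) outside document"
            )
        if full[start:end] != surface:
            raise CorpusIntegrityError(
                f"pmid {pmid} term {term}: surface {surface!r} != text slice "
                f"{full[start:end]!r}"
            )
        m = EntityMention(pmid, term, etype, start, end, surface)
        mentions[pmid].append(m)
        term_index[(pmid, term)] = m

    relations: list[RelationRecord] = []
    if relation_path is not None:
        for ln, cols in _read_tsv(relation_path):
            if len(cols) not in (5, 6):
                raise CorpusFormatError(f"{relation_path}:{ln}: expected 5-6 columns")
            if len(cols) == 6:
                pmid, cpr_s, flag, label, arg1, arg2 = cols
            else:  # some exports drop the eval flag
                pmid, cpr_s, label, arg1, arg2 = cols
                flag = "Y"
            if not cpr_s.startswith("CPR:"):
                raise CorpusFormatError(f"{relation_path}:{ln}: bad CPR field {cpr_s!r}")
            cpr = int(cpr_s[4:])
            if not 1 <= cpr <= 10:
                raise CorpusFormatError(f"{relation_path}:{ln}: CPR {cpr} outside 1-10")
            t1, t2 = arg1.removeprefix("Arg1:"), arg2.removeprefix("Arg2:")
            for t in (t1, t2):
                if (pmid, t) not in term_index:
                    raise CorpusFormatError(
                        f"{relation_path}:{ln}: dangling relation argument {t} (pmid {pmid})"
                    )
            relations.append(
                RelationRecord(pmid, cpr, t1, t2, evaluated=flag.strip().upper().startswith("Y"),
                               label=label)
            )
    return Corpus(documents, mentions, relations)


def write_corpus(corpus: Corpus, directory: str | Path, prefix: str = "corpus") -> dict[str, Path]:
    """Write a corpus back to the three-file TSV dialect. Returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abstracts": directory / f"{prefix}_abstracts.tsv",
        "entities": directory / f"{prefix}_entities.tsv",
        "relations": directory / f"{prefix}_relations.tsv",
    }
    with open(paths["abstracts"], "w", encoding="utf-8") as fh:
        for doc in corpus.documents.values():
            fh.write(f"{doc.pmid}\t{doc.title}\t{doc.body}\n")
    with open(paths["entities"], "w", encoding="utf-8") as fh:
        for pmid in corpus.documents:
            for m in corpus.mentions_for(pmid):
                fh.write(f"{m.pmid}\t{m.term_id}\t{m.etype}\t{m.start}\t{m.end}\t{m.surface}\n")
    with open(paths["relations"], "w", encoding="utf-8") as fh:
        for r in corpus.relations:
            flag = "Y" if r.evaluated else "N"
            label = r.label or f"CPR:{r.cpr}"
            fh.write(f"{r.pmid}\tCPR:{r.cpr}\t{flag}\t{label}\tArg1:{r.arg1_term}\tArg2:{r.arg2_term}\n")
    return paths


def write_predictions(preds: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write challenge-format predictions, one TSV line per relation.

    Lines are ``pmid<TAB>CPR:k<TAB>Arg1:Tn<TAB>Arg2:Tm`` sorted by
    (pmid, arg1, arg2, cpr).  Only the evaluated groups may be emitted and
    records must be unique.
    """
    seen = set()
    for p in preds:
        if p.cpr not in EVALUATED_CPR:
            raise ValueError(f"prediction {p}: CPR:{p.cpr} is not an evaluated group")
        key = (p.pmid, p.cpr, p.arg1_term, p.arg2_term)
        if key in seen:
            raise ValueError(f"duplicate prediction record {p}")
        seen.add(key)

    def sort_key(p: PredictionRecord):
        return (p.pmid, int(p.arg1_term[1:]), int(p.arg2_term[1:]), p.cpr)

    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(preds, key=sort_key):
            fh.write(f"{p.pmid}\tCPR:{p.cpr}\tArg1:{p.arg1_term}\tArg2:{p.arg2_term}\n")


def read_relations(path: str | Path) -> list[RelationRecord]:
    """Read a relations TSV standalone (no corpus validation); for scoring."""
    relations = []
    for ln, cols in _read_tsv(path):
        if len(cols) not in (5, 6) or not cols[1].startswith("CPR:"):
            raise CorpusFormatError(f"{path}:{ln}: malformed relation line")
        if len(cols) == 6:
            pmid, cpr_s, flag, label, arg1, arg2 = cols
        else:
            pmid, cpr_s, label, arg1, arg2 = cols
            flag = "Y"
        relations.append(
            RelationRecord(
                pmid, int(cpr_s[4:]),
                arg1.removeprefix("Arg1:"), arg2.removeprefix("Arg2:"),
                evaluated=flag.strip().upper().startswith("Y"), label=label,
            )
        )
    return relations


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    preds = []
    for ln, cols in _read_tsv(path):
        if len(cols) != 4 or not cols[1].startswith("CPR:"):
            raise CorpusFormatError(f"{path}:{ln}: malformed prediction line")
        preds.append(
            PredictionRecord(
                cols[0], int(cols[1][4:]),
                cols[2].removeprefix("Arg1:"), cols[3].removeprefix("Arg2:"),
            )
        )
    return preds
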