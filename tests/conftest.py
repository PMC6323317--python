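"""Shared fixtures: a hand-built masking example, synthetic corpora and a
fast-config trained pipeline reused across integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from cpimine.candidates import build_pairs, load_seed_dictionary
from cpimine.io import DocumentRecord, EntityMention, split_sentences
from cpimine.pipeline import CPIPipeline
from cpimine.stacker import StackerConfig
from cpimine.synthetic import SynthConfig, generate_corpus

AGONIST_BODY = (
    "P2Y(2) receptor agonist INS37217 enhances functional recovery after "
    "detachment caused by subretinal injection in normal and rds mice."
)


@pytest.fixture(scope="session")
def agonist_doc():
    """An abstract whose body is the classic agonist sentence, with the
    protein (T15), the focal chemical (T16) and a chemical span embedded
    inside the word 'subretinal' (T10)."""
    doc = DocumentRecord("14507899", "Title.", AGONIST_BODY)
    base = len("Title.") + 1

    def at(sub: str, length: int | None = None, shift: int = 0):
        start = base + AGONIST_BODY.index(sub) + shift
        return start, start + (length if length else len(sub))

    s, e = at("P2Y(2) receptor")
    prot = EntityMention("14507899", "T15", "GENE-Y", s, e, "P2Y(2) receptor")
    s, e = at("INS37217")
    chem = EntityMention("14507899", "T16", "CHEMICAL", s, e, "INS37217")
    s, e = at("subretinal", length=7, shift=3)
    sub = EntityMention("14507899", "T10", "CHEMICAL", s, e, "retinal")
    return doc, [prot, chem, sub]


@pytest.fixture(scope="session")
def agonist_pair(agonist_doc):
    doc, mentions = agonist_doc
    sent = split_sentences(doc)[1]
    pairs = build_pairs(sent, mentions)
    pair = next(p for p in pairs if p.chem.term_id == "T16")
    return sent, mentions, pair


@pytest.fixture(scope="session")
def seed_dictionary():
    return load_seed_dictionary()


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(SynthConfig(n_documents=25, seed=5))


FAST_STACKER = dict(n_estimators=60, xgb_estimators=40)


def fast_pipeline(seed: int = 7) -> CPIPipeline:
    return CPIPipeline(stacker_config=StackerConfig(seed=seed, **FAST_STACKER))


@pytest.fixture(scope="session")
def trained_pipeline():
    """One trained pipeline + held-out corpus shared by integration tests."""
    train_c, _ = generate_corpus(SynthConfig(n_documents=80, seed=11))
    test_c, test_gold = generate_corpus(SynthConfig(n_documents=40, seed=1011))
    pipe = fast_pipeline(seed=7).train(train_c)
    return pipe, train_c, test_c, test_gold


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
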