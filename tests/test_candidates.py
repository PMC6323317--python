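"""Candidate construction: dictionary, matching, pairing, labels, masking."""

import pytest

from cpimine.candidates import (
    CandidatePair,
    assign_labels,
    build_candidates,
    build_pairs,
    build_triplets,
    load_dictionary,
    mask_entities,
    match_interaction_words,
    unmask_tokens,
)
from cpimine.io import DocumentRecord, EntityMention, RelationRecord, split_sentences
from cpimine.synthetic import SynthConfig, generate_corpus


class TestDictionary:
    def test_load_and_case_fold(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("agonist\t5\nAgonist\t5\nenhances\t3\n")
        entries = load_dictionary(p)
        assert {(e.word, e.mapped_cpr) for e in entries} == {("agonist", 5), ("enhances", 3)}

    def test_empty_file_gives_empty_dictionary(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("")
        assert load_dictionary(p) == []

    def test_conflicting_mapping_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("agonist\t5\nagonist\t6\n")
        with pytest.raises(ValueError, match="agonist"):
            load_dictionary(p)

    def test_bad_cpr_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("agonist\t11\n")
        with pytest.raises(ValueError):
            load_dictionary(p)

    def test_seed_dictionary_maps_table_words(self, seed_dictionary):
        lookup = {e.word: e.mapped_cpr for e in seed_dictionary}
        assert lookup["agonist"] == 5
        assert lookup["enhances"] == 3
        assert lookup["caused"] == 9


class TestMatching:
    def test_three_matches_in_agonist_sentence(self, agonist_pair, seed_dictionary):
        sent, mentions, pair = agonist_pair
        masked = mask_entities(sent, mentions, pair)
        matches = match_interaction_words(masked.tokens, seed_dictionary)
        assert [m.word for m in matches] == ["agonist", "enhances", "caused"]
        assert [m.entry.mapped_cpr for m in matches] == [5, 3, 9]
        assert [m.token_index for m in matches] == sorted(m.token_index for m in matches)

    def test_no_dictionary_words(self, seed_dictionary):
        assert match_interaction_words(["alpha", "beta"], seed_dictionary) == []

    def test_repeated_word_matches_twice(self, seed_dictionary):
        matches = match_interaction_words(
            ["CHEM", "inhibits", "and", "inhibits", "PROT"], seed_dictionary
        )
        assert [m.token_index for m in matches] == [1, 3]

    def test_brute_force_scan_agrees(self, seed_dictionary, rng):
        vocab = ["agonist", "inhibits", "foo", "bar", "CHEM", "PROT", "the"]
        lookup = {e.word: e for e in seed_dictionary}
        for _ in range(50):
            toks = [vocab[i] for i in rng.integers(0, len(vocab), size=rng.integers(0, 12))]
            expect = [(i, t) for i, t in enumerate(toks) if t.lower() in lookup]
            got = [(m.token_index, m.word) for m in
                   match_interaction_words(toks, seed_dictionary)]
            assert got == expect

    def test_stemming_optional(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("inhibit\t4\n")
        d = load_dictionary(p)
        assert match_interaction_words(["inhibited"], d) == []
        assert len(match_interaction_words(["inhibited"], d, stem=True)) == 1


class TestPairsTriplets:
    def _sentence_with(self, n_chem, n_prot):
        words, mentions, pos = [], [], 0
        text_parts = []
        for i in range(n_chem + n_prot):
            name = f"ent{i}x"
            text_parts.append(name)
        body = " ".join(text_parts) + " end."
        doc = DocumentRecord("7", "T.", body)
        base = len("T.") + 1
        cursor = 0
        for i in range(n_chem + n_prot):
            name = f"ent{i}x"
            start = base + cursor
            etype = "CHEMICAL" if i < n_chem else "GENE-N"
            mentions.append(EntityMention("7", f"T{i+1}", etype, start, start + len(name), name))
            cursor += len(name) + 1
        sent = split_sentences(doc)[1]
        return sent, mentions

    @pytest.mark.parametrize("n_chem,n_prot", [(2, 3), (0, 4), (1, 1)])
    def test_cartesian_product(self, n_chem, n_prot):
        sent, mentions = self._sentence_with(n_chem, n_prot)
        pairs = build_pairs(sent, mentions)
        assert len(pairs) == n_chem * n_prot
        keys = [(p.chem.start, p.prot.start) for p in pairs]
        assert keys == sorted(keys)

    def test_agonist_sentence_has_two_pairs(self, agonist_pair):
        sent, mentions, _ = agonist_pair
        assert len(build_pairs(sent, mentions)) == 2  # 2 chemicals x 1 protein

    def test_triplets_inherit_label_and_count(self, agonist_pair, seed_dictionary):
        sent, mentions, pair = agonist_pair
        pair.label = 5
        masked = mask_entities(sent, mentions, pair)
        matches = match_interaction_words(masked.tokens, seed_dictionary)
        trips = build_triplets(pair, matches)
        assert len(trips) == len(matches) == 3
        assert all(t.label == 5 for t in trips)
        assert build_triplets(pair, []) == []


class TestAssignLabels:
    def test_annotated_unannotated_and_coverage(self, agonist_pair):
        sent, mentions, _ = agonist_pair
        pairs = build_pairs(sent, mentions)
        relations = [
            RelationRecord("14507899", 5, "T16", "T15"),
            RelationRecord("14507899", 4, "T99", "T98"),  # never co-occurs
        ]
        report = assign_labels(pairs, relations)
        by_chem = {p.chem.term_id: p.label for p in pairs}
        assert by_chem["T16"] == 5
        assert by_chem["T10"] == 10
        assert report == {"annotations": 2, "labeled_pairs": 1, "unreachable": 1}

    def test_conflict_keeps_evaluated_then_lowest(self, agonist_pair):
        sent, mentions, _ = agonist_pair
        pairs = build_pairs(sent, mentions)
        relations = [
            RelationRecord("14507899", 2, "T16", "T15"),
            RelationRecord("14507899", 9, "T16", "T15"),
            RelationRecord("14507899", 5, "T16", "T15"),
        ]
        assign_labels(pairs, relations)
        assert {p.chem.term_id: p.label for p in pairs}["T16"] == 5

    def test_labels_total_on_synthetic_corpus(self, small_corpus, seed_dictionary):
        corpus, _ = small_corpus
        candset = build_candidates(corpus, seed_dictionary)
        assert all(1 <= p.label <= 10 for p in candset.pairs)
        assert candset.coverage["unreachable"] == 0


class TestMasking:
    def test_agonist_sentence_masked_exactly(self, agonist_pair):
        sent, mentions, pair = agonist_pair
        masked = mask_entities(sent, mentions, pair)
        assert masked.text == (
            "PROT agonist CHEM enhances functional recovery after detachment "
            "caused by subCPT10 injection in normal and rds mice."
        )
        assert masked.tokens[masked.chem_index] == "CHEM"
        assert masked.tokens[masked.prot_index] == "PROT"
        assert [m.term_id for m in masked.cpt_indices.values()] == ["T10"]

    def test_partial_span_preserves_prefix(self, agonist_pair):
        sent, mentions, pair = agonist_pair
        masked = mask_entities(sent, mentions, pair)
        assert "subCPT10" in masked.tokens

    def test_only_focal_entities_no_cpt(self):
        body = "Alphachem binds BETAPROT strongly."
        doc = DocumentRecord("3", "T.", body)
        base = len("T.") + 1
        ments = [
            EntityMention("3", "T1", "CHEMICAL", base, base + 9, "Alphachem"),
            EntityMention("3", "T2", "GENE-Y", base + 16, base + 24, "BETAPROT"),
        ]
        sent = split_sentences(doc)[1]
        pair = build_pairs(sent, ments)[0]
        masked = mask_entities(sent, ments, pair)
        assert masked.cpt_indices == {}
        assert masked.tokens == ["CHEM", "binds", "PROT", "strongly", "."]

    def test_overlapping_focal_mentions_rejected(self):
        doc = DocumentRecord("3", "T.", "ABCDEF binds.")
        base = len("T.") + 1
        chem = EntityMention("3", "T1", "CHEMICAL", base, base + 6, "ABCDEF")
        prot = EntityMention("3", "T2", "GENE-Y", base + 3, base + 6, "DEF")
        sent = split_sentences(doc)[1]
        pair = CandidatePair(sent, chem, prot)
        with pytest.raises(ValueError, match="overlap"):
            mask_entities(sent, [chem, prot], pair)

    def test_mask_unmask_round_trip_on_corpus(self, small_corpus, seed_dictionary):
        corpus, _ = small_corpus
        candset = build_candidates(corpus, seed_dictionary)
        from cpimine.io import tokenize

        for idx in range(len(candset.pairs)):
            masked = candset.masked_for(idx)
            assert masked.unmask_text() == masked.sentence.text
            assert unmask_tokens(masked) == [t.text for t in masked.sentence.tokens]

    def test_recount_invariants_on_corpus(self, small_corpus, seed_dictionary):
        """#pairs = #chem x #prot and #triplets = sum over pairs of #matches."""
        from cpimine.io import sentences_for_document

        corpus, _ = small_corpus
        candset = build_candidates(corpus, seed_dictionary)
        n_pairs = n_trips = 0
        for pmid, doc in corpus.documents.items():
            mentions = corpus.mentions_for(pmid)
            sents, _ = sentences_for_document(doc, mentions)
            for sent in sents:
                chems = [m for m in mentions if sent.contains(m) and m.is_chemical]
                prots = [m for m in mentions if sent.contains(m) and m.is_protein]
                n_pairs += len(chems) * len(prots)
                if chems and prots:
                    pair = build_pairs(sent, mentions)[0]
                    masked = mask_entities(sent, mentions, pair)
                    k = len(match_interaction_words(masked.tokens, seed_dictionary))
                    n_trips += k * len(chems) * len(prots)
        assert n_pairs == len(candset.pairs)
        assert n_trips == len(candset.triplets)
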