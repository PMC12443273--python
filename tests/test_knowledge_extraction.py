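"""Lexicon loading, keyword matching and data adjustment."""

import pytest

from ncd_listener import knowledge_extraction as kx, nlp_core as nc
from ncd_listener.knowledge_extraction import Lexicon, LexiconEntry


def tok(text, seq=1):
    return nc.tokenize_comment(seq, text)


def brute_force_match(tokenized, lexicon, category):
    """Independent oracle: scan every term of every entry directly."""
    hits = []
    for entry in lexicon.entries(category):
        best = None
        for term in entry.en:
            needle = kx._normalize_term(term)
            hay = tokenized.normalized_tokens
            for i in range(len(hay) - len(needle) + 1):
                if tuple(hay[i : i + len(needle)]) == needle:
                    best = i if best is None else min(best, i)
                    break
        for term in entry.th:
            p = tokenized.text.find(term)
            if p >= 0:
                best = p if best is None else min(best, p)
        if best is not None:
            hits.append((best, entry.label))
    hits.sort(key=lambda t: (t[0], t[1]))
    out = []
    for _, label in hits:
        if label not in out:
            out.append(label)
    return out


class TestLoadLexicon:
    def test_starter_lexicon_covers_ncd_groups(self, lexicon):
        labels = {e.label for e in lexicon.entries("disease")}
        assert {"cancer", "heart disease", "diabetes", "chronic respiratory disease"} <= labels

    def test_duplicate_label_rejected(self):
        with pytest.raises(kx.LexiconError, match="duplicate"):
            Lexicon({"disease": [LexiconEntry("x", en=("a",)), LexiconEntry("x", en=("b",))]})

    def test_empty_category_rejected(self):
        with pytest.raises(kx.LexiconError, match="empty"):
            Lexicon({"disease": []})

    def test_entry_without_terms_rejected(self):
        with pytest.raises(kx.LexiconError, match="no terms"):
            LexiconEntry("x")

    def test_unknown_category_rejected(self):
        with pytest.raises(kx.LexiconError):
            Lexicon({"moods": [LexiconEntry("x", en=("a",))]})

    def test_yaml_round_trip(self, tmp_path, lexicon):
        import yaml

        path = tmp_path / "lex.yaml"
        doc = {
            cat: [
                {"label": e.label, "en": list(e.en), "th": list(e.th)}
                for e in entries
            ]
            for cat, entries in lexicon.categories.items()
        }
        path.write_text(yaml.safe_dump(doc, allow_unicode=True), "utf-8")
        loaded = kx.load_lexicon(path)
        assert {c: [e.label for e in es] for c, es in loaded.categories.items()} == {
            c: [e.label for e in es] for c, es in lexicon.categories.items()
        }


class TestMatchCategory:
    def test_single_entry_match(self, lexicon):
        out = kx.match_category(tok("my mother survived lung cancer"), lexicon, "disease")
        assert out == ["cancer"]

    def test_no_term_present(self, lexicon):
        assert kx.match_category(tok("lovely weather today friends"), lexicon, "disease") == []

    def test_two_entries_occurrence_order(self, lexicon):
        out = kx.match_category(
            tok("first the diabetes then the cancer came"), lexicon, "disease"
        )
        assert out == ["diabetes", "cancer"]

    def test_multiword_term_contiguous(self, lexicon):
        assert kx.match_category(tok("she has heart disease now"), lexicon, "disease") == [
            "heart disease"
        ]

    def test_thai_substring_match(self, lexicon):
        assert kx.match_category(tok("ผมเป็นเบาหวานมานาน"), lexicon, "disease") == ["diabetes"]

    def test_inflected_form_matches_via_normalization(self, lexicon):
        # "cigarettes" matches the "cigarette" term after lemmatization
        out = kx.match_category(tok("too many cigarettes every day"), lexicon, "behavior_cause")
        assert out == ["smoking"]

    def test_monotone_under_lexicon_growth(self, lexicon, clean_corpus):
        records, _ = clean_corpus
        bigger = lexicon.with_entry("disease", LexiconEntry("stroke", en=("stroke",)))
        for rec in records[:50]:
            t = tok(rec.text, rec.seq)
            base = set(kx.match_category(t, lexicon, "disease"))
            grown = set(kx.match_category(t, bigger, "disease"))
            assert base <= grown

    def test_agrees_with_brute_force_oracle(self, lexicon, clean_corpus):
        records, _ = clean_corpus
        for rec in records:
            t = tok(rec.text, rec.seq)
            for cat in ("disease", "symptom", "treatment", "behavior_cause"):
                assert kx.match_category(t, lexicon, cat) == brute_force_match(t, lexicon, cat)


class TestExtractVariables:
    def test_kin_term_gives_family_source(self, lexicon):
        k = kx.extract_variables(tok("my mother survived lung cancer"), lexicon)
        assert k.source == "family_member"
        assert k.gender == "female"
        assert k.diseases == ["cancer"]

    def test_cue_free_comment_defaults(self, lexicon):
        k = kx.extract_variables(tok("lovely weather in town today"), lexicon)
        assert k.gender == "unknown"
        assert k.source == "general"
        assert k.diseases == k.symptoms == k.treatments == k.behaviors == []

    def test_conflicting_gender_cues_unknown(self, lexicon):
        k = kx.extract_variables(tok("he and she both recovered well"), lexicon)
        assert k.gender == "unknown"

    def test_category_left_unset(self, lexicon):
        assert kx.extract_variables(tok("anything at all"), lexicon).category is None

    def test_matches_planted_ground_truth(self, lexicon, clean_corpus):
        records, truth = clean_corpus
        for rec, entry in zip(records, truth.entries):
            k = kx.extract_variables(tok(rec.text, rec.seq), lexicon)
            assert set(k.diseases) == set(entry.diseases)
            assert set(k.symptoms) == set(entry.symptoms)
            assert set(k.treatments) == set(entry.treatments)
            assert set(k.behaviors) == set(entry.behaviors)
            assert k.gender == entry.gender
            assert k.source == entry.source


class TestWordFrequency:
    def test_hand_counted_example(self):
        corpus = [
            tok("cancer is scary", 1),
            tok("cancer again", 2),
            tok("cancer and hope", 3),
        ]
        out = kx.word_frequency(corpus, top_k=10)
        assert out[0] == ("cancer", 3)
        assert ("hope", 1) in out

    def test_empty_corpus(self):
        assert kx.word_frequency([], top_k=5) == []

    def test_tie_broken_lexicographically(self):
        out = kx.word_frequency([tok("zebra apple", 1)], top_k=5)
        assert out == [("apple", 1), ("zebra", 1)]

    def test_conservation_of_counts(self, clean_corpus):
        records, _ = clean_corpus
        corpus = [tok(r.text, r.seq) for r in records]
        total_tokens = sum(len(c.normalized_tokens) for c in corpus)
        assert sum(n for _, n in kx.word_frequency(corpus, top_k=None)) == total_tokens


class TestAdjustSelection:
    def make_knowledge(self, lexicon, corpus):
        records, truth = corpus
        return (
            [kx.extract_variables(tok(r.text, r.seq), lexicon) for r in records],
            truth,
        )

    def test_include_keeps_exactly_mentioning_comments(self, lexicon, clean_corpus):
        knowledge, truth = self.make_knowledge(lexicon, clean_corpus)
        kept = kx.adjust_selection(knowledge, include={"diabetes"})
        expected = {
            e.seq
            for e in truth.entries
            if "diabetes" in e.diseases or "diabetes" in e.symptoms
        }
        assert {k.seq for k in kept} == expected

    def test_exclude_removes_all_mentions(self, lexicon, clean_corpus):
        knowledge, _ = self.make_knowledge(lexicon, clean_corpus)
        kept = kx.adjust_selection(knowledge, exclude={"cancer"})
        assert all("cancer" not in k.diseases for k in kept)

    def test_empty_filters_identity(self, lexicon, clean_corpus):
        knowledge, _ = self.make_knowledge(lexicon, clean_corpus)
        assert kx.adjust_selection(knowledge) == knowledge

    def test_overlapping_sets_error(self):
        with pytest.raises(ValueError):
            kx.adjust_selection([], include={"a"}, exclude={"a"})

    def test_subset_and_idempotent(self, lexicon, clean_corpus):
        knowledge, _ = self.make_knowledge(lexicon, clean_corpus)
        kept = kx.adjust_selection(knowledge, include={"cancer"}, exclude={"fatigue"})
        assert set(map(id, kept)) <= set(map(id, knowledge))
        assert kx.adjust_selection(kept, include={"cancer"}, exclude={"fatigue"}) == kept
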