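"""HTML/CSV ingestion and the preprocessing pipeline."""

import pytest

from ncd_listener import ingestion, nlp_core
from ncd_listener.ingestion import CommentRecord


def make_records(texts, aliases=None):
    aliases = aliases or [f"user{i}" for i in range(1, len(texts) + 1)]
    return [
        CommentRecord(seq=i, alias=a, text=t, likes=i, replies=0)
        for i, (a, t) in enumerate(zip(aliases, texts), start=1)
    ]


FIXTURE_HTML = """
<html><body>
<div class="comment">
  <span class="author">alice</span>
  <div class="comment-text">My mother was treated for lung cancer</div>
  <span class="like-count">12</span>
  <span class="reply-count">3</span>
</div>
<div class="comment">
  <span class="author">somchai</span>
  <div class="comment-text">What are the symptoms of diabetes?</div>
  <span class="like-count">1.2K</span>
  <span class="reply-count">0</span>
</div>
<div class="comment">
  <span class="author">bob</span>
  <div class="comment-text">thanks for sharing</div>
  <span class="reply-count">1</span>
</div>
</body></html>
"""


class TestParseHtml:
    def test_three_blocks_in_document_order(self, selector_config):
        records = ingestion.parse_comments_html(FIXTURE_HTML, selector_config)
        assert [r.seq for r in records] == [1, 2, 3]
        assert records[0].alias == "alice"
        assert records[1].likes == 1200  # "1.2K" rendered count
        assert records[2].likes == 0  # likes element missing -> default

    def test_empty_document_yields_empty_list(self, selector_config):
        assert ingestion.parse_comments_html("<html></html>", selector_config) == []

    def test_language_detected_at_parse_time(self, selector_config):
        html = (
            '<div class="comment"><span class="author">x</span>'
            '<div class="comment-text">ผมเป็นเบาหวานมานาน</div></div>'
        )
        [rec] = ingestion.parse_comments_html(html, selector_config)
        assert rec.language == nlp_core.THAI


@pytest.mark.parametrize(
    "raw,expected",
    [("3", 3), ("1.2K", 1200), ("2M", 2_000_000), ("", 0), (None, 0), ("1,234", 1234)],
)
def test_parse_count(raw, expected):
    assert ingestion.parse_count(raw) == expected


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path):
        records = make_records(
            ["hello world one", 'with, comma and "quotes"', "line\nbreak survives"]
        )
        path = tmp_path / "t.csv"
        ingestion.write_comment_table(records, path)
        back = ingestion.read_comment_table(path)
        assert [(r.alias, r.text, r.likes, r.replies) for r in records] == [
            (r.alias, r.text, r.likes, r.replies) for r in back
        ]

    def test_columns_matched_by_name_not_position(self, tmp_path):
        path = tmp_path / "reordered.csv"
        path.write_text("likes,name,replies,comments\n7,alice,2,hello there\n")
        [rec] = ingestion.read_comment_table(path)
        assert (rec.alias, rec.text, rec.likes, rec.replies) == ("alice", "hello there", 7, 2)

    def test_missing_column_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,likes,replies\na,1,2\n")
        with pytest.raises(ingestion.IngestionError, match="comments"):
            ingestion.read_comment_table(path)

    def test_malformed_integer_names_row(self, tmp_path):
        path = tmp_path / "bad2.csv"
        path.write_text("name,comments,likes,replies\na,hi,xx,0\n")
        with pytest.raises(ingestion.IngestionError, match="row 2"):
            ingestion.read_comment_table(path)


class TestDeduplicate:
    def test_first_occurrence_kept(self):
        records = make_records(["aaa", "bbb", "ccc", "bbb"])
        out = ingestion.deduplicate(records)
        assert [r.seq for r in out] == [1, 2, 3]

    def test_whitespace_collapsed_comparison(self):
        records = make_records(["a  b c", "a b\tc"])
        assert len(ingestion.deduplicate(records)) == 1

    def test_distinct_input_unchanged_and_idempotent(self):
        records = make_records(["a1 b", "a2 b", "a3 b"])
        once = ingestion.deduplicate(records)
        assert once == records
        assert ingestion.deduplicate(once) == once

    def test_output_is_subsequence_of_input(self):
        records = make_records(["x", "y", "x", "z", "y"])
        out = ingestion.deduplicate(records)
        seqs = [r.seq for r in out]
        assert seqs == sorted(seqs)
        assert set(seqs) <= {r.seq for r in records}


class TestFilterShort:
    def test_five_word_boundary_removed_six_retained(self):
        five = "one two three four five"
        six = "one two three four five six"
        records = make_records([five, six])
        out = ingestion.filter_short(records)
        assert [r.text for r in out] == [six]

    def test_thai_comment_counted_by_segmentation(self):
        # segments to 4 dictionary tokens -> removed
        short_th = "ผมเป็นเบาหวานแล้ว"
        long_th = "ผมเป็นเบาหวานมาสองปีแล้ว"
        assert len(nlp_core.tokenize(short_th, nlp_core.THAI)) <= 5
        assert len(nlp_core.tokenize(long_th, nlp_core.THAI)) >= 6
        out = ingestion.filter_short(make_records([short_th, long_th]))
        assert [r.text for r in out] == [long_th]

    def test_retained_records_all_exceed_threshold(self, small_corpus):
        records, _ = small_corpus
        out = ingestion.filter_short(records)
        for rec in out:
            assert len(ingestion.default_tokenizer(rec)) >= 6


class TestAnonymize:
    def test_alias_replaced_with_seq_token(self):
        rec = CommentRecord(seq=3, alias="somchai", text="hello")
        [out] = ingestion.anonymize([rec])
        assert out.alias == "Name(3)"

    def test_idempotent(self):
        records = make_records(["a b c d e f g"] )
        once = ingestion.anonymize(records)
        assert ingestion.anonymize(once) == once

    def test_alias_set_enumeration(self):
        records = make_records(["t"] * 10)
        assert {r.alias for r in ingestion.anonymize(records)} == {
            f"Name({i})" for i in range(1, 11)
        }


class TestPipeline:
    def test_counts_match_planted_ground_truth(self, small_corpus):
        records, truth = small_corpus
        out = ingestion.preprocess_pipeline(records)
        assert len(out) == len(records) - truth.n_duplicates - truth.n_short

    def test_no_original_alias_survives(self, small_corpus, tmp_path):
        records, _ = small_corpus
        out = ingestion.preprocess_pipeline(records)
        path = tmp_path / "out.csv"
        ingestion.write_comment_table(out, path)
        serialized = path.read_text("utf-8")
        for rec in records:
            assert rec.alias not in serialized

    def test_seq_not_renumbered(self, small_corpus):
        records, _ = small_corpus
        out = ingestion.preprocess_pipeline(records)
        kept = {r.seq for r in out}
        assert kept <= {r.seq for r in records}
        for rec in out:
            assert rec.alias == f"Name({rec.seq})"

    def test_deterministic_byte_identical_output(self, small_corpus, tmp_path):
        records, _ = small_corpus
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ingestion.write_comment_table(ingestion.preprocess_pipeline(records), p1)
        ingestion.write_comment_table(ingestion.preprocess_pipeline(records), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_input(self):
        assert ingestion.preprocess_pipeline([]) == []


def test_selector_config_requires_all_fields():
    with pytest.raises(ingestion.IngestionError, match="replies"):
        ingestion.SelectorConfig(
            platform="x",
            comment_container_selector="div.c",
            field_selectors={"name": "a", "comment": "b", "likes": "c"},
        )


def test_bundled_selector_yaml_loads():
    from importlib import resources as ilr

    with ilr.as_file(ilr.files("ncd_listener.resources").joinpath("selectors.yaml")) as p:
        for platform in ("facebook", "reddit"):
            cfg = ingestion.load_selector_config(p, platform)
            assert cfg.platform == platform
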