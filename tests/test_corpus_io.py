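import io

import pytest

from litdisc.corpus_io import (ABBREVIATIONS, CorpusFormatError, Document,
                               Mention, SentenceSpan,
                               assign_mentions_to_sentences, prepare_corpus,
                               read_jsonl, read_pubtator, read_year_sidecar,
                               segment_sentences, write_jsonl, write_pubtator)

PUBTATOR_RECORD = (
    "123|t|p53 and cancer.\n"
    "123|a|TP53 regulates apoptosis.\n"
    "123\t0\t3\tp53\tGene\tPR:000003035\n"
    "123\t16\t20\tTP53\tGene\tPR:000003035\n"
    "\n"
)


class TestReadPubtator:
    def test_single_record(self):
        docs, mentions = read_pubtator(io.StringIO(PUBTATOR_RECORD))
        assert len(docs) == 1
        assert docs[0].doc_id == "123"
        assert docs[0].text == "p53 and cancer. TP53 regulates apoptosis."
        assert len(mentions) == 2
        assert {m.entity_id for m in mentions} == {"PR:000003035"}
        assert docs[0].text[mentions[1].start:mentions[1].end] == "TP53"

    def test_empty_stream(self):
        docs, mentions = read_pubtator(io.StringIO(""))
        assert docs == [] and mentions == []

    @pytest.mark.parametrize("id_field", ["-", ""])
    def test_ungrounded_annotation(self, id_field):
        text = ("9|t|A title.\n9|a|Body here.\n"
                f"9\t2\t7\ttitle\tChemical\t{id_field}\n\n")
        _, mentions = read_pubtator(io.StringIO(text))
        assert len(mentions) == 1
        assert mentions[0].entity_id is None

    def test_offset_mismatch_skipped(self, caplog):
        text = ("9|t|A title.\n9|a|Body.\n"
                "9\t0\t1\tX\tGene\tG:1\n"          # mismatch: text[0:1] == "A"
                "9\t2\t7\ttitle\tChemical\tM:1\n\n")
        with caplog.at_level("WARNING"):
            docs, mentions = read_pubtator(io.StringIO(text))
        assert len(docs) == 1
        assert [m.entity_id for m in mentions] == ["M:1"]
        assert "offset mismatch" in caplog.text

    def test_malformed_annotation_line_reports_line_number(self):
        text = "9|t|A title.\n9|a|Body.\n9\tnot_enough_fields\n\n"
        with pytest.raises(CorpusFormatError, match="line 3"):
            read_pubtator(io.StringIO(text))

    def test_duplicate_title_rejects_record(self, caplog):
        text = ("9|t|One.\n9|t|Two.\n9|a|Body.\n\n"
                "10|t|Keep.\n10|a|This one.\n\n")
        with caplog.at_level("WARNING"):
            docs, _ = read_pubtator(io.StringIO(text))
        assert [d.doc_id for d in docs] == ["10"]
        assert "record rejected" in caplog.text

    def test_year_sidecar_and_default(self):
        years = read_year_sidecar(io.StringIO("123\t1999\n"))
        docs, _ = read_pubtator(io.StringIO(PUBTATOR_RECORD), years=years)
        assert docs[0].year == 1999
        docs, _ = read_pubtator(io.StringIO(PUBTATOR_RECORD), default_year=2005)
        assert docs[0].year == 2005
        docs, _ = read_pubtator(io.StringIO(PUBTATOR_RECORD))
        assert docs[0].year is None


class TestSegmentation:
    def test_two_sentences(self):
        doc = Document("d", "p53 and cancer. TP53 regulates apoptosis.")
        segment_sentences(doc)
        spans = [(s.start, s.end) for s in doc.sentences]
        assert spans == [(0, 15), (16, 41)]

    def test_no_terminal_punctuation(self):
        doc = Document("d", "no terminal punctuation")
        segment_sentences(doc)
        assert [(s.start, s.end) for s in doc.sentences] == [(0, 23)]

    def test_abbreviation_guard(self):
        text = "E. coli grows. So does B. subtilis."
        doc = Document("d", text)
        segment_sentences(doc)
        sents = [text[s.start:s.end] for s in doc.sentences]
        assert sents == ["E. coli grows.", "So does B. subtilis."]
        assert "E." in ABBREVIATIONS and "B." in ABBREVIATIONS

    def test_spans_cover_non_whitespace(self):
        text = "First one.  Second here! Third? Done with 4 words."
        doc = Document("d", text)
        segment_sentences(doc)
        covered = set()
        last_start = -1
        for s in doc.sentences:
            assert s.start < s.end
            assert s.start > last_start
            last_start = s.start
            assert not covered & set(range(s.start, s.end))
            covered |= set(range(s.start, s.end))
        outside = set(range(len(text))) - covered
        assert all(text[i].isspace() for i in outside)

    def test_empty_text_raises(self):
        with pytest.raises(ValueError):
            segment_sentences(Document("d", "   "))


class TestMentionAssignment:
    @pytest.fixture
    def doc(self):
        d = Document("d", "p53 and cancer. TP53 regulates apoptosis.")
        return segment_sentences(d)

    def _mention(self, start, end):
        return Mention(doc_id="d", start=start, end=end, surface="x",
                       entity_type="Gene", entity_id="G:1")

    def test_second_sentence(self, doc):
        [m] = assign_mentions_to_sentences(doc, [self._mention(16, 20)])
        assert m.sentence_index == 1

    def test_offset_zero(self, doc):
        [m] = assign_mentions_to_sentences(doc, [self._mention(0, 3)])
        assert m.sentence_index == 0

    def test_boundary_crossing_uses_start(self, doc):
        [m] = assign_mentions_to_sentences(doc, [self._mention(13, 20)])
        assert m.sentence_index == 0

    def test_offset_beyond_text_raises(self, doc):
        with pytest.raises(ValueError, match="d.*beyond"):
            assign_mentions_to_sentences(doc, [self._mention(999, 1002)])


class TestJsonlRoundTrip:
    def test_pubtator_to_jsonl_round_trip(self):
        docs, mentions = read_pubtator(io.StringIO(PUBTATOR_RECORD),
                                       default_year=1990)
        docs, mentions = prepare_corpus(docs, mentions)
        buf = io.StringIO()
        write_jsonl(docs, mentions, buf)
        buf.seek(0)
        docs2, mentions2 = read_jsonl(buf)
        assert docs2 == docs
        assert sorted(mentions2, key=lambda m: m.start) == \
            sorted(mentions, key=lambda m: m.start)

    def test_empty_corpus(self):
        buf = io.StringIO()
        write_jsonl([], [], buf)
        buf.seek(0)
        assert read_jsonl(buf) == ([], [])

    def test_ungrounded_preserved(self):
        doc = segment_sentences(Document("d", "Some text here.", year=2000))
        m = Mention("d", 5, 9, "text", "Chemical", None, 0)
        buf = io.StringIO()
        write_jsonl([doc], [m], buf)
        buf.seek(0)
        _, mentions = read_jsonl(buf)
        assert mentions[0].entity_id is None

    def test_schema_violation_reports_doc(self):
        with pytest.raises(CorpusFormatError, match="line 1"):
            read_jsonl(io.StringIO('{"doc_id": "x"}\n'))

    def test_duplicate_doc_id_rejected(self):
        line = '{"doc_id": "x", "text": "T.", "year": 1, "sentences": [], "mentions": []}\n'
        with pytest.raises(CorpusFormatError, match="duplicate"):
            read_jsonl(io.StringIO(line + line))


def test_pubtator_round_trip_preserves_fields():
    docs, mentions = read_pubtator(io.StringIO(PUBTATOR_RECORD))
    docs, mentions = prepare_corpus(docs, mentions)
    buf = io.StringIO()
    write_pubtator(docs, mentions, buf)
    buf.seek(0)
    docs2, mentions2 = read_pubtator(buf)
    assert [(d.doc_id, d.text) for d in docs2] == [(d.doc_id, d.text) for d in docs]
    key = lambda m: (m.doc_id, m.start, m.end)
    for a, b in zip(sorted(mentions, key=key), sorted(mentions2, key=key)):
        assert (a.doc_id, a.start, a.end, a.surface, a.entity_type, a.entity_id) == \
            (b.doc_id, b.start, b.end, b.surface, b.entity_type, b.entity_id)
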