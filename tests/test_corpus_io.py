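"""Corpus parsing, cleaning, tokenization, vocabulary and batching."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capstriage import corpus_io as cio

PM_JSON = {
    "documents": [
        {
            "id": "9685346",
            "infons": {"relevant": "no"},
            "passages": [
                {"infons": {"type": "title"}, "text": "A protein study."},
                {"infons": {"type": "abstract"}, "text": "It binds another protein."},
            ],
        },
        {
            "id": "17308308",
            "infons": {"relevant": "yes"},
            "passages": [
                {"infons": {"type": "title"}, "text": "Mutation affects binding."}
            ],
        },
        {
            "id": "11111111",
            "infons": {},
            "passages": [{"infons": {"type": "title"}, "text": "Unlabeled record."}],
        },
    ]
}


class TestPmJsonParser:
    def test_labels_pmids_and_text(self, tmp_path):
        path = tmp_path / "pm.json"
        path.write_text(json.dumps(PM_JSON))
        docs = cio.parse_pm_json(path)
        assert [d.pmid for d in docs] == ["9685346", "17308308", "11111111"]
        assert [d.label for d in docs] == [
            cio.NEGATIVE,
            cio.POSITIVE,
            cio.UNLABELED,
        ]
        assert docs[0].title == "A protein study."
        assert docs[0].text() == "A protein study. It binds another protein."

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("[]")
        assert cio.parse_pm_json(path) == []

    def test_record_without_id_is_skipped(self, tmp_path, caplog):
        path = tmp_path / "noid.json"
        path.write_text(json.dumps([{"passages": [], "infons": {}}]))
        with caplog.at_level("WARNING", logger="capstriage"):
            assert cio.parse_pm_json(path) == []
        assert "no 'id'" in caplog.text

    def test_malformed_json_reports_byte_offset(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"documents": [}')
        with pytest.raises(cio.CorpusFormatError, match="byte offset"):
            cio.parse_pm_json(path)


BC_XML = """<?xml version="1.0"?>
<documents>
  <document>
    <PMID>123</PMID>
    <TITLE>Interaction of two proteins.</TITLE>
    <ABSTRACT>They interact strongly.</ABSTRACT>
    <CURATIONRELEVANCE>positive</CURATIONRELEVANCE>
  </document>
  <document>
    <PMID>456</PMID>
    <TITLE>A title only record.</TITLE>
    <ABSTRACT></ABSTRACT>
    <CURATIONRELEVANCE>negative</CURATIONRELEVANCE>
  </document>
</documents>
"""


class TestBcXmlParser:
    def test_labels_and_partial_text(self, tmp_path):
        path = tmp_path / "ias.xml"
        path.write_text(BC_XML)
        docs = cio.parse_bc_xml(path)
        assert [d.label for d in docs] == [cio.POSITIVE, cio.NEGATIVE]
        # empty abstract with non-empty title is retained
        assert docs[1].pmid == "456"
        assert docs[1].abstract == ""
        assert docs[1].title

    def test_malformed_xml_reports_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<documents>\n<document>\n</documents>")
        with pytest.raises(cio.CorpusFormatError, match="line"):
            cio.parse_bc_xml(path)

    def test_unknown_relevance_value_is_an_error(self, tmp_path):
        path = tmp_path / "weird.xml"
        path.write_text(
            "<documents><document><PMID>1</PMID><TITLE>t t</TITLE>"
            "<CURATIONRELEVANCE>maybe</CURATIONRELEVANCE></document></documents>"
        )
        with pytest.raises(cio.CorpusFormatError, match="maybe"):
            cio.parse_bc_xml(path)


class TestCleanText:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("p53-mediated (PPI)!", "p53 mediated PPI"),
            ("", ""),
            ("ABC123", "ABC123"),
            ("a  b\t\nc", "a b c"),
        ],
    )
    def test_examples(self, raw, expected):
        assert cio.clean_text(raw) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(max_size=80))
    def test_idempotent_and_alphabet(self, raw):
        once = cio.clean_text(raw)
        assert cio.clean_text(once) == once
        assert all(c.isalnum() or c == " " for c in once)


class TestTokenization:
    def test_two_sentence_example(self):
        doc = cio.Document(pmid="1", title="A binds B.", abstract="C mutates.")
        tok = cio.split_and_tokenize(doc, max_sentences=30, max_words=50)
        assert tok.sentences == [["a", "binds", "b"], ["c", "mutates"]]

    def test_single_word_document_survives(self):
        doc = cio.Document(pmid="1", title="Spliceosomal")
        tok = cio.split_and_tokenize(doc, max_sentences=30, max_words=50)
        assert tok.sentences == [["spliceosomal"]]

    def test_sentence_truncation(self):
        doc = cio.Document(
            pmid="1", title="A binds B.", abstract="C mutates fast. D folds here."
        )
        tok = cio.split_and_tokenize(doc, max_sentences=1, max_words=50)
        assert tok.sentences == [["a", "binds", "b"]]

    def test_word_truncation(self):
        doc = cio.Document(pmid="1", title="one two three four")
        tok = cio.split_and_tokenize(doc, max_sentences=5, max_words=2)
        assert tok.sentences == [["one", "two"]]

    def test_noisy_short_sentences_dropped_when_others_exist(self):
        doc = cio.Document(pmid="1", title="Ok.", abstract="This sentence survives.")
        tok = cio.split_and_tokenize(doc, max_sentences=5, max_words=10)
        assert tok.sentences == [["this", "sentence", "survives"]]

    def test_empty_document_raises_and_corpus_filter_drops(self):
        doc = cio.Document(pmid="1", title="!!!", abstract="...")
        with pytest.raises(cio.EmptyDocumentError):
            cio.split_and_tokenize(doc)
        assert cio.tokenize_corpus([doc]) == []


class TestVocabulary:
    def test_frequency_then_lexicographic_order(self):
        corpus = [cio.TokenizedDocument(pmid="1", sentences=[["a", "b", "a"]])]
        vocab = cio.build_vocabulary(corpus, min_count=1)
        assert vocab.token_to_index == {
            cio.PAD_TOKEN: 0,
            cio.OOV_TOKEN: 1,
            "a": 2,
            "b": 3,
        }

    def test_min_count_filters_to_reserved_only(self):
        corpus = [cio.TokenizedDocument(pmid="1", sentences=[["a", "b"]])]
        assert len(cio.build_vocabulary(corpus, min_count=5)) == 2

    def test_deterministic(self):
        corpus = [
            cio.TokenizedDocument(pmid="1", sentences=[["x", "y", "x"], ["z", "y"]])
        ]
        v1 = cio.build_vocabulary(corpus)
        v2 = cio.build_vocabulary(corpus)
        assert v1.token_to_index == v2.token_to_index

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            cio.build_vocabulary([])


class TestIndexBatch:
    def _vocab(self):
        return cio.build_vocabulary(
            [cio.TokenizedDocument(pmid="1", sentences=[["a", "b", "a"]])]
        )

    def test_single_token_grid(self):
        vocab = self._vocab()
        doc = cio.TokenizedDocument(pmid="1", sentences=[["a"]], label=cio.POSITIVE)
        batch = cio.index_batch([doc], vocab, max_sentences=2, max_words=3)
        np.testing.assert_array_equal(batch.ids, [[[2, 0, 0], [0, 0, 0]]])
        assert batch.labels.tolist() == [1]
        assert not batch.mask[0, 1].any()  # all-pad row fully unmasked

    def test_oov_maps_to_one(self):
        vocab = self._vocab()
        doc = cio.TokenizedDocument(pmid="1", sentences=[["zzz"]], label=cio.NEGATIVE)
        batch = cio.index_batch([doc], vocab, 1, 1)
        assert batch.ids[0, 0, 0] == cio.OOV_ID

    def test_mask_count_equals_token_count_and_round_trip(self):
        docs = [
            cio.TokenizedDocument(
                pmid=str(i),
                sentences=[["a", "b"], ["b", "a", "b"]][: i + 1],
                label=cio.NEGATIVE,
            )
            for i in range(2)
        ]
        vocab = self._vocab()
        batch = cio.index_batch(docs, vocab, 3, 4)
        for d, doc in enumerate(docs):
            assert batch.mask[d].sum() == doc.n_tokens()
        assert cio.unindex_batch(batch, vocab) == [d.sentences for d in docs]

    def test_oversized_document_rejected(self):
        vocab = self._vocab()
        doc = cio.TokenizedDocument(pmid="1", sentences=[["a"] * 5], label=cio.POSITIVE)
        with pytest.raises(ValueError, match="exceeds"):
            cio.index_batch([doc], vocab, 2, 3)

    def test_unlabeled_rejected_unless_allowed(self):
        vocab = self._vocab()
        doc = cio.TokenizedDocument(pmid="1", sentences=[["a"]])
        with pytest.raises(ValueError, match="unlabeled"):
            cio.index_batch([doc], vocab, 1, 1)
        batch = cio.index_batch([doc], vocab, 1, 1, allow_unlabeled=True)
        assert batch.labels.tolist() == [-1]


class TestPretrainedEmbeddings:
    def _write_w2v(self, path, dim=4):
        path.write_text(
            f"2 {dim}\n"
            "protein " + " ".join(["0.5"] * dim) + "\n"
            "binds " + " ".join(["-1.0"] * dim) + "\n"
        )

    def _vocab(self):
        v = cio.Vocabulary()
        v.token_to_index.update({"protein": 2, "missing": 3})
        return v

    def test_file_vectors_copied_pad_zero_missing_random(self, tmp_path):
        path = tmp_path / "emb.txt"
        self._write_w2v(path)
        vocab = self._vocab()
        emb = cio.load_pretrained_embeddings(path, vocab, dim=4, seed=1)
        np.testing.assert_array_equal(emb[2], [0.5] * 4)
        np.testing.assert_array_equal(emb[cio.PAD_ID], np.zeros(4))
        assert np.all(np.abs(emb[3]) <= 0.05) and np.any(emb[3] != 0)

    def test_seeded_loads_identical(self, tmp_path):
        path = tmp_path / "emb.txt"
        self._write_w2v(path)
        vocab = self._vocab()
        e1 = cio.load_pretrained_embeddings(path, vocab, dim=4, seed=3)
        e2 = cio.load_pretrained_embeddings(path, vocab, dim=4, seed=3)
        np.testing.assert_array_equal(e1, e2)

    def test_dim_mismatch_and_missing_file(self, tmp_path):
        path = tmp_path / "emb.txt"
        self._write_w2v(path, dim=4)
        with pytest.raises(cio.CorpusFormatError, match="dimension"):
            cio.load_pretrained_embeddings(path, self._vocab(), dim=8)
        with pytest.raises(FileNotFoundError, match="random"):
            cio.load_pretrained_embeddings(tmp_path / "nope.txt", self._vocab(), dim=4)
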