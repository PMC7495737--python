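"""Corpus readers, text preprocessing and batch indexing.

Two corpus dialects are supported, matching the public BioCreative triage
corpora:

* a BioC-style JSON dialect (BioCreative VI precision-medicine track): each
  record carries a PMID under ``id``, a relevance flag (``yes``/``no``) under
  ``relevant`` in the record's ``infons``, and title/abstract passages;
* an XML dialect (BioCreative II IAS / III ACT): per-record ``PMID``,
  ``TITLE``, ``ABSTRACT`` elements with the relevance label under
  ``CURATIONRELEVANCE``.

Preprocessing keeps only letters and digits, splits sentences on terminal
punctuation *before* cleaning, lowercases tokens, filters noisy (very short)
sentences and pads everything into a fixed ``[docs, sentences, words]``
integer grid over a frequency-ordered vocabulary with ``<PAD/>`` at index 0
and an out-of-vocabulary token at index 1.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

logger = logging.getLogger("capstriage")

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

PAD_TOKEN = "<PAD/>"
OOV_TOKEN = "<OOV/>"
PAD_ID = 0
OOV_ID = 1

#: label string -> integer class (positive class is 1 throughout)
LABEL_TO_INT = {NEGATIVE: 0, POSITIVE: 1}

_POSITIVE_VALUES = {"positive", "pos", "yes", "true", "1"}
_NEGATIVE_VALUES = {"negative", "neg", "no", "false", "0"}


class CorpusFormatError(ValueError):
    """A corpus file could not be parsed (position information included)."""


class EmptyDocumentError(ValueError):
    """A document has no usable text after cleaning."""


@dataclass
class Document:
    """One labeled title+abstract record identified by its PMID."""

    pmid: str
    title: str = ""
    abstract: str = ""
    label: str = UNLABELED

    def text(self) -> str:
        """Title and abstract concatenated with a single space."""
        return " ".join(part for part in (self.title, self.abstract) if part)


@dataclass
class TokenizedDocument:
    pmid: str
    sentences: list[list[str]]
    label: str = UNLABELED

    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass
class Vocabulary:
    """Dense token->index map with reserved pad (0) and OOV (1) slots."""

    token_to_index: dict[str, int] = field(
        default_factory=lambda: {PAD_TOKEN: PAD_ID, OOV_TOKEN: OOV_ID}
    )

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, OOV_ID)

    def tokens(self) -> list[str]:
        """Tokens ordered by index."""
        return sorted(self.token_to_index, key=self.token_to_index.get)


@dataclass
class IndexedBatch:
    """Padded integer grid [n_docs, max_sentences, max_words] plus labels/mask."""

    ids: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    pmids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return self.ids.shape[0]

    def sentence_mask(self) -> np.ndarray:
        """Boolean [n_docs, max_sentences]: sentences with >=1 real token."""
        return self.mask.any(axis=2)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def _relevance_label(value: str | None, *, pmid: str) -> str:
    if value is None:
        return UNLABELED
    norm = value.strip().lower()
    if norm in _POSITIVE_VALUES:
        return POSITIVE
    if norm in _NEGATIVE_VALUES:
        return NEGATIVE
    raise CorpusFormatError(
        f"record {pmid!r}: unknown relevance value {value!r} "
        f"(expected one of {sorted(_POSITIVE_VALUES | _NEGATIVE_VALUES)})"
    )


def parse_pm_json(path: str | Path) -> list[Document]:
    """Parse the JSON triage dialect (title/abstract passages, 'relevant', 'id').

    Records without an ``id`` are skipped with a logged warning.  Raises
    :class:`CorpusFormatError` naming the byte offset on malformed JSON.
    """
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(
            f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    records = data.get("documents", []) if isinstance(data, dict) else data
    docs: list[Document] = []
    for i, rec in enumerate(records):
        pmid = str(rec.get("id", "")).strip()
        if not pmid:
            logger.warning("%s: record %d has no 'id'; skipped", path, i)
            continue
        infons = rec.get("infons", {}) or {}
        relevant = infons.get("relevant", rec.get("relevant"))
        label = _relevance_label(relevant, pmid=pmid)
        title_parts: list[str] = []
        abstract_parts: list[str] = []
        for passage in rec.get("passages", []):
            ptype = (passage.get("infons", {}) or {}).get("type", "").lower()
            text = (passage.get("text") or "").strip()
            if not text:
                continue
            if ptype == "title":
                title_parts.append(text)
            else:
                abstract_parts.append(text)
        docs.append(
            Document(
                pmid=pmid,
                title=" ".join(title_parts),
                abstract=" ".join(abstract_parts),
                label=label,
            )
        )
    return docs


def parse_bc_xml(path: str | Path) -> list[Document]:
    """Parse the XML triage dialect (PMID/TITLE/ABSTRACT/CURATIONRELEVANCE).

    Raises :class:`CorpusFormatError` with the line number on malformed XML
    and on unknown relevance values.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(
            f"{path}: malformed XML at line {exc.lineno}: {exc.msg}"
        ) from exc

    def _text(elem, tag: str) -> str | None:
        child = elem.find(tag)
        if child is None:
            child = elem.find(tag.lower())
        return None if child is None or child.text is None else child.text.strip()

    docs: list[Document] = []
    for i, rec in enumerate(tree.getroot().iter("document")):
        pmid = _text(rec, "PMID") or ""
        if not pmid:
            logger.warning("%s: document %d has no PMID; skipped", path, i)
            continue
        label = _relevance_label(_text(rec, "CURATIONRELEVANCE"), pmid=pmid)
        docs.append(
            Document(
                pmid=pmid,
                title=_text(rec, "TITLE") or "",
                abstract=_text(rec, "ABSTRACT") or "",
                label=label,
            )
        )
    return docs


# ---------------------------------------------------------------------------
# Writers (canonical serializations; also exercised by the synthetic corpus)
# ---------------------------------------------------------------------------


def write_pm_json(docs: list[Document], path: str | Path) -> None:
    """Serialize documents in the JSON dialect understood by parse_pm_json."""
    records = []
    for doc in docs:
        infons = {}
        if doc.label == POSITIVE:
            infons["relevant"] = "yes"
        elif doc.label == NEGATIVE:
            infons["relevant"] = "no"
        passages = []
        if doc.title:
            passages.append({"infons": {"type": "title"}, "text": doc.title})
        if doc.abstract:
            passages.append({"infons": {"type": "abstract"}, "text": doc.abstract})
        records.append({"id": doc.pmid, "infons": infons, "passages": passages})
    Path(path).write_text(
        json.dumps({"documents": records}, indent=1, sort_keys=True), encoding="utf-8"
    )


def write_bc_xml(docs: list[Document], path: str | Path) -> None:
    """Serialize documents in the XML dialect understood by parse_bc_xml."""
    root = etree.Element("documents")
    for doc in docs:
        rec = etree.SubElement(root, "document")
        etree.SubElement(rec, "PMID").text = doc.pmid
        etree.SubElement(rec, "TITLE").text = doc.title
        etree.SubElement(rec, "ABSTRACT").text = doc.abstract
        if doc.label != UNLABELED:
            etree.SubElement(rec, "CURATIONRELEVANCE").text = doc.label
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def write_tsv(docs: list[Document], path: str | Path) -> None:
    """Canonical flat form: pmid <tab> label <tab> text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pmid\tlabel\ttext\n")
        for doc in docs:
            text = re.sub(r"\s+", " ", doc.text()).strip()
            fh.write(f"{doc.pmid}\t{doc.label}\t{text}\n")


# ---------------------------------------------------------------------------
# Cleaning / tokenization
# ---------------------------------------------------------------------------

_NON_ALNUM = re.compile(r"[^0-9A-Za-z]+")
_SENTENCE_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9])")


def clean_text(raw: str) -> str:
    """Replace every character outside letters/digits with a space and collapse.

    Total and idempotent; case is preserved (lowercasing happens at
    tokenization time).
    """
    return _NON_ALNUM.sub(" ", raw).strip()


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting on [.?!] + whitespace + capital/digit.

    Applied before character cleaning so boundary punctuation is still
    available.
    """
    return [s for s in _SENTENCE_BOUNDARY.split(text) if s.strip()]


def split_and_tokenize(
    doc: Document,
    max_sentences: int = 30,
    max_words: int = 50,
    min_sentence_tokens: int = 2,
) -> TokenizedDocument:
    """Sentence-split, clean, lowercase and truncate one document.

    Sentences with fewer than ``min_sentence_tokens`` tokens are treated as
    noise and dropped — unless that would empty the document, in which case
    the longest sentence is kept (a one-word document survives as a single
    one-token sentence).  Raises :class:`EmptyDocumentError` when no text
    survives cleaning; callers drop such records.
    """
    sentences: list[list[str]] = []
    for raw_sentence in split_sentences(doc.text()):
        tokens = clean_text(raw_sentence).lower().split()
        if tokens:
            sentences.append(tokens)
    if not sentences:
        raise EmptyDocumentError(f"document {doc.pmid!r}: no text after cleaning")
    kept = [s for s in sentences if len(s) >= min_sentence_tokens]
    if not kept:
        kept = [max(sentences, key=len)]
    kept = [s[:max_words] for s in kept[:max_sentences]]
    return TokenizedDocument(pmid=doc.pmid, sentences=kept, label=doc.label)


def tokenize_corpus(
    docs: list[Document],
    max_sentences: int = 30,
    max_words: int = 50,
    min_sentence_tokens: int = 2,
) -> list[TokenizedDocument]:
    """Tokenize a corpus, dropping empty-text records with a warning."""
    out: list[TokenizedDocument] = []
    for doc in docs:
        try:
            out.append(
                split_and_tokenize(doc, max_sentences, max_words, min_sentence_tokens)
            )
        except EmptyDocumentError:
            logger.warning("dropping empty document %r", doc.pmid)
    return out


# ---------------------------------------------------------------------------
# Vocabulary / indexing
# ---------------------------------------------------------------------------


def build_vocabulary(
    corpus: list[TokenizedDocument], min_count: int = 1
) -> Vocabulary:
    """Frequency-ordered vocabulary (count desc, then lexicographic) from index 2."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for doc in corpus:
        for sentence in doc.sentences:
            for token in sentence:
                counts[token] = counts.get(token, 0) + 1
    vocab = Vocabulary()
    ordered = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    for i, token in enumerate(ordered, start=2):
        vocab.token_to_index[token] = i
    return vocab


def index_batch(
    docs: list[TokenizedDocument],
    vocab: Vocabulary,
    max_sentences: int = 30,
    max_words: int = 50,
    allow_unlabeled: bool = False,
) -> IndexedBatch:
    """Left-aligned padded grid; unknown tokens map to the OOV index.

    Labels are encoded positive=1, negative=0 (unlabeled=-1 only when
    ``allow_unlabeled``, i.e. prediction mode).  Documents exceeding the
    limits must be pre-truncated.
    """
    n = len(docs)
    ids = np.zeros((n, max_sentences, max_words), dtype=np.int64)
    mask = np.zeros((n, max_sentences, max_words), dtype=bool)
    labels = np.full(n, -1, dtype=np.int64)
    pmids: list[str] = []
    for d, doc in enumerate(docs):
        if len(doc.sentences) > max_sentences or any(
            len(s) > max_words for s in doc.sentences
        ):
            raise ValueError(
                f"document {doc.pmid!r} exceeds limits "
                f"({max_sentences} sentences x {max_words} words); truncate first"
            )
        if doc.label in LABEL_TO_INT:
            labels[d] = LABEL_TO_INT[doc.label]
        elif not allow_unlabeled:
            raise ValueError(f"document {doc.pmid!r} is unlabeled")
        for s, sentence in enumerate(doc.sentences):
            for w, token in enumerate(sentence):
                ids[d, s, w] = vocab.index(token)
                mask[d, s, w] = True
        pmids.append(doc.pmid)
    return IndexedBatch(ids=ids, labels=labels, mask=mask, pmids=pmids)


def unindex_batch(batch: IndexedBatch, vocab: Vocabulary) -> list[list[list[str]]]:
    """Invert index_batch: recover token lists from unmasked positions."""
    inv = {i: t for t, i in vocab.token_to_index.items()}
    docs = []
    for d in range(batch.n_docs):
        sentences = []
        for s in range(batch.ids.shape[1]):
            toks = [
                inv[batch.ids[d, s, w]]
                for w in range(batch.ids.shape[2])
                if batch.mask[d, s, w]
            ]
            if toks:
                sentences.append(toks)
        docs.append(sentences)
    return docs


# ---------------------------------------------------------------------------
# Pretrained embeddings (word2vec text format)
# ---------------------------------------------------------------------------


def random_embeddings(vocab: Vocabulary, dim: int, seed: int = 0) -> np.ndarray:
    """Uniform(-0.05, 0.05) embedding matrix with an all-zero pad row."""
    rng = np.random.default_rng(seed)
    emb = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
    emb[PAD_ID] = 0.0
    return emb


def load_pretrained_embeddings(
    path: str | Path, vocab: Vocabulary, dim: int, seed: int = 0
) -> np.ndarray:
    """Load word2vec text-format vectors for the vocabulary.

    In-file tokens get their file vectors; the pad row is zero; OOV and
    missing tokens keep the seeded uniform initialization.  Raises on a
    header/dim mismatch, and FileNotFoundError (suggesting random
    initialization) when the file is absent.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"{path}: embedding file not found; use random_embeddings() instead"
        )
    emb = random_embeddings(vocab, dim, seed=seed)
    with open(p, encoding="utf-8", errors="replace") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}: expected 'count dim' header")
        file_dim = int(header[1])
        if file_dim != dim:
            raise CorpusFormatError(
                f"{path}: file dimension {file_dim} != requested {dim}"
            )
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            token = parts[0]
            if token in vocab.token_to_index and token != PAD_TOKEN:
                vec = np.asarray(parts[1 : dim + 1], dtype=np.float64)
                emb[vocab.token_to_index[token]] = vec
    emb[PAD_ID] = 0.0
    return emb
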