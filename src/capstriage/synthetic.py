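"""Synthetic labeled triage corpora with a planted, tunable class signal.

Documents are drawn token-by-token from a Zipf background vocabulary; class
signal is planted by inserting discriminative keyword tokens (analogues of
the strong relevance indicators such as "mutation" / "interaction") into
sentences at class-conditional rates.  The generator emits the corpus in
both supported dialects (JSON and XML) so every parser, the preprocessing
pipeline and the trainer can be exercised without any download.

Hard negatives emulate the documents real triage models confuse: they carry
the positive-class keywords at the positive rate, but co-occurring with a
subtler counter-indicator token.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus_io import (
    NEGATIVE,
    POSITIVE,
    Document,
    write_bc_xml,
    write_pm_json,
    write_tsv,
)

#: tokens marking a hard negative alongside the planted positive keywords
COUNTER_TOKENS = ("unaffected", "unrelated")


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults give a cleanly separable corpus."""

    n_docs: int = 400
    positive_fraction: float = 0.5
    vocab_size: int = 500
    signal_tokens: tuple[str, ...] = ("mutation", "interaction")
    signal_rate_pos: float = 0.8
    signal_rate_neg: float = 0.05
    sentences_per_doc: tuple[int, int] = (3, 8)
    words_per_sentence: tuple[int, int] = (5, 12)
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_docs <= 0:
            problems.append("n_docs must be positive")
        if not 0.0 < self.positive_fraction < 1.0:
            problems.append("positive_fraction must lie in (0, 1)")
        if self.vocab_size <= 0:
            problems.append("vocab_size must be positive")
        if not self.signal_tokens:
            problems.append("signal_tokens must be non-empty")
        for name in ("signal_rate_pos", "signal_rate_neg"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.label_noise < 0.5:
            problems.append("label_noise must lie in [0, 0.5)")
        for name in ("sentences_per_doc", "words_per_sentence"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                problems.append(f"{name} must be a positive (lo, hi) range")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))


def _zipf_probs(vocab_size: int) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=np.float64)
    p = 1.0 / ranks
    return p / p.sum()


def _sentence(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    probs: np.ndarray,
    signal_rate: float,
    counter: bool = False,
) -> tuple[str, bool]:
    lo, hi = spec.words_per_sentence
    n_words = int(rng.integers(lo, hi + 1))
    tokens = [f"w{i}" for i in rng.choice(spec.vocab_size, size=n_words, p=probs)]
    planted = rng.random() < signal_rate
    if planted:
        sig = spec.signal_tokens[int(rng.integers(len(spec.signal_tokens)))]
        tokens[int(rng.integers(n_words))] = sig
        if counter:
            ctr = COUNTER_TOKENS[int(rng.integers(len(COUNTER_TOKENS)))]
            tokens.append(ctr)
    text = " ".join(tokens).capitalize() + "."
    return text, planted


def _make_document(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    probs: np.ndarray,
    pmid: str,
    label: str,
    signal_rate: float,
    counter: bool = False,
    force_signal: bool = False,
) -> Document:
    lo, hi = spec.sentences_per_doc
    n_sent = int(rng.integers(lo, hi + 1))
    sentences = []
    any_planted = False
    for _ in range(n_sent):
        text, planted = _sentence(rng, spec, probs, signal_rate, counter=counter)
        any_planted |= planted
        sentences.append(text)
    if force_signal and not any_planted:
        text, _ = _sentence(rng, spec, probs, 1.0, counter=counter)
        sentences[-1] = text
    return Document(
        pmid=pmid,
        title=sentences[0],
        abstract=" ".join(sentences[1:]),
        label=label,
    )


def generate_corpus(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> list[Document]:
    """Generate a labeled corpus; optionally write it in both dialects.

    Exactly ``round(n_docs * positive_fraction)`` documents are positive
    before label noise; noise then flips each label independently with
    probability ``label_noise``.  Deterministic given ``spec.seed``.  When
    ``out_dir`` is given, ``corpus.json`` (JSON dialect), ``corpus.xml``
    (XML dialect) and ``truth.tsv`` are written there.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = _zipf_probs(spec.vocab_size)
    n_pos = round(spec.n_docs * spec.positive_fraction)
    labels = np.array([POSITIVE] * n_pos + [NEGATIVE] * (spec.n_docs - n_pos))
    rng.shuffle(labels)
    docs = []
    for i, label in enumerate(labels):
        rate = spec.signal_rate_pos if label == POSITIVE else spec.signal_rate_neg
        doc = _make_document(rng, spec, probs, pmid=f"{7000000 + i}", label=str(label), signal_rate=rate)
        if spec.label_noise > 0.0 and rng.random() < spec.label_noise:
            doc = replace(doc, label=POSITIVE if doc.label == NEGATIVE else NEGATIVE)
        docs.append(doc)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pm_json(docs, out / "corpus.json")
        write_bc_xml(docs, out / "corpus.xml")
        write_tsv(docs, out / "truth.tsv")
    return docs


def generate_hard_negatives(spec: SyntheticSpec) -> list[Document]:
    """Negatives that carry the positive keywords plus a counter-indicator.

    Every document contains at least one signal token (planted at the
    *positive* rate), each planted sentence also carries a counter token,
    and all labels are negative — mimicking near-miss articles that mention
    the relevance keywords without describing the relevant relation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    probs = _zipf_probs(spec.vocab_size)
    return [
        _make_document(
            rng,
            spec,
            probs,
            pmid=f"{8000000 + i}",
            label=NEGATIVE,
            signal_rate=spec.signal_rate_pos,
            counter=True,
            force_signal=True,
        )
        for i in range(spec.n_docs)
    ]
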