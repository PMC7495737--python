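"""Scaled dot-product attention, multi-head attention and the two-level
(word, then sentence) hierarchical encoder.

These are the reference NumPy implementations of the attention stages: the
trainable model mirrors them on the autodiff graph, and the test suite holds
the two routes together.  Masked (pad) key positions are excluded by adding a
large negative constant to their logits before the softmax, so every weight
row is a distribution over real positions only.

After word-level self-attention a sentence is summarized as the masked mean
of its attended token vectors — a parameter-free pooling that preserves the
attention reweighting.  No positional encoding, residual connections or layer
normalization are used: each level is a single multi-head self-attention
layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MASK_NEG = -1e9  # additive logit for masked key positions


@dataclass
class AttentionParams:
    """Projection matrices for one multi-head self-attention layer.

    ``wq``/``wk`` have shape [h, d_model, d_k], ``wv`` [h, d_model, d_v] and
    the output projection ``wo`` [h*d_v, d_model].
    """

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray

    @property
    def n_heads(self) -> int:
        return self.wq.shape[0]

    @property
    def d_k(self) -> int:
        return self.wq.shape[2]

    @property
    def d_v(self) -> int:
        return self.wv.shape[2]

    @property
    def d_model(self) -> int:
        return self.wq.shape[1]

    def validate(self) -> None:
        h, dm, dk = self.wq.shape
        if self.wk.shape != (h, dm, dk):
            raise ValueError("wk shape inconsistent with wq")
        if self.wv.shape[:2] != (h, dm):
            raise ValueError("wv shape inconsistent with wq")
        if self.wo.shape != (h * self.wv.shape[2], dm):
            raise ValueError("wo must map h*d_v -> d_model")
        for m in (self.wq, self.wk, self.wv, self.wo):
            if not np.all(np.isfinite(m)):
                raise ValueError("non-finite attention parameters")

    @classmethod
    def init(
        cls, d_model: int, n_heads: int, d_k: int, d_v: int, rng: np.random.Generator
    ) -> "AttentionParams":
        """Glorot-uniform initialization of all projections."""

        def glorot(shape):
            fan_in, fan_out = shape[-2], shape[-1]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        return cls(
            wq=glorot((n_heads, d_model, d_k)),
            wk=glorot((n_heads, d_model, d_k)),
            wv=glorot((n_heads, d_model, d_v)),
            wo=glorot((n_heads * d_v, d_model)),
        )


@dataclass
class HierarchicalConfig:
    """Head counts and per-head dimensions for the two attention levels."""

    word_heads: int = 8
    word_dim: int = 32
    sent_heads: int = 8
    sent_dim: int = 32

    def validate(self) -> None:
        for name in ("word_heads", "word_dim", "sent_heads", "sent_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def masked_softmax(logits: np.ndarray, mask: np.ndarray | None, axis: int = -1):
    """Row softmax with masked positions forced to zero weight."""
    if mask is not None:
        logits = np.where(mask, logits, logits + MASK_NEG)
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """softmax(Q Kᵀ / sqrt(d_k)) V with pad keys masked out.

    Returns ``(output [n, d_v], weights [n, m])``; each weight row sums to 1
    over unmasked key positions.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must have the same number of positions")
    for a in (Q, K, V):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite attention inputs")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("attention over fully masked keys is undefined")
    d_k = Q.shape[-1]
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    # the key mask [m] broadcasts across query rows
    weights = masked_softmax(logits, mask)
    out = weights @ V
    return out, weights


def multi_head_attention(
    X: np.ndarray,
    params: AttentionParams,
    mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Multi-head self-attention: per-head projections, concat, output map.

    ``X`` is [n, d_model]; queries, keys and values are all projections of
    ``X``.  With ``return_weights`` the per-head weight matrices
    [h, n, n] are returned alongside the [n, d_model] output.
    """
    X = np.asarray(X, dtype=np.float64)
    params.validate()
    if X.ndim != 2 or X.shape[1] != params.d_model:
        raise ValueError(
            f"X must be [n, d_model={params.d_model}], got {X.shape}"
        )
    heads = []
    all_weights = []
    for i in range(params.n_heads):
        out, w = scaled_dot_attention(
            X @ params.wq[i], X @ params.wk[i], X @ params.wv[i], mask=mask
        )
        heads.append(out)
        all_weights.append(w)
    result = np.concatenate(heads, axis=-1) @ params.wo
    if return_weights:
        return result, np.stack(all_weights)
    return result


def masked_mean(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean of the rows of X selected by mask (>=1 true entry required)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("masked_mean over an empty selection")
    return X[mask].mean(axis=0)


def encode_words(
    embedded_sentence: np.ndarray,
    params: AttentionParams,
    mask: np.ndarray,
) -> np.ndarray:
    """Word-level self-attention + masked mean -> one sentence vector.

    An all-pad sentence yields the zero vector (flagged downstream by the
    sentence mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(params.d_model)
    attended = multi_head_attention(embedded_sentence, params, mask=mask)
    return masked_mean(attended, mask)


def encode_sentences(
    sentence_vectors: np.ndarray,
    params: AttentionParams,
    sent_mask: np.ndarray,
) -> np.ndarray:
    """Sentence-level self-attention over the sentence vectors.

    Returns the full attended sequence (consumed by the convolution stage)
    with pad-sentence rows zeroed.
    """
    sent_mask = np.asarray(sent_mask, dtype=bool)
    if not sent_mask.any():
        raise ValueError("document with no real sentences")
    attended = multi_head_attention(sentence_vectors, params, mask=sent_mask)
    return attended * sent_mask[:, None]


def hierarchical_encode(
    embedded: np.ndarray,
    mask: np.ndarray,
    word_params: AttentionParams,
    sent_params: AttentionParams,
) -> np.ndarray:
    """Full two-level encoder for one document.

    ``embedded`` is [max_sentences, max_words, d_model] with token mask of
    the same leading shape; the result is the attended sentence sequence
    [max_sentences, d_model].
    """
    sent_vecs = np.stack(
        [
            encode_words(embedded[s], word_params, mask[s])
            for s in range(embedded.shape[0])
        ]
    )
    return encode_sentences(sent_vecs, sent_params, mask.any(axis=1))


def export_attention_weights(tok_doc, state) -> list[dict]:
    """Serialize per-head word-word and sentence-sentence attention weights.

    ``state`` is a trained or initialized model state exposing ``embedding``,
    ``vocab``, ``word_attention`` and ``sent_attention``.  Returns one record
    per (level, head, sentence) as ``{pmid, level, head, sentence_index,
    tokens, weights}`` — ready for JSON-lines dumping and plotting.
    """
    records: list[dict] = []
    emb = state.embedding
    vocab = state.vocab
    sent_vecs = []
    for s_idx, sentence in enumerate(tok_doc.sentences):
        ids = np.array([vocab.index(t) for t in sentence])
        X = emb[ids]
        mask = np.ones(len(sentence), dtype=bool)
        _, weights = multi_head_attention(
            X, state.word_attention, mask=mask, return_weights=True
        )
        for h in range(weights.shape[0]):
            records.append(
                {
                    "pmid": tok_doc.pmid,
                    "level": "word",
                    "head": h,
                    "sentence_index": s_idx,
                    "tokens": list(sentence),
                    "weights": weights[h].tolist(),
                }
            )
        sent_vecs.append(encode_words(X, state.word_attention, mask))
    sent_vecs = np.stack(sent_vecs)
    sent_mask = np.ones(len(tok_doc.sentences), dtype=bool)
    _, sweights = multi_head_attention(
        sent_vecs, state.sent_attention, mask=sent_mask, return_weights=True
    )
    for h in range(sweights.shape[0]):
        records.append(
            {
                "pmid": tok_doc.pmid,
                "level": "sentence",
                "head": h,
                "sentence_index": -1,
                "tokens": [f"s{i}" for i in range(len(tok_doc.sentences))],
                "weights": sweights[h].tolist(),
            }
        )
    return records
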