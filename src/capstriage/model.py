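"""The hierarchical attention-based capsule classifier: assembly and training.

Pipeline (the ``full`` architecture):

    embedding -> dropout -> word-level multi-head self-attention (masked mean
    pooling to sentence vectors) -> sentence-level multi-head self-attention
    -> parallel convolutions (windows 3/4/5, 128 maps each) -> primary
    capsules (squashed feature groups) -> class capsules via dynamic routing
    -> dense hidden layer -> dropout -> dense softmax over {negative,
    positive}.

Training minimizes categorical cross-entropy with Adam; 10% of the training
documents are held out as a development split and the parameters from the
best-dev-F1 epoch are returned.  Everything is reproducible from the config
seed.

The ablation architectures used in the component-contribution experiments
are built from the same configuration schema: ``cnn`` (convolutions +
stride-2 max pooling), ``capsule`` (convolutions + capsules, no attention),
``selfatt`` (word-level attention + convolutions), ``hieratt`` (both
attention levels + convolutions, max pooling instead of capsules) and
``full``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .attention import MASK_NEG, AttentionParams
from .capsule import SQUASH_EPS
from .corpus_io import (
    IndexedBatch,
    TokenizedDocument,
    Vocabulary,
    index_batch,
    random_embeddings,
)
from .evaluation import evaluate

ABLATION_ARCHS = ("cnn", "capsule", "selfatt", "hieratt", "full")

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """All hyperparameters of the model and its training run.

    Defaults are the corpus-scale settings: 200-dim embeddings, a 100-unit
    hidden layer, batch size 128, 50 epochs, dropout 0.5 (embeddings) and
    0.8 (pre-output), kernels 3/4/5 with 128 feature maps, 8 heads of
    dimension 32 at both attention levels, 32-dim capsules with 3 routing
    iterations, and Adam at learning rate 0.01.
    """

    embed_dim: int = 200
    hidden: int = 100
    batch_size: int = 128
    epochs: int = 50
    dropout_embed: float = 0.5
    dropout_output: float = 0.8
    conv_windows: tuple[int, ...] = (3, 4, 5)
    conv_feature_maps: int = 128
    word_heads: int = 8
    word_dim: int = 32
    sent_heads: int = 8
    sent_dim: int = 32
    capsule_dim: int = 32
    n_class_capsules: int = 10
    routing_iters: int = 3
    learning_rate: float = 0.01
    max_sentences: int = 30
    max_words: int = 50
    min_sentence_tokens: int = 2
    min_count: int = 1
    dev_fraction: float = 0.1
    arch: str = "full"
    seed: int = 0

    def validate(self) -> None:
        if self.arch not in ABLATION_ARCHS:
            raise ValueError(f"arch must be one of {ABLATION_ARCHS}")
        for name in (
            "embed_dim",
            "hidden",
            "batch_size",
            "epochs",
            "conv_feature_maps",
            "word_heads",
            "word_dim",
            "sent_heads",
            "sent_dim",
            "capsule_dim",
            "n_class_capsules",
            "routing_iters",
            "max_sentences",
            "max_words",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout_embed", "dropout_output"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        total = len(self.conv_windows) * self.conv_feature_maps
        if self.arch in ("full", "capsule") and total % self.capsule_dim:
            raise ValueError(
                f"total feature maps {total} must be divisible by capsule_dim "
                f"{self.capsule_dim}"
            )

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """Test-scale configuration: same architecture, small dimensions.

        Used for desk-scale training runs (synthetic corpora, learnability
        and determinism checks) where the corpus-scale widths are
        unnecessary.
        """
        base = dict(
            embed_dim=32,
            hidden=32,
            batch_size=8,
            epochs=10,
            learning_rate=1e-3,
            dropout_embed=0.5,
            dropout_output=0.5,
            conv_windows=(2, 3),
            conv_feature_maps=16,
            word_heads=2,
            word_dim=8,
            sent_heads=2,
            sent_dim=8,
            capsule_dim=8,
            n_class_capsules=4,
            routing_iters=3,
            max_sentences=8,
            max_words=14,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["conv_windows"] = list(self.conv_windows)
        Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "conv_windows" in data:
            data["conv_windows"] = tuple(data["conv_windows"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def ablation_config(arch: str, base: ModelConfig) -> ModelConfig:
    """Derive one of the component-ablation configurations from a base config.

    The ``cnn`` baseline uses two kernel widths (3 and 8) with stride-2 max
    pooling, as in the traditional text-CNN reference configuration; the
    other architectures keep the base kernels.
    """
    if arch not in ABLATION_ARCHS:
        raise ValueError(f"arch must be one of {ABLATION_ARCHS}")
    cfg = dataclasses.replace(base, arch=arch)
    if arch == "cnn":
        cfg = dataclasses.replace(cfg, conv_windows=(3, 8))
    cfg.validate()
    return cfg


@dataclass
class ModelState:
    """All trainable tensors plus the bookkeeping needed to reuse them."""

    config: ModelConfig
    vocab: Vocabulary
    params: dict[str, ad.Tensor]
    epoch: int = 0
    loss_history: list[dict] = field(default_factory=list)

    # NumPy views used by the reference/export code paths ------------------

    @property
    def embedding(self) -> np.ndarray:
        return self.params["embedding"].data

    @property
    def word_attention(self) -> AttentionParams:
        return AttentionParams(
            wq=self.params["word_wq"].data,
            wk=self.params["word_wk"].data,
            wv=self.params["word_wv"].data,
            wo=self.params["word_wo"].data,
        )

    @property
    def sent_attention(self) -> AttentionParams:
        return AttentionParams(
            wq=self.params["sent_wq"].data,
            wk=self.params["sent_wk"].data,
            wv=self.params["sent_wv"].data,
            wo=self.params["sent_wo"].data,
        )

    def parameter_snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_snapshot(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in snap.items():
            self.params[k].data = v.copy()


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[-2] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def _head_input_dim(config: ModelConfig) -> int:
    total_maps = len(config.conv_windows) * config.conv_feature_maps
    if config.arch in ("full", "capsule"):
        return config.n_class_capsules * config.capsule_dim
    if config.arch == "cnn":
        return ((config.max_sentences + 1) // 2) * total_maps
    return total_maps  # global max pooling


def build_state(
    config: ModelConfig,
    vocab: Vocabulary,
    embedding: np.ndarray | None = None,
) -> ModelState:
    """Initialize every parameter tensor (seeded Glorot uniform)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    de = config.embed_dim
    if embedding is None:
        embedding = random_embeddings(vocab, de, seed=config.seed)
    if embedding.shape != (len(vocab), de):
        raise ValueError(
            f"embedding shape {embedding.shape} does not match "
            f"vocabulary {len(vocab)} x embed_dim {de}"
        )
    params: dict[str, ad.Tensor] = {
        "embedding": ad.Tensor(embedding.copy(), requires_grad=True)
    }
    for prefix, h, dim in (
        ("word", config.word_heads, config.word_dim),
        ("sent", config.sent_heads, config.sent_dim),
    ):
        params[f"{prefix}_wq"] = ad.Tensor(_glorot(rng, (h, de, dim)), requires_grad=True)
        params[f"{prefix}_wk"] = ad.Tensor(_glorot(rng, (h, de, dim)), requires_grad=True)
        params[f"{prefix}_wv"] = ad.Tensor(_glorot(rng, (h, de, dim)), requires_grad=True)
        params[f"{prefix}_wo"] = ad.Tensor(_glorot(rng, (h * dim, de)), requires_grad=True)
    for w in config.conv_windows:
        params[f"conv_w{w}"] = ad.Tensor(
            _glorot(rng, (w * de, config.conv_feature_maps)), requires_grad=True
        )
        params[f"conv_b{w}"] = ad.Tensor(
            np.zeros(config.conv_feature_maps), requires_grad=True
        )
    if config.arch in ("full", "capsule"):
        total_maps = len(config.conv_windows) * config.conv_feature_maps
        n_child_types = total_maps // config.capsule_dim
        params["caps_w"] = ad.Tensor(
            _glorot(
                rng,
                (
                    n_child_types,
                    config.n_class_capsules,
                    config.capsule_dim,
                    config.capsule_dim,
                ),
            ),
            requires_grad=True,
        )
    d_in = _head_input_dim(config)
    params["dense_w1"] = ad.Tensor(_glorot(rng, (d_in, config.hidden)), requires_grad=True)
    params["dense_b1"] = ad.Tensor(np.zeros(config.hidden), requires_grad=True)
    params["dense_w2"] = ad.Tensor(_glorot(rng, (config.hidden, 2)), requires_grad=True)
    params["dense_b2"] = ad.Tensor(np.zeros(2), requires_grad=True)
    return ModelState(config=config, vocab=vocab, params=params)


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def _graph_squash(s: ad.Tensor) -> ad.Tensor:
    sq = (s * s).sum(axis=-1, keepdims=True)
    norm = (sq + SQUASH_EPS).sqrt()
    return s * sq / ((1.0 + sq) * norm)


def _graph_mha(
    X: ad.Tensor,
    mask: np.ndarray,
    wq: ad.Tensor,
    wk: ad.Tensor,
    wv: ad.Tensor,
    wo: ad.Tensor,
) -> ad.Tensor:
    """Batched multi-head self-attention.

    ``X`` is [N, L, d_model], ``mask`` [N, L] boolean over key positions.
    Fully masked rows degrade to a uniform (and later discarded) weighting.
    """
    n, length, _ = X.shape
    h, _, dk = wq.shape
    X4 = X.reshape(n, 1, length, X.shape[-1])
    Q = X4 @ wq  # [N, h, L, dk]
    K = X4 @ wk
    V = X4 @ wv
    logits = (Q @ K.swapaxes(-1, -2)) / np.sqrt(dk)
    additive = np.where(mask, 0.0, MASK_NEG)[:, None, None, :]
    weights = (logits + additive).softmax(axis=-1)
    out = weights @ V  # [N, h, L, dv]
    out = out.swapaxes(1, 2).reshape(n, length, -1)
    return out @ wo


def _dropout(
    X: ad.Tensor, p: float, train_mode: bool, rng: np.random.Generator | None
) -> ad.Tensor:
    if not train_mode or p <= 0.0:
        return X
    if rng is None:
        raise ValueError("train-mode dropout requires an rng")
    keep = (rng.random(X.shape) >= p) / (1.0 - p)
    return X * keep


def forward(
    batch: IndexedBatch,
    state: ModelState,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> ad.Tensor:
    """Class probability matrix [n_docs, 2]; rows sum to 1.

    Deterministic in eval mode; dropout (embedding-side and pre-output) is
    active only when ``train_mode``.
    """
    cfg = state.config
    p = state.params
    if int(batch.ids.max(initial=0)) >= len(state.vocab):
        raise ValueError("batch indexed with an incompatible vocabulary")
    B, S, W = batch.ids.shape
    mask = batch.mask
    smask = batch.sentence_mask()  # [B, S]

    E = ad.embedding(p["embedding"], batch.ids)  # [B, S, W, de]
    E = _dropout(E, cfg.dropout_embed, train_mode, rng)

    token_mask = mask.reshape(B * S, W)
    tokf = token_mask.astype(np.float64)[:, :, None]
    counts = np.maximum(tokf.sum(axis=1), 1.0)  # [B*S, 1]
    E2 = E.reshape(B * S, W, cfg.embed_dim)

    if cfg.arch in ("full", "hieratt", "selfatt"):
        attended = _graph_mha(
            E2, token_mask, p["word_wq"], p["word_wk"], p["word_wv"], p["word_wo"]
        )
    else:  # no word-level attention: pool the raw embeddings
        attended = E2
    sent_vecs = (attended * tokf).sum(axis=1) / counts  # masked mean, [B*S, de]
    H = sent_vecs.reshape(B, S, cfg.embed_dim)

    if cfg.arch in ("full", "hieratt"):
        H = _graph_mha(H, smask, p["sent_wq"], p["sent_wk"], p["sent_wv"], p["sent_wo"])
    H = H * smask.astype(np.float64)[:, :, None]  # zero pad-sentence rows

    conv_outs = []
    for w in cfg.conv_windows:
        left, right = (w - 1) // 2, w // 2
        Hp = ad.pad_axis(H, 1, left, right)
        windows = ad.concat([Hp[:, k : k + S, :] for k in range(w)], axis=-1)
        conv_outs.append((windows @ p[f"conv_w{w}"] + p[f"conv_b{w}"]).relu())
    F = ad.concat(conv_outs, axis=-1)  # [B, S, total_maps]
    total_maps = len(cfg.conv_windows) * cfg.conv_feature_maps

    if cfg.arch in ("full", "capsule"):
        n_ct = total_maps // cfg.capsule_dim
        dc = cfg.capsule_dim
        u = _graph_squash(F.reshape(B, S, n_ct, dc))
        # û_{j|i} = W_{type(i), j} u_i, transforms shared across positions
        w6 = p["caps_w"].reshape(1, 1, n_ct, cfg.n_class_capsules, dc, dc)
        u6 = u.reshape(B, S, n_ct, 1, dc, 1)
        u_hat = (w6 @ u6).reshape(B, S * n_ct, cfg.n_class_capsules, dc)
        v = _graph_routing(u_hat, cfg.routing_iters)
        feat = v.reshape(B, cfg.n_class_capsules * cfg.capsule_dim)
    elif cfg.arch == "cnn":
        # stride-2 max pooling over sentence positions, then flatten
        S2 = S + (S % 2)
        Fp = ad.pad_axis(F, 1, 0, S2 - S) if S2 != S else F
        pooled = Fp.reshape(B, S2 // 2, 2, total_maps).max(axis=2)
        feat = pooled.reshape(B, (S2 // 2) * total_maps)
    else:  # hieratt / selfatt: global max pooling over positions
        feat = F.max(axis=1)

    hidden = (feat @ p["dense_w1"] + p["dense_b1"]).relu()
    hidden = _dropout(hidden, cfg.dropout_output, train_mode, rng)
    logits = hidden @ p["dense_w2"] + p["dense_b2"]
    return logits.softmax(axis=-1)


def _graph_routing(u_hat: ad.Tensor, r: int) -> ad.Tensor:
    """Differentiable routing-by-agreement on [B, n_child, n_parent, dp]."""
    B, n_child, n_parent, dp = u_hat.shape
    z = ad.Tensor(np.zeros((B, n_child, n_parent)))
    for it in range(r):
        c = z.softmax(axis=-1)
        s = (c.reshape(B, n_child, n_parent, 1) * u_hat).sum(axis=1)
        v = _graph_squash(s)  # [B, n_parent, dp]
        if it < r - 1:
            z = z + (u_hat * v.reshape(B, 1, n_parent, dp)).sum(axis=-1)
    return v


def cross_entropy(probs: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    """Mean categorical cross-entropy against integer labels."""
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0:
        raise ValueError("training requires labeled documents (labels 0/1)")
    n = probs.shape[0]
    # clip away from exact 0 for the log
    picked = probs[np.arange(n), labels]
    return -((picked + 1e-12).log().mean())


def predict(batch: IndexedBatch, state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probability of the predicted class) per document.

    Argmax with ties broken toward class 0 (negative); deterministic and
    invariant to batch partitioning.
    """
    probs = forward(batch, state, train_mode=False).data
    labels = (probs[:, 1] > probs[:, 0]).astype(np.int64)
    return labels, probs[np.arange(len(labels)), labels]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, ad.Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _slice_batch(batch: IndexedBatch, idx: np.ndarray) -> IndexedBatch:
    return IndexedBatch(
        ids=batch.ids[idx],
        labels=batch.labels[idx],
        mask=batch.mask[idx],
        pmids=[batch.pmids[i] for i in idx] if batch.pmids else [],
    )


def dev_split(
    batch: IndexedBatch, fraction: float, seed: int
) -> tuple[IndexedBatch, IndexedBatch]:
    """Seeded random split into (train, dev); dev gets ceil(fraction * n)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(batch.n_docs)
    n_dev = max(1, int(np.ceil(fraction * batch.n_docs)))
    return _slice_batch(batch, order[n_dev:]), _slice_batch(batch, order[:n_dev])


def train_model(
    batch: IndexedBatch,
    config: ModelConfig,
    vocab: Vocabulary,
    embedding: np.ndarray | None = None,
    dev: IndexedBatch | None = None,
    log_path: str | Path | None = None,
) -> ModelState:
    """Train on a labeled indexed corpus; return the best-dev-epoch state.

    When no dev batch is supplied, ``config.dev_fraction`` (default 10%) of
    the documents are split off for development.  The returned parameters
    are those of the epoch with the lowest development cross-entropy (the
    selection criterion matches the training objective; selecting on dev F1
    instead degenerates on signal-free data, where F1 rewards all-positive
    predictors).  Per-epoch records ``{epoch, train_loss, dev_loss, dev_P,
    dev_R, dev_F1, seconds}`` are stored in ``state.loss_history`` and
    appended to ``log_path`` (JSON lines) when given.  Raises on unlabeled
    documents or a NaN loss.
    """
    config.validate()
    if (batch.labels < 0).any():
        raise ValueError("training corpus contains unlabeled documents")
    if dev is None:
        batch, dev = dev_split(batch, config.dev_fraction, config.seed)
    state = build_state(config, vocab, embedding=embedding)
    opt = Adam(state.params, config.learning_rate)
    shuffle_rng = np.random.default_rng((config.seed, 1))
    dropout_rng = np.random.default_rng((config.seed, 2))
    best_dev_loss = np.inf
    best_snapshot = state.parameter_snapshot()
    log_fh = open(log_path, "a", encoding="utf-8") if log_path else None
    try:
        for epoch in range(1, config.epochs + 1):
            tic = time.perf_counter()
            order = shuffle_rng.permutation(batch.n_docs)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, batch.n_docs, config.batch_size):
                idx = order[start : start + config.batch_size]
                mini = _slice_batch(batch, idx)
                opt.zero_grad()
                probs = forward(state=state, batch=mini, train_mode=True, rng=dropout_rng)
                loss = cross_entropy(probs, mini.labels)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(batch starting at {start}); lower the learning rate"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            dev_probs = forward(dev, state, train_mode=False)
            dev_loss = float(cross_entropy(dev_probs, dev.labels).data)
            pred = (dev_probs.data[:, 1] > dev_probs.data[:, 0]).astype(np.int64)
            res = evaluate(dev.labels, pred)
            record = {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "dev_loss": dev_loss,
                "dev_P": res.precision,
                "dev_R": res.recall,
                "dev_F1": res.f1,
                "seconds": time.perf_counter() - tic,
            }
            state.loss_history.append(record)
            state.epoch = epoch
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if dev_loss < best_dev_loss:
                best_dev_loss = dev_loss
                best_snapshot = state.parameter_snapshot()
    finally:
        if log_fh:
            log_fh.close()
    state.load_snapshot(best_snapshot)
    return state


def prepare_corpus(
    tokenized: list[TokenizedDocument],
    config: ModelConfig,
    vocab: Vocabulary | None = None,
    allow_unlabeled: bool = False,
) -> tuple[IndexedBatch, Vocabulary]:
    """Index a tokenized corpus under the config's grid limits."""
    from .corpus_io import build_vocabulary

    if vocab is None:
        vocab = build_vocabulary(tokenized, min_count=config.min_count)
    batch = index_batch(
        tokenized,
        vocab,
        max_sentences=config.max_sentences,
        max_words=config.max_words,
        allow_unlabeled=allow_unlabeled,
    )
    return batch, vocab


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Single-file archive: versioned header, config, vocabulary, parameters."""
    header = {
        "version": CHECKPOINT_VERSION,
        "config": {
            **dataclasses.asdict(state.config),
            "conv_windows": list(state.config.conv_windows),
        },
        "vocab": state.vocab.tokens(),
        "epoch": state.epoch,
        "loss_history": state.loss_history,
    }
    arrays = {k: v.data for k, v in state.params.items()}
    np.savez(path, __header__=json.dumps(header), **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["__header__"]))
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        cfg_data = header["config"]
        cfg_data["conv_windows"] = tuple(cfg_data["conv_windows"])
        config = ModelConfig(**cfg_data)
        vocab = Vocabulary(token_to_index={t: i for i, t in enumerate(header["vocab"])})
        params = {
            k: ad.Tensor(npz[k].copy(), requires_grad=True)
            for k in npz.files
            if k != "__header__"
        }
    state = ModelState(config=config, vocab=vocab, params=params)
    state.epoch = header["epoch"]
    state.loss_history = header["loss_history"]
    return state
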