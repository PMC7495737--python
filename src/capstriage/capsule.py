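"""Capsule layers: squashing, prediction vectors and routing-by-agreement.

A capsule's activity is a vector whose length (kept in [0, 1) by the squash
nonlinearity) encodes feature presence and whose orientation encodes feature
attributes.  Parent capsules receive a coupling-weighted sum of per-child
prediction vectors; the coupling coefficients are a softmax over parents per
child, iteratively sharpened toward parents whose output agrees with the
child's prediction (dynamic routing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SQUASH_EPS = 1e-8  # regularizes the norm at s = 0


@dataclass
class CapsuleParams:
    """Child->parent transforms and routing geometry.

    ``w`` has shape [n_child_types, n_parent, dim_parent, dim_child]; the
    transform is shared across spatial positions per (child type, parent)
    pair.
    """

    w: np.ndarray
    routing_iters: int = 3

    @property
    def n_child_types(self) -> int:
        return self.w.shape[0]

    @property
    def n_parent(self) -> int:
        return self.w.shape[1]

    @property
    def dim_parent(self) -> int:
        return self.w.shape[2]

    @property
    def dim_child(self) -> int:
        return self.w.shape[3]

    def validate(self) -> None:
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite capsule transforms")

    @classmethod
    def init(
        cls,
        n_child_types: int,
        n_parent: int,
        dim_parent: int,
        dim_child: int,
        routing_iters: int,
        rng: np.random.Generator,
    ) -> "CapsuleParams":
        limit = np.sqrt(6.0 / (dim_child + dim_parent))
        return cls(
            w=rng.uniform(
                -limit, limit, size=(n_child_types, n_parent, dim_parent, dim_child)
            ),
            routing_iters=routing_iters,
        )


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """v = (‖s‖²/(1+‖s‖²)) · s/‖s‖ along `axis`; ‖v‖ ∈ [0, 1).

    Direction is preserved; the zero vector maps to itself (the norm is
    regularized by a small epsilon).
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite capsule input")
    sq = (s**2).sum(axis=axis, keepdims=True)
    norm = np.sqrt(sq + SQUASH_EPS)
    return s * sq / ((1.0 + sq) * norm)


def prediction_vectors(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """û_{j|i} = W_ij · u_i for every (child i, parent j) pair.

    ``u`` is [n_child, dim_child]; ``w`` is [n_child, n_parent, dim_parent,
    dim_child]; result is [n_child, n_parent, dim_parent].
    """
    u = np.asarray(u, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if u.ndim != 2 or w.ndim != 4 or w.shape[0] != u.shape[0] or w.shape[3] != u.shape[1]:
        raise ValueError(
            f"inconsistent shapes: u {u.shape}, w {w.shape} "
            "(expected [n_child, dim_child] and [n_child, n_parent, dim_parent, dim_child])"
        )
    return np.einsum("ijpd,id->ijp", w, u)


def routing_softmax(z: np.ndarray) -> np.ndarray:
    """Coupling coefficients c_ij = exp(z_ij)/Σ_k exp(z_ik) over parents."""
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def dynamic_routing(
    u_hat: np.ndarray, r: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Routing-by-agreement over prediction vectors.

    ``u_hat`` is [n_child, n_parent, dim_parent].  Logits start at zero;
    each iteration computes couplings, parent pre-activations and squashed
    outputs, then raises the logit of every (child, parent) pair by the
    scalar agreement û·v (skipped after the final iteration).  Returns the
    final parent outputs [n_parent, dim_parent] and couplings
    [n_child, n_parent].
    """
    u_hat = np.asarray(u_hat, dtype=np.float64)
    if not np.all(np.isfinite(u_hat)):
        raise ValueError("non-finite prediction vectors")
    if r < 1:
        raise ValueError("routing requires at least one iteration")
    n_child, n_parent, _ = u_hat.shape
    z = np.zeros((n_child, n_parent))
    for it in range(r):
        c = routing_softmax(z)
        s = np.einsum("ij,ijp->jp", c, u_hat)
        v = squash(s)
        if it < r - 1:
            z = z + np.einsum("ijp,jp->ij", u_hat, v)
    return v, c


def primary_capsules(features: np.ndarray, dim_child: int) -> np.ndarray:
    """Group scalar features into dim_child-vectors and squash them.

    ``features`` is [n_positions, n_features]; n_features must be divisible
    by dim_child.  Returns [n_positions * n_features/dim_child, dim_child].
    """
    features = np.asarray(features, dtype=np.float64)
    n_pos, n_feat = features.shape
    if n_feat % dim_child != 0:
        raise ValueError(
            f"feature count {n_feat} not divisible by capsule dimension "
            f"{dim_child}; adjust feature_maps or dim_child in the config"
        )
    children = features.reshape(n_pos * (n_feat // dim_child), dim_child)
    return squash(children)


def capsule_layer(
    u: np.ndarray, params: CapsuleParams, n_positions: int
) -> tuple[np.ndarray, np.ndarray]:
    """Full child->parent pass with spatially shared transforms.

    ``u`` is [n_positions * n_child_types, dim_child] (child types cycling
    fastest, as produced by :func:`primary_capsules`).  The transform for a
    child is looked up by its type, so parameters are shared across
    positions.
    """
    params.validate()
    n_child = u.shape[0]
    types = np.tile(np.arange(params.n_child_types), n_positions)
    if types.shape[0] != n_child:
        raise ValueError("child count inconsistent with positions x child types")
    w_full = params.w[types]  # [n_child, n_parent, dim_parent, dim_child]
    u_hat = prediction_vectors(u, w_full)
    return dynamic_routing(u_hat, params.routing_iters)
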