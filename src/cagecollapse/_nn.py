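"""Dense/graph network primitives: batched forward, backprop, Adam.

The encoder mirrors the message-passing update

    X^0       = relu(X_raw @ W_in)
    X^{l+1}_i = relu(W^l (X^l_i + sum_{j in N(i)} order(i,j) X^l_j))

with a single learnable matrix per layer and no bias terms, so a zero
feature matrix propagates to a zero molecule vector regardless of graph
topology.  Molecule vectors are sums over atom embeddings (sum pooling),
which makes precursor-level attribution additive over atoms.  The
classifier head is an ordinary biased MLP ending in two logits.

Batching: atoms of many molecules are stacked into one matrix with a
block-diagonal sparse adjacency and a segment-id vector mapping atoms to
molecules; pooling and its adjoint are segment sums/gathers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "EncoderParams",
    "ClassifierParams",
    "init_encoder",
    "init_classifier",
    "stack_graphs",
    "encode_forward",
    "encode_backward",
    "mlp_forward",
    "mlp_backward",
    "softmax",
    "AdamState",
]


@dataclass
class EncoderParams:
    """Input projection + per-layer message-passing weights (no biases)."""

    w_in: np.ndarray                # (feature_dim, hidden)
    w_msg: list[np.ndarray]         # L matrices, each (hidden, hidden)

    def __post_init__(self) -> None:
        if len(self.w_msg) < 1:
            raise ValueError("encoder needs at least one message-passing layer")
        h = self.w_in.shape[1]
        for w in self.w_msg:
            if w.shape != (h, h):
                raise ValueError(
                    f"message weight shape {w.shape} inconsistent with hidden {h}"
                )

    @property
    def hidden_dim(self) -> int:
        return self.w_in.shape[1]

    def arrays(self) -> list[np.ndarray]:
        return [self.w_in, *self.w_msg]


@dataclass
class ClassifierParams:
    """Biased MLP over the concatenated cage fingerprint; 2 output neurons."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.weights[-1].shape[1] != 2:
            raise ValueError("output layer must have exactly 2 neurons")
        for w, b in zip(self.weights, self.biases):
            if b.shape != (w.shape[1],):
                raise ValueError("bias/weight shape mismatch")

    def arrays(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def init_encoder(
    rng: np.random.Generator, feature_dim: int, hidden_dim: int, n_layers: int
) -> EncoderParams:
    return EncoderParams(
        w_in=_he(rng, feature_dim, hidden_dim),
        w_msg=[_he(rng, hidden_dim, hidden_dim) for _ in range(n_layers)],
    )


def init_classifier(
    rng: np.random.Generator, input_dim: int, hidden_dims: tuple[int, ...]
) -> ClassifierParams:
    dims = [input_dim, *hidden_dims, 2]
    return ClassifierParams(
        weights=[_he(rng, a, b) for a, b in zip(dims[:-1], dims[1:])],
        biases=[np.zeros(b) for b in dims[1:]],
    )


def stack_graphs(
    features: list[np.ndarray], adjacencies: list[sparse.spmatrix]
) -> tuple[np.ndarray, sparse.csr_matrix, np.ndarray, int]:
    """Stack per-molecule feature matrices into one batch.

    Returns (X, A, seg, n_mol): stacked features, block-diagonal adjacency
    and the molecule index of each atom row.
    """
    if not features:
        raise ValueError("empty batch")
    X = np.vstack(features)
    A = sparse.block_diag(adjacencies, format="csr")
    seg = np.concatenate(
        [np.full(f.shape[0], m, dtype=np.intp) for m, f in enumerate(features)]
    )
    return X, A, seg, len(features)


def encode_forward(
    X: np.ndarray,
    A: sparse.csr_matrix,
    seg: np.ndarray,
    n_mol: int,
    enc: EncoderParams,
) -> tuple[np.ndarray, dict]:
    """Message-passing encoder; returns (molecule vectors, cache)."""
    if X.shape[1] != enc.w_in.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match encoder input "
            f"{enc.w_in.shape[0]}"
        )
    cache: dict = {"X": X, "A": A, "seg": seg, "pre": [], "H": [], "M": []}
    pre0 = X @ enc.w_in
    H = np.maximum(pre0, 0.0)
    cache["pre"].append(pre0)
    cache["H"].append(H)
    for w in enc.w_msg:
        M = H + A @ H
        pre = M @ w
        H = np.maximum(pre, 0.0)
        cache["M"].append(M)
        cache["pre"].append(pre)
        cache["H"].append(H)
    mol = np.zeros((n_mol, enc.hidden_dim))
    np.add.at(mol, seg, H)
    return mol, cache


def encode_backward(
    dmol: np.ndarray, cache: dict, enc: EncoderParams
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Adjoint of :func:`encode_forward`.

    Returns (dX, grads) with grads ordered as ``EncoderParams.arrays()``.
    """
    A = cache["A"]
    seg = cache["seg"]
    dH = dmol[seg]  # adjoint of sum pooling
    dw_msg = [np.zeros_like(w) for w in enc.w_msg]
    for layer in range(len(enc.w_msg) - 1, -1, -1):
        dpre = dH * (cache["pre"][layer + 1] > 0)
        dw_msg[layer] = cache["M"][layer].T @ dpre
        dM = dpre @ enc.w_msg[layer].T
        dH = dM + A.T @ dM  # A symmetric, kept explicit
    dpre0 = dH * (cache["pre"][0] > 0)
    dw_in = cache["X"].T @ dpre0
    dX = dpre0 @ enc.w_in.T
    return dX, [dw_in, *dw_msg]


def mlp_forward(V: np.ndarray, clf: ClassifierParams) -> tuple[np.ndarray, dict]:
    """ReLU MLP head; returns (logits, cache)."""
    cache: dict = {"acts": [V], "pre": []}
    H = V
    last = len(clf.weights) - 1
    for k, (w, b) in enumerate(zip(clf.weights, clf.biases)):
        pre = H @ w + b
        cache["pre"].append(pre)
        H = pre if k == last else np.maximum(pre, 0.0)
        cache["acts"].append(H)
    return H, cache


def mlp_backward(
    dlogits: np.ndarray, cache: dict, clf: ClassifierParams
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Adjoint of :func:`mlp_forward`; grads ordered as ``arrays()``."""
    dW = [np.zeros_like(w) for w in clf.weights]
    db = [np.zeros_like(b) for b in clf.biases]
    last = len(clf.weights) - 1
    dH = dlogits
    for k in range(last, -1, -1):
        dpre = dH if k == last else dH * (cache["pre"][k] > 0)
        dW[k] = cache["acts"][k].T @ dpre
        db[k] = dpre.sum(axis=0)
        dH = dpre @ clf.weights[k].T
    return dH, [*dW, *db]


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z) | np.isneginf(z)):
        raise ValueError("softmax received NaN or +inf logits")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class AdamState:
    """Adam optimiser state over a flat list of parameter arrays."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
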