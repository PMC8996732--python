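"""Cage shape-persistence classifier: shared GNN encoder + MLP head.

A cage is a pair (building-block SMILES, linker SMILES).  Both precursors
are encoded by one shared message-passing encoder into fixed-length neural
fingerprints, which are concatenated — building block first, linker second;
the order is semantic — and classified by a multi-layer network with a
two-neuron softmax output read as (p_collapsed, p_not_collapsed).

The encoder carries no bias terms, so a zero-feature "baseline cage"
always maps to the zero fingerprint and its prediction is controlled
entirely by the classifier head.  Training can append such baseline cages
to each epoch with half/half labels (``baseline_fraction``) to drive the
baseline prediction toward the uninformative 0.5 required by
integrated-gradients attribution.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import softmax  # noqa: F401  (public re-export)
from .chem import ELEMENT_VOCABULARY, AtomFeaturizer, MolecularGraph, parse_smiles

__all__ = ["CageCollapseClassifier", "CagePrediction", "softmax", "predict_cage"]

COLLAPSED = "collapsed"
NOT_COLLAPSED = "not collapsed"


@dataclass(frozen=True)
class CagePrediction:
    """Logits, class probabilities and the argmax label for one cage."""

    logits: tuple[float, float]          # (z_collapsed, z_not_collapsed)
    p_collapsed: float
    p_not_collapsed: float
    label: str

    def __post_init__(self) -> None:
        total = self.p_collapsed + self.p_not_collapsed
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


class CageCollapseClassifier(ClassifierMixin, BaseEstimator):
    """Predict whether a [4+6] organic cage collapses, from precursor SMILES.

    Parameters
    ----------
    hidden_dim : width of the atom embeddings / molecule fingerprints.
    n_message_layers : number of message-passing layers L (>= 1).
    classifier_hidden : hidden widths of the MLP head.
    learning_rate, n_epochs, batch_size : Adam training schedule.
    baseline_fraction : fraction of the training-set size appended each
        epoch as zero-feature baseline cages, labelled half collapsed /
        half not collapsed; 0 disables augmentation.
    classifier_hidden_biases : when False (default) only the output layer
        of the classifier carries biases.  The whole network is then
        positively homogeneous, so along the straight attribution path
        the logits are affine in the interpolation coordinate and the
        integrated-gradients completeness identity holds essentially
        exactly at any step count.  Set True for a conventional fully
        biased MLP head (completeness then holds only approximately).
    vocabulary : element vocabulary handed to the featurizer.
    random_state : seed; fixes initialisation, shuffling and augmentation.

    Attributes
    ----------
    classes_ : ndarray of the two class labels seen in ``y``.
    featurizer_ : AtomFeaturizer fitted on the training precursors only.
    encoder_, classifier_ : fitted parameter bundles.
    loss_curve_ : mean cross-entropy per epoch.
    """

    _estimator_type = "classifier"

    def __init__(
        self,
        hidden_dim: int = 64,
        n_message_layers: int = 2,
        classifier_hidden: tuple[int, ...] = (128, 128),
        learning_rate: float = 1e-3,
        n_epochs: int = 50,
        batch_size: int = 64,
        baseline_fraction: float = 0.1,
        classifier_hidden_biases: bool = False,
        vocabulary: tuple[str, ...] = ELEMENT_VOCABULARY,
        random_state: int = 0,
        verbose: bool = False,
    ):
        self.hidden_dim = hidden_dim
        self.n_message_layers = n_message_layers
        self.classifier_hidden = classifier_hidden
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.baseline_fraction = baseline_fraction
        self.classifier_hidden_biases = classifier_hidden_biases
        self.vocabulary = vocabulary
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #

    def fit(self, X, y) -> "CageCollapseClassifier":
        """Fit on cages ``X`` (n, 2 SMILES columns: building block, linker).

        ``y`` must contain exactly two classes; the "collapsed" label (or,
        for generic labels, the lexicographically larger one) is treated as
        the positive class.
        """
        pairs = self._validate_pairs(X)
        y = np.asarray(y, dtype=object)
        if len(y) != len(pairs):
            raise ValueError("X and y length mismatch")
        if len(pairs) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"training needs exactly 2 classes, got {list(self.classes_)}"
            )
        self.positive_class_ = (
            COLLAPSED if COLLAPSED in self.classes_ else self.classes_[-1]
        )
        # neuron 0 <-> positive (collapsed), neuron 1 <-> negative
        y_idx = np.where(y == self.positive_class_, 0, 1)

        if self.baseline_fraction < 0:
            raise ValueError("baseline_fraction must be >= 0")

        rng = np.random.default_rng(self.random_state)
        smiles_index, bb_ids, lk_ids = self._index_precursors(pairs)
        graphs = {s: parse_smiles(s) for s in smiles_index}
        self.featurizer_ = AtomFeaturizer(vocabulary=self.vocabulary).fit(
            graphs.values()
        )
        feats = [self.featurizer_.transform(graphs[s]) for s in smiles_index]
        adjs = [graphs[s].adjacency() for s in smiles_index]

        d = self.featurizer_.feature_dim
        self.encoder_ = _nn.init_encoder(
            rng, d, self.hidden_dim, self.n_message_layers
        )
        self.classifier_ = _nn.init_classifier(
            rng, 2 * self.hidden_dim, tuple(self.classifier_hidden)
        )
        if self.classifier_hidden_biases:
            trainable_biases = self.classifier_.biases
        else:
            trainable_biases = [self.classifier_.biases[-1]]
        params = (
            self.encoder_.arrays()
            + self.classifier_.weights
            + trainable_biases
        )
        adam = _nn.AdamState(lr=self.learning_rate)

        n = len(pairs)
        n_aug = int(round(self.baseline_fraction * n))
        self.loss_curve_ = []
        for epoch in range(self.n_epochs):
            # baseline cages resampled each epoch: zero features, half/half labels
            aug_y = np.array(
                [0] * (n_aug // 2) + [1] * (n_aug - n_aug // 2), dtype=np.intp
            )
            rng.shuffle(aug_y)
            ep_bb = np.concatenate([bb_ids, np.full(n_aug, -1)])
            ep_lk = np.concatenate([lk_ids, np.full(n_aug, -1)])
            ep_y = np.concatenate([y_idx, aug_y]).astype(np.intp)
            order = rng.permutation(len(ep_y))
            losses = []
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                losses.append(
                    self._train_batch(
                        ep_bb[sel], ep_lk[sel], ep_y[sel], feats, adjs,
                        params, adam,
                    )
                )
            self.loss_curve_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.n_epochs}: "
                      f"loss {self.loss_curve_[-1]:.4f}")
        self.n_features_in_ = 2
        return self

    def _train_batch(self, bb, lk, y_idx, feats, adjs, params, adam) -> float:
        B = len(y_idx)
        real = bb >= 0
        h = self.hidden_dim
        V = np.zeros((B, 2 * h))
        if real.any():
            used = np.unique(np.concatenate([bb[real], lk[real]]))
            pos = {u: k for k, u in enumerate(used)}
            X, A, seg, n_mol = _nn.stack_graphs(
                [feats[u] for u in used], [adjs[u] for u in used]
            )
            mol, cache = _nn.encode_forward(X, A, seg, n_mol, self.encoder_)
            bb_rows = np.array([pos[u] for u in bb[real]])
            lk_rows = np.array([pos[u] for u in lk[real]])
            V[real, :h] = mol[bb_rows]
            V[real, h:] = mol[lk_rows]
        logits, mcache = _nn.mlp_forward(V, self.classifier_)
        P = softmax(logits)
        Y = np.zeros_like(P)
        Y[np.arange(B), y_idx] = 1.0
        loss = -np.mean(np.log(np.clip(P[np.arange(B), y_idx], 1e-12, None)))
        dlogits = (P - Y) / B
        dV, clf_grads = _nn.mlp_backward(dlogits, mcache, self.classifier_)
        n_layers = len(self.classifier_.weights)
        dW, db = clf_grads[:n_layers], clf_grads[n_layers:]
        clf_grads = dW + (db if self.classifier_hidden_biases else [db[-1]])
        if real.any():
            dmol = np.zeros_like(mol)
            np.add.at(dmol, bb_rows, dV[real, :h])
            np.add.at(dmol, lk_rows, dV[real, h:])
            _, enc_grads = _nn.encode_backward(dmol, cache, self.encoder_)
        else:
            enc_grads = [np.zeros_like(a) for a in self.encoder_.arrays()]
        adam.step(params, enc_grads + clf_grads)
        return float(loss)

    # ------------------------------------------------------------------ #
    # inference
    # ------------------------------------------------------------------ #

    def encode_molecule(
        self, molecule: str | MolecularGraph, features: np.ndarray | None = None
    ) -> np.ndarray:
        """Neural fingerprint of one precursor (sum-pooled atom embeddings)."""
        check_is_fitted(self, "encoder_")
        graph = parse_smiles(molecule) if isinstance(molecule, str) else molecule
        if features is None:
            features = self.featurizer_.transform(graph)
        if features.shape[0] != graph.n_atoms:
            raise ValueError("feature rows do not match graph atoms")
        seg = np.zeros(graph.n_atoms, dtype=np.intp)
        mol, _ = _nn.encode_forward(
            features, graph.adjacency().tocsr(), seg, 1, self.encoder_
        )
        return mol[0]

    def _cage_logits(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        uniq = sorted({s for p in pairs for s in p})
        vec = {s: self.encode_molecule(s) for s in uniq}
        V = np.stack([np.concatenate([vec[b], vec[l]]) for b, l in pairs])
        logits, _ = _nn.mlp_forward(V, self.classifier_)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, columns ordered as ``classes_``."""
        pairs = self._validate_pairs(X)
        P = softmax(self._cage_logits(pairs))  # columns: (positive, negative)
        cols = [
            P[:, 0] if c == self.positive_class_ else P[:, 1]
            for c in self.classes_
        ]
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        pairs = self._validate_pairs(X)
        P = softmax(self._cage_logits(pairs))
        neg = next(c for c in self.classes_ if c != self.positive_class_)
        return np.where(P[:, 0] >= P[:, 1], self.positive_class_, neg)

    def p_collapsed(self, X) -> np.ndarray:
        """Probability of the positive ("collapsed") class per cage."""
        pairs = self._validate_pairs(X)
        return softmax(self._cage_logits(pairs))[:, 0]

    def forward_cage(
        self, bb: str | MolecularGraph, linker: str | MolecularGraph
    ) -> CagePrediction:
        """Full deterministic forward pass for one cage."""
        v = np.concatenate(
            [self.encode_molecule(bb), self.encode_molecule(linker)]
        )
        return predict_cage(v[: self.hidden_dim], v[self.hidden_dim:], self)

    def baseline_probability(self) -> float:
        """p_collapsed of the all-zero-feature baseline cage.

        With the bias-free encoder every baseline cage maps to the zero
        fingerprint, so this is a single number per fitted model.
        """
        check_is_fitted(self, "classifier_")
        logits, _ = _nn.mlp_forward(
            np.zeros((1, 2 * self.hidden_dim)), self.classifier_
        )
        return float(softmax(logits)[0, 0])

    # ------------------------------------------------------------------ #
    # gradients along an attribution path (used by the attribution module)
    # ------------------------------------------------------------------ #

    def path_gradients(
        self,
        bb_graph: MolecularGraph,
        lk_graph: MolecularGraph,
        bb_features: np.ndarray,
        lk_features: np.ndarray,
        alphas: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """p_collapsed and its input-gradients at scaled inputs ``alpha * x``.

        Evaluates the model at every path point ``alpha_k * (bb, lk)``
        (zero baseline) in a single batched pass.  Returns
        ``(F, grad_bb_sum, grad_lk_sum)`` where ``F[k]`` is p_collapsed at
        path point k and the gradient matrices are summed over path points.
        """
        check_is_fitted(self, "encoder_")
        S = len(alphas)
        feats = [a * bb_features for a in alphas] + [a * lk_features for a in alphas]
        adjs = [bb_graph.adjacency()] * S + [lk_graph.adjacency()] * S
        X, A, seg, n_mol = _nn.stack_graphs(feats, adjs)
        mol, cache = _nn.encode_forward(X, A, seg, n_mol, self.encoder_)
        V = np.hstack([mol[:S], mol[S:]])
        logits, mcache = _nn.mlp_forward(V, self.classifier_)
        P = softmax(logits)
        F = P[:, 0]
        # dF/dlogits for F = softmax(...)[0]
        dlogits = np.empty_like(P)
        dlogits[:, 0] = F * (1.0 - F)
        dlogits[:, 1] = -F * P[:, 1]
        dV, _ = _nn.mlp_backward(dlogits, mcache, self.classifier_)
        h = self.hidden_dim
        dmol = np.vstack([dV[:, :h], dV[:, h:]])
        dX, _ = _nn.encode_backward(dmol, cache, self.encoder_)
        if not np.all(np.isfinite(dX)):
            bad = int(np.where(~np.isfinite(dX))[0][0])
            raise FloatingPointError(
                f"non-finite gradient at stacked atom row {bad}"
            )
        nb = bb_graph.n_atoms
        grad_bb = dX[: S * nb].reshape(S, nb, -1).sum(axis=0)
        grad_lk = dX[S * nb:].reshape(S, lk_graph.n_atoms, -1).sum(axis=0)
        return F, grad_bb, grad_lk

    # ------------------------------------------------------------------ #
    # persistence
    # ------------------------------------------------------------------ #

    def save(self, path: str) -> None:
        """Single-file archive: weights + featurizer state + JSON header."""
        check_is_fitted(self, "encoder_")
        header = {
            "format": "cagecollapse-model-v1",
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "classes": [str(c) for c in self.classes_],
            "positive_class": str(self.positive_class_),
            "featurizer": self.featurizer_.to_header(),
            "loss_curve": getattr(self, "loss_curve_", []),
        }
        arrays = {"w_in": self.encoder_.w_in}
        for i, w in enumerate(self.encoder_.w_msg):
            arrays[f"w_msg_{i}"] = w
        for i, (w, b) in enumerate(
            zip(self.classifier_.weights, self.classifier_.biases)
        ):
            arrays[f"clf_w_{i}"] = w
            arrays[f"clf_b_{i}"] = b
        with open(path, "wb") as fh:
            np.savez(fh, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path: str) -> "CageCollapseClassifier":
        with np.load(path, allow_pickle=False) as npz:
            header = json.loads(str(npz["header"]))
            params = dict(header["params"])
            params["classifier_hidden"] = tuple(params["classifier_hidden"])
            params["vocabulary"] = tuple(params["vocabulary"])
            est = cls(**params)
            est.classes_ = np.asarray(header["classes"], dtype=object)
            est.positive_class_ = header["positive_class"]
            est.featurizer_ = AtomFeaturizer.from_header(header["featurizer"])
            est.loss_curve_ = list(header["loss_curve"])
            n_msg = sum(1 for k in npz.files if k.startswith("w_msg_"))
            est.encoder_ = _nn.EncoderParams(
                w_in=npz["w_in"],
                w_msg=[npz[f"w_msg_{i}"] for i in range(n_msg)],
            )
            n_clf = sum(1 for k in npz.files if k.startswith("clf_w_"))
            est.classifier_ = _nn.ClassifierParams(
                weights=[npz[f"clf_w_{i}"] for i in range(n_clf)],
                biases=[npz[f"clf_b_{i}"] for i in range(n_clf)],
            )
            est.n_features_in_ = 2
        return est

    # ------------------------------------------------------------------ #
    # helpers
    # ------------------------------------------------------------------ #

    @staticmethod
    def _validate_pairs(X) -> list[tuple[str, str]]:
        if isinstance(X, np.ndarray):
            X = X.tolist()
        pairs = []
        for row in X:
            if len(row) != 2:
                raise ValueError(
                    "each cage must be a (building-block, linker) SMILES pair"
                )
            b, l = row
            if not isinstance(b, str) or not isinstance(l, str) or not b or not l:
                raise ValueError(f"invalid SMILES pair: {row!r}")
            pairs.append((b, l))
        return pairs

    @staticmethod
    def _index_precursors(pairs):
        smiles_index = sorted({s for p in pairs for s in p})
        lut = {s: i for i, s in enumerate(smiles_index)}
        bb = np.array([lut[b] for b, _ in pairs], dtype=np.intp)
        lk = np.array([lut[l] for _, l in pairs], dtype=np.intp)
        return smiles_index, bb, lk


def predict_cage(
    bb_vector: np.ndarray,
    linker_vector: np.ndarray,
    model: CageCollapseClassifier,
) -> CagePrediction:
    """Classify a cage from precomputed precursor fingerprints.

    Concatenation order is always (building block | linker); swapping the
    two vectors is a different input.
    """
    check_is_fitted(model, "classifier_")
    if bb_vector.shape != (model.hidden_dim,) or linker_vector.shape != (
        model.hidden_dim,
    ):
        raise ValueError(
            f"fingerprints must have width {model.hidden_dim}, got "
            f"{bb_vector.shape} and {linker_vector.shape}"
        )
    v = np.concatenate([bb_vector, linker_vector])[None, :]
    logits, _ = _nn.mlp_forward(v, model.classifier_)
    p = softmax(logits)[0]
    neg = next(c for c in model.classes_ if c != model.positive_class_)
    label = model.positive_class_ if p[0] >= p[1] else neg
    return CagePrediction(
        logits=(float(logits[0, 0]), float(logits[0, 1])),
        p_collapsed=float(p[0]),
        p_not_collapsed=float(p[1]),
        label=str(label),
    )
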