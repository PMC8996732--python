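"""Classifier forward pass, softmax, gradients, persistence, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from sklearn.base import clone

import cagecollapse as cc
from cagecollapse import _nn
from cagecollapse.model import CageCollapseClassifier, predict_cage, softmax
from cagecollapse.train_eval import records_to_xy


class TestSoftmax:
    def test_symmetric_logits(self):
        assert np.allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_closed_form(self):
        p = softmax(np.array([1.0, 0.0]))
        assert p[0] == pytest.approx(np.e / (1 + np.e))

    def test_large_logits_no_overflow(self):
        p = softmax(np.array([1000.0, 0.0]))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)

    @given(
        a=st.floats(-50, 50), b=st.floats(-50, 50), c=st.floats(-100, 100)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shift_invariance_and_normalisation(self, a, b, c):
        p = softmax(np.array([a, b]))
        q = softmax(np.array([a + c, b + c]))
        assert abs(p.sum() - 1.0) < 1e-9
        assert np.allclose(p, q, atol=1e-12)

    def test_nan_logits_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.nan, 0.0]))


class TestForwardPass:
    def test_zero_features_give_zero_fingerprint(self, tiny_model):
        model, _, _ = tiny_model
        g = cc.parse_smiles("c1ccccc1")
        x = np.zeros((g.n_atoms, model.featurizer_.feature_dim))
        vec = model.encode_molecule(g, features=x)
        assert np.array_equal(vec, np.zeros(model.hidden_dim))

    def test_single_atom_encoding_matches_manual_chain(self, tiny_model):
        """For one atom there are no messages: v = relu(W2 relu(W1 relu(Win x)))."""
        model, _, _ = tiny_model
        x = model.featurizer_.transform("C")[0]
        h = np.maximum(x @ model.encoder_.w_in, 0.0)
        for w in model.encoder_.w_msg:
            h = np.maximum(h @ w, 0.0)
        assert np.allclose(model.encode_molecule("C"), h)

    def test_benzene_fingerprint_is_six_times_any_atom(self, tiny_model):
        model, _, _ = tiny_model
        g = cc.parse_smiles("c1ccccc1")
        x = model.featurizer_.transform(g)
        mol, cache = _nn.encode_forward(
            x, g.adjacency().tocsr(), np.zeros(6, dtype=np.intp), 1,
            model.encoder_,
        )
        atom_embeddings = cache["H"][-1]
        assert np.allclose(atom_embeddings, atom_embeddings[0])
        assert np.allclose(mol[0], 6 * atom_embeddings[0])

    def test_forward_deterministic(self, tiny_model):
        model, _, test = tiny_model
        r = test[0]
        p1 = model.forward_cage(r.bb_smiles, r.linker_smiles)
        p2 = model.forward_cage(r.bb_smiles, r.linker_smiles)
        assert p1.p_collapsed == p2.p_collapsed

    def test_prediction_invariant_to_atom_relabelling(self, tiny_model):
        model, _, test = tiny_model
        r = test[0]
        mol = Chem.MolFromSmiles(r.bb_smiles)
        rng = np.random.default_rng(4)
        p_ref = model.forward_cage(r.bb_smiles, r.linker_smiles).p_collapsed
        for _ in range(3):
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            renumbered = Chem.MolToSmiles(
                Chem.RenumberAtoms(mol, perm), canonical=False
            )
            p = model.forward_cage(renumbered, r.linker_smiles).p_collapsed
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_swapping_precursors_changes_prediction(self, tiny_model):
        """Concatenation order is semantic: (bb | linker), never the reverse."""
        model, _, test = tiny_model
        v_bb = model.encode_molecule(test[0].bb_smiles)
        v_lk = model.encode_molecule(test[0].linker_smiles)
        p = predict_cage(v_bb, v_lk, model).p_collapsed
        p_swapped = predict_cage(v_lk, v_bb, model).p_collapsed
        assert p != pytest.approx(p_swapped, abs=1e-12)

    def test_probabilities_sum_to_one(self, tiny_model):
        model, _, test = tiny_model
        X, _ = records_to_xy(test[:20])
        P = model.predict_proba(X)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_width_mismatch_rejected(self, tiny_model):
        model, _, _ = tiny_model
        with pytest.raises(ValueError, match="width"):
            predict_cage(np.zeros(3), np.zeros(3), model)

    def test_baseline_probability_equals_output_bias_softmax(self, tiny_model):
        """Bias-free encoder + hidden layers: the zero cage sees only the
        output-layer biases."""
        model, _, _ = tiny_model
        expected = softmax(model.classifier_.biases[-1][None, :])[0, 0]
        assert model.baseline_probability() == pytest.approx(expected, abs=1e-12)


class TestGradients:
    def test_input_gradient_matches_finite_differences(self, tiny_model):
        model, _, test = tiny_model
        r = test[0]
        g_bb = cc.parse_smiles(r.bb_smiles)
        g_lk = cc.parse_smiles(r.linker_smiles)
        x_bb = model.featurizer_.transform(g_bb)
        x_lk = model.featurizer_.transform(g_lk)
        one = np.array([1.0])
        _, grad_bb, _ = model.path_gradients(g_bb, g_lk, x_bb, x_lk, one)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for _ in range(10):
            i = int(rng.integers(x_bb.shape[0]))
            j = int(rng.integers(x_bb.shape[1]))
            xp, xm = x_bb.copy(), x_bb.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fp, _, _ = model.path_gradients(g_bb, g_lk, xp, x_lk, one)
            fm, _, _ = model.path_gradients(g_bb, g_lk, xm, x_lk, one)
            fd = (fp[0] - fm[0]) / (2 * eps)
            assert grad_bb[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTraining:
    def test_separable_toy_set_reaches_low_loss(self):
        """Loss on a toy set separable by building-block identity -> < 0.1."""
        bbs = {"c1c(C=O)cc(C=O)cc1C=O": "collapsed",
               "C(CC=O)(CC=O)CC=O": "not collapsed"}
        linkers = ["NCCN", "NCCCN", "Nc1ccc(N)cc1", "NCc1ccc(CN)cc1",
                   "NCCCCN", "Nc1ccc(CN)cc1", "NCCOCCN", "NCC(C)CN",
                   "Nc1cccc(N)c1", "NCCSCCN"]
        X = [[bb, lk] for bb in bbs for lk in linkers]
        y = [bbs[bb] for bb in bbs for lk in linkers]
        est = CageCollapseClassifier(
            n_epochs=200, batch_size=8, baseline_fraction=0.0, random_state=0
        ).fit(X, y)
        assert est.loss_curve_[-1] < 0.1

    def test_same_seed_reproduces_weights(self, tiny_dataset):
        records, _, _ = tiny_dataset
        train_recs, _ = cc.split_all_vs_all(records, 0.8, seed=0)
        X, y = records_to_xy(train_recs[:60])
        m1 = CageCollapseClassifier(n_epochs=3, random_state=11).fit(X, y)
        m2 = CageCollapseClassifier(n_epochs=3, random_state=11).fit(X, y)
        assert np.array_equal(m1.encoder_.w_in, m2.encoder_.w_in)
        for w1, w2 in zip(m1.classifier_.weights, m2.classifier_.weights):
            assert np.array_equal(w1, w2)

    def test_label_permutation_control_near_chance(self, tiny_dataset):
        """Permuted labels destroy the signal: accuracy ~ 0.5 on balanced data."""
        records, _, _ = tiny_dataset
        train_recs, test_recs = cc.split_all_vs_all(records, 0.8, seed=2)
        X, y = records_to_xy(train_recs)
        rng = np.random.default_rng(13)
        y_perm = rng.permutation(y)
        est = CageCollapseClassifier(n_epochs=15, random_state=0).fit(X, y_perm)
        Xt, yt = records_to_xy(test_recs)
        # balance the test set before scoring
        coll = [i for i, lab in enumerate(yt) if lab == "collapsed"]
        notc = [i for i, lab in enumerate(yt) if lab == "not collapsed"]
        k = min(len(coll), len(notc))
        idx = coll[:k] + notc[:k]
        acc = (est.predict(Xt[idx]) == yt[idx]).mean()
        assert 0.3 < acc < 0.7

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            CageCollapseClassifier().fit(
                [["CC=O", "NCCN"]], ["collapsed"]
            )

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CageCollapseClassifier().fit([], [])

    def test_invalid_pair_shape_rejected(self):
        with pytest.raises(ValueError):
            CageCollapseClassifier().fit([["CC=O"]], ["collapsed"])

    def test_sklearn_clone_contract(self, tiny_model):
        model, _, _ = tiny_model
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        model, _, test = tiny_model
        path = str(tmp_path / "model.npz")
        model.save(path)
        loaded = CageCollapseClassifier.load(path)
        X, _ = records_to_xy(test[:10])
        assert np.array_equal(model.predict_proba(X), loaded.predict_proba(X))
        assert list(loaded.classes_) == list(model.classes_)
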