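"""Integrated gradients: quadrature, completeness, aggregation, recovery."""

import numpy as np
import pytest
from scipy import stats

import cagecollapse as cc
from cagecollapse.attribution import (
    AttributionResult,
    BaselineCage,
    CompletenessError,
    IntegratedGradients,
    augment_training_set,
    completeness_report,
    highlight_atoms,
    make_baseline,
    midpoint_integrated_gradients,
    precursor_attribution,
    rank_precursors,
    substructure_collapse_rate,
)
from cagecollapse.chem import parse_smiles


def make_result(bb_scores, lk_scores, p=0.7, p0=0.5, steps=10):
    """AttributionResult with prescribed per-atom scores (one feature dim)."""
    return AttributionResult(
        bb_smiles="C" * len(bb_scores) if len(bb_scores) else "C",
        linker_smiles="C" * len(lk_scores) if len(lk_scores) else "C",
        ig_bb=np.asarray(bb_scores, dtype=float)[:, None],
        ig_lk=np.asarray(lk_scores, dtype=float)[:, None],
        p_collapsed=p,
        p_baseline=p0,
        steps=steps,
    )


class TestBaseline:
    def test_make_baseline_preserves_shapes(self):
        g1, g2 = parse_smiles("CCO"), parse_smiles("NCCN")
        b = make_baseline(g1, g2, np.ones((3, 5)), np.ones((4, 5)))
        assert b.bb_features.shape == (3, 5)
        assert not b.bb_features.any() and not b.lk_features.any()

    def test_baseline_of_baseline_is_itself(self):
        g1, g2 = parse_smiles("CCO"), parse_smiles("NCCN")
        b = make_baseline(g1, g2, np.ones((3, 5)), np.ones((4, 5)))
        b2 = make_baseline(b.bb_graph, b.lk_graph, b.bb_features, b.lk_features)
        assert np.array_equal(b.bb_features, b2.bb_features)

    def test_nonzero_baseline_rejected(self):
        g1, g2 = parse_smiles("CC"), parse_smiles("CC")
        with pytest.raises(ValueError, match="zero"):
            BaselineCage(g1, g2, np.ones((2, 3)), np.zeros((2, 3)))


class TestAugmentation:
    def records(self, n):
        return [
            cc.CageRecord("CC=O", "NCCN", "aldehyde3amine2",
                          "collapsed", f"c{i}")
            for i in range(n)
        ]

    def test_fraction_zero_is_identity(self):
        recs = self.records(10)
        stream = augment_training_set(recs, 0.0, seed=0)
        assert [a.record for a in stream] == recs
        assert not any(a.is_baseline for a in stream)

    def test_counts_and_label_balance(self):
        stream = augment_training_set(self.records(1000), 0.1, seed=0)
        baselines = [a for a in stream if a.is_baseline]
        assert len(baselines) == 100
        labels = [a.record.label for a in baselines]
        assert labels.count("collapsed") == 50
        assert labels.count("not collapsed") == 50

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            augment_training_set(self.records(5), -0.1)


class TestMidpointQuadrature:
    def test_linear_function_exact_at_any_step_count(self):
        """For F(x) = w.x with zero baseline, IG_i = w_i x_i exactly."""
        rng = np.random.default_rng(0)
        w = rng.normal(size=7)
        x = rng.normal(size=7)
        ig = midpoint_integrated_gradients(lambda z: w, x, steps=1)
        assert np.array_equal(ig, w * x)
        for steps in (3, 300):
            ig = midpoint_integrated_gradients(lambda z: w, x, steps=steps)
            assert np.allclose(ig, w * x, rtol=1e-12, atol=0)

    def test_sigmoid_matches_fine_grid_oracle(self):
        """300 midpoint steps vs a 100,000-step trapezoid-rule oracle."""
        rng = np.random.default_rng(1)
        w = rng.normal(size=6)
        x = rng.normal(size=6)

        def grad(z):
            s = 1.0 / (1.0 + np.exp(-(w @ z)))
            return s * (1 - s) * w

        ig = midpoint_integrated_gradients(grad, x, steps=300)
        alphas = np.linspace(0.0, 1.0, 100_001)
        fine = np.array([grad(a * x) for a in alphas])
        oracle = x * np.trapezoid(fine, alphas, axis=0)
        assert np.allclose(ig, oracle, atol=1e-4)

    def test_zero_path_gradient_gives_zero_attribution(self):
        """Sensitivity: a dimension with zero gradient everywhere gets IG 0."""
        w = np.array([1.0, 0.0, 2.0])
        x = np.array([3.0, 5.0, 1.0])
        ig = midpoint_integrated_gradients(lambda z: w, x, steps=20)
        assert ig[1] == 0.0

    def test_identical_input_and_baseline_gives_zero(self):
        x = np.ones(4)
        ig = midpoint_integrated_gradients(
            lambda z: np.ones(4), x, baseline=x, steps=5
        )
        assert np.array_equal(ig, np.zeros(4))

    def test_invalid_steps(self):
        with pytest.raises(ValueError):
            midpoint_integrated_gradients(lambda z: z, np.ones(2), steps=0)


class TestModelAttribution:
    def test_completeness_per_cage(self, tiny_model):
        """ΔP − Σ_ig vanishes per cage for the homogeneous architecture."""
        model, _, test = tiny_model
        ig = IntegratedGradients(model, steps=300)
        for rec in test[:10]:
            res = ig.attribute(rec.bb_smiles, rec.linker_smiles)
            assert abs(res.residual) < 1e-6

    def test_attribution_zero_where_input_zero(self, tiny_model):
        model, _, test = tiny_model
        res = IntegratedGradients(model, steps=50).attribute(
            test[0].bb_smiles, test[0].linker_smiles
        )
        x_bb = model.featurizer_.transform(test[0].bb_smiles)
        assert np.all(res.ig_bb[x_bb == 0.0] == 0.0)

    def test_atom_scores_partition_sigma(self, tiny_model):
        model, _, test = tiny_model
        res = IntegratedGradients(model, steps=25).attribute(
            test[1].bb_smiles, test[1].linker_smiles
        )
        assert res.atom_scores.sum() == pytest.approx(res.sigma_ig, abs=1e-9)

    def test_residual_shrinks_with_steps_on_biased_head(self, biased_head_model):
        """With a fully biased head, completeness is approximate and the
        residual magnitude shrinks (in expectation) as steps grow."""
        model, test = biased_head_model
        means = []
        for steps in (25, 400):
            ig = IntegratedGradients(model, steps=steps)
            res = [
                ig.attribute(r.bb_smiles, r.linker_smiles) for r in test[:25]
            ]
            means.append(abs(np.mean([r.residual for r in res])))
        assert means[1] <= means[0] + 1e-3


class TestAggregation:
    def test_precursor_scores_partition_sigma(self):
        res = make_result([0.1, 0.2], [0.3, -0.05])
        pa = precursor_attribution(res)
        assert pa.bb_score == pytest.approx(0.3, abs=1e-12)
        assert pa.linker_score == pytest.approx(0.25, abs=1e-12)
        assert pa.bb_score + pa.linker_score == pytest.approx(
            res.sigma_ig, abs=1e-9
        )

    def test_all_attribution_on_bb_gives_zero_linker_score(self):
        res = make_result([0.4, 0.1], [0.0, 0.0])
        pa = precursor_attribution(res)
        assert pa.linker_score == 0.0

    def test_custom_atom_map_must_cover_all_atoms(self):
        res = make_result([0.1], [0.2, 0.3])
        with pytest.raises(ValueError, match="covers"):
            precursor_attribution(res, atom_to_precursor=["bb", "linker"])

    def test_highlight_thresholds(self):
        res = make_result([0.02, 0.005], [-0.03])
        assert list(highlight_atoms(res, 0.01)) == [0]
        assert list(highlight_atoms(res, np.inf)) == []
        assert list(highlight_atoms(res, -np.inf)) == [0, 1, 2]


class TestRankings:
    def test_single_precursor_single_row(self, tiny_model):
        model, _, test = tiny_model
        recs = [r for r in test if r.bb_smiles == test[0].bb_smiles][:3]
        bb_tab, _ = rank_precursors(recs, model, steps=10)
        assert len(bb_tab) == 1

    def test_ranking_is_permutation_of_unique_precursors(self, tiny_model):
        from rdkit import Chem

        model, _, test = tiny_model
        recs = test[:15]
        bb_tab, lk_tab = rank_precursors(recs, model, steps=10)
        assert set(bb_tab.smiles) == {
            Chem.CanonSmiles(r.bb_smiles) for r in recs
        }
        assert set(lk_tab.smiles) == {
            Chem.CanonSmiles(r.linker_smiles) for r in recs
        }

    def test_empty_records_rejected(self, tiny_model):
        model, _, _ = tiny_model
        with pytest.raises(ValueError):
            rank_precursors([], model)


class TestSubstructureRate:
    def test_zero_support_flagged(self, tiny_dataset):
        records, _, _ = tiny_dataset
        rate = substructure_collapse_rate("[Au]", records)
        assert rate.zero_support
        assert np.isnan(rate.fraction_collapsed)

    def test_match_everything_gives_overall_rate(self, tiny_dataset):
        records, _, _ = tiny_dataset
        usable = cc.train_eval.determinate(records)
        overall = np.mean([r.label == "collapsed" for r in usable])
        rate = substructure_collapse_rate("[#6,#7]", records)
        assert rate.n_matched == len(usable)
        assert rate.fraction_collapsed == pytest.approx(overall)

    def test_planted_core_enriched_over_base_rate(self, tiny_dataset):
        """Cages built on a flagged flexible core collapse more often."""
        records, _, library = tiny_dataset
        usable = cc.train_eval.determinate(records)
        base_rate = np.mean([r.label == "collapsed" for r in usable])
        flagged = [t for t in library.ditopic if t.collapse_core]
        assert flagged, "library must contain flagged ditopic cores"
        core = flagged[0].functionalise("amine")
        rate = substructure_collapse_rate(
            __import__("rdkit").Chem.MolFromSmiles(core), records
        )
        assert not rate.zero_support
        assert rate.fraction_collapsed > base_rate

    def test_invalid_pattern_rejected(self, tiny_dataset):
        records, _, _ = tiny_dataset
        with pytest.raises(ValueError, match="query"):
            substructure_collapse_rate("not a smarts((", records)


class TestCompletenessReport:
    def test_report_on_trained_model(self, tiny_model):
        model, _, test = tiny_model
        report = completeness_report(test[:15], model, steps=100)
        assert abs(report.mean) < 1e-6
        assert len(report.residuals) == 15
        assert report.hist_counts.sum() == 15

    def test_fails_loudly_beyond_tolerance(self, biased_head_model):
        model, test = biased_head_model
        with pytest.raises(CompletenessError):
            completeness_report(
                test[:10], model, steps=5, mean_tolerance=1e-12
            )
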