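import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odortransfer.containers import DescriptorLexicon, RatingsTable
from odortransfer.evaluation import (
    Z_CAP,
    auc_paradigm,
    curve_points,
    cv_curves,
    dependent_z,
    descriptor_sweep,
    evaluate_model,
    fisher_z,
    ks_uniformity,
    paradigm_family_test,
    per_molecule_correlation,
)


def _lex(n, prefix="d"):
    return DescriptorLexicon([f"{prefix}{i}" for i in range(n)])


def _table(values, prefix="d"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return RatingsTable(
        tuple(f"m{i}" for i in range(values.shape[0])),
        _lex(values.shape[1], prefix),
        values,
        check_bounds=False,
    )


class TestPerMoleculeCorrelation:
    def test_perfect_and_anticorrelated(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert per_molecule_correlation(v, v) == pytest.approx(1.0)
        assert per_molecule_correlation(-v, v) == pytest.approx(-1.0)

    def test_constant_profile_gives_nan(self):
        assert math.isnan(per_molecule_correlation([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_requires_three_descriptors(self):
        with pytest.raises(ValueError, match="at least 3"):
            per_molecule_correlation([1.0, 2.0], [3.0, 4.0])


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-0.999, 0.999))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestDependentZ:
    def test_equal_correlations_give_zero(self):
        assert dependent_z(0.5, 0.5, 0.3, 100) == 0.0

    def test_n_of_three_rejected(self):
        with pytest.raises(ValueError, match="N >= 4"):
            dependent_z(0.5, 0.4, 0.3, 3)

    def test_invalid_triple_rejected(self):
        # r_gm = r_gb = 0.9 with r_mb = -0.9 is not a correlation matrix
        with pytest.raises(ValueError):
            dependent_z(0.9, 0.8, -0.9, 50)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sign_agrees_with_correlation_difference(self, seed):
        rng = np.random.default_rng(seed)
        # sample a valid correlation matrix via a random Gram matrix
        A = rng.normal(size=(3, 4))
        C = np.corrcoef(A)
        r_gm, r_gb, r_mb = C[0, 1], C[0, 2], C[1, 2]
        if max(abs(r_gm), abs(r_gb), abs(r_mb)) >= 0.999:
            return
        z = dependent_z(r_gm, r_gb, r_mb, 50)
        assert np.sign(z) == np.sign(r_gm - r_gb)

    def test_null_calibration_quick(self):
        """Under equal population correlations the Z is ~N(0,1)."""
        rng = np.random.default_rng(0)
        C = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.5], [0.4, 0.5, 1.0]])
        L = np.linalg.cholesky(C)
        zs = []
        for _ in range(400):
            X = rng.normal(size=(131, 3)) @ L.T
            cc = np.corrcoef(X.T)
            zs.append(dependent_z(cc[0, 1], cc[0, 2], cc[1, 2], 131))
        rej = np.mean(np.abs(zs) > 1.96)
        assert 0.02 <= rej <= 0.09


class TestEvaluateModel:
    def test_perfect_predictions_capped_z(self):
        truth = _table(np.random.default_rng(0).normal(size=(4, 6)))
        report = evaluate_model(truth, truth, no_baseline=True)
        assert report.median_r == pytest.approx(1.0)
        assert np.all(report.per_molecule_z == Z_CAP)

    def test_predictions_equal_to_baseline_give_zero_z(self, rng):
        truth = _table(rng.normal(size=(5, 8)))
        baseline = _table(np.tile(rng.normal(size=8), (5, 1)))
        report = evaluate_model(baseline, truth, baseline_preds=baseline)
        assert np.allclose(report.per_molecule_z, 0.0)
        assert report.median_z == 0.0

    def test_invariant_to_common_affine_transform(self, rng):
        truth = _table(rng.normal(size=(6, 10)))
        preds = _table(rng.normal(size=(6, 10)))
        baseline = _table(np.tile(rng.normal(size=10), (6, 1)))
        r1 = evaluate_model(preds, truth, baseline_preds=baseline)
        scaled = _table(3.0 * preds.values + 7.0)
        r2 = evaluate_model(scaled, truth, baseline_preds=baseline)
        assert np.allclose(r1.per_molecule_r, r2.per_molecule_r, atol=1e-12)
        assert np.allclose(r1.per_molecule_z, r2.per_molecule_z, atol=1e-9)

    def test_per_descriptor_correlations_computed_across_molecules(self, rng):
        truth_vals = rng.normal(size=(8, 4))
        pred_vals = truth_vals.copy()
        pred_vals[:, 0] = -truth_vals[:, 0]  # one descriptor anti-predicted
        report = evaluate_model(_table(pred_vals), _table(truth_vals),
                                no_baseline=True)
        assert report.per_descriptor_r[0] == pytest.approx(-1.0)
        assert np.allclose(report.per_descriptor_r[1:], 1.0)

    def test_end_to_end_median_matches_reference_loop(self, rng):
        """Medians agree with a directly scripted per-molecule computation."""
        truth = _table(rng.normal(size=(7, 9)))
        preds = _table(truth.values + 0.5 * rng.normal(size=(7, 9)))
        report = evaluate_model(preds, truth, no_baseline=True)
        ref = np.median(
            [np.corrcoef(preds.values[i], truth.values[i])[0, 1]
             for i in range(7)]
        )
        assert report.median_r == pytest.approx(ref, abs=1e-12)


class TestCvCurves:
    def test_baseline_scored_against_itself_is_zero(self, small_scenario,
                                                    quick_config):
        sc = small_scenario
        tgt = sc.target_ratings.subset_molecules(sc.shared_ids)
        tidy = cv_curves(
            sc.source_ratings, tgt,
            kinds=("baseline",), n_train_grid=(5, 15), reps=2, folds=5,
            seed=0, config=quick_config,
        )
        assert np.allclose(tidy["median_z"], 0.0)

    def test_deterministic_given_seed(self, small_scenario, quick_config):
        sc = small_scenario
        tgt = sc.target_ratings.subset_molecules(sc.shared_ids)
        kwargs = dict(
            kinds=("dirsem",), n_train_grid=(5,), reps=2, folds=5,
            config=quick_config,
        )
        a = cv_curves(sc.source_ratings, tgt, sc.space_source,
                      sc.space_target, seed=3, **kwargs)
        b = cv_curves(sc.source_ratings, tgt, sc.space_source,
                      sc.space_target, seed=3, **kwargs)
        assert a.equals(b)

    def test_zero_train_only_for_semantic_and_baseline(self, small_scenario,
                                                       quick_config):
        sc = small_scenario
        tgt = sc.target_ratings.subset_molecules(sc.shared_ids)
        with pytest.raises(ValueError, match="n_train=0"):
            cv_curves(sc.source_ratings, tgt, sc.space_source, sc.space_target,
                      kinds=("dirrat",), n_train_grid=(0,), reps=1, folds=5,
                      seed=0, config=quick_config)

    def test_curve_points_aggregate(self, small_scenario, quick_config):
        sc = small_scenario
        tgt = sc.target_ratings.subset_molecules(sc.shared_ids)
        tidy = cv_curves(sc.source_ratings, tgt, sc.space_source,
                         sc.space_target, kinds=("baseline", "dirsem"),
                         n_train_grid=(5, 10), reps=3, folds=5, seed=0,
                         config=quick_config)
        pts = curve_points(tidy)
        assert len(pts) == 4
        assert all(p.n_reps == 3 for p in pts)


class TestDescriptorSweep:
    def test_contract_and_full_set_consistency(self, noiseless_scenario,
                                               unpenalized_config):
        sc = noiseless_scenario
        tgt = sc.target_ratings.subset_molecules(sc.shared_ids)
        order = list(sc.source_ratings.lexicon)
        out = descriptor_sweep(
            order, sc.space_source, sc.space_target,
            sc.source_ratings, tgt, config=unpenalized_config,
            k_grid=(1, 5, len(order)),
        )
        assert list(out["k"]) == [1, 5, len(order)]
        # zero-noise scenario: the full source set predicts near-perfectly
        # (the added leave-one-out baseline vector keeps r just below 1)
        assert out["median_r"].iloc[-1] > 0.99
        # and a single descriptor cannot beat the full set
        assert out["median_r"].iloc[0] <= out["median_r"].iloc[-1] + 1e-9

    def test_order_must_cover_lexicon(self, small_scenario, quick_config):
        sc = small_scenario
        tgt = sc.target_ratings.subset_molecules(sc.shared_ids)
        with pytest.raises(ValueError, match="cover"):
            descriptor_sweep(["s01"], sc.space_source, sc.space_target,
                             sc.source_ratings, tgt, config=quick_config)


class TestAuc:
    def test_separable_and_reversed(self):
        scores = np.array([5.0, 4.0, 3.0, 1.0, 0.5])
        assert auc_paradigm(scores, [0, 1]) == 1.0
        assert auc_paradigm(-scores, [0, 1]) == 0.0

    def test_all_ties_give_half(self):
        assert auc_paradigm(np.ones(6), [0, 3]) == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_complement_identity_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.normal(size=n).round(1)  # rounding forces ties
        k = int(rng.integers(1, n))
        pos = rng.choice(n, size=k, replace=False)
        assert auc_paradigm(scores, pos) + auc_paradigm(-scores, pos) == 1.0

    def test_degenerate_classes_rejected(self):
        with pytest.raises(ValueError):
            auc_paradigm(np.ones(3), [0, 1, 2])


class TestParadigmTests:
    def test_identical_distributions_boundary(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        p = paradigm_family_test(scores, [0, 1, 2])
        assert p == pytest.approx(0.5)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        neg = rng.normal(size=30)
        pos = rng.normal(size=10) + 10.0
        scores = np.concatenate([pos, neg])
        assert paradigm_family_test(scores, range(10)) < 1e-4

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paradigm_family_test(np.ones(8), [0, 1])

    def test_ks_uniform_calibration(self):
        rng = np.random.default_rng(1)
        ok = sum(
            ks_uniformity(rng.uniform(size=1000)) > 0.01 for _ in range(100)
        )
        assert ok >= 95

    def test_ks_detects_non_uniform(self):
        rng = np.random.default_rng(2)
        assert ks_uniformity(rng.uniform(size=500) ** 3) < 1e-6
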