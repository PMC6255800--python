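import numpy as np
import pytest

from odortransfer.containers import (
    ChemFeatureTable,
    DescriptorLexicon,
    RatingsTable,
    SemanticSpace,
)
from odortransfer.regression import ElasticNetConfig
from odortransfer.transfer import (
    TransferModel,
    compute_baseline,
    fit_chem_to_perception,
    fit_ratings_transfer,
    fit_semantic_transfer,
    fit_transfer_model,
    load_model,
    predict,
    save_model,
)


def _lex(n, prefix="d"):
    return DescriptorLexicon([f"{prefix}{i}" for i in range(n)])


class TestComputeBaseline:
    def test_elementwise_mean(self):
        t = RatingsTable(("a", "b"), _lex(2), [[0.0, 2.0], [4.0, 2.0]])
        assert np.allclose(compute_baseline(t), [2.0, 2.0])

    def test_identical_rows_return_that_row(self):
        t = RatingsTable(("a", "b"), _lex(3), [[1.0, 2.0, 3.0]] * 2)
        assert np.allclose(compute_baseline(t), [1.0, 2.0, 3.0])

    def test_empty_training_set_gives_zero_vector(self):
        assert np.array_equal(compute_baseline(None, _lex(4)), np.zeros(4))
        empty = RatingsTable((), _lex(4), np.empty((0, 4)))
        assert np.array_equal(compute_baseline(empty), np.zeros(4))


class TestSemanticTransfer:
    def test_planted_map_recovered_exactly_without_noise(self, rng,
                                                         unpenalized_config):
        dim, d_s, d_t = 60, 6, 15
        E_s = rng.normal(size=(d_s, dim))
        A = rng.normal(size=(d_t, d_s))
        src = SemanticSpace(_lex(d_s, "s"), E_s)
        tgt = SemanticSpace(_lex(d_t, "t"), A @ E_s)
        S = fit_semantic_transfer(src, tgt, unpenalized_config)
        assert np.allclose(S.weights, A, atol=1e-4)
        assert np.allclose(S.offset, 0.0)

    def test_identical_lexicons_give_diagonal_dominance(self, rng,
                                                        unpenalized_config):
        E = rng.normal(size=(8, 50))
        space = SemanticSpace(_lex(8), E)
        S = fit_semantic_transfer(space, space, unpenalized_config)
        assert np.allclose(S.weights, np.eye(8), atol=1e-8)

    def test_recovery_error_monotone_in_noise(self, rng, unpenalized_config):
        dim, d_s, d_t = 80, 6, 12
        E_s = rng.normal(size=(d_s, dim))
        A = rng.normal(size=(d_t, d_s))
        errs = []
        for sigma in (0.0, 0.1, 0.5):
            tgt_vectors = A @ E_s + sigma * rng.normal(size=(d_t, dim))
            S = fit_semantic_transfer(
                SemanticSpace(_lex(d_s, "s"), E_s),
                SemanticSpace(_lex(d_t, "t"), tgt_vectors),
                unpenalized_config,
            )
            errs.append(float(np.linalg.norm(S.weights - A)))
        assert errs[0] < errs[1] < errs[2]

    def test_single_source_descriptor_rejected(self, rng, unpenalized_config):
        src = SemanticSpace(_lex(1, "s"), rng.normal(size=(1, 10)))
        tgt = SemanticSpace(_lex(3, "t"), rng.normal(size=(3, 10)))
        with pytest.raises(ValueError, match="at least 2"):
            fit_semantic_transfer(src, tgt, unpenalized_config)


class TestRatingsTransfer:
    def test_planted_doubling_recovered(self, rng, unpenalized_config):
        src_vals = rng.uniform(0, 50, size=(20, 4))
        src = RatingsTable(tuple(f"m{i}" for i in range(20)), _lex(4), src_vals)
        tgt = RatingsTable(src.molecule_ids, _lex(4), 2.0 * src_vals,
                           check_bounds=False)
        R = fit_ratings_transfer(src, tgt, np.zeros(4), unpenalized_config)
        assert np.allclose(R.weights, 2.0 * np.eye(4), atol=1e-8)

    def test_constant_target_equal_to_baseline_gives_zero_weights(
        self, rng, unpenalized_config
    ):
        src_vals = rng.uniform(0, 50, size=(15, 3))
        baseline = np.array([1.0, 2.0, 3.0])
        src = RatingsTable(tuple(f"m{i}" for i in range(15)), _lex(3), src_vals)
        tgt = RatingsTable(src.molecule_ids, _lex(3),
                           np.tile(baseline, (15, 1)), check_bounds=False)
        R = fit_ratings_transfer(src, tgt, baseline, unpenalized_config)
        assert np.allclose(R.weights, 0.0, atol=1e-8)
        assert np.allclose(R.offset, 0.0, atol=1e-8)

    def test_noisy_planted_map_recovered_with_high_correlation(self):
        rng = np.random.default_rng(5)
        n, d_s, d_t = 50, 4, 6
        A = rng.normal(size=(d_t, d_s))
        src_vals = rng.uniform(0, 10, size=(n, d_s))
        tgt_vals = src_vals @ A.T + 0.1 * rng.normal(size=(n, d_t))
        src = RatingsTable(tuple(f"m{i}" for i in range(n)), _lex(d_s), src_vals)
        tgt = RatingsTable(src.molecule_ids, _lex(d_t, "t"), tgt_vals,
                           check_bounds=False)
        R = fit_ratings_transfer(src, tgt, np.zeros(d_t),
                                 ElasticNetConfig((0.0, 0.01), (0.0,), inner_folds=5))
        r = np.corrcoef(R.weights.ravel(), A.ravel())[0, 1]
        assert r > 0.95

    def test_too_few_molecules_rejected(self, unpenalized_config):
        src = RatingsTable(("m1",), _lex(3), [[1.0, 2.0, 3.0]])
        tgt = RatingsTable(("m1",), _lex(3), [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="at least 2"):
            fit_ratings_transfer(src, tgt, None, unpenalized_config)


class TestChemToPerception:
    def test_zero_noise_planted_map_recovered(self, rng, unpenalized_config):
        n, p, q = 80, 30, 4
        X = rng.normal(size=(n, p))
        C = rng.normal(size=(q, p))
        feats = ChemFeatureTable(tuple(f"m{i}" for i in range(n)),
                                 tuple(f"f{j}" for j in range(p)), X)
        ratings = RatingsTable(feats.molecule_ids, _lex(q), X @ C.T,
                               check_bounds=False)
        fitted = fit_chem_to_perception(feats, ratings, unpenalized_config)
        assert np.allclose(fitted.weights, C, atol=1e-4)

    def test_planted_sparse_map_predicts_held_out_molecules(self):
        """20 of 500 active features, n=300, sigma=0.05: held-out r > 0.95."""
        rng = np.random.default_rng(11)
        n, p, q = 300, 500, 3
        X = rng.normal(size=(n + 50, p))
        C = np.zeros((q, p))
        for k in range(q):
            C[k, rng.choice(p, 20, replace=False)] = rng.normal(size=20)
        Y = X @ C.T + 0.05 * rng.normal(size=(n + 50, q))
        feats = ChemFeatureTable(tuple(f"m{i}" for i in range(n)),
                                 tuple(f"f{j}" for j in range(p)), X[:n])
        ratings = RatingsTable(feats.molecule_ids, _lex(q), Y[:n],
                               check_bounds=False)
        fitted = fit_chem_to_perception(
            feats, ratings,
            ElasticNetConfig((1.0, 10.0), (1.0,), inner_folds=3, seed=0),
        )
        preds = fitted.predict(X[n:])
        for k in range(q):
            assert np.corrcoef(preds[:, k], Y[n:, k])[0, 1] > 0.95

    def test_all_zero_features_predict_offset(self, rng, unpenalized_config):
        n, p, q = 20, 5, 2
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q))
        feats = ChemFeatureTable(tuple(f"m{i}" for i in range(n)),
                                 tuple(f"f{j}" for j in range(p)), X)
        ratings = RatingsTable(feats.molecule_ids, _lex(q), Y, check_bounds=False)
        fitted = fit_chem_to_perception(feats, ratings, unpenalized_config)
        assert np.allclose(fitted.predict(np.zeros((3, p))), fitted.offset)


class TestPredict:
    def _model(self, rng, d_s=4, d_t=6):
        S = rng.normal(size=(d_t, d_s))
        R = rng.normal(size=(d_t, d_s))
        baseline = rng.normal(size=d_t)
        from odortransfer.regression import LinearMap

        return TransferModel(
            "mixed",
            _lex(d_t, "t"),
            S=LinearMap(S, np.zeros(d_t)),
            R=LinearMap(R, np.zeros(d_t)),
            baseline_vector=baseline,
            source_lexicon=_lex(d_s, "s"),
        )

    def test_mixed_equals_mean_of_components_exactly(self, rng):
        from dataclasses import replace

        model = self._model(rng)
        src = RatingsTable(("m1", "m2"), _lex(4, "s"),
                           rng.uniform(0, 100, (2, 4)))
        mixed = predict(model, src).values
        sem = predict(replace(model, kind="dirsem"), src).values
        rat = predict(replace(model, kind="dirrat"), src).values
        assert np.array_equal(mixed, 0.5 * (sem + rat))

    def test_equal_maps_make_mixed_equal_dirsem(self, rng):
        from dataclasses import replace

        model = self._model(rng)
        model = replace(model, R=model.S)
        src = RatingsTable(("m1",), _lex(4, "s"), rng.uniform(0, 100, (1, 4)))
        assert np.allclose(
            predict(model, src).values,
            predict(replace(model, kind="dirsem"), src).values,
        )

    def test_baseline_model_broadcasts_mean_vector(self, rng):
        baseline = rng.normal(size=5)
        model = TransferModel("baseline", _lex(5, "t"), baseline_vector=baseline)
        src = RatingsTable(("m1", "m2", "m3"), _lex(2, "s"), np.ones((3, 2)))
        out = predict(model, src)
        assert np.array_equal(out.values, np.tile(baseline, (3, 1)))

    def test_missing_map_raises_naming_requirement(self):
        with pytest.raises(ValueError, match="requires map S"):
            TransferModel("dirsem", _lex(3, "t"))

    def test_imputed_kind_rejects_ratings_input(self, rng):
        from odortransfer.regression import LinearMap

        model = TransferModel(
            "impsem",
            _lex(3, "t"),
            S=LinearMap(rng.normal(size=(3, 2)), np.zeros(3)),
            C=LinearMap(rng.normal(size=(2, 4)), np.zeros(2)),
        )
        src = RatingsTable(("m1",), _lex(2, "s"), [[1.0, 2.0]])
        with pytest.raises(TypeError, match="ChemFeatureTable"):
            predict(model, src)


class TestZeroShotProperty:
    def test_semantic_fitter_accepts_no_ratings(self):
        """The semantic map's fit signature admits no ratings tables at all."""
        import inspect

        params = inspect.signature(fit_semantic_transfer).parameters
        assert all("rating" not in name for name in params)


class TestModelRoundtrip:
    def test_save_load_preserves_predictions(self, tmp_path, rng):
        from odortransfer.regression import LinearMap

        model = TransferModel(
            "dirsem",
            _lex(5, "t"),
            S=LinearMap(rng.normal(size=(5, 3)), rng.normal(size=5),
                        (0.1, 1.0)),
            baseline_vector=rng.normal(size=5),
            source_lexicon=_lex(3, "s"),
            target_scale=(0.0, 5.0),
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        src = RatingsTable(("m1", "m2"), _lex(3, "s"), rng.uniform(0, 9, (2, 3)))
        assert np.allclose(predict(back, src).values, predict(model, src).values,
                           atol=1e-12)
        assert back.kind == model.kind
        assert back.target_scale == model.target_scale


class TestFitTransferModel:
    def test_end_to_end_kinds_on_scenario(self, small_scenario, quick_config):
        sc = small_scenario
        tgt_shared = sc.target_ratings.subset_molecules(sc.shared_ids)
        model = fit_transfer_model(
            "dirsem",
            space_source=sc.space_source,
            space_target=sc.space_target,
            target_ratings=tgt_shared,
            config=quick_config,
        )
        preds = predict(model, sc.source_ratings)
        assert preds.values.shape == (len(sc.shared_ids),
                                      len(sc.space_target.lexicon))

        imp = fit_transfer_model(
            "imprat",
            source_ratings=sc.source_ratings,
            target_ratings=sc.target_ratings,
            features=sc.features,
            config=quick_config,
        )
        extra = [m for m in sc.target_ratings.molecule_ids
                 if m not in sc.shared_ids]
        preds2 = predict(imp, sc.features.subset_molecules(extra))
        assert preds2.values.shape == (len(extra), sc.target_ratings.n_descriptors)
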