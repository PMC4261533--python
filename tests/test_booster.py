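import numpy as np
import pytest

from rankcost import (
    LossParams,
    PairSet,
    TrainConfig,
    build_pairs,
    compute_threshold,
    fit,
    indicator_loss,
    line_search_rho,
    load_model,
    relaxed_loss,
    save_model,
)
from rankcost.booster import RankCostModel
from conftest import random_ranking_instance


class TestLineSearch:
    def test_zero_direction_returns_zero(self):
        pairs = build_pairs(np.array([1, -1]))
        assert line_search_rho(np.zeros(2), np.zeros(2), pairs, LossParams(1.0)) == 0.0

    def test_single_pair_closed_form(self):
        # g(rho) = 1/2 max(0, 1 - 2 rho)^2, minimized first at rho = 1/2
        pairs = build_pairs(np.array([1, -1]))
        rho = line_search_rho(np.zeros(2), np.array([1.0, -1.0]), pairs, LossParams(1.0))
        assert rho == pytest.approx(0.5, abs=1e-7)

    def test_beats_random_probes(self, rng):
        for _ in range(5):
            _, scores, tau, pairs = random_ranking_instance(rng)
            direction = rng.normal(size=scores.shape[0])
            params = LossParams(tau)
            rho = line_search_rho(scores, direction, pairs, params, rho_max=100.0)
            best = relaxed_loss(scores + rho * direction, pairs, params)
            probes = rng.uniform(0, 100.0, size=1000)
            for p in probes:
                assert best <= relaxed_loss(scores + p * direction, pairs, params) + 1e-7


class TestThreshold:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [([2.0, 2.0], [0.0], 1.0), ([3.0], [3.0, 3.0], 3.0), ([1.0, 3.0], [0.0, 0.0, 0.0], 1.0)],
    )
    def test_midpoint_of_class_means(self, pos, neg, expected):
        assert compute_threshold(np.array(pos), np.array(neg)) == pytest.approx(expected)

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            compute_threshold(np.array([]), np.array([1.0]))


class TestFit:
    def test_initial_loss_is_half_k_tau_squared(self, moderate_data):
        config = TrainConfig(max_iter=5, tau=0.7, seed=0)
        model = fit(moderate_data, config)
        k = moderate_data.n_pos * moderate_data.n_neg
        assert model.loss_trace[0] == pytest.approx(0.5 * k * 0.7**2)

    def test_loss_trace_never_increases(self, separable_data, moderate_data, null_data):
        for data in (separable_data, moderate_data, null_data):
            trace = np.array(fit(data, TrainConfig(seed=1)).loss_trace)
            assert np.all(np.diff(trace) <= 1e-9 * max(1.0, trace[0]))

    def test_separable_fixture_is_perfectly_ranked(self, separable_data):
        model = fit(separable_data, TrainConfig(seed=1))
        pairs = build_pairs(separable_data.labels)
        scores = model.score(separable_data.features)
        assert indicator_loss(scores, pairs) == 0
        np.testing.assert_array_equal(model.predict(separable_data.features),
                                      separable_data.labels)

    def test_final_trace_entry_matches_rescoring(self, moderate_data):
        config = TrainConfig(seed=2)
        model = fit(moderate_data, config)
        pairs = build_pairs(moderate_data.labels)
        scores = model.score(moderate_data.features)
        assert relaxed_loss(scores, pairs, LossParams(config.tau)) == pytest.approx(
            model.loss_trace[-1], rel=1e-9, abs=1e-12
        )

    def test_threshold_lies_between_class_mean_scores(self, moderate_data, null_data):
        for data in (moderate_data, null_data):
            model = fit(data, TrainConfig(seed=3))
            scores = model.score(data.features)
            mu_pos = scores[data.labels == 1].mean()
            mu_neg = scores[data.labels == -1].mean()
            lo, hi = sorted([mu_pos, mu_neg])
            assert lo - 1e-12 <= model.threshold <= hi + 1e-12

    def test_fit_is_deterministic(self, moderate_data):
        a = fit(moderate_data, TrainConfig(seed=5))
        b = fit(moderate_data, TrainConfig(seed=5))
        assert a.loss_trace == b.loss_trace
        np.testing.assert_array_equal(a.predict(moderate_data.features),
                                      b.predict(moderate_data.features))

    def test_single_class_is_an_error(self):
        from rankcost import LabeledDataset
        data = LabeledDataset(np.zeros((3, 1)), np.array([1, 1, 1]))
        with pytest.raises(ValueError):
            fit(data, TrainConfig(max_iter=1))

    def test_shrinkage_and_depth_are_honored(self, moderate_data):
        model = fit(moderate_data, TrainConfig(max_iter=3, shrinkage=0.5,
                                               tree_max_depth=1, seed=0))
        assert model.shrinkage == 0.5
        for tree in model.base_learners:
            assert tree.children_left.size <= 3  # depth-1 tree: root + 2 leaves


class TestScorePredict:
    def zero_model(self, p=2):
        return RankCostModel(base_learners=[], multipliers=[], tau=1.0,
                             threshold=0.0, n_features=p)

    def test_zero_iteration_model_scores_zero_and_predicts_minority(self):
        model = self.zero_model()
        X = np.random.default_rng(0).normal(size=(5, 2))
        assert np.all(model.score(X) == 0.0)
        # ties go to the minority class by the >= rule
        assert np.all(model.predict(X) == 1)

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="columns"):
            self.zero_model(p=3).score(np.zeros((2, 2)))

    def test_single_tree_model_is_scaled_tree_output(self, moderate_data):
        model = fit(moderate_data, TrainConfig(max_iter=1, shrinkage=0.8, seed=0))
        assert len(model.base_learners) == 1
        raw = model.base_learners[0].predict(moderate_data.features)
        np.testing.assert_allclose(model.score(moderate_data.features),
                                   0.8 * model.multipliers[0] * raw)


class TestSerialization:
    def test_round_trip_scores_identically(self, moderate_data, tmp_path, rng):
        model = fit(moderate_data, TrainConfig(seed=4))
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        probe = rng.normal(size=(40, moderate_data.features.shape[1]))
        np.testing.assert_array_equal(model.score(probe), loaded.score(probe))
        np.testing.assert_array_equal(model.predict(probe), loaded.predict(probe))
        assert loaded.loss_trace == model.loss_trace
        assert [m.name for m in loaded.feature_meta] == [m.name for m in model.feature_meta]

    def test_truncated_file_is_a_structured_error(self, separable_data, tmp_path):
        path = tmp_path / "model.json"
        save_model(fit(separable_data, TrainConfig(max_iter=2, seed=0)), path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ValueError, match="malformed"):
            load_model(path)

    def test_foreign_and_wrong_version_files_rejected(self, tmp_path):
        p = tmp_path / "other.json"
        p.write_text('{"hello": 1}')
        with pytest.raises(ValueError, match="not a rankcost model"):
            load_model(p)
        p.write_text('{"format": "rankcost-model", "version": 99}')
        with pytest.raises(ValueError, match="version"):
            load_model(p)
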