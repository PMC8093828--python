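"""Model grid, kappa, OOB training and the minimum-depth decision."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from ampdepth import (
    AsvTable,
    ModelGridResult,
    ModelRecord,
    ParameterError,
    RfConfig,
    build_model_grid,
    cohen_kappa,
    default_mtry,
    evaluate_level,
    kappa_band,
    min_depth_for_target,
    rarefy_table,
    to_relative_abundance,
    train_rf_oob,
)


class TestDefaultMtry:
    @pytest.mark.parametrize(
        "p, expected", [(3039, 55), (1, 1), (49, 7), (4, 2), (2, 1)]
    )
    def test_floor_sqrt(self, p, expected):
        assert default_mtry(p) == expected

    def test_invalid(self):
        with pytest.raises(ParameterError):
            default_mtry(0)


class TestModelGrid:
    def test_default_grid_is_21_configs(self):
        grid = build_model_grid(3039)
        assert len(grid) == 21
        assert sorted({c.mtry for c in grid}) == [52, 53, 54, 55, 56, 57, 58]
        assert len({c.seed for c in grid}) == 3

    def test_clipping_deduplicates_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            grid = build_model_grid(4)
        # default mtry 2, offsets -3..+3 clipped into [1, 4]
        assert sorted({c.mtry for c in grid}) == [1, 2, 3, 4]
        assert len(grid) == 12

    def test_degenerate_grid(self):
        grid = build_model_grid(100, offsets=(0,), n_runs=1)
        assert len(grid) == 1 and grid[0].mtry == 10


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(["a", "b", "c"], ["a", "b", "c"]) == 1.0

    def test_hand_computed_confusion(self):
        # confusion [[2,1],[1,2]]: p_o=2/3, p_e=1/2 -> kappa 1/3
        y_true = ["x", "x", "x", "y", "y", "y"]
        y_pred = ["x", "x", "y", "x", "y", "y"]
        assert cohen_kappa(y_true, y_pred) == pytest.approx(1 / 3)

    def test_relabeling_invariance(self):
        y_true = ["a", "a", "b", "c", "b", "c", "a"]
        y_pred = ["a", "b", "b", "c", "c", "c", "a"]
        swap = {"a": "z", "b": "y", "c": "x"}
        assert cohen_kappa(y_true, y_pred) == pytest.approx(
            cohen_kappa([swap[v] for v in y_true], [swap[v] for v in y_pred])
        )

    def test_both_constant_and_equal_is_one(self):
        assert cohen_kappa(["a", "a"], ["a", "a"]) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            cohen_kappa([], [])

    def test_matches_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            y1 = rng.integers(0, 3, size=40)
            y2 = rng.integers(0, 3, size=40)
            assert cohen_kappa(y1, y2) == pytest.approx(
                cohen_kappa_score(y1, y2), abs=1e-12
            )


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.88, "almost_perfect"),
            (0.82, "almost_perfect"),
            (0.71, "moderate"),
            (0.8, "moderate"),  # strictly > 0.8 rule
            (0.6, "moderate"),  # strictly < 0.6 rule
            (0.59, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_boundaries(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            kappa_band(float("nan"))


class TestTrainRfOob:
    def test_separable_classes_near_perfect(self, hard_table):
        rel = to_relative_abundance(hard_table)
        res = train_rf_oob(rel, RfConfig(n_trees=500, mtry=18, seed=0))
        assert res.oob_error < 0.05
        assert res.kappa > 0.8

    def test_permuted_labels_near_zero_kappa(self, hard_table):
        rel = to_relative_abundance(hard_table)
        kappas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            perm = pd.Series(
                rng.permutation(rel.labels.to_numpy()), index=rel.values.index
            )
            shuffled = type(rel)(rel.values, perm)
            res = train_rf_oob(shuffled, RfConfig(n_trees=200, mtry=18, seed=1))
            kappas.append(res.kappa)
        assert abs(np.median(kappas)) < 0.15

    def test_reproducible_from_seed(self, hard_table):
        rel = to_relative_abundance(hard_table)
        cfg = RfConfig(n_trees=120, mtry=10, seed=9)
        r1, r2 = train_rf_oob(rel, cfg), train_rf_oob(rel, cfg)
        assert r1.oob_error == r2.oob_error and r1.kappa == r2.kappa

    def test_single_class_errors(self, hard_table):
        rel = to_relative_abundance(hard_table)
        one = type(rel)(
            rel.values, pd.Series("x", index=rel.values.index)
        )
        with pytest.raises(ParameterError, match="2 classes"):
            train_rf_oob(one, RfConfig(n_trees=10, mtry=5, seed=0))

    def test_tiny_forest_excludes_unscored_samples_with_warning(self, hard_table):
        rel = to_relative_abundance(hard_table)
        with pytest.warns(UserWarning, match="out-of-bag"):
            res = train_rf_oob(rel, RfConfig(n_trees=2, mtry=5, seed=0))
        assert res.n_excluded > 0
        assert len(res.predictions) == hard_table.n_samples - res.n_excluded


class TestEvaluateLevel:
    def test_record_count_matches_grid(self, hard_table):
        grid = build_model_grid(
            hard_table.n_asvs, offsets=(-1, 0, 1), n_runs=2, n_trees=60
        )
        result = evaluate_level(hard_table, grid, depth_level="full")
        assert len(result.records) == len(grid) == 6
        assert result.band == kappa_band(result.median_kappa)

    def test_reproducible_summaries(self, hard_table):
        grid = build_model_grid(hard_table.n_asvs, offsets=(0,), n_runs=2, n_trees=60)
        r1 = evaluate_level(hard_table, grid)
        r2 = evaluate_level(hard_table, grid)
        assert r1.median_kappa == r2.median_kappa
        assert r1.mean_oob_error == r2.mean_oob_error

    def test_best_model_tie_breaking(self):
        records = [
            ModelRecord(mtry=5, seed=0, oob_error=0.2, kappa=0.9),
            ModelRecord(mtry=4, seed=0, oob_error=0.1, kappa=0.9),
            ModelRecord(mtry=3, seed=0, oob_error=0.1, kappa=0.9),
            ModelRecord(mtry=2, seed=0, oob_error=0.3, kappa=0.5),
        ]
        best = ModelGridResult("full", records).best
        assert (best.mtry, best.oob_error) == (3, 0.1)


def _grid_result(depth, kappa):
    return ModelGridResult(
        depth, [ModelRecord(mtry=5, seed=0, oob_error=0.1, kappa=kappa)]
    )


class TestMinDepthDecision:
    LADDER = (15_177, 12_500, 10_000, 7_500, 5_000, 2_500, 1_000)

    def test_contiguous_almost_perfect_run(self):
        # AP down to 5000, then moderate: minimum sufficient depth is 5000
        kappas = (0.9, 0.9, 0.88, 0.85, 0.83, 0.7, 0.65)
        decision = min_depth_for_target(
            _grid_result("full", 0.9),
            [_grid_result(d, k) for d, k in zip(self.LADDER, kappas)],
        )
        assert decision.benchmark_band == "almost_perfect"
        assert decision.min_depth == 5_000

    def test_all_levels_pass_gives_shallowest(self):
        decision = min_depth_for_target(
            _grid_result("full", 0.85),
            [_grid_result(d, 0.9) for d in self.LADDER],
        )
        assert decision.min_depth == self.LADDER[-1]

    def test_band_above_benchmark_counts_as_passing(self):
        # moderate benchmark; ladder mixes almost-perfect and moderate
        kappas = (0.9, 0.7, 0.85, 0.65, 0.7, 0.5, 0.4)
        decision = min_depth_for_target(
            _grid_result("full", 0.7),
            [_grid_result(d, k) for d, k in zip(self.LADDER, kappas)],
        )
        assert decision.benchmark_band == "moderate"
        assert decision.min_depth == 5_000

    def test_first_level_failing_is_not_reached(self):
        decision = min_depth_for_target(
            _grid_result("full", 0.9),
            [_grid_result(d, 0.7) for d in self.LADDER],
        )
        assert decision.min_depth is None
        assert not decision.reached

    def test_gap_breaks_contiguity(self):
        # a failing level mid-ladder stops the run even if deeper... levels pass
        kappas = (0.9, 0.9, 0.7, 0.9, 0.9, 0.9, 0.9)
        decision = min_depth_for_target(
            _grid_result("full", 0.9),
            [_grid_result(d, k) for d, k in zip(self.LADDER, kappas)],
        )
        assert decision.min_depth == 12_500

    def test_misordered_ladder_rejected(self):
        with pytest.raises(ParameterError, match="decreasing"):
            min_depth_for_target(
                _grid_result("full", 0.9),
                [_grid_result(1_000, 0.9), _grid_result(5_000, 0.9)],
            )

    def test_empty_ladder_rejected(self):
        with pytest.raises(ParameterError):
            min_depth_for_target(_grid_result("full", 0.9), [])
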