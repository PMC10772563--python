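"""Time-varying AUROC, bootstrap, calibration, importance, subgroups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ecgdynrisk import experiments
from ecgdynrisk.evaluation import (
    bootstrap_ci,
    calibration_deciles,
    calibration_slope,
    interval_aurocs,
    mean_time_varying_auroc,
    permutation_importance,
    subgroup_performance,
    time_specific_auroc,
)
from ecgdynrisk.survival import Hyperparams, fit_hazard_forest


def _auroc_pairwise(pred, event):
    """O(n^2) oracle: P(case > control) + half credit for ties."""
    cases = pred[event == 1]
    controls = pred[event == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestTimeSpecificAuroc:
    def test_perfect_separation(self):
        pred = np.array([0.9] * 5 + [0.1] * 5)
        event = np.array([1] * 5 + [0] * 5)
        assert time_specific_auroc(pred, event) == 1.0

    def test_all_ties_give_half(self):
        pred = np.full(10, 0.3)
        event = np.array([1] * 4 + [0] * 6)
        assert time_specific_auroc(pred, event) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = 50
            pred = rng.choice([0.1, 0.2, 0.3, 0.5, 0.8], size=n)
            event = rng.integers(0, 2, n)
            if event.sum() in (0, n):
                continue
            assert time_specific_auroc(pred, event) == pytest.approx(
                _auroc_pairwise(pred, event), abs=1e-12
            )

    @given(
        hnp.arrays(np.float64, 30, elements=st.floats(1e-3, 1.0)),
        st.integers(0, 10**6),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, pred, seed):
        event = np.random.default_rng(seed).integers(0, 2, 30)
        if event.sum() in (0, 30):
            return
        a = time_specific_auroc(pred, event)
        b = time_specific_auroc(np.exp(3 * pred), event)
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            time_specific_auroc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestMeanTimeVarying:
    def _per(self, aurocs, valid=None):
        valid = valid if valid is not None else [True] * len(aurocs)
        return pd.DataFrame(
            {"k": range(len(aurocs)), "n_at_risk": 10, "n_events": 3,
             "auroc": aurocs, "valid": valid}
        )

    def test_constant_intervals(self):
        m, s = mean_time_varying_auroc(self._per([0.7, 0.7, 0.7]))
        assert m == pytest.approx(0.7) and s == pytest.approx(0.0)

    def test_two_interval_mean(self):
        m, _ = mean_time_varying_auroc(self._per([0.6, 0.8]))
        assert m == pytest.approx(0.7)

    def test_invalid_intervals_excluded(self):
        m, _ = mean_time_varying_auroc(
            self._per([0.6, np.nan, 0.8], [True, False, True])
        )
        assert m == pytest.approx(0.7)

    def test_no_valid_intervals_error(self):
        with pytest.raises(ValueError):
            mean_time_varying_auroc(self._per([np.nan], [False]))

    def test_interval_table_flags_sparse_intervals(self):
        rows = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8)],
                "k": [0] * 4 + [1] * 4,
                "event": [1, 1, 0, 0, 1, 0, 0, 0],
                "pred": [0.8, 0.7, 0.2, 0.1, 0.9, 0.1, 0.2, 0.3],
            }
        )
        per = interval_aurocs(rows)
        assert per.loc[per["k"] == 0, "valid"].item()
        assert not per.loc[per["k"] == 1, "valid"].item()  # single event


class TestBootstrap:
    def _rows(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)],
             "value": rng.normal(size=n)}
        )

    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci(self._rows(), lambda df: 1.0, n_boot=50, seed=0)
        assert lo == hi == 1.0

    def test_clt_width_for_mean(self):
        rows = self._rows(200, seed=1)
        lo, hi = bootstrap_ci(
            rows, lambda df: df["value"].mean(), n_boot=500, seed=2
        )
        expect = 2 * 1.96 / np.sqrt(200)
        assert (hi - lo) == pytest.approx(expect, rel=0.25)

    def test_seeded_reproducibility(self):
        rows = self._rows(50, seed=3)
        a = bootstrap_ci(rows, lambda df: df["value"].mean(), 100, seed=7)
        b = bootstrap_ci(rows, lambda df: df["value"].mean(), 100, seed=7)
        assert a == b

    def test_point_estimate_inside_own_ci(self):
        # the statistic on the original data falls inside its 95% CI in the
        # vast majority of replicates
        inside = 0
        for seed in range(20):
            rows = self._rows(80, seed=100 + seed)
            stat = rows["value"].mean()
            lo, hi = bootstrap_ci(
                rows, lambda df: df["value"].mean(), 200, seed=seed
            )
            inside += int(lo <= stat <= hi)
        assert inside >= 18


class TestCalibration:
    def test_constructed_perfect_calibration(self):
        ps = np.repeat(np.linspace(0.05, 0.95, 10), 20)
        rng = np.random.default_rng(0)
        # exact group rates: event count per group = round(p * 20)
        d = np.concatenate(
            [np.repeat([1, 0], [round(p * 20), 20 - round(p * 20)])
             for p in np.linspace(0.05, 0.95, 10)]
        )
        table = calibration_deciles(ps, d)
        assert len(table) == 10
        np.testing.assert_allclose(table["mean_pred"], table["obs_rate"],
                                   atol=1e-12)

    def test_well_specified_simulation_slope_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.02, 0.5, 5000)
        d = (rng.random(5000) < p).astype(int)
        table = calibration_deciles(p, d)
        assert 0.8 <= calibration_slope(table) <= 1.2

    def test_all_tied_predictions_collapse_to_one_group(self):
        table = calibration_deciles(np.full(100, 0.3),
                                    np.random.default_rng(0).integers(0, 2, 100))
        assert len(table) == 1

    def test_counts_sum_to_rows(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        table = calibration_deciles(p, rng.integers(0, 2, 500))
        assert table["n"].sum() == 500


class TestPermutationImportance:
    @pytest.fixture(scope="class")
    def forest_rows(self):
        rows = experiments.hazard_recovery_cohort(500, seed=0)
        rng = np.random.default_rng(1)
        rows["noise"] = rng.normal(size=len(rows))
        rows["constant"] = 1.0  # can never be split on
        forest = fit_hazard_forest(
            rows, Hyperparams(n_trees=50), seed=0,
            feature_cols=["x", "noise", "constant"],
        )
        return forest, rows

    def test_unsplittable_feature_has_no_importance(self, forest_rows):
        forest, rows = forest_rows
        imp = permutation_importance(forest, rows, ["constant"], seed=0)
        assert abs(imp.iloc[0]["importance"]) < 0.005

    def test_signal_feature_outranks_noise(self, forest_rows):
        forest, rows = forest_rows
        imp = permutation_importance(forest, rows, ["x", "noise"], seed=1)
        imp = imp.set_index("feature")
        assert imp.loc["x", "importance"] > imp.loc["noise", "importance"]
        wins = sum(
            imp.loc["x", f"repeat_{i}"] > imp.loc["noise", f"repeat_{i}"]
            for i in range(5)
        )
        assert wins >= 4

    def test_five_repeats_reported_and_seeded(self, forest_rows):
        forest, rows = forest_rows
        a = permutation_importance(forest, rows, ["x"], seed=3)
        b = permutation_importance(forest, rows, ["x"], seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert {f"repeat_{i}" for i in range(5)} <= set(a.columns)

    def test_importance_sum_bounded_by_total_discrimination(self, forest_rows):
        # no set of permutations can destroy more discrimination than the
        # model has: sum of importances < n_features * (baseline - 0.5) + tol
        from ecgdynrisk.evaluation import (
            interval_aurocs,
            mean_time_varying_auroc,
        )

        forest, rows = forest_rows
        feats = ["x", "noise", "constant"]
        imp = permutation_importance(forest, rows, feats, seed=5)
        scored = rows.assign(pred=forest.predict_proba(rows))
        baseline, _ = mean_time_varying_auroc(interval_aurocs(scored))
        bound = len(feats) * (baseline - 0.5) + 0.05
        assert imp["importance"].sum() < bound

    def test_unknown_feature_rejected(self, forest_rows):
        forest, rows = forest_rows
        with pytest.raises(ValueError):
            permutation_importance(forest, rows, ["does_not_exist"])


class TestSubgroups:
    def _rows(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 400
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "k": rng.integers(0, 4, n),
                "event": rng.integers(0, 2, n),
                "pred": rng.random(n),
                "grp": rng.integers(0, 2, n),
            }
        )

    def test_identical_distributions_give_similar_aurocs(self):
        rows = self._rows()
        out = subgroup_performance(rows, "grp")
        vals = out["mean_auroc"].to_numpy()
        assert abs(vals[0] - vals[1]) < 0.15  # Monte-Carlo error band

    def test_eventless_group_flagged(self):
        rows = self._rows(1)
        rows.loc[rows["grp"] == 1, "event"] = 0
        out = subgroup_performance(rows, "grp")
        assert out.set_index("grp").loc[1, "degenerate"]

    def test_constant_grouping_equals_overall(self):
        rows = self._rows(2)
        rows["grp"] = 1
        out = subgroup_performance(rows, "grp")
        overall, _ = mean_time_varying_auroc(interval_aurocs(rows))
        assert len(out) == 1
        assert out.iloc[0]["mean_auroc"] == pytest.approx(overall)
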