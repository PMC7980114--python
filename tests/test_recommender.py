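"""Feeling-of-health model, feature partition, linear propagation, and
the NSGA-II counterfactual search against exhaustive grid oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseman import recommender as rec
from pulseman.errors import (ContractError, InsufficientDataError,
                             ParameterError)
from pulseman.synth import gen_wellbeing_dataset


def dominance_oracle(points):
    """O(n^2) front peeling by direct definition (minimization)."""
    remaining = list(range(len(points)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                all(points[j][k] <= points[i][k] for k in range(2))
                and any(points[j][k] < points[i][k] for k in range(2))
                for j in remaining if j != i)
            if not dominated:
                front.append(i)
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


def _rule_problem(label_noise):
    rng = np.random.default_rng(0)
    temp = rng.normal(24.0, 4.0, 500)
    noise = rng.random(500) < label_noise
    good = (temp <= 25.0) ^ noise
    df = pd.DataFrame({"temperature": temp,
                       "label": np.where(good, "good", "bad")})
    model = rec.train_health_model(df, seed=0)
    part = rec.partition_features(df, ["temperature"])
    return df, model, part


@pytest.fixture(scope="module")
def rule_problem():
    """Temperature-rule dataset (2% label noise) with model + partition."""
    return _rule_problem(0.02)


@pytest.fixture(scope="module")
def rule_problem_clean():
    """Noise-free temperature rule: the learned boundary is a single
    threshold, so grid oracles describe one contiguous good region."""
    return _rule_problem(0.0)


class TestHealthModel:
    def test_rule_recovered_with_high_accuracy(self, rule_problem):
        _, model, _ = rule_problem
        assert model.holdout_accuracy >= 95.0

    def test_predictions_binary(self, rule_problem):
        df, model, _ = rule_problem
        preds = model.predict(df.drop(columns="label"))
        assert set(preds) <= {"good", "bad"}

    def test_seeded_determinism(self, rule_problem):
        df, model, _ = rule_problem
        again = rec.train_health_model(df, seed=0)
        assert again.holdout_accuracy == model.holdout_accuracy

    def test_single_label_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "label": ["good", "good"]})
        with pytest.raises(InsufficientDataError):
            rec.train_health_model(df)


class TestPartition:
    def test_copied_feature_is_correlated(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=200)
        df = pd.DataFrame({"m": m, "copy": m,
                           "label": np.where(m > 0, "good", "bad")})
        part = rec.partition_features(df, ["m"])
        assert "copy" in part.correlated
        assert part.correlated["copy"].r_squared == pytest.approx(1.0)

    def test_independent_noise_is_uncorrelated(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"m": rng.normal(size=1000),
                           "noise": rng.normal(size=1000),
                           "label": ["good", "bad"] * 500})
        part = rec.partition_features(df, ["m"], threshold=0.3)
        assert part.uncorrelated == ("noise",)

    def test_constructed_correlation_detected(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=1000)
        f = 0.6 * m + 0.8 * rng.normal(size=1000)   # population r = 0.6
        df = pd.DataFrame({"m": m, "f": f, "label": ["good", "bad"] * 500})
        part = rec.partition_features(df, ["m"], threshold=0.3)
        assert "f" in part.correlated

    def test_sets_disjoint_and_cover_schema(self, wellbeing):
        df, _ = wellbeing
        part = rec.partition_features(df, ["temperature", "humidity"])
        groups = (set(part.modifiable), set(part.correlated),
                  set(part.uncorrelated))
        assert sum(len(g) for g in groups) == len(df.columns) - 1
        assert set().union(*groups) == set(df.columns) - {"label"}

    def test_constant_feature_warned_uncorrelated(self):
        df = pd.DataFrame({"m": np.arange(50.0), "const": 1.0,
                           "label": ["good", "bad"] * 25})
        with pytest.warns(UserWarning):
            part = rec.partition_features(df, ["m"])
        assert part.uncorrelated == ("const",)


class TestCorrelatedModels:
    def test_exact_linear_fit(self):
        m = np.linspace(-3, 3, 100)
        df = pd.DataFrame({"m": m, "f": 2.0 * m,
                           "label": ["good", "bad"] * 50})
        part = rec.partition_features(df, ["m"])
        lin = part.correlated["f"]
        assert lin.coef["m"] == pytest.approx(2.0)
        assert lin.intercept == pytest.approx(0.0, abs=1e-9)
        assert lin.r_squared == pytest.approx(1.0)

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=1000)
        df = pd.DataFrame({"m": m, "f": 3.0 + 0.5 * m + rng.normal(0, 0.1, 1000),
                           "label": ["good", "bad"] * 500})
        part = rec.partition_features(df, ["m"])
        assert 0.45 <= part.correlated["f"].coef["m"] <= 0.55

    def test_rank_deficient_design_warned(self):
        df = pd.DataFrame({"m1": np.arange(50.0), "m2": 2.0 * np.arange(50.0),
                           "f": np.arange(50.0), "label": ["good", "bad"] * 25})
        with pytest.warns(UserWarning):
            rec.partition_features(df, ["m1", "m2"])


class TestPropagate:
    @pytest.fixture()
    def linear_partition(self):
        m = np.linspace(-3, 3, 100)
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"m": m, "f": 2.0 * m,
                           "u": rng.normal(size=100),
                           "label": ["good", "bad"] * 50})
        return df, rec.partition_features(df, ["m"])

    def test_zero_deltas_identity(self, linear_partition):
        df, part = linear_partition
        record = df.drop(columns="label").iloc[7]
        out = rec.propagate(record, {"m": 0.0}, part)
        assert out.equals(record)

    def test_linear_shift(self, linear_partition):
        df, part = linear_partition
        record = df.drop(columns="label").iloc[7]
        out = rec.propagate(record, {"m": 1.0}, part)
        assert out["m"] == record["m"] + 1.0
        assert out["f"] == pytest.approx(record["f"] + 2.0)

    def test_uncorrelated_untouched(self, linear_partition):
        df, part = linear_partition
        record = df.drop(columns="label").iloc[7]
        out = rec.propagate(record, {"m": 5.0}, part)
        assert out["u"] == record["u"]

    def test_delta_on_nonmodifiable_rejected(self, linear_partition):
        df, part = linear_partition
        with pytest.raises(ContractError):
            rec.propagate(df.drop(columns="label").iloc[0], {"f": 1.0}, part)


class TestObjectives:
    def test_zero(self):
        assert rec.objectives({"a": 0.0}, {"a": 10.0}) == (0.0, 0)

    def test_half_range(self):
        vol, n = rec.objectives({"a": 5.0}, {"a": 10.0})
        assert vol == 0.5 and n == 1

    def test_additive_over_disjoint_sets(self):
        ranges = {"a": 10.0, "b": 4.0}
        va, _ = rec.objectives({"a": 2.0}, ranges)
        vb, _ = rec.objectives({"b": 1.0}, ranges)
        vab, n = rec.objectives({"a": 2.0, "b": 1.0}, ranges)
        assert vab == pytest.approx(va + vb) and n == 2

    def test_zero_range_rejected(self):
        with pytest.raises(ParameterError):
            rec.objectives({"a": 1.0}, {"a": 0.0})


class TestNondominatedSort:
    def test_single_point(self):
        assert rec.nondominated_sort([(1.0, 1.0)]) == [[0]]

    def test_hand_example(self):
        fronts = rec.nondominated_sort([(1, 1), (2, 2), (1, 2), (2, 1)])
        assert fronts[0] == [0]
        assert sorted(fronts[1]) == [2, 3]
        assert fronts[2] == [1]

    def test_front_members_mutually_nondominating(self):
        rng = np.random.default_rng(6)
        pts = [tuple(p) for p in rng.integers(0, 5, (30, 2))]
        for front in rec.nondominated_sort(pts):
            for i in front:
                for j in front:
                    if i != j:
                        assert not rec._dominates(pts[i], pts[j])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 50))
    def test_matches_bruteforce_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = [tuple(p) for p in
               np.column_stack([rng.random(n), rng.integers(0, 4, n)])]
        got = [sorted(f) for f in rec.nondominated_sort(pts)]
        want = [sorted(f) for f in dominance_oracle(pts)]
        assert got == want


class TestRecommend:
    def test_already_good_record(self, rule_problem_clean):
        _, model, part = rule_problem_clean
        front = rec.recommend(pd.Series({"temperature": 18.0}), model, part,
                              {"temperature": (-10.0, 10.0)}, seed=0)
        assert front.status == "already-good" and len(front) == 0

    def test_1d_toy_matches_grid_oracle(self, rule_problem_clean):
        _, model, part = rule_problem_clean
        record = pd.Series({"temperature": 27.0})
        bounds = {"temperature": (-10.0, 10.0)}
        front = rec.recommend(record, model, part, bounds, seed=3)
        assert front.status == "ok" and len(front) == 1
        sol = front.solutions[0]
        assert sol.n_changed == 1
        # exhaustive grid search at step 0.01 over the bound box
        grid = np.arange(-10.0, 10.0001, 0.01)
        cand = pd.DataFrame({"temperature": 27.0 + grid})
        ok = model.predict(cand) == "good"
        oracle = np.min(np.abs(grid[ok])) / part.ranges["temperature"]
        assert abs(sol.volume - oracle) <= 0.02
        assert sol.deltas["temperature"] == pytest.approx(-2.0, abs=0.5)

    def test_2d_toy_single_feature_minima(self):
        """Either feature can flip the label; the front's single-feature
        solution matches the cheaper of the two axis-grid minima."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 600)
        b = rng.normal(0.0, 1.0, 600)
        good = (a <= 0.0) | (b <= 0.0)
        df = pd.DataFrame({"a": a, "b": b,
                           "label": np.where(good, "good", "bad")})
        model = rec.train_health_model(df, seed=0)
        part = rec.partition_features(df, ["a", "b"])
        record = pd.Series({"a": 1.0, "b": 1.5})
        bounds = {"a": (-4.0, 4.0), "b": (-4.0, 4.0)}
        front = rec.recommend(record, model, part, bounds, seed=4)
        assert front.status == "ok"
        # axis-wise grid oracles
        grid = np.arange(-4.0, 4.0001, 0.01)
        minima = {}
        for feat in ("a", "b"):
            cand = pd.DataFrame({f: np.full(grid.size, record[f])
                                 for f in ("a", "b")})
            cand[feat] = record[feat] + grid
            ok = model.predict(cand) == "good"
            minima[feat] = np.min(np.abs(grid[ok])) / part.ranges[feat]
        best1 = min(minima.values())
        ours1 = [s.volume for s in front if s.n_changed == 1]
        assert ours1 and abs(ours1[0] - best1) <= 0.02
        # mutual non-domination of the returned front
        pts = [(s.volume, s.n_changed) for s in front]
        assert rec.nondominated_sort(pts)[0] == list(range(len(pts)))

    def test_full_front_admissible(self, wellbeing):
        df, _ = wellbeing
        model = rec.train_health_model(df, seed=0)
        part = rec.partition_features(df, ["temperature", "humidity"])
        bounds = {"temperature": (-10.0, 10.0), "humidity": (-30.0, 30.0)}
        records = df.drop(columns="label")
        bad_rows = records[model.predict(records) == "bad"]
        for idx in bad_rows.index[:3]:
            front = rec.recommend(bad_rows.loc[idx], model, part, bounds,
                                  seed=8)
            assert front.status == "ok"
            for sol in front:
                assert sol.admissible
                after = rec.propagate(bad_rows.loc[idx], sol.deltas, part)
                assert model.predict(after.to_frame().T)[0] == "good"

    def test_no_solution_within_tight_bounds(self, rule_problem_clean):
        _, model, part = rule_problem_clean
        front = rec.recommend(pd.Series({"temperature": 35.0}), model, part,
                              {"temperature": (-0.5, 0.5)}, seed=0,
                              config=rec.NSGAConfig(population=20,
                                                    generations=10))
        assert front.status == "no-solution" and len(front) == 0
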