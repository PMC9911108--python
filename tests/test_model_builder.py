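"""Feature maps, spline designs, final SVM fit, prediction, stepwise search."""

import numpy as np
import pandas as pd
import pytest

from hingeselect.model_builder import (
    FeatureEntry,
    FeatureMap,
    PredictionError,
    TrainedModel,
    build_design,
    correlation_matrix,
    predict,
    select_spline_order,
    stepwise_forward,
    train_model,
)
from hingeselect.preprocessing import CohortTable
from hingeselect.validation import loo_cv


def _table(X, y, names=None):
    names = names or [f"v{j}" for j in range(X.shape[1])]
    data = pd.DataFrame(X, columns=names)
    labels = pd.Series(np.asarray(y, dtype=np.int8), index=data.index)
    return CohortTable(data=data, labels=labels)


class TestBuildDesign:
    def test_column_count_mixed_map(self, rng):
        X = rng.standard_normal((10, 3))
        t = _table(X, np.r_[np.ones(5), -np.ones(5)])
        fmap = FeatureMap((
            FeatureEntry("v0", "linear"),
            FeatureEntry("v1", "linear"),
            FeatureEntry("v2", "bspline", order=4),
        )).with_domains_from(t)
        d = build_design(t, fmap)
        assert d.values.shape == (10, 1 + 2 + 4)

    def test_partition_of_unity(self, rng):
        X = rng.standard_normal((50, 1))
        t = _table(X, np.where(rng.random(50) < 0.5, 1, -1))
        for order in (2, 3, 4):
            fmap = FeatureMap((FeatureEntry("v0", "bspline", order=order),)
                              ).with_domains_from(t)
            d = build_design(t, fmap)
            np.testing.assert_allclose(d.values[:, 1:].sum(axis=1), 1.0)

    def test_mirror_symmetry_of_basis(self):
        """On a symmetric domain, basis(x) equals reversed basis(-x)."""
        from hingeselect._splines import bspline_basis

        x = np.linspace(-2, 2, 41)
        B = bspline_basis(x, -2.0, 2.0, 4)
        B_mirror = bspline_basis(-x, -2.0, 2.0, 4)
        np.testing.assert_allclose(B, B_mirror[:, ::-1], atol=1e-12)

    def test_out_of_domain_clamped(self, rng):
        X = rng.standard_normal((20, 1))
        t = _table(X, np.where(rng.random(20) < 0.5, 1, -1))
        fmap = FeatureMap((FeatureEntry("v0", "bspline", order=3,
                                        domain=(-0.5, 0.5)),))
        d = build_design(t, fmap)
        from hingeselect._splines import bspline_basis

        hi = bspline_basis(0.5, -0.5, 0.5, 3)[0]
        big = X[:, 0] > 0.5
        if big.any():
            np.testing.assert_allclose(d.values[big, 1:],
                                       np.tile(hi, (int(big.sum()), 1)))

    def test_empty_map_rejected(self, toy_table):
        with pytest.raises(ValueError, match="empty"):
            build_design(toy_table, FeatureMap(()))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            FeatureEntry("x", "bspline", order=7)


class TestFitPredict:
    def test_separable_linear_toy_perfect(self, rng):
        x = np.r_[rng.normal(-2, 0.3, 10), rng.normal(2, 0.3, 10)]
        y = np.r_[-np.ones(10), np.ones(10)]
        model = train_model(_table(x[:, None], y), FeatureMap((FeatureEntry("v0", "linear"),)))
        preds = [model.predict({"v0": v})[1] for v in x]
        assert np.mean(np.asarray(preds) == y) == 1.0

    def test_huge_ridge_shrinks_to_intercept(self, rng):
        x = rng.standard_normal(30)
        y = np.where(x > 0, 1, -1)
        model = train_model(_table(x[:, None], y), FeatureMap((FeatureEntry("v0", "linear"),)),
                            ridge_lambda=1e6)
        assert abs(model.linear_coefs["v0"]) < 1e-3
        assert model.predict({"v0": 5.0})[1] == np.sign(model.intercept) or model.intercept == 0

    def test_agreement_with_reference_svm_solver(self):
        """Decision boundary within 2 degrees of sklearn's hinge SVM on a toy."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(5)
        n = 20
        X = np.r_[rng.normal([-1.5, -1.0], 0.6, (n // 2, 2)),
                  rng.normal([1.5, 1.0], 0.6, (n // 2, 2))]
        y = np.r_[-np.ones(n // 2), np.ones(n // 2)]
        C = 1.0
        ref = SVC(kernel="linear", C=C).fit(X, y)
        w_ref = ref.coef_[0]

        from hingeselect.smooth_hinge import DesignMatrix, FitConfig, PenaltySpec, fit_penalized

        design = DesignMatrix(np.column_stack([np.ones(n), X]), ("a", "b"))
        fit = fit_penalized(design, y, PenaltySpec("ridge", 1.0 / (2 * n * C)),
                            FitConfig(gamma=500.0, gamma_schedule=(5, 25, 100, 500)))
        w = fit.beta[1:]
        cos = w @ w_ref / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 2.0

    def test_predict_missing_variable_names_it(self, rng):
        x = rng.standard_normal(20)
        y = np.where(x > 0, 1, -1)
        model = train_model(_table(x[:, None], y), FeatureMap((FeatureEntry("v0", "linear"),)))
        with pytest.raises(PredictionError, match="v0"):
            predict(model, {"other": 1.0})

    def test_row_order_invariance_and_score_decomposition(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.where(X[:, 0] + np.abs(X[:, 1]) > 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        fmap = FeatureMap((FeatureEntry("v0", "linear"),
                           FeatureEntry("v1", "bspline", order=3)))
        model = train_model(_table(X, y), fmap)
        row = {"v0": 0.3, "v1": -0.7}
        s1, c1 = predict(model, row)
        s2, c2 = predict(model, dict(reversed(list(row.items()))))
        assert s1 == s2 and c1 == c2

    def test_json_round_trip_predicts_identically(self, rng):
        X = rng.standard_normal((50, 3))
        y = np.where(X[:, 0] - X[:, 1] ** 2 > -0.5, 1, -1)
        fmap = FeatureMap((FeatureEntry("v0", "linear"),
                           FeatureEntry("v1", "bspline", order=4),
                           FeatureEntry("v2", "linear")))
        model = train_model(_table(X, y), fmap)
        clone = TrainedModel.from_json(model.to_json())
        rows = rng.standard_normal((100, 3)) * 2
        for r in rows:
            row = {"v0": r[0], "v1": r[1], "v2": r[2]}
            assert clone.predict(row) == model.predict(row)


class TestStepwiseForward:
    def _signal_table(self, seed, n=60, p=5):
        r = np.random.default_rng(seed)
        X = r.standard_normal((n, p))
        y = np.where(1.8 * X[:, 0] - 1.6 * X[:, 1] + r.logistic(size=n) > 0, 1, -1)
        return _table(X, y)

    def test_matches_exhaustive_search(self):
        """Greedy growth equals brute force over all <=2-variable models."""
        t = self._signal_table(0, n=40, p=3)
        enc = {f"v{j}": "linear" for j in range(3)}
        model, trace = stepwise_forward(t, [f"v{j}" for j in range(3)], enc, max_vars=2)

        def acc(variables):
            fmap = FeatureMap(tuple(FeatureEntry(v, "linear") for v in variables))
            return loo_cv(t, fmap).accuracy

        # brute force: all one- and two-variable models reachable greedily
        best1 = max([("v%d" % j,) for j in range(3)], key=lambda s: acc(s))
        cands = [c for c in ["v0", "v1", "v2"] if c != best1[0]]
        best2 = max([best1 + (c,) for c in cands] + [best1], key=lambda s: acc(s))
        assert tuple(model.feature_map.variables) == best2

    def test_single_candidate(self):
        t = self._signal_table(1, n=30, p=2)
        model, trace = stepwise_forward(t, ["v0"], {"v0": "linear"}, max_vars=3)
        assert model.feature_map.variables == ["v0"]
        assert len(trace) == 1

    def test_signal_pair_found_among_decoys(self):
        """Variables carrying the signal enter within the first two steps."""
        hits = 0
        for seed in range(10):
            t = self._signal_table(seed, n=80, p=7)
            enc = {f"v{j}": "linear" for j in range(7)}
            model, trace = stepwise_forward(t, [f"v{j}" for j in range(7)], enc, max_vars=2)
            chosen = set(model.feature_map.variables)
            hits += int(trace.loc[0, "added"] in {"v0", "v1"} and chosen == {"v0", "v1"})
        assert hits >= 8

    def test_empty_candidates_rejected(self, toy_table):
        with pytest.raises(ValueError, match="candidate"):
            stepwise_forward(toy_table, [], {}, max_vars=1)


class TestSelectSplineOrder:
    def test_linear_truth_resolves_to_order_two(self):
        r = np.random.default_rng(2)
        x = r.standard_normal(80)
        y = np.where(2.5 * x + r.logistic(size=80) > 0, 1, -1)
        order = select_spline_order(_table(x[:, None], y), "v0", B=29, seed=0)
        assert order == 2

    def test_cubic_signal_prefers_higher_order(self):
        """An S-shaped dose-response beats the linear-like order-2 encoding."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal(100)
            f = np.tanh(3 * x) * 3.0
            y = np.where(f + r.logistic(size=100) > 0, 1, -1)
            t = _table(x[:, None], y)
            fmap2 = FeatureMap((FeatureEntry("v0", "bspline", order=2),))
            fmap4 = FeatureMap((FeatureEntry("v0", "bspline", order=4),))
            wins += int(loo_cv(t, fmap4).accuracy >= loo_cv(t, fmap2).accuracy)
        assert wins >= 8

    def test_pure_noise_returns_none(self):
        r = np.random.default_rng(4)
        x = r.standard_normal(40)
        y = np.where(r.random(40) < 0.5, 1, -1)
        order = select_spline_order(_table(x[:, None], y), "v0", B=49, seed=1,
                                    overfit_alpha=0.01)
        assert order is None


class TestCorrelationMatrix:
    def test_basic_identities(self, rng, tmp_path):
        x = rng.standard_normal(50)
        X = np.column_stack([x, -x, rng.standard_normal(50)])
        t = _table(X, np.where(rng.random(50) < 0.5, 1, -1))
        out = tmp_path / "heat.png"
        c = correlation_matrix(t, ["v0", "v1", "v2"], heatmap_path=out)
        assert c.loc["v0", "v0"] == pytest.approx(1.0)
        assert c.loc["v0", "v1"] == pytest.approx(-1.0)
        pd.testing.assert_frame_equal(c, c.T)
        assert out.exists()

    def test_constant_column_zeroed(self, rng, caplog):
        X = np.column_stack([np.full(20, 3.0), rng.standard_normal(20)])
        t = _table(X, np.where(rng.random(20) < 0.5, 1, -1))
        with caplog.at_level("WARNING"):
            c = correlation_matrix(t, ["v0", "v1"])
        assert c.loc["v0", "v1"] == 0.0
        assert c.loc["v0", "v0"] == 1.0

    def test_needs_two_variables(self, toy_table):
        with pytest.raises(ValueError, match="at least 2"):
            correlation_matrix(toy_table, ["a"])
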