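"""Standardized OLS, AIC scale selection, VIFs, landscape filtering."""

import numpy as np
import pandas as pd
import pytest

from forestscape.models import (
    CollinearityError,
    ComparabilityError,
    DegeneratePredictorError,
    FitResult,
    ModelSpec,
    ScaleSelectingLinearModel,
    fit_glm,
    select_locations,
    select_scale,
    standardize,
    transform_response,
)


class TestStandardize:
    def test_three_point_column_sample_sd(self):
        out = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.standard_normal(100)
        z = (x - x.mean()) / x.std(ddof=1)
        out = standardize(pd.DataFrame({"a": z}))
        np.testing.assert_allclose(out["a"], z, atol=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(DegeneratePredictorError, match="a"):
            standardize(pd.DataFrame({"a": [2.0, 2.0, 2.0]}))

    def test_moments_after_standardizing(self, rng):
        df = pd.DataFrame(rng.uniform(0, 100, (50, 3)), columns=list("abc"))
        out = standardize(df)
        assert np.abs(out.mean()).max() < 1e-10
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-10)


class TestTransformResponse:
    def test_negative_inverse_values(self):
        np.testing.assert_allclose(
            transform_response([1.0, 0.0], "negative-inverse"), [-0.5, -1.0]
        )

    def test_identity_passthrough(self):
        y = np.array([0.0, 3.5, 2.0])
        np.testing.assert_array_equal(transform_response(y, "identity"), y)

    def test_monotone_increasing(self):
        y = np.arange(0, 10, dtype=float)
        t = transform_response(y, "negative-inverse")
        assert (np.diff(t) > 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            transform_response([-1.0], "negative-inverse")

    def test_strict_variant(self):
        np.testing.assert_allclose(
            transform_response([2.0], "negative-inverse", strict=True), [-0.5]
        )
        with pytest.raises(ValueError):
            transform_response([0.0], "negative-inverse", strict=True)


def _sim_data(n, rng, beta_fa=0.34, beta_ag=-0.22, sigma=1.0, rho=0.3):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=n)
    fa = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
    ag = (X[:, 1] - X[:, 1].mean()) / X[:, 1].std(ddof=1)
    y = beta_fa * fa + beta_ag * ag + sigma * rng.standard_normal(n)
    return pd.DataFrame({"FA": fa, "AG": ag, "y": y})


class TestFitGLM:
    SPEC = ModelSpec(response="y", scale=1.0, landscape_predictors=("FA", "AG"))

    def test_recovers_true_betas_within_ci(self):
        rng = np.random.default_rng(0)
        data = _sim_data(5000, rng)
        res = fit_glm(self.SPEC, data)
        fa = res.effect("FA")
        ag = res.effect("AG")
        assert fa["lo"] <= 0.34 <= fa["hi"]
        assert ag["lo"] <= -0.22 <= ag["hi"]
        assert fa["beta"] == pytest.approx(0.34, abs=0.05)

    def test_ci_is_beta_pm_z_se(self):
        rng = np.random.default_rng(1)
        res = fit_glm(self.SPEC, _sim_data(500, rng))
        eff = res.effects
        np.testing.assert_allclose(eff["lo"], eff["beta"] - 1.96 * eff["se"])
        np.testing.assert_allclose(eff["hi"], eff["beta"] + 1.96 * eff["se"])

    def test_duplicate_predictor_raises_collinearity(self):
        rng = np.random.default_rng(2)
        data = _sim_data(200, rng)
        data["FA2"] = data["FA"]
        spec = ModelSpec(response="y", scale=1.0,
                         landscape_predictors=("FA", "FA2", "AG"))
        with pytest.raises(CollinearityError):
            fit_glm(spec, data)

    def test_orthonormal_predictors_unit_vif(self, rng):
        n = 400
        # orthonormal columns also orthogonal to the intercept
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        )
        data = pd.DataFrame(q[:, 1:], columns=["FA", "FPD", "AG"])
        data["y"] = rng.standard_normal(n)
        spec = ModelSpec(response="y", scale=1.0,
                         landscape_predictors=("FA", "FPD", "AG"))
        res = fit_glm(spec, data)
        for v in res.vif.values():
            assert v == pytest.approx(1.0, abs=1e-6)

    def test_standardized_beta_invariant_to_predictor_scaling(self):
        rng = np.random.default_rng(3)
        data = _sim_data(800, rng)
        res1 = fit_glm(self.SPEC, data)
        scaled = data.assign(FA=data["FA"] * 37.5)
        res2 = fit_glm(self.SPEC, scaled)
        assert res1.effect("FA")["beta"] == pytest.approx(
            res2.effect("FA")["beta"], abs=1e-10
        )

    def test_categorical_covariate_dummies_with_reference(self):
        rng = np.random.default_rng(4)
        data = _sim_data(300, rng)
        data["observer"] = rng.choice(["a", "b", "c"], 300, p=[0.6, 0.25, 0.15])
        spec = ModelSpec(response="y", scale=1.0, landscape_predictors=("FA", "AG"),
                         covariates_categorical=("observer",))
        res = fit_glm(spec, data)
        preds = set(res.effects["predictor"])
        # most frequent level "a" is the reference: no dummy for it
        assert "observer[b]" in preds and "observer[c]" in preds
        assert "observer[a]" not in preds

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(5)
        data = _sim_data(100, rng)
        data.loc[3, "FA"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_glm(self.SPEC, data)

    def test_ci_coverage_nominal(self):
        """95% CIs cover the truth at close to nominal rate."""
        rng = np.random.default_rng(42)
        hits = trials = 0
        for _ in range(200):
            res = fit_glm(self.SPEC, _sim_data(400, rng))
            for name, truth in (("FA", 0.34), ("AG", -0.22)):
                e = res.effect(name)
                hits += e["lo"] <= truth <= e["hi"]
                trials += 1
        assert 0.93 <= hits / trials <= 0.97

    def test_aic_invariant_to_response_shift(self):
        rng = np.random.default_rng(6)
        data = _sim_data(300, rng)
        res1 = fit_glm(self.SPEC, data)
        res2 = fit_glm(self.SPEC, data.assign(y=data["y"] + 100.0))
        assert res1.aic == pytest.approx(res2.aic, abs=1e-6)


def _fit_result(scale, aic, locs=(0, 1, 2)):
    eff = pd.DataFrame({"predictor": ["FA"], "beta": [0.1], "se": [0.05],
                        "lo": [0.0], "hi": [0.2]})
    return FitResult(scale=scale, effects=eff, aic=aic, n=len(locs),
                     location_ids=tuple(locs))


class TestSelectScale:
    def test_lowest_aic_wins(self):
        best = select_scale([_fit_result(1.0, 100.0), _fit_result(2.0, 90.0)])
        assert best.scale == 2.0

    def test_exact_tie_goes_to_smaller_radius(self):
        best = select_scale([_fit_result(2.0, 100.0), _fit_result(0.5, 100.0)])
        assert best.scale == 0.5

    def test_different_location_sets_not_comparable(self):
        with pytest.raises(ComparabilityError):
            select_scale(
                [_fit_result(1.0, 10.0, (0, 1, 2)), _fit_result(2.0, 9.0, (0, 1, 3))]
            )


class TestSelectLocations:
    def _locs(self):
        return pd.DataFrame({
            "location_id": [0, 1, 2, 3],
            "x": [50.0, 50.0, 50.0, 5.0],
            "y": [50.0, 50.0, 50.0, 50.0],
        })

    def test_forest_threshold_inclusive(self):
        fa = pd.Series({0: 0.5, 1: 0.49, 2: 0.9, 3: 0.9})
        out = select_locations(self._locs(), fa, (0, 0, 100, 100), max_radius=16.0)
        assert list(out["location_id"]) == [0, 2]

    def test_border_exclusion(self):
        fa = pd.Series({0: 0.9, 1: 0.9, 2: 0.9, 3: 0.9})
        out = select_locations(self._locs(), fa, (0, 0, 100, 100), max_radius=16.0)
        assert 3 not in set(out["location_id"])  # 5 km from the west edge


class TestScaleSelectingLinearModel:
    def _metrics(self, rng, n=300, radii=(0.5, 1.0, 2.0), rho=0.85):
        base_fa = rng.standard_normal(n)
        base_ag = rng.standard_normal(n)
        frames = []
        for r in radii:
            frames.append(pd.DataFrame({
                "location_id": np.arange(n), "radius": r,
                "FA": rho * base_fa + np.sqrt(1 - rho**2) * rng.standard_normal(n),
                "AG": rho * base_ag + np.sqrt(1 - rho**2) * rng.standard_normal(n),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_recovers_generating_scale_majority(self):
        """AIC picks the true scale of effect in most seeded replicates."""
        wins = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            X = self._metrics(rng)
            true = X[X["radius"] == 1.0].set_index("location_id")
            y = pd.Series(
                0.5 * true["FA"].to_numpy() - 0.3 * true["AG"].to_numpy()
                + rng.standard_normal(len(true)),
                index=true.index, name="y",
            )
            model = ScaleSelectingLinearModel(landscape_predictors=("FA", "AG"))
            model.fit(X, y)
            wins += model.best_scale_ == 1.0
        assert wins >= int(0.9 * n_rep)

    def test_identical_predictors_tie_to_smallest_radius(self, rng):
        n = 100
        fa = rng.standard_normal(n)
        frames = [
            pd.DataFrame({"location_id": np.arange(n), "radius": r, "FA": fa})
            for r in (0.5, 1.0)
        ]
        X = pd.concat(frames, ignore_index=True)
        y = pd.Series(fa + rng.standard_normal(n), name="y")
        model = ScaleSelectingLinearModel(landscape_predictors=("FA",)).fit(X, y)
        assert model.best_scale_ == 0.5

    def test_listwise_deletion_equalizes_n_across_scales(self, rng):
        X = self._metrics(rng, n=120)
        # knock out FCI-like missingness in one scale's FA
        X.loc[(X["radius"] == 0.5) & (X["location_id"] < 10), "FA"] = np.nan
        true = X[X["radius"] == 1.0].set_index("location_id")
        y = pd.Series(rng.standard_normal(len(true)), index=true.index, name="y")
        model = ScaleSelectingLinearModel(landscape_predictors=("FA", "AG")).fit(X, y)
        ns = {res.n for res in model.results_.values()}
        assert ns == {110}
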