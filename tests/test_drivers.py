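import numpy as np
import pytest

from landchange.change import aggregate_to_categories, category_code
from landchange.drivers import (
    DesignInfo,
    TransitionModelFit,
    TransitionObservations,
    assemble_observations,
    build_design,
    fit_multinomial,
    fit_subsampled,
    predict_transition_probabilities,
    relative_risk_ratios,
)
from landchange.grids import CATEGORY_SCHEME, CovariateStack, GridTransform, LandCoverGrid


F = category_code("forest")
S = category_code("shrubland")
A = category_code("agriculture_developed")


@pytest.fixture(scope="module")
def cat_pair(scene):
    return aggregate_to_categories(scene.epoch1), aggregate_to_categories(scene.epoch2)


def _intercept_only_obs(counts=(70, 20, 10)):
    outcome = np.concatenate([np.full(c, k) for k, c in enumerate(counts)])
    n = outcome.size
    return TransitionObservations(
        source="forest",
        outcome_names=("forest", "shrubland", "agriculture_developed"),
        outcome=outcome,
        table={},
        categorical=frozenset(),
        rows=np.zeros(n, dtype=int),
        cols=np.arange(n),
    )


class TestAssemble:
    def test_all_stay_constant_outcome(self):
        e = LandCoverGrid(np.full((5, 5), F, dtype=np.int32), scheme=CATEGORY_SCHEME)
        stack = CovariateStack(layers={"x": np.random.default_rng(0).random((5, 5))},
                               transform=GridTransform())
        obs = assemble_observations(e, e, stack, "forest")
        assert np.all(obs.outcome == 0)

    def test_record_count_conservation(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("slope", "dist_village"))
        census = int((e1.values == F).sum())
        assert obs.n + obs.n_excluded == census

    def test_outcome_frequencies_match_truth(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("slope",))
        counts = scene.truth["transition_counts"]
        # category order: alpine, forest, shrubland, agriculture_developed, other
        assert (obs.outcome == 0).sum() == counts[1, 1]
        assert (obs.outcome == 1).sum() == counts[1, 2]
        assert (obs.outcome == 2).sum() == counts[1, 3]

    def test_unknown_source_rejected(self, scene, cat_pair):
        e1, e2 = cat_pair
        with pytest.raises(ValueError, match="unsupported source"):
            assemble_observations(e1, e2, scene.covariates, "alpine")

    def test_missing_layer_rejected(self, scene, cat_pair):
        e1, e2 = cat_pair
        with pytest.raises(ValueError, match="missing covariate"):
            assemble_observations(e1, e2, scene.covariates, "forest",
                                  covariate_names=("nope",))


class TestDesign:
    def test_continuous_standardized(self):
        table = {"x": np.array([1.0, 2.0, 3.0, 4.0])}
        X, info = build_design(table, frozenset())
        assert X[:, 1].mean() == pytest.approx(0.0)
        assert X[:, 1].std() == pytest.approx(1.0)

    def test_categorical_one_hot_drops_first(self):
        table = {"soil": np.array([1.0, 2.0, 3.0, 1.0])}
        X, info = build_design(table, frozenset({"soil"}))
        assert X.shape[1] == 3  # intercept + 2 dummies
        assert info.categorical_levels["soil"] == (1.0, 2.0, 3.0)

    def test_constant_layer_dropped(self):
        table = {"x": np.zeros(5), "y": np.arange(5.0)}
        X, info = build_design(table, frozenset())
        assert info.layer_order == ("y",)
        assert X.shape[1] == 2

    def test_reencoding_matches_original(self):
        rng = np.random.default_rng(0)
        table = {"x": rng.random(20), "soil": rng.choice([1.0, 2.0], 20)}
        X, info = build_design(table, frozenset({"soil"}))
        X2, _ = build_design(table, frozenset({"soil"}), info=info)
        np.testing.assert_array_equal(X, X2)


class TestFitMultinomial:
    def test_intercept_only_closed_form(self):
        obs = _intercept_only_obs((70, 20, 10))
        fit = fit_multinomial(obs)
        np.testing.assert_allclose(
            fit.mean_coefficients[:, 0], [np.log(20 / 70), np.log(10 / 70)], atol=1e-5
        )

    def test_predicted_probabilities_sum_to_one(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("slope", "temperature", "dist_village"))
        fit = fit_multinomial(obs)
        probs = predict_transition_probabilities(
            fit, scene.covariates, e1.values == F
        )
        sums = np.nansum(probs, axis=0)
        np.testing.assert_allclose(sums[e1.values == F], 1.0)

    def test_intercept_only_prediction_reproduces_shares(self):
        obs = _intercept_only_obs((70, 20, 10))
        fit = fit_multinomial(obs)
        stack = CovariateStack(layers={"z": np.zeros((2, 2))}, transform=GridTransform())
        probs = predict_transition_probabilities(fit, stack, np.ones((2, 2), dtype=bool))
        np.testing.assert_allclose(probs[:, 0, 0], [0.7, 0.2, 0.1], atol=1e-5)

    def test_single_outcome_level_fails(self):
        obs = _intercept_only_obs((50, 0, 0))
        with pytest.raises(RuntimeError):
            fit_multinomial(obs)


class TestSubsampled:
    def test_replicate_count_stored(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("temperature", "dist_village"))
        fit = fit_subsampled(obs, fraction=0.3, replicates=25, seed=0)
        assert fit.replicates.shape[0] + fit.n_failed == 25

    def test_seeded_determinism(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("temperature",))
        a = fit_subsampled(obs, fraction=0.3, replicates=10, seed=5)
        b = fit_subsampled(obs, fraction=0.3, replicates=10, seed=5)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_full_fraction_single_replicate_equals_full_fit(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("temperature", "dist_village"))
        sub = fit_subsampled(obs, fraction=1.0, replicates=1, seed=0)
        full = fit_multinomial(obs)
        np.testing.assert_allclose(sub.mean_coefficients, full.mean_coefficients, atol=1e-6)

    def test_mean_approaches_full_mle_as_fraction_grows(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("temperature", "dist_village"))
        full = fit_multinomial(obs).mean_coefficients
        errs = []
        for fraction in (0.1, 0.5, 1.0):
            fit = fit_subsampled(obs, fraction=fraction, replicates=30, seed=2)
            errs.append(np.abs(fit.mean_coefficients - full).max())
        assert errs[2] < errs[0]

    def test_ci_brackets_mean(self, scene, cat_pair):
        e1, e2 = cat_pair
        obs = assemble_observations(e1, e2, scene.covariates, "forest",
                                    covariate_names=("temperature",))
        fit = fit_subsampled(obs, fraction=0.3, replicates=40, seed=1)
        assert np.all(fit.ci_low <= fit.mean_coefficients + 1e-9)
        assert np.all(fit.ci_high >= fit.mean_coefficients - 1e-9)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            fit_subsampled(_intercept_only_obs(), fraction=0.0, replicates=2)


class TestRRR:
    def _fit_with_coefs(self, coefs):
        coefs = np.asarray(coefs, dtype=float)
        info = DesignInfo(
            column_names=tuple(["intercept"] + [f"x{i}" for i in range(coefs.shape[1] - 1)]),
            layer_order=tuple(f"x{i}" for i in range(coefs.shape[1] - 1)),
            continuous_stats={f"x{i}": (0.0, 1.0) for i in range(coefs.shape[1] - 1)},
            categorical_levels={},
        )
        return TransitionModelFit(
            source="forest",
            outcome_names=("forest", "shrubland", "agriculture_developed"),
            design=info,
            replicates=coefs[None, ...],
            mean_coefficients=coefs,
            ci_low=coefs - 0.5,
            ci_high=coefs + 0.5,
            n_replicates=1,
            n_failed=0,
            subsample_fraction=1.0,
            seed=0,
        )

    def test_zero_beta_gives_unit_rrr(self):
        fit = self._fit_with_coefs(np.zeros((2, 2)))
        table = relative_risk_ratios(fit)
        np.testing.assert_allclose(table["rrr"], 1.0)

    def test_log2_beta_gives_rrr_two(self):
        fit = self._fit_with_coefs(np.full((2, 2), np.log(2.0)))
        table = relative_risk_ratios(fit)
        np.testing.assert_allclose(table["rrr"], 2.0)

    def test_rrr_is_exact_exp_of_coefficients(self):
        rng = np.random.default_rng(3)
        coefs = rng.normal(size=(2, 4))
        fit = self._fit_with_coefs(coefs)
        table = relative_risk_ratios(fit)
        np.testing.assert_array_equal(table["rrr"].to_numpy(),
                                      np.exp(table["mean"].to_numpy()))

    def test_ci_ordering_preserved_under_exp(self):
        fit = self._fit_with_coefs(np.array([[0.3, -1.2], [2.0, 0.0]]))
        table = relative_risk_ratios(fit)
        assert (table["rrr_low"] <= table["rrr"]).all()
        assert (table["rrr"] <= table["rrr_high"]).all()
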