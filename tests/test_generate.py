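import numpy as np
import pandas as pd
import pytest

from causaltransport.generate import (ExogenousSource, GenerationError,
                                      InterventionError, build_study_settings,
                                      generate_cohort, override_mechanism,
                                      replace_exogenous, sample_exogenous,
                                      set_prevalence, setting_seed)
from causaltransport.graph import parse_graph
from causaltransport.sem import EquationSpec, NormalizationInfo, SemParameterSet
from causaltransport import fixtures as fx


def linear_gaussian_system():
    """Small all-continuous system with a closed-form mean/covariance.

    x exogenous; y = 1 + 2x + e_y; z = -0.5 + 0.5x + 0.3y + e_z.
    """
    g = parse_graph("x -> y\nx -> z\ny -> z")
    eqs = {"y": EquationSpec("y", 1.0, {"x": 2.0}, residual_sd=0.5),
           "z": EquationSpec("z", -0.5, {"x": 0.5, "y": 0.3}, residual_sd=0.7)}
    return g, SemParameterSet(g.graph_hash(), eqs)


def propagate_moments(mu_x=0.0, var_x=1.0):
    """Independent oracle: exact mean/covariance via (I-B)^-1 algebra."""
    # order (x, y, z); B[i, j] = coefficient of j in equation for i
    B = np.array([[0.0, 0.0, 0.0],
                  [2.0, 0.0, 0.0],
                  [0.5, 0.3, 0.0]])
    c = np.array([mu_x, 1.0, -0.5])
    A = np.linalg.inv(np.eye(3) - B)
    mean = A @ c
    noise = np.diag([var_x, 0.5**2, 0.7**2])
    cov = A @ noise @ A.T
    return mean, cov


class TestSampleExogenous:
    def test_single_row_bootstrap_repeats_it(self):
        src = ExogenousSource(table=pd.DataFrame({"a": [3.0], "b": [1.0]}))
        out = sample_exogenous(src, 5, seed=0)
        assert out.n == 5
        assert (out.data["a"] == 3.0).all() and (out.data["b"] == 1.0).all()

    def test_parametric_bernoulli_prevalence(self):
        src = ExogenousSource(parametric={"g": {"dist": "bernoulli", "p": 0.05}})
        out = sample_exogenous(src, 100_000, seed=1)
        assert abs(out.data["g"].mean() - 0.05) < 0.005

    def test_parametric_normal_mean(self):
        src = ExogenousSource(parametric={"age": {"dist": "normal",
                                                  "mean": 35.0, "sd": 10.0}})
        out = sample_exogenous(src, 10_000, seed=2)
        assert abs(out.data["age"].mean() - 35.0) < 0.5

    def test_nonpositive_n_rejected(self):
        src = ExogenousSource(parametric={"x": {"dist": "normal",
                                                "mean": 0, "sd": 1}})
        with pytest.raises(GenerationError, match="n"):
            sample_exogenous(src, 0, seed=0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(GenerationError):
            ExogenousSource(parametric={"x": {"dist": "normal", "mean": 0, "sd": 0}})
        with pytest.raises(GenerationError):
            ExogenousSource(parametric={"x": {"dist": "bernoulli", "p": 1.5}})
        with pytest.raises(GenerationError):
            ExogenousSource(table=pd.DataFrame({"a": []}))

    def test_joint_bootstrap_preserves_row_dependence(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(500)
        src = ExogenousSource(table=pd.DataFrame({"a": a, "b": a}))
        out = sample_exogenous(src, 2000, seed=4)
        assert (out.data["a"] == out.data["b"]).all()


class TestGenerateCohort:
    def test_noiseless_linear_map(self):
        g = parse_graph("a -> b")
        params = SemParameterSet(
            g.graph_hash(), {"b": EquationSpec("b", 0.0, {"a": 2.0},
                                               residual_sd=0.0)})
        src = ExogenousSource(table=pd.DataFrame({"a": [1.0]}))
        out = generate_cohort(g, params, src, 10, seed=0)
        assert (out.data["b"] == 2.0).all()

    def test_means_and_covariance_match_closed_form(self):
        g, params = linear_gaussian_system()
        src = ExogenousSource(parametric={"x": {"dist": "normal",
                                                "mean": 0.0, "sd": 1.0}})
        out = generate_cohort(g, params, src, 50_000, seed=5)
        mean, cov = propagate_moments()
        sample = out.data[["x", "y", "z"]].to_numpy()
        assert np.allclose(sample.mean(axis=0), mean, atol=0.05)
        assert np.allclose(np.cov(sample.T), cov, atol=0.12)

    def test_determinism(self, fig1_graph, default_params, default_exo):
        a = generate_cohort(fig1_graph, default_params, default_exo, 500, seed=9)
        b = generate_cohort(fig1_graph, default_params, default_exo, 500, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_exogenous_intervention_never_alters_equations(
            self, fig1_graph, default_params, default_exo):
        before = default_params.copy()
        generate_cohort(fig1_graph, default_params, default_exo, 500, seed=1,
                        interventions=[replace_exogenous("age", 35, 10),
                                       set_prevalence("apoe4", 0.05)])
        assert default_params == before

    def test_mechanism_override_never_mutates_parameter_set(
            self, fig1_graph, default_params, default_exo):
        before = default_params.copy()
        generate_cohort(fig1_graph, default_params, default_exo, 500, seed=1,
                        interventions=fx.standard_interventions()["tau"])
        assert default_params == before

    def test_natural_scale_intervention_converted_with_normalization(
            self, fig1_graph, default_params, default_exo):
        out = generate_cohort(fig1_graph, default_params, default_exo,
                              20_000, seed=3,
                              interventions=[replace_exogenous("age", 35, 10)])
        mean, sd = default_params.normalization.stats["age"]
        assert abs(out.data["age"].mean() - (35 - mean) / sd) < 0.05
        assert abs(out.data["age"].std(ddof=1) - 10 / sd) < 0.05

    def test_tau_mechanism_intervention_raises_tau(
            self, fig1_graph, default_params, default_exo):
        base = generate_cohort(fig1_graph, default_params, default_exo,
                               20_000, seed=6)
        shifted = generate_cohort(fig1_graph, default_params, default_exo,
                                  20_000, seed=6,
                                  interventions=fx.standard_interventions()["tau"])
        assert shifted.data["tau"].mean() > base.data["tau"].mean() + 1.0

    def test_intervention_validation(self, fig1_graph, default_params,
                                     default_exo):
        with pytest.raises(InterventionError, match="non-exogenous"):
            generate_cohort(fig1_graph, default_params, default_exo, 200, 0,
                            interventions=[replace_exogenous("tau", 0, 1)])
        with pytest.raises(InterventionError, match="non-exogenous"):
            generate_cohort(fig1_graph, default_params, default_exo, 200, 0,
                            interventions=[set_prevalence("cogn", 0.5)])
        with pytest.raises(InterventionError, match="non-parent"):
            generate_cohort(fig1_graph, default_params, default_exo, 200, 0,
                            interventions=[override_mechanism(
                                "tau", coefficients={"mmse": 1.0})])

    def test_set_prevalence_hits_target_across_seeds(
            self, fig1_graph, default_params, default_exo):
        p, n = 0.05, 10_000
        bound = 4 * np.sqrt(p * (1 - p) / n)
        for seed in range(20):
            out = generate_cohort(fig1_graph, default_params, default_exo, n,
                                  seed=seed,
                                  interventions=[set_prevalence("apoe4", p)])
            assert abs(out.data["apoe4"].mean() - p) < bound

    def test_raising_latent_mean_of_binary_node_raises_prevalence(
            self, fig1_graph, default_params, default_exo):
        # outcome prevalence is monotone in the latent mean: grids over the
        # outcome intercept and over the coefficient of a positive-mean
        # parent (apoe4 carriage ~0.47) must weakly raise prevalence
        for grid in ([{"intercept": v} for v in (0.2, 0.5, 0.8)],
                     [{"coefficients": {"apoe4": v}} for v in (0.6, 0.9, 1.2)]):
            prevalences = []
            for kw in grid:
                out = generate_cohort(
                    fig1_graph, default_params, default_exo, 20_000, seed=11,
                    interventions=[override_mechanism("cogn", **kw)])
                prevalences.append(out.data["cogn"].mean())
            assert prevalences[-1] > prevalences[0]
            assert (np.diff(prevalences) >= -0.005).all()


class TestStudySettings:
    def test_default_config_builds_six_settings(self, fig1_graph,
                                                default_params, default_exo):
        settings = build_study_settings(fig1_graph, default_params, default_exo,
                                        fx.standard_interventions(),
                                        n=300, master_seed=1)
        assert list(settings) == ["train", "internal", "age", "age2",
                                  "apoe4", "tau"]
        assert all(c.n == 300 for c in settings.values())
        # train and internal share the mechanism but not the draws
        assert not settings["train"].data.equals(settings["internal"].data)

    def test_age2_setting_centres_age_at_65(self, fig1_graph, default_params,
                                            default_exo):
        settings = build_study_settings(fig1_graph, default_params, default_exo,
                                        fx.standard_interventions(),
                                        n=20_000, master_seed=2)
        mean, sd = default_params.normalization.stats["age"]
        assert abs(settings["age2"].data["age"].mean() - (65 - mean) / sd) < 0.05

    def test_same_master_seed_is_bit_identical(self, fig1_graph,
                                               default_params, default_exo):
        s1 = build_study_settings(fig1_graph, default_params, default_exo,
                                  fx.standard_interventions(), n=200,
                                  master_seed=3)
        s2 = build_study_settings(fig1_graph, default_params, default_exo,
                                  fx.standard_interventions(), n=200,
                                  master_seed=3)
        for label in s1:
            pd.testing.assert_frame_equal(s1[label].data, s2[label].data)

    def test_sub_seeds_differ_across_settings_and_reps(self):
        seeds = {str(setting_seed(5, rep, idx).spawn_key)
                 for rep in range(3) for idx in range(6)}
        assert len(seeds) == 18
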