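"""Parameter layout, likelihood, fitting, and error-model selection."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.base import clone

from indecision.estimation import (
    Dataset,
    FitOptions,
    IndecisionModel,
    default_alpha_bounds,
    enumerate_error_models,
    fit,
    free_parameter_layout,
    negative_log_likelihood,
    select_error_model,
)
from indecision.model import ErrorModelSpec, predicted_probabilities
from indecision.simulate import (
    SCENARIOS,
    TrueParams,
    design_levels,
    draw_true_params,
    simulate_responses,
)

Z75 = 0.6744897501960817  # unit-normal 75th quantile


def _noise_free_dataset(true, spec, n=40):
    """Counts = round(n * Psi): deterministic data at the model's own
    response probabilities."""
    from indecision.simulate import build_sensory_model

    levels = design_levels(spec, true)
    s = build_sensory_model(spec, true)
    psi = predicted_probabilities(
        levels, s, true.boundaries, true.errors(spec.error_regime),
        spec.response_format,
    )
    counts = np.round(n * psi).astype(int)
    standard = -np.inf if spec.task == "detection" else -1.0
    return Dataset(levels, counts, standard, spec.response_format)


def _simulated(name, seed, **spec_kw):
    spec = replace(SCENARIOS[name], **spec_kw)
    true = draw = TrueParams(
        -2.5, 0.075, -3.0, 2.5, 0.4, np.zeros((2, 3)), np.full((2, 3), 0.5)
    )
    levels = design_levels(spec, true)
    data = simulate_responses(levels, true, spec, np.random.default_rng(seed))
    return true, data


class TestDataset:
    def test_levels_sorted_and_duplicates_merged(self):
        levels = [0.3, 0.1, 0.3, 0.2]
        counts = np.arange(2 * 3 * 4).reshape(2, 3, 4)
        d = Dataset(levels, counts, standard=0.0)
        assert np.array_equal(d.levels, [0.1, 0.2, 0.3])
        # the two 0.3 columns (original columns 0 and 2) are summed
        assert np.array_equal(d.counts[:, :, 2], counts[:, :, 0] + counts[:, :, 2])

    def test_structural_zero_validation(self):
        counts = np.ones((2, 3, 2), dtype=int)
        with pytest.raises(ValueError, match="U"):
            Dataset([0.0, 1.0], counts, 0.0, "2AFC")
        with pytest.raises(ValueError, match="F"):
            Dataset([0.0, 1.0], counts, 0.0, "equality")

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            Dataset([0.0], -np.ones((2, 3, 1)), 0.0)
        with pytest.raises(ValueError):
            Dataset([0.0], np.full((2, 3, 1), 0.5), 0.0)


class TestParameterLayout:
    def test_detection_base_model_has_four_parameters(self):
        _, data = _simulated("ternary-detection", 1)
        layout = free_parameter_layout(data, FitOptions())
        assert layout.names == ["alpha_t", "beta_t", "delta1", "width"]

    def test_full_error_model_adds_six_per_order(self):
        _, data = _simulated("ternary-discrimination-same", 1)
        o = FitOptions(error_model=ErrorModelSpec((1, 1, 1), (1, 1, 1)))
        layout = free_parameter_layout(data, o)
        assert layout.n_free == 16

    def test_free_anchor_adds_one(self):
        _, data = _simulated("ternary-discrimination-same", 1)
        layout = free_parameter_layout(data, FitOptions(psyfun_type="diff"))
        assert "anchor" in layout.names and layout.n_free == 5

    def test_2afc_format_fixed_parameters_not_free(self):
        _, data = _simulated("2AFC-discrimination-same", 1)
        layout = free_parameter_layout(data, FitOptions())
        assert layout.names == [
            "alpha_t", "beta_t", "delta1", "width", "kappa_UF_1", "kappa_UF_2",
        ]
        o = FitOptions(error_model=ErrorModelSpec((1, 1, 1), (1, 1, 1)))
        # per order: eps_F, eps_S and the guessing bias kappa_UF
        assert free_parameter_layout(data, o).n_free == 4 + 6

    def test_single_boundary_eliminates_three_parameters(self):
        _, data = _simulated("2AFC-discrimination-same", 1)
        layout = free_parameter_layout(
            data, FitOptions(enforce_single_boundary=True)
        )
        # width, kappa_UF_1 and kappa_UF_2 all gone
        assert layout.names == ["alpha_t", "beta_t", "delta1"]

    def test_equality_with_single_boundary_rejected(self):
        _, data = _simulated("equality-discrimination-same", 1)
        with pytest.raises(ValueError, match="same-different"):
            free_parameter_layout(data, FitOptions(enforce_single_boundary=True))

    def test_alpha_bound_rules(self):
        levels = np.linspace(-2.9, -1.9, 11)
        lo, hi = default_alpha_bounds(levels, detection=True)
        assert (lo, hi) == pytest.approx((3 * -2.9 - 2 * -1.9, -1.9))
        lo, hi = default_alpha_bounds(levels, detection=False)
        assert hi == pytest.approx(2 * -2.9 + 1.9)


class TestLikelihood:
    def test_hand_computed_minus2loglik(self):
        # symmetric triple: boundaries at +-sqrt(2) z.75 make pU = 0.5 and
        # pF = pS = 0.25 at the standard level
        counts = np.zeros((2, 3, 1), dtype=int)
        counts[0, :, 0] = (10, 20, 10)
        d = Dataset([-0.7], counts, standard=-0.7)
        z = Z75 * np.sqrt(2)
        o = FitOptions(alpha_bounds=(-3.0, 1.0))  # single level: no data rule
        layout_names = free_parameter_layout(d, o).names
        assert layout_names == ["alpha_t", "beta_t", "delta1", "width"]
        theta = [-1.0, 0.1, -z, 2 * z]
        nll = negative_log_likelihood(theta, d, o)
        assert 2 * nll == pytest.approx(83.178, abs=1e-3)

    def test_zero_counts_give_zero(self):
        d = Dataset([-0.7], np.zeros((2, 3, 1), dtype=int), standard=-0.7)
        o = FitOptions(alpha_bounds=(-3.0, 1.0))
        assert negative_log_likelihood([-1.0, 0.1, -1.0, 2.0], d, o) == 0.0

    def test_observed_frequencies_are_the_optimum(self):
        # Gibbs: any parametric Psi does worse than the saturated frequencies
        rng = np.random.default_rng(3)
        d = Dataset(
            np.linspace(-1.5, -0.5, 11),
            rng.multinomial(40, [0.3, 0.4, 0.3], size=(2, 11)).transpose(0, 2, 1),
            standard=-1.0,
        )
        freqs = d.counts / d.counts.sum(axis=1, keepdims=True)
        saturated = -np.sum(d.counts * np.log(np.maximum(freqs, 1e-12)))
        nll = negative_log_likelihood([-1.0, 0.1, -1.0, 2.0], d, FitOptions())
        assert nll >= saturated


class TestFit:
    def test_noise_free_parameter_recovery(self):
        true = TrueParams(
            -2.4, 0.07, -2.5, 2.5, 0.0, np.zeros((2, 3)), np.full((2, 3), 0.5)
        )
        spec = SCENARIOS["ternary-detection"]
        data = _noise_free_dataset(true, spec, n=10_000)
        r = fit(data, FitOptions())
        assert r.alpha_t == pytest.approx(true.alpha_t, rel=0.02)
        assert r.beta_t == pytest.approx(true.beta_t, rel=0.02)
        assert r.delta1 == pytest.approx(true.delta1, rel=0.02)
        assert r.delta2 == pytest.approx(true.delta2, rel=0.02)
        assert not r.boundaries_reached

    def test_fit_is_deterministic(self):
        _, data = _simulated("ternary-discrimination-same", 5)
        r1 = fit(data, FitOptions())
        r2 = fit(data, FitOptions())
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.minus2loglik == r2.minus2loglik

    def test_minus2loglik_consistent_with_estimates(self):
        _, data = _simulated("ternary-discrimination-same", 5)
        r = fit(data, FitOptions())
        recomputed = 2 * negative_log_likelihood(r.theta, data, FitOptions())
        assert r.minus2loglik == pytest.approx(recomputed, abs=1e-6)

    def test_alpha_flat_direction_in_suprathreshold_discrimination(self):
        # alpha_t is unidentifiable: restarts move the estimate along the
        # flat direction without changing the attained likelihood
        _, data = _simulated("ternary-discrimination-same", 5)
        o = FitOptions()
        r1 = fit(data, o)
        r2 = fit(data, replace(o, alpha_starts=(r1.alpha_t + 0.3,)))
        assert abs(r2.alpha_t - r1.alpha_t) > 0.1
        assert abs(r2.minus2loglik - r1.minus2loglik) < 1e-4

    def test_nesting_never_hurts_likelihood(self):
        _, data = _simulated("ternary-discrimination-same", 5)
        lls = []
        for masks in [((0, 0, 0), (0, 0, 0)), ((1, 0, 0), (0, 0, 0)),
                      ((1, 1, 1), (1, 1, 1))]:
            r = fit(data, FitOptions(error_model=ErrorModelSpec(*masks)))
            lls.append(r.minus2loglik)
        assert lls[1] <= lls[0] + 1e-3
        assert lls[2] <= lls[1] + 1e-3

    def test_ternary_model_reduces_to_2afc_on_binary_data(self):
        # fitting the intact ternary model (full error layer) to 2AFC data
        # drives eps_U to 1 and reproduces the 2AFC fit's curves
        _, data = _simulated("2AFC-discrimination-same", 6)
        r_2afc = fit(data, FitOptions())
        as_ternary = Dataset(data.levels, data.counts, data.standard, "ternary")
        r_tern = fit(
            as_ternary, FitOptions(error_model=ErrorModelSpec((1, 1, 1), (1, 1, 1)))
        )
        assert r_tern.errors_order1["eps_U"] > 0.95
        assert r_tern.errors_order2["eps_U"] > 0.95
        # error-free data leave the genuine lapse rates at zero
        assert r_tern.errors_order1["eps_F"] < 0.01
        assert r_tern.errors_order1["eps_S"] < 0.01
        assert abs(r_tern.minus2loglik - r_2afc.minus2loglik) < 0.5
        psi_a, psi_t = r_2afc.predicted(), r_tern.predicted()
        assert np.abs(psi_a[0, 0] - psi_t[0, 0]).max() < 0.02  # F, test first
        assert np.abs(psi_a[1, 2] - psi_t[1, 2]).max() < 0.02  # S, test second

    def test_accuracy_improves_with_trials_per_level(self):
        spec = SCENARIOS["ternary-discrimination-same"]
        errs = {40: [], 400: []}
        for n in errs:
            spec_n = replace(spec, trials_per_level_per_order=n)
            for rep in range(20):
                true = draw_true_params(
                    np.random.default_rng(np.random.SeedSequence([3, rep]))
                )
                levels = design_levels(spec_n, true)
                data = simulate_responses(
                    levels, true, spec_n,
                    np.random.default_rng(np.random.SeedSequence([3, rep, n])),
                )
                r = fit(data, FitOptions())
                errs[n].append(
                    [abs(r.beta_t - true.beta_t), abs(r.delta1 - true.delta1),
                     abs(r.delta2 - true.delta2)]
                )
        med40 = np.median(errs[40], axis=0)
        med400 = np.median(errs[400], axis=0)
        assert np.all(med400 < med40)


class TestErrorModelEnumeration:
    def test_counts_per_format(self):
        ternary = enumerate_error_models("ternary")
        assert len(ternary) == 64
        assert len({m.order1 for m in ternary}) == 8
        assert len(enumerate_error_models("2AFC")) == 16
        assert len(enumerate_error_models("equality")) == 16

    def test_base_model_first_with_no_error_parameters(self):
        first = enumerate_error_models("ternary")[0]
        assert first.label == "(0,0)"
        _, data = _simulated("ternary-detection", 1)
        assert free_parameter_layout(data, FitOptions(error_model=first)).n_free == 4


class TestSelection:
    def test_loglik_winner_minimizes_minus2loglik(self):
        _, data = _simulated("equality-discrimination-same", 9)
        o = FitOptions()
        fits = [
            fit(data, replace(o, error_model=spec))
            for spec in enumerate_error_models("equality")
        ]
        winner = select_error_model(data, replace(o, selection_criterion="loglik"))
        assert winner.minus2loglik <= min(f.minus2loglik for f in fits) + 1e-6
        assert winner.requested_model == "best"
        assert winner.selection_criterion == "loglik"

    def test_bic_selection_avoids_spurious_error_parameters(self):
        # data generated without response errors: BIC should keep the base
        # model in nearly every replicate
        spec = SCENARIOS["equality-discrimination-same"]
        base = 0
        n_rep = 10
        for rep in range(n_rep):
            true = draw_true_params(
                np.random.default_rng(np.random.SeedSequence([17, rep]))
            )
            levels = design_levels(spec, true)
            data = simulate_responses(
                levels, true, spec,
                np.random.default_rng(np.random.SeedSequence([17, rep, 5])),
            )
            r = select_error_model(data, FitOptions(selection_criterion="bic"))
            base += r.fitted_model == "(0,0)"
        assert base >= 9


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        est = IndecisionModel(standard=-1.0, delta1_bounds=(-6.0, 1.0))
        est2 = clone(est)
        assert est2.get_params()["delta1_bounds"] == (-6.0, 1.0)
        est2.set_params(beta_bounds=(0.02, 0.8))
        assert est2.get_params()["beta_bounds"] == (0.02, 0.8)

    def test_fit_sets_fitted_attributes_and_matches_function(self):
        _, data = _simulated("ternary-discrimination-same", 5)
        est = IndecisionModel(standard=-1.0).fit(data.levels, data.counts)
        reference = fit(data, FitOptions())
        assert est.minus2loglik_ == reference.minus2loglik
        assert est.alpha_ == reference.alpha_t
        assert est.delta1_ == reference.delta1
        psi = est.predict_proba(data.levels)
        assert psi.shape == (2, 3, data.n_levels)
        assert np.allclose(psi.sum(axis=1), 1.0, atol=1e-12)
        assert est.score(data.levels, data.counts) == pytest.approx(
            -reference.minus2loglik / 2 / data.n_trials
        )
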