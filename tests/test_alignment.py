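"""The alignment model: transforms, mixture likelihood, priors, MAP fit."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, strategies as hst
from scipy.optimize import approx_fprime

from rtalign import (
    AlignmentModel,
    ExperimentParams,
    FitOptions,
    Hyperpriors,
    ReferenceRT,
    fit_map,
    initialize_model,
    inverse_transform,
    log_likelihood,
    log_posterior,
    mixture_log_likelihood,
    residual_sd,
    two_segment_transform,
)
from rtalign.alignment import _FitData, _Parameterization, _objective
from rtalign.errors import NumericalError
from rtalign.simulate import SimConfig, simulate_dataset

from conftest import roundtrip_evidence
from rtalign import filter_for_alignment


PARAMS = ExperimentParams(
    beta0=5.0, beta1=1.2, beta2=0.8, split=30.0,
    sigma_intercept=0.05, sigma_slope=0.01, null_mean=30.0, null_sd=10.0,
)


class TestTransform:
    def test_identity(self):
        p = ExperimentParams(0.0, 1.0, 1.0, 25.0, 0.1, 0.0, 30.0, 10.0)
        assert two_segment_transform(p, 10.0) == pytest.approx(10.0)

    def test_worked_second_segment(self):
        # 5 + 1.2*30 + 0.8*(40-30)
        assert two_segment_transform(PARAMS, 40.0) == pytest.approx(49.0)

    def test_continuous_at_split(self):
        at = two_segment_transform(PARAMS, PARAMS.split)
        assert at == pytest.approx(PARAMS.beta0 + PARAMS.beta1 * PARAMS.split)

    @given(
        hst.floats(0.0, 60.0),
        hst.floats(0.0, 60.0),
    )
    def test_strictly_increasing(self, mu1, mu2):
        lo, hi = sorted([mu1, mu2])
        if hi - lo < 1e-9:
            return
        assert two_segment_transform(PARAMS, hi) > two_segment_transform(PARAMS, lo)


class TestInverseTransform:
    def test_worked_inverse(self):
        assert inverse_transform(PARAMS, 49.0) == pytest.approx(40.0)

    @given(hst.floats(0.0, 60.0))
    def test_round_trip(self, mu):
        rho = two_segment_transform(PARAMS, mu)
        assert inverse_transform(PARAMS, rho) == pytest.approx(mu, abs=1e-9)

    def test_extrapolates_below_range(self):
        p = ExperimentParams(0.0, 1.0, 1.0, 25.0, 0.1, 0.0, 30.0, 10.0)
        assert inverse_transform(p, -1.0) == pytest.approx(-1.0)

    def test_degenerate_slope_raises(self):
        bad = ExperimentParams(0.0, 1e-15, 1.0, 25.0, 0.1, 0.0, 30.0, 10.0)
        with pytest.raises(NumericalError):
            inverse_transform(bad, 10.0)


class TestResidualSd:
    def test_constant_and_linear(self):
        p = ExperimentParams(0.0, 1.0, 1.0, 25.0, 0.1, 0.0, 30.0, 10.0)
        assert residual_sd(p, 50.0) == pytest.approx(0.1)
        p2 = ExperimentParams(0.0, 1.0, 1.0, 25.0, 0.05, 0.01, 30.0, 10.0)
        assert residual_sd(p2, 20.0) == pytest.approx(0.25)

    @given(hst.floats(0.0, 60.0), hst.floats(0.0, 60.0))
    def test_monotone_in_mu(self, m1, m2):
        lo, hi = sorted([m1, m2])
        assert residual_sd(PARAMS, lo) <= residual_sd(PARAMS, hi)


class TestMixtureLikelihood:
    """The per-PSM density against independent scipy closed forms."""

    def test_collapses_to_laplace_at_lambda_zero(self):
        got = mixture_log_likelihood(12.0, 0.0, 10.0, 0.5, (30.0, 10.0))
        want = st.laplace.logpdf(12.0, 10.0, 0.5)
        assert got == pytest.approx(want, abs=1e-12)

    def test_collapses_to_normal_at_lambda_one(self):
        got = mixture_log_likelihood(12.0, 1.0, 10.0, 0.5, (30.0, 10.0))
        want = st.norm.logpdf(12.0, 30.0, 10.0)
        assert got == pytest.approx(want, abs=1e-12)

    def test_blend_matches_direct_arithmetic(self):
        # Laplace density at its center is 1/(2 sigma)
        got = mixture_log_likelihood(10.0, 0.5, 10.0, 0.5, (30.0, 10.0))
        want = math.log(
            0.5 * st.laplace.pdf(10.0, 10.0, 0.5) + 0.5 * st.norm.pdf(10.0, 30.0, 10.0)
        )
        assert got == pytest.approx(want, abs=1e-12)
        assert st.laplace.pdf(10.0, 10.0, 0.5) == pytest.approx(1.0)

    def test_support_indicator(self):
        assert mixture_log_likelihood(-0.5, 0.5, 10.0, 0.5, (30.0, 10.0)) == -np.inf

    @pytest.mark.parametrize("lam,sigma", [(-0.1, 0.5), (1.1, 0.5), (0.5, 0.0)])
    def test_domain_errors(self, lam, sigma):
        with pytest.raises(ValueError):
            mixture_log_likelihood(10.0, lam, 10.0, sigma, (30.0, 10.0))


def _one_psm_model(lam=0.0, rho=None):
    p = ExperimentParams(2.0, 1.1, 0.9, 25.0, 0.2, 0.004, 30.0, 12.0)
    mu = 20.0
    rho = two_segment_transform(p, mu) if rho is None else rho
    data = pd.DataFrame(
        {
            "observed_rt": [rho],
            "spectral_pep": [lam],
            "experiment_id": ["e1"],
            "peptide_key": ["PEPK"],
        }
    )
    hyper = Hyperpriors(rt_mean=30.0, rt_sd=15.0, rt_max=60.0)
    model = AlignmentModel(
        experiment_params={"e1": p},
        reference_rts={"PEPK": ReferenceRT("PEPK", mu, 1)},
        hyperpriors=hyper,
    )
    return model, data, p, mu


class TestLogPosterior:
    def test_single_psm_closed_form(self):
        """One Laplace term at zero residual plus all log priors (scipy oracle)."""
        model, data, p, mu = _one_psm_model(lam=0.0)
        sigma = p.sigma_intercept + p.sigma_slope * mu
        h = model.hyperpriors
        b_global = p.sigma_slope  # geometric mean of the single experiment
        want = (
            math.log(1.0 / (2.0 * sigma))
            + st.norm.logpdf(mu, h.rt_mean, h.rt_sd)
            + st.norm.logpdf(p.beta0, 0.0, 10.0)
            + st.lognorm.logpdf(p.beta1, 0.5, scale=1.0)
            + st.lognorm.logpdf(p.beta2, 0.5, scale=1.0)
            + st.lognorm.logpdf(p.sigma_intercept, 2.0, scale=1.0)
            + st.lognorm.logpdf(p.sigma_slope, 1.0, scale=b_global)
            + st.lognorm.logpdf(b_global, 0.5, scale=math.exp(0.1))
        )
        assert log_posterior(model, data) == pytest.approx(want, rel=1e-10)

    def test_null_psm_adds_exactly_its_normal_density(self):
        model, data, p, mu = _one_psm_model(lam=0.0)
        base = log_posterior(model, data)
        extra = pd.DataFrame(
            {
                "observed_rt": [p.null_mean],
                "spectral_pep": [1.0],
                "experiment_id": ["e1"],
                "peptide_key": ["PEPK"],
            }
        )
        both = log_posterior(model, pd.concat([data, extra], ignore_index=True))
        assert both - base == pytest.approx(
            st.norm.logpdf(p.null_mean, p.null_mean, p.null_sd), abs=1e-10
        )

    def test_doubling_sigma_costs_n_log_two(self):
        """With residuals at zero, the Laplace normalization is the whole story."""
        model, data, p, mu = _one_psm_model(lam=0.0)
        data = pd.concat([data] * 7, ignore_index=True)
        ll1 = log_likelihood(model, data)
        doubled = ExperimentParams(
            p.beta0, p.beta1, p.beta2, p.split,
            2 * p.sigma_intercept, 2 * p.sigma_slope, p.null_mean, p.null_sd,
        )
        model.experiment_params["e1"] = doubled
        ll2 = log_likelihood(model, data)
        assert ll1 - ll2 == pytest.approx(7 * math.log(2.0), abs=1e-10)


def test_objective_gradient_matches_finite_differences():
    cfg = SimConfig(n_experiments=3, n_peptides=25, observation_rate=0.9, seed=5)
    table, _ = simulate_dataset(cfg)
    table = table.rename(
        columns={
            "Retention time": "observed_rt",
            "PEP": "spectral_pep",
            "Raw file": "experiment_id",
            "Sequence": "peptide_key",
        }
    )
    fd = _FitData(table)
    hyper = Hyperpriors(rt_mean=30.0, rt_sd=15.0, rt_max=60.0)
    fd.set_null(np.full(fd.n_exp, 30.0), np.full(fd.n_exp, 12.0))
    par = _Parameterization(fd.n_pep, fd.n_exp, 60.0, True)
    rng = np.random.default_rng(0)
    u = par.pack(
        np.maximum(table.groupby("peptide_key")["observed_rt"].median().sort_index().to_numpy(), 1.0),
        np.full(fd.n_exp, 0.5),
        np.full(fd.n_exp, 1.0),
        np.full(fd.n_exp, 0.9),
        np.full(fd.n_exp, 28.0),
        np.full(fd.n_exp, 0.15),
        np.full(fd.n_exp, 0.004),
        0.004,
    ) + rng.normal(0, 0.01, par.size)
    f0, grad = _objective(u, fd, hyper, par)
    num = approx_fprime(u, lambda v: _objective(v, fd, hyper, par)[0], 1e-7)
    denom = np.maximum(np.abs(num), 1.0)
    assert np.max(np.abs(grad - num) / denom) < 1e-4


class TestInitialization:
    def test_identity_data_gives_identity_transform(self, tmp_path):
        cfg = SimConfig(
            n_experiments=4, n_peptides=60,
            beta0_range=(0.0, 0.0), beta1_range=(1.0, 1.0), beta2_range=(1.0, 1.0),
            min_slope_separation=0.0,
            sigma_intercept_range=(0.01, 0.01), sigma_slope_range=(1e-4, 1e-4),
            incorrect_rate=0.0, seed=2,
        )
        table, _ = simulate_dataset(cfg)
        records = roundtrip_evidence(table, tmp_path)
        model = initialize_model(records)
        for p in model.experiment_params.values():
            assert p.beta1 == pytest.approx(1.0, abs=0.05)
            assert p.beta0 == pytest.approx(0.0, abs=0.5)

    def test_null_moments_are_empirical(self, study):
        model = initialize_model(study["eligible"])
        for exp_id, sub in study["eligible"].groupby("experiment_id"):
            p = model.experiment_params[str(exp_id)]
            assert p.null_mean == pytest.approx(sub["observed_rt"].mean())
            assert p.null_sd == pytest.approx(sub["observed_rt"].std(ddof=0))

    def test_underpopulated_experiment_dropped(self, study):
        df = study["eligible"].copy()
        lone = df.iloc[[0]].copy()
        lone["experiment_id"] = "lonely_run"
        with pytest.warns(UserWarning, match="lonely_run"):
            model = initialize_model(pd.concat([df, lone], ignore_index=True))
        assert "lonely_run" in model.dropped_experiments
        assert "lonely_run" not in model.experiment_params


class TestMapFit:
    def test_reference_rt_recovery(self, study):
        model, truth = study["model"], study["truth"]
        keys = sorted(model.reference_rts)
        est = np.array([model.reference_rts[k].mu for k in keys])
        tru = np.array([truth.reference_rts[k] for k in keys])
        assert np.corrcoef(est, tru)[0, 1] > 0.99

    def test_fit_improves_log_posterior(self, study):
        init = initialize_model(study["eligible"])
        assert study["model"].log_posterior >= init.log_posterior
        assert np.isfinite(study["model"].log_posterior)

    def test_single_slope_data_gives_equal_segments(self, tmp_path):
        cfg = SimConfig(
            n_experiments=5, n_peptides=120,
            beta1_range=(1.0, 1.0), beta2_range=(1.0, 1.0),
            min_slope_separation=0.0, seed=3,
        )
        table, _ = simulate_dataset(cfg)
        records = roundtrip_evidence(table, tmp_path)
        eligible, _, _ = filter_for_alignment(records)
        model = fit_map(eligible)
        for p in model.experiment_params.values():
            assert p.beta2 == pytest.approx(p.beta1, rel=0.15)

    def test_row_order_does_not_change_the_fit(self, tmp_path):
        cfg = SimConfig(n_experiments=4, n_peptides=80, seed=6)
        table, _ = simulate_dataset(cfg)
        records = roundtrip_evidence(table, tmp_path)
        eligible, _, _ = filter_for_alignment(records)
        m1 = fit_map(eligible)
        shuffled = eligible.sample(frac=1.0, random_state=1)
        m2 = fit_map(shuffled)
        for e in m1.experiment_params:
            p1, p2 = m1.experiment_params[e], m2.experiment_params[e]
            assert p1.beta1 == pytest.approx(p2.beta1, abs=1e-8)
            assert p1.split == pytest.approx(p2.split, abs=1e-6)

    def test_segmented_fit_beats_linear_on_kinked_data(self, study):
        from rtalign.alignment import predict_aligned

        eligible = study["eligible"]
        linear = fit_map(eligible, opts=FitOptions(segmented=False))
        res_seg = predict_aligned(study["model"], eligible)["residual_rt"]
        res_lin = predict_aligned(linear, eligible)["residual_rt"]
        assert np.median(np.abs(res_seg)) < np.median(np.abs(res_lin))


def test_model_serialization_round_trip(study, tmp_path):
    model = study["model"]
    path = tmp_path / "model.json"
    model.to_json(path)
    back = AlignmentModel.from_json(path)
    assert back.experiment_params == model.experiment_params
    assert back.sigma_inflation == model.sigma_inflation
    key = next(iter(model.reference_rts))
    assert back.reference_rts[key].mu == model.reference_rts[key].mu
    assert len(back.reference_rts) == len(model.reference_rts)
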