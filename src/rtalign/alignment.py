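"""Global Bayesian retention-time alignment.

Model
-----
Each peptide *i* has a latent, experiment-independent reference RT mu_i. Each
experiment (LC-MS/MS run) *k* distorts the reference scale through a monotone
two-segment linear map

    g_k(mu) = beta0_k + beta1_k * min(mu, s_k) + beta2_k * max(mu - s_k, 0)

with positive slopes, an intercept constrained so g_k(0) >= 0, and a split
point s_k in (0, max RT). The observed RT of a correct PSM scatters around
g_k(mu_i) with Laplace residuals whose scale grows linearly along the
gradient, sigma_ik = a_k + b_k * mu_i. An incorrect PSM carries no RT
information about its assigned peptide; its RT is modeled by a broad
per-experiment Normal "null" with empirical moments. The two cases are mixed
per PSM, weighted by the search engine's posterior error probability
lambda_ik, so low-confidence PSMs still contribute (weakly) to the alignment:

    P(rho | ...) ∝ 1{rho>0} [ (1-lambda) Laplace(rho; g_k(mu_i), sigma_ik)
                              + lambda  Normal(rho; null_mean_k, null_sd_k) ]

All reference RTs and experiment parameters are inferred jointly by maximum a
posteriori optimization (L-BFGS with analytic gradients on an unconstrained
reparameterization: log for positive parameters, scaled logit for the split
point). The null moments are fixed at their empirical values and never
optimized. The support indicator is honored without renormalizing the
truncated densities: RT mass near zero is negligible on real gradients.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import NumericalError

_LOG_2PI = math.log(2.0 * math.pi)
_MIN_SLOPE = 1e-12


@dataclass
class ExperimentParams:
    """Per-experiment alignment parameters.

    beta0/beta1/beta2/split define the two-segment map; sigma_intercept and
    sigma_slope (a_k, b_k) the RT-dependent Laplace residual scale;
    null_mean/null_sd the empirical Normal of incorrect-match RTs.
    """

    beta0: float
    beta1: float
    beta2: float
    split: float
    sigma_intercept: float
    sigma_slope: float
    null_mean: float
    null_sd: float

    def validate(self) -> None:
        if not (
            self.beta1 > 0
            and self.beta2 > 0
            and self.sigma_intercept > 0
            and self.sigma_slope >= 0
            and self.null_sd > 0
            and self.beta0 >= 0
            and self.split >= 0
        ):
            raise NumericalError(f"invalid experiment parameters: {self}")


@dataclass
class ReferenceRT:
    """Latent reference RT of one peptide, plus bootstrap replicates."""

    peptide_key: str
    mu: float
    n_observations: int
    bootstrap_replicates: np.ndarray | None = None


@dataclass
class Hyperpriors:
    """Global data-derived constants and prior hyperparameters.

    rt_mean/rt_sd are the mean and SD of all observed RTs (prior for the
    reference RTs); rt_max bounds the split point. The remaining constants
    are the (log-location, log-scale) pairs of the lognormal priors and the
    Normal SD of the intercept prior.
    """

    rt_mean: float
    rt_sd: float
    rt_max: float
    beta0_prior_sd: float = 10.0
    beta_slope_prior: tuple[float, float] = (0.0, 0.5)
    sigma_intercept_prior: tuple[float, float] = (0.0, 2.0)
    sigma_slope_prior_scale: float = 1.0
    b_global_prior: tuple[float, float] = (0.1, 0.5)

    @classmethod
    def from_data(cls, data: pd.DataFrame) -> "Hyperpriors":
        rt = data["observed_rt"].to_numpy(dtype=float)
        sd = float(np.std(rt))
        return cls(
            rt_mean=float(np.mean(rt)),
            rt_sd=max(sd, 1e-6),
            rt_max=float(np.max(rt)),
        )


@dataclass
class AlignmentModel:
    """The fitted parameter collection: all experiments, all reference RTs."""

    experiment_params: dict[str, ExperimentParams]
    reference_rts: dict[str, ReferenceRT]
    hyperpriors: Hyperpriors
    log_posterior: float = float("nan")
    converged: bool = False
    iterations: int = 0
    dropped_experiments: list[str] = field(default_factory=list)
    # finite-sample correction for the maximum-likelihood residual scale: an
    # L1 fit with p location parameters interpolates ~p of n observations,
    # deflating the fitted scale by ~(1 - p/n); downstream density
    # evaluations multiply sigma_ik by this factor (ddof-style correction)
    sigma_inflation: float = 1.0

    # -- serialization (plain JSON so align and update can run separately) --
    def to_json(self, path: str | Path, include_replicates: bool = True) -> None:
        peptides = {}
        for key, ref in self.reference_rts.items():
            rec: dict = {"mu": ref.mu, "n_observations": ref.n_observations}
            if include_replicates and ref.bootstrap_replicates is not None:
                rec["bootstrap_replicates"] = [
                    float(x) for x in ref.bootstrap_replicates
                ]
            peptides[key] = rec
        doc = {
            "hyperpriors": asdict(self.hyperpriors),
            "experiments": {k: asdict(p) for k, p in self.experiment_params.items()},
            "peptides": peptides,
            "log_posterior": self.log_posterior,
            "converged": self.converged,
            "iterations": self.iterations,
            "dropped_experiments": list(self.dropped_experiments),
            "sigma_inflation": self.sigma_inflation,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignmentModel":
        doc = json.loads(Path(path).read_text())
        hp = doc["hyperpriors"]
        for key in ("beta_slope_prior", "sigma_intercept_prior", "b_global_prior"):
            hp[key] = tuple(hp[key])
        refs = {}
        for key, rec in doc["peptides"].items():
            reps = rec.get("bootstrap_replicates")
            refs[key] = ReferenceRT(
                peptide_key=key,
                mu=rec["mu"],
                n_observations=rec["n_observations"],
                bootstrap_replicates=None if reps is None else np.asarray(reps, float),
            )
        return cls(
            experiment_params={
                k: ExperimentParams(**p) for k, p in doc["experiments"].items()
            },
            reference_rts=refs,
            hyperpriors=Hyperpriors(**hp),
            log_posterior=doc["log_posterior"],
            converged=doc["converged"],
            iterations=doc["iterations"],
            dropped_experiments=list(doc["dropped_experiments"]),
            sigma_inflation=doc.get("sigma_inflation", 1.0),
        )


# ---------------------------------------------------------------------------
# elementary operations


def two_segment_transform(params: ExperimentParams, mu):
    """Map a reference RT into an experiment's RT scale (clamped at 0)."""
    mu_arr = np.asarray(mu, dtype=float)
    out = (
        params.beta0
        + params.beta1 * np.minimum(mu_arr, params.split)
        + params.beta2 * np.maximum(mu_arr - params.split, 0.0)
    )
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(mu) else out


def inverse_transform(params: ExperimentParams, rho):
    """Exact piecewise-linear inverse of :func:`two_segment_transform`.

    Outside the modeled range the adjacent linear piece is extrapolated, so
    the inverse is total on the reals.
    """
    if params.beta1 <= _MIN_SLOPE or params.beta2 <= _MIN_SLOPE:
        raise NumericalError(
            f"degenerate transform slope (beta1={params.beta1}, beta2={params.beta2})"
        )
    rho_arr = np.asarray(rho, dtype=float)
    rho_split = params.beta0 + params.beta1 * params.split
    below = rho_arr < rho_split
    out = np.where(
        below,
        (rho_arr - params.beta0) / params.beta1,
        params.split + (rho_arr - rho_split) / params.beta2,
    )
    return float(out) if np.isscalar(rho) else out


def residual_sd(params: ExperimentParams, mu):
    """Laplace scale of the RT residual at reference RT ``mu``."""
    mu_arr = np.asarray(mu, dtype=float)
    out = params.sigma_intercept + params.sigma_slope * mu_arr
    return float(out) if np.isscalar(mu) else out


def _laplace_logpdf(x, loc, scale):
    return -np.log(2.0 * scale) - np.abs(x - loc) / scale


def _normal_logpdf(x, loc, sd):
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((x - loc) / sd) ** 2


def mixture_log_likelihood(
    rho: float,
    lam: float,
    mu_ik: float,
    sigma_ik: float,
    null_params: tuple[float, float],
) -> float:
    """Log of the PEP-weighted two-component RT density at one observation.

    ``(1-lam) * Laplace(rho; mu_ik, sigma_ik) + lam * Normal(rho; null)``,
    restricted to rho > 0 (non-positive rho has log-density -inf; the
    truncated components are not renormalized).
    """
    null_mean, null_sd = null_params
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma_ik <= 0 or null_sd <= 0:
        raise ValueError("sigma_ik and null_sd must be positive")
    if rho <= 0:
        return float("-inf")
    terms = []
    if lam < 1.0:
        terms.append(math.log1p(-lam) + float(_laplace_logpdf(rho, mu_ik, sigma_ik)))
    if lam > 0.0:
        terms.append(math.log(lam) + float(_normal_logpdf(rho, null_mean, null_sd)))
    if len(terms) == 1:
        return terms[0]
    return float(np.logaddexp(terms[0], terms[1]))


# ---------------------------------------------------------------------------
# vectorized fit machinery


class _FitData:
    """Column-array view of the eligible PSM set, factorized for the fit."""

    def __init__(self, data: pd.DataFrame):
        self.rho = data["observed_rt"].to_numpy(dtype=float)
        self.lam = np.clip(data["spectral_pep"].to_numpy(dtype=float), 0.0, 1.0)
        # sorted-unique factorization => row order never affects the fit
        self.exp_ids, self.exp_idx = np.unique(
            data["experiment_id"].to_numpy(), return_inverse=True
        )
        self.pep_keys, self.pep_idx = np.unique(
            data["peptide_key"].to_numpy(), return_inverse=True
        )
        self.n_exp = len(self.exp_ids)
        self.n_pep = len(self.pep_keys)
        self.n_obs = len(self.rho)

    def set_null(self, null_mean: np.ndarray, null_sd: np.ndarray) -> None:
        self.null_mean = null_mean
        self.null_sd = null_sd
        self.log_f0 = _normal_logpdf(
            self.rho, null_mean[self.exp_idx], null_sd[self.exp_idx]
        )


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


class _Parameterization:
    """Pack/unpack between model parameters and the unconstrained vector.

    Layout: [log mu (N)] [log beta0 (K)] [log beta1 (K)] [log beta2 (K)]
    [logit(s/rt_max) (K)] [log a (K)] [log b (K)] [log b_global].
    With ``segmented=False`` the beta2 block is slaved to beta1 (single
    slope; the split point becomes inert).
    """

    def __init__(self, n_pep: int, n_exp: int, rt_max: float, segmented: bool):
        self.n_pep = n_pep
        self.n_exp = n_exp
        self.rt_max = rt_max
        self.segmented = segmented
        self.size = n_pep + 6 * n_exp + 1

    def pack(self, mu, beta0, beta1, beta2, split, a, b, b_global):
        frac = np.clip(np.asarray(split, float) / self.rt_max, 1e-6, 1 - 1e-6)
        return np.concatenate(
            [
                np.log(np.maximum(mu, 1e-9)),
                np.log(np.maximum(beta0, 1e-9)),
                np.log(beta1),
                np.log(beta2),
                _logit(frac),
                np.log(a),
                np.log(b),
                [np.log(b_global)],
            ]
        )

    def unpack(self, u):
        n, k = self.n_pep, self.n_exp
        u = np.clip(u, -40.0, 40.0)  # keep exp() and its squares finite
        mu = np.exp(u[:n])
        blocks = [u[n + i * k : n + (i + 1) * k] for i in range(6)]
        beta0 = np.exp(blocks[0])
        beta1 = np.exp(blocks[1])
        beta2 = np.exp(blocks[2]) if self.segmented else beta1
        sfrac = _sigmoid(blocks[3])
        split = self.rt_max * sfrac
        a = np.exp(blocks[4])
        b = np.exp(blocks[5])
        b_global = float(np.exp(u[-1]))
        return mu, beta0, beta1, beta2, split, sfrac, a, b, b_global


def _lognormal_logpdf_and_grad(x, loc, scale):
    """Returns (sum logpdf, d logpdf / dx elementwise)."""
    lx = np.log(x)
    z = (lx - loc) / scale
    logpdf = -lx - math.log(scale) - 0.5 * _LOG_2PI - 0.5 * z**2
    grad = -(1.0 + z / scale) / x
    return float(np.sum(logpdf)), grad


def _objective(u, fd: _FitData, hyper: Hyperpriors, par: _Parameterization):
    """Negative log posterior and its gradient in unconstrained coordinates."""
    mu, beta0, beta1, beta2, split, sfrac, a, b, b_global = par.unpack(u)
    ei, pi = fd.exp_idx, fd.pep_idx
    m = mu[pi]
    s_k = split[ei]
    lo = np.minimum(m, s_k)
    hi = np.maximum(m - s_k, 0.0)
    g = beta0[ei] + beta1[ei] * lo + beta2[ei] * hi
    sigma = a[ei] + b[ei] * m
    r = fd.rho - g
    abs_r = np.abs(r)

    log_f1 = -np.log(2.0 * sigma) - abs_r / sigma
    with np.errstate(divide="ignore"):
        lt1 = np.log1p(-fd.lam) + log_f1  # -inf where lam == 1
        lt2 = np.log(fd.lam) + fd.log_f0  # -inf where lam == 0
    ll = np.logaddexp(lt1, lt2)
    loglik = float(np.sum(ll))

    # responsibility of the correct-match component
    w = np.exp(lt1 - ll)
    c_g = w * np.sign(r) / sigma  # d loglik / d g  (per PSM)
    c_s = w * (abs_r - sigma) / sigma**2  # d loglik / d sigma

    K = fd.n_exp
    d_beta0 = np.bincount(ei, weights=c_g, minlength=K)
    d_beta1 = np.bincount(ei, weights=c_g * lo, minlength=K)
    d_beta2 = np.bincount(ei, weights=c_g * hi, minlength=K)
    on_second = (m >= s_k).astype(float)
    d_split = np.bincount(
        ei, weights=c_g * on_second * (beta1[ei] - beta2[ei]), minlength=K
    )
    d_a = np.bincount(ei, weights=c_s, minlength=K)
    d_b = np.bincount(ei, weights=c_s * m, minlength=K)
    slope_at = np.where(m < s_k, beta1[ei], beta2[ei])
    d_mu = np.bincount(
        pi, weights=c_g * slope_at + c_s * b[ei], minlength=fd.n_pep
    )

    # ---- priors ----
    logprior = 0.0
    # mu ~ Normal(rt_mean, rt_sd)
    z = (mu - hyper.rt_mean) / hyper.rt_sd
    logprior += float(
        np.sum(-0.5 * _LOG_2PI - math.log(hyper.rt_sd) - 0.5 * z**2)
    )
    d_mu = d_mu - z / hyper.rt_sd
    # beta0 ~ Normal(0, 10) truncated to beta0 >= 0 (constant normalization)
    sd0 = hyper.beta0_prior_sd
    logprior += float(np.sum(-0.5 * _LOG_2PI - math.log(sd0) - 0.5 * (beta0 / sd0) ** 2))
    d_beta0 = d_beta0 - beta0 / sd0**2
    # slopes ~ Lognormal(0, 0.5)
    lp, gr = _lognormal_logpdf_and_grad(beta1, *hyper.beta_slope_prior)
    logprior += lp
    d_beta1 = d_beta1 + gr
    if par.segmented:
        lp, gr = _lognormal_logpdf_and_grad(beta2, *hyper.beta_slope_prior)
        logprior += lp
        d_beta2 = d_beta2 + gr
    # a ~ Lognormal(0, 2)
    lp, gr = _lognormal_logpdf_and_grad(a, *hyper.sigma_intercept_prior)
    logprior += lp
    d_a = d_a + gr
    # b ~ Lognormal(log b_global, 1)
    lp, gr = _lognormal_logpdf_and_grad(
        b, math.log(b_global), hyper.sigma_slope_prior_scale
    )
    logprior += lp
    d_b = d_b + gr
    zb = (np.log(b) - math.log(b_global)) / hyper.sigma_slope_prior_scale**2
    d_bg = float(np.sum(zb)) / b_global
    # b_global ~ Lognormal(0.1, 0.5)
    lp, gr = _lognormal_logpdf_and_grad(
        np.asarray([b_global]), *hyper.b_global_prior
    )
    logprior += lp
    d_bg += float(gr[0])
    # s ~ Uniform(0, rt_max): constant within support (enforced by the logit)

    f = loglik + logprior

    # ---- chain rule to unconstrained coordinates ----
    g_mu = d_mu * mu
    g_b0 = d_beta0 * beta0
    if par.segmented:
        g_b1 = d_beta1 * beta1
        g_b2 = d_beta2 * beta2
    else:
        g_b1 = (d_beta1 + d_beta2) * beta1
        g_b2 = np.zeros_like(g_b1)
    g_s = d_split * par.rt_max * sfrac * (1.0 - sfrac)
    g_a = d_a * a
    g_b = d_b * b
    g_bg = d_bg * b_global
    grad = np.concatenate([g_mu, g_b0, g_b1, g_b2, g_s, g_a, g_b, [g_bg]])
    return -f, -grad


def _build_arrays(model: AlignmentModel, data: pd.DataFrame) -> tuple[_FitData, np.ndarray, _Parameterization]:
    fd = _FitData(data)
    missing_exp = set(fd.exp_ids) - set(model.experiment_params)
    missing_pep = set(fd.pep_keys) - set(model.reference_rts)
    if missing_exp or missing_pep:
        raise KeyError(
            f"model does not cover data: experiments {sorted(missing_exp)[:3]}, "
            f"peptides {sorted(missing_pep)[:3]}"
        )
    ep = [model.experiment_params[e] for e in fd.exp_ids]
    fd.set_null(
        np.array([p.null_mean for p in ep]), np.array([p.null_sd for p in ep])
    )
    par = _Parameterization(fd.n_pep, fd.n_exp, model.hyperpriors.rt_max, True)
    b_global = getattr(model, "_b_global", None)
    if b_global is None:
        b_global = float(np.exp(np.mean(np.log([p.sigma_slope for p in ep]))))
    u = par.pack(
        np.array([model.reference_rts[k].mu for k in fd.pep_keys]),
        np.array([p.beta0 for p in ep]),
        np.array([p.beta1 for p in ep]),
        np.array([p.beta2 for p in ep]),
        np.array([p.split for p in ep]),
        np.array([p.sigma_intercept for p in ep]),
        np.array([p.sigma_slope for p in ep]),
        b_global,
    )
    return fd, u, par


def log_likelihood(model: AlignmentModel, data: pd.DataFrame) -> float:
    """Sum of the PEP-weighted mixture log density over all PSMs in ``data``."""
    fd = _FitData(data)
    ep = [model.experiment_params[e] for e in fd.exp_ids]
    fd.set_null(
        np.array([p.null_mean for p in ep]), np.array([p.null_sd for p in ep])
    )
    mu = np.array([model.reference_rts[k].mu for k in fd.pep_keys])
    beta0 = np.array([p.beta0 for p in ep])
    beta1 = np.array([p.beta1 for p in ep])
    beta2 = np.array([p.beta2 for p in ep])
    split = np.array([p.split for p in ep])
    a = np.array([p.sigma_intercept for p in ep])
    b = np.array([p.sigma_slope for p in ep])
    m = mu[fd.pep_idx]
    s_k = split[fd.exp_idx]
    g = (
        beta0[fd.exp_idx]
        + beta1[fd.exp_idx] * np.minimum(m, s_k)
        + beta2[fd.exp_idx] * np.maximum(m - s_k, 0.0)
    )
    sigma = a[fd.exp_idx] + b[fd.exp_idx] * m
    log_f1 = -np.log(2.0 * sigma) - np.abs(fd.rho - g) / sigma
    with np.errstate(divide="ignore"):
        lt1 = np.log1p(-fd.lam) + log_f1
        lt2 = np.log(fd.lam) + fd.log_f0
    ll = np.logaddexp(lt1, lt2)
    ll = np.where(fd.rho > 0, ll, -np.inf)
    return float(np.sum(ll))


def log_posterior(model: AlignmentModel, data: pd.DataFrame) -> float:
    """Joint log posterior: likelihood plus all log priors at the model's values."""
    fd, u, par = _build_arrays(model, data)
    neg_f, _ = _objective(u, fd, model.hyperpriors, par)
    return -neg_f


# ---------------------------------------------------------------------------
# initialization and MAP fit


@dataclass
class FitOptions:
    """Optimizer settings: relative-objective tolerance and iteration cap."""

    tolerance: float = 1e-7
    max_iterations: int = 20000
    segmented: bool = True
    min_peptides_per_experiment: int = 2
    # profile the split point over a coarse grid after the joint fit;
    # guards against the kink settling in a local optimum near its start
    refine_splits: bool = True
    split_grid: tuple[float, ...] = (0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85)


def _segmented_least_squares(
    x: np.ndarray, y: np.ndarray, n_grid: int = 9
) -> tuple[float, float, float, float]:
    """Continuous two-segment least squares with the split on a quantile grid.

    One outlier-trimming pass (5x the median absolute residual) keeps
    incorrect matches from dragging the segments. Returns
    (beta0, beta1, beta2, split), slopes clamped positive.
    """
    grid = np.quantile(x, np.linspace(0.15, 0.85, n_grid))

    def _fit(xs, ys):
        best = None
        for s in grid:
            X = np.column_stack(
                [np.ones_like(xs), np.minimum(xs, s), np.maximum(xs - s, 0.0)]
            )
            coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
            sse = float(np.sum((ys - X @ coef) ** 2))
            if best is None or sse < best[0]:
                best = (sse, float(s), coef)
        return best

    _, s, coef = _fit(x, y)
    pred = coef[0] + coef[1] * np.minimum(x, s) + coef[2] * np.maximum(x - s, 0.0)
    resid = np.abs(y - pred)
    mad = max(float(np.median(resid)), 1e-6)
    keep = resid <= 5.0 * mad
    if keep.sum() >= 10 and keep.sum() < len(x):
        _, s, coef = _fit(x[keep], y[keep])
    beta0 = max(float(coef[0]), 1e-6)
    beta1 = max(float(coef[1]), 5e-2)
    beta2 = max(float(coef[2]), 5e-2)
    return beta0, beta1, beta2, float(s)


def initialize_model(
    data: pd.DataFrame, hyper: Hyperpriors | None = None, n_rounds: int = 3
) -> AlignmentModel:
    """Closed-form initialization of all parameters.

    Round zero takes each peptide's median observed RT as its reference and
    fits per-experiment regressions of observed RT on the references.
    Subsequent rounds alternate (i) a two-segment least-squares refit per
    experiment with the split on a coarse quantile grid and one
    outlier-trimming pass, and (ii) re-estimation of each reference RT as
    the median of its inverse-transformed observations. The residual scale
    splits the median absolute residual between intercept and slope, and the
    null moments are fixed at the experiment's empirical RT mean/SD.
    Experiments with fewer than two distinct alignable peptides are dropped
    with a warning.
    """
    data = data.sort_values(
        ["experiment_id", "peptide_key", "observed_rt", "spectral_pep"],
        kind="stable",
    )
    hyper = hyper or Hyperpriors.from_data(data)
    grouped = data.groupby("peptide_key")
    mu = grouped["observed_rt"].median()
    n_obs = grouped.size()

    dropped: list[str] = []
    for exp_id, sub in data.groupby("experiment_id"):
        if sub["peptide_key"].nunique() < 2:
            warnings.warn(
                f"experiment {exp_id!r} has fewer than 2 alignable peptides; dropped"
            )
            dropped.append(str(exp_id))
    kept = data[~data["experiment_id"].isin(dropped)]

    fits: dict[str, tuple[float, float, float, float]] = {}
    for round_idx in range(max(n_rounds, 1)):
        for exp_id, sub in kept.groupby("experiment_id"):
            x = mu.reindex(sub["peptide_key"]).to_numpy(dtype=float)
            y = sub["observed_rt"].to_numpy(dtype=float)
            if round_idx == 0:
                slope, intercept = np.polyfit(x, y, 1)
                s = float(np.median(y))
                fits[str(exp_id)] = (
                    max(float(intercept), 1e-6),
                    max(float(slope), 5e-2),
                    max(float(slope), 5e-2),
                    s,
                )
            else:
                fits[str(exp_id)] = _segmented_least_squares(x, y)
        if round_idx == max(n_rounds, 1) - 1:
            break
        # re-estimate references as medians in the inverse-transformed space
        back = np.empty(len(kept))
        pos = 0
        for exp_id, sub in kept.groupby("experiment_id"):
            beta0, beta1, beta2, s = fits[str(exp_id)]
            p = ExperimentParams(beta0, beta1, beta2, s, 1.0, 0.0, 0.0, 1.0)
            back[pos : pos + len(sub)] = inverse_transform(
                p, sub["observed_rt"].to_numpy(dtype=float)
            )
            pos += len(sub)
        order_keys = np.concatenate(
            [sub["peptide_key"].to_numpy() for _, sub in kept.groupby("experiment_id")]
        )
        mu = (
            pd.Series(back, index=order_keys)
            .groupby(level=0)
            .median()
            .clip(lower=1e-6)
        )

    refs = {
        key: ReferenceRT(
            peptide_key=key,
            mu=max(float(mu[key]), 1e-6),
            n_observations=int(n_obs[key]),
        )
        for key in mu.index
    }
    params: dict[str, ExperimentParams] = {}
    for exp_id, sub in kept.groupby("experiment_id"):
        beta0, beta1, beta2, s = fits[str(exp_id)]
        x = mu.reindex(sub["peptide_key"]).to_numpy(dtype=float)
        y = sub["observed_rt"].to_numpy(dtype=float)
        pred = beta0 + beta1 * np.minimum(x, s) + beta2 * np.maximum(x - s, 0.0)
        med_abs = max(float(np.median(np.abs(y - pred))), 1e-3)
        mean_mu = max(float(np.mean(x)), 1.0)
        s = min(max(s, 0.02 * hyper.rt_max), 0.98 * hyper.rt_max)
        params[str(exp_id)] = ExperimentParams(
            beta0=beta0,
            beta1=beta1,
            beta2=beta2,
            split=s,
            sigma_intercept=med_abs / 2.0,
            sigma_slope=max(med_abs / (2.0 * mean_mu), 1e-5),
            null_mean=float(np.mean(y)),
            null_sd=max(float(np.std(y, ddof=0)), 1e-3),
        )
    model = AlignmentModel(
        experiment_params=params,
        reference_rts=refs,
        hyperpriors=hyper,
        dropped_experiments=dropped,
    )
    if params:
        model.log_posterior = log_posterior(model, kept)
    return model


def _refine_split_points(
    u: np.ndarray,
    f_current: float,
    fd: _FitData,
    hyper: Hyperpriors,
    par: _Parameterization,
    split_grid: Iterable[float],
) -> np.ndarray:
    """Profile each experiment's split over a coarse grid.

    For each experiment in turn, restart its six parameters from every grid
    position of the split fraction and conditionally re-optimize them (all
    other parameters held fixed); improvements are accepted, so the joint
    objective can only go up. Experiments are conditionally independent
    given the reference RTs, which makes this a valid block ascent.
    """
    u = u.copy()
    n, K = par.n_pep, par.n_exp
    for j in range(K):
        idx = np.array([n + i * K + j for i in range(6)])

        def sub_obj(v, idx=idx):
            uu = u.copy()
            uu[idx] = v
            f, g = _objective(uu, fd, hyper, par)
            return f, g[idx]

        best_f = f_current
        best_v = u[idx].copy()
        for sfrac in split_grid:
            v0 = u[idx].copy()
            v0[3] = float(_logit(np.asarray(sfrac)))
            r = minimize(
                sub_obj, v0, method="L-BFGS-B", jac=True, options={"maxiter": 200}
            )
            if np.isfinite(r.fun) and r.fun < best_f:
                best_f = r.fun
                best_v = r.x
        u[idx] = best_v
        f_current = best_f
    return u


def fit_map(
    data: pd.DataFrame,
    hyper: Hyperpriors | None = None,
    opts: FitOptions | None = None,
) -> AlignmentModel:
    """Maximum a posteriori fit of the global alignment.

    Returns a model whose log posterior is at least that of the
    initialization; ``converged`` reflects whether the relative-change
    stopping rule fired before the iteration cap. Deterministic given the
    data (row order is irrelevant: peptides and experiments are factorized in
    sorted order).
    """
    opts = opts or FitOptions()
    # canonical row order: the fit is bit-identical under input permutation
    data = data.sort_values(
        ["experiment_id", "peptide_key", "observed_rt", "spectral_pep"],
        kind="stable",
    )
    init = initialize_model(data, hyper)
    kept = data[~data["experiment_id"].isin(init.dropped_experiments)]
    fd = _FitData(kept)
    ep = [init.experiment_params[e] for e in fd.exp_ids]
    fd.set_null(
        np.array([p.null_mean for p in ep]), np.array([p.null_sd for p in ep])
    )
    par = _Parameterization(
        fd.n_pep, fd.n_exp, init.hyperpriors.rt_max, opts.segmented
    )
    b_arr = np.array([p.sigma_slope for p in ep])
    u0 = par.pack(
        np.array([init.reference_rts[k].mu for k in fd.pep_keys]),
        np.array([p.beta0 for p in ep]),
        np.array([p.beta1 for p in ep]),
        np.array([p.beta2 for p in ep]),
        np.array([p.split for p in ep]),
        np.array([p.sigma_intercept for p in ep]),
        b_arr,
        float(np.exp(np.mean(np.log(b_arr)))),
    )
    res = minimize(
        _objective,
        u0,
        args=(fd, init.hyperpriors, par),
        method="L-BFGS-B",
        jac=True,
        options={
            "maxiter": opts.max_iterations,
            "ftol": opts.tolerance,
            "maxfun": 10 * opts.max_iterations,
        },
    )
    if not np.isfinite(res.fun):
        raise NumericalError("non-finite objective at optimizer solution")
    n_iter = int(res.nit)
    if opts.refine_splits and opts.segmented and fd.n_exp > 0:
        for _ in range(3):  # alternate block ascent on splits with joint polish
            u_ref = _refine_split_points(
                res.x, res.fun, fd, init.hyperpriors, par, opts.split_grid
            )
            polish = minimize(
                _objective,
                u_ref,
                args=(fd, init.hyperpriors, par),
                method="L-BFGS-B",
                jac=True,
                options={"maxiter": opts.max_iterations, "ftol": opts.tolerance},
            )
            n_iter += int(polish.nit)
            improved = polish.fun < res.fun - abs(res.fun) * opts.tolerance * 10
            if polish.fun <= res.fun:
                res = polish
            if not improved:
                break
    mu, beta0, beta1, beta2, split, _, a, b, b_global = par.unpack(res.x)
    n_obs = np.bincount(fd.pep_idx, minlength=fd.n_pep)
    refs = {
        key: ReferenceRT(peptide_key=key, mu=float(m), n_observations=int(n))
        for key, m, n in zip(fd.pep_keys, mu, n_obs)
    }
    params = {}
    for j, exp_id in enumerate(fd.exp_ids):
        p0 = init.experiment_params[exp_id]
        params[str(exp_id)] = ExperimentParams(
            beta0=float(beta0[j]),
            beta1=float(beta1[j]),
            beta2=float(beta2[j]),
            split=float(split[j]),
            sigma_intercept=float(a[j]),
            sigma_slope=float(b[j]),
            null_mean=p0.null_mean,
            null_sd=p0.null_sd,
        )
    model = AlignmentModel(
        experiment_params=params,
        reference_rts=refs,
        hyperpriors=init.hyperpriors,
        log_posterior=float(-res.fun),
        converged=bool(res.success),
        iterations=int(res.nit),
        dropped_experiments=init.dropped_experiments,
    )
    model.iterations = n_iter
    n_location_params = fd.n_pep + 4 * fd.n_exp
    model.sigma_inflation = float(
        min(max(fd.n_obs / max(fd.n_obs - n_location_params, 1), 1.0), 1.5)
    )
    model._b_global = b_global
    if not res.success and res.status != 1:
        warnings.warn(f"optimizer stopped without convergence: {res.message}")
    elif not res.success:
        warnings.warn("optimizer hit the iteration cap before convergence")
    return model


def predict_aligned(model: AlignmentModel, data: pd.DataFrame) -> pd.DataFrame:
    """Per-PSM aligned quantities from a fitted model.

    Returns a frame indexed like ``data`` with columns ``reference_rt``
    (MAP mu of the peptide), ``aligned_rt`` (g_k(mu)), ``residual_rt`` and
    ``sigma`` (the modeled Laplace scale). Rows whose peptide or experiment
    is absent from the model get NaN.
    """
    n = len(data)
    out = pd.DataFrame(
        {
            "reference_rt": np.full(n, np.nan),
            "aligned_rt": np.full(n, np.nan),
            "residual_rt": np.full(n, np.nan),
            "sigma": np.full(n, np.nan),
        },
        index=data.index,
    )
    mu = data["peptide_key"].map(
        {k: r.mu for k, r in model.reference_rts.items()}
    )
    known = mu.notna() & data["experiment_id"].isin(model.experiment_params)
    for exp_id, sub in data[known].groupby("experiment_id"):
        p = model.experiment_params[str(exp_id)]
        m = mu[sub.index].to_numpy(dtype=float)
        g = two_segment_transform(p, m)
        out.loc[sub.index, "reference_rt"] = m
        out.loc[sub.index, "aligned_rt"] = g
        out.loc[sub.index, "residual_rt"] = (
            sub["observed_rt"].to_numpy(dtype=float) - g
        )
        out.loc[sub.index, "sigma"] = residual_sd(p, m)
    return out
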