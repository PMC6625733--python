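"""Bayesian update of PSM error probabilities using aligned-RT evidence.

For each PSM the spectral posterior error probability lambda is treated as
the prior probability of an incorrect match. The RT likelihood ratio between
the peptide's aligned Laplace density and the experiment's null density then
updates it through Bayes' theorem. Uncertainty in the reference RTs is
propagated with a parametric bootstrap: each replicate resamples every
observation of a peptide from its fitted mixture, maps it back to the
reference scale through the inverse alignment, and takes the median across
experiments (the maximum-likelihood location of a Laplace sample). The
updated probability of a correct match averages the Laplace density over the
B replicate reference RTs:

    P(correct | rho) ~= (1-lam) * mean_b f(rho | g_k(mu_b), sigma_ik)
                        / [ same + lam * f0(rho) ]

Alignment-parameter uncertainty is deliberately ignored — those parameters
are pinned down by thousands of observations per experiment, while each
reference RT rests on at most a handful.

Set-wide q-values are recomputed as the running mean of sorted PEPs: the
q-value at rank r is the mean of the r smallest PEPs, i.e. the expected
fraction of false positives among the PSMs accepted at that rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    AlignmentModel,
    inverse_transform,
    residual_sd,
    two_segment_transform,
    _laplace_logpdf,
    _normal_logpdf,
)
from .errors import NumericalError

PEP_FLOOR = 1e-16


@dataclass
class BootstrapSettings:
    """Parametric-bootstrap controls for reference-RT uncertainty."""

    n_replicates: int = 100
    seed: int = 0
    scheme: str = "parametric-mixture"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class UpdateSettings:
    """Controls for the confidence-update stage.

    ``qvalue_scope`` selects whether q-values are computed over target PSMs
    only (decoys get no q-value) or over targets and decoys together.
    """

    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    qvalue_scope: str = "targets"  # or "all"
    pep_floor: float = PEP_FLOOR
    compute_qvalues: bool = True


def bootstrap_reference_rts(
    model: AlignmentModel,
    data: pd.DataFrame,
    settings: BootstrapSettings | None = None,
) -> dict[str, np.ndarray]:
    """Draw B bootstrap replicates of every reference RT in ``data``.

    ``data`` should be the alignment-eligible PSM set the model was fitted
    on. Replicates are stored on the model's :class:`ReferenceRT` records and
    returned as a mapping peptide_key -> (B,) array. Reproducible given the
    seed. Raises ``KeyError`` for peptides or experiments absent from the
    model (the caller must route such PSMs to pass-through).
    """
    settings = settings or BootstrapSettings()
    rng = np.random.default_rng(settings.seed)
    missing = set(data["peptide_key"]) - set(model.reference_rts)
    if missing:
        raise KeyError(f"peptides absent from model: {sorted(missing)[:5]}")
    missing_exp = set(data["experiment_id"].astype(str)) - set(
        model.experiment_params
    )
    if missing_exp:
        raise KeyError(f"experiments absent from model: {sorted(missing_exp)[:5]}")

    B = settings.n_replicates
    n = len(data)
    lam = np.clip(data["spectral_pep"].to_numpy(dtype=float), 0.0, 1.0)
    pep_keys, pep_idx = np.unique(data["peptide_key"].to_numpy(), return_inverse=True)
    exp_ids = data["experiment_id"].astype(str).to_numpy()

    mu_hat = np.array([model.reference_rts[k].mu for k in pep_keys])[pep_idx]
    mu_ik = np.empty(n)
    sigma_ik = np.empty(n)
    null_mean = np.empty(n)
    null_sd = np.empty(n)
    infl = model.sigma_inflation
    for exp_id in np.unique(exp_ids):
        p = model.experiment_params[exp_id]
        rows = exp_ids == exp_id
        mu_ik[rows] = two_segment_transform(p, mu_hat[rows])
        sigma_ik[rows] = infl * residual_sd(p, mu_hat[rows])
        null_mean[rows] = p.null_mean
        null_sd[rows] = p.null_sd

    correct = rng.random((n, B)) >= lam[:, None]
    lap = rng.laplace(mu_ik[:, None], sigma_ik[:, None], size=(n, B))
    nul = rng.normal(null_mean[:, None], null_sd[:, None], size=(n, B))
    rho_b = np.where(correct, lap, nul)

    # back to the reference scale through the inverse alignment
    back = np.empty_like(rho_b)
    for exp_id in np.unique(exp_ids):
        p = model.experiment_params[exp_id]
        rows = exp_ids == exp_id
        back[rows] = inverse_transform(p, rho_b[rows])

    order = np.argsort(pep_idx, kind="stable")
    bounds = np.searchsorted(pep_idx[order], np.arange(len(pep_keys) + 1))
    replicates: dict[str, np.ndarray] = {}
    for j, key in enumerate(pep_keys):
        rows = order[bounds[j] : bounds[j + 1]]
        replicates[key] = np.median(back[rows], axis=0)
        model.reference_rts[key].bootstrap_replicates = replicates[key]
    return replicates


def update_pep(
    psm: pd.Series,
    model: AlignmentModel,
    replicates: np.ndarray,
    pep_floor: float = PEP_FLOOR,
) -> dict:
    """Updated error probability of a single PSM (scalar reference path).

    Returns a dict with ``updated_pep``, ``reference_rt``, ``aligned_rt``,
    ``residual_rt``. The Laplace scale is evaluated at the MAP reference RT
    (held fixed across the bootstrap average).
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size == 0:
        raise ValueError("replicates must be non-empty")
    exp_id = str(psm["experiment_id"])
    p = model.experiment_params[exp_id]
    mu_map = model.reference_rts[psm["peptide_key"]].mu
    lam = float(np.clip(psm["spectral_pep"], 0.0, 1.0))
    rho = float(psm["observed_rt"])
    sigma = model.sigma_inflation * residual_sd(p, mu_map)
    locs = two_segment_transform(p, replicates)
    lap_mean = float(np.mean(np.exp(_laplace_logpdf(rho, locs, sigma))))
    f0 = float(np.exp(_normal_logpdf(rho, p.null_mean, p.null_sd)))
    num = (1.0 - lam) * lap_mean
    den = num + lam * f0
    if not np.isfinite(den):
        raise NumericalError(f"non-finite density for psm_id={psm.get('psm_id')}")
    pep = lam if den == 0.0 else 1.0 - num / den
    aligned = two_segment_transform(p, mu_map)
    return {
        "updated_pep": float(np.clip(pep, pep_floor, 1.0)),
        "reference_rt": float(mu_map),
        "aligned_rt": float(aligned),
        "residual_rt": rho - float(aligned),
    }


def compute_qvalues(peps) -> np.ndarray:
    """q-values as prefix means of ascending-sorted PEPs.

    The q-value at rank r is ``sum of the r smallest PEPs / r``; tied PEPs
    all receive the q of the last tied rank (conservative and order
    invariant). The result is reported in the input order.
    """
    p = np.asarray(peps, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("PEPs must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.cumsum(ps) / np.arange(1, p.size + 1)
    last_tied = np.searchsorted(ps, ps, side="right") - 1
    q_tied = q_sorted[last_tied]
    out = np.empty_like(q_tied)
    out[order] = q_tied
    return out


def apply_update(
    records: pd.DataFrame,
    model: AlignmentModel,
    settings: UpdateSettings | None = None,
) -> pd.DataFrame:
    """Update every updatable PSM and recompute set-wide q-values.

    A PSM is updatable when its peptide has a reference RT and its experiment
    has fitted alignment parameters — this covers the alignment-eligible set
    and any pass-through PSM whose peptide gained a reference elsewhere. All
    other rows carry their spectral PEP forward. The bootstrap is drawn from
    the rows marked ``alignment_eligible`` (all updatable rows if the marker
    column is absent).
    """
    settings = settings or UpdateSettings()
    df = records.copy()
    n = len(df)

    has_ref = df["peptide_key"].isin(model.reference_rts).to_numpy()
    has_exp = df["experiment_id"].astype(str).isin(model.experiment_params).to_numpy()
    finite_rt = np.isfinite(df["observed_rt"].to_numpy(dtype=float))
    updatable = has_ref & has_exp & finite_rt

    if "alignment_eligible" in df.columns:
        boot_rows = df["alignment_eligible"].fillna(False).to_numpy(dtype=bool)
        boot_rows &= updatable
    else:
        boot_rows = updatable
    if boot_rows.any():
        replicates = bootstrap_reference_rts(
            model, df.loc[boot_rows], settings.bootstrap
        )
    else:
        replicates = {}

    updated_pep = df["spectral_pep"].to_numpy(dtype=float).copy()
    reference_rt = np.full(n, np.nan)
    aligned_rt = np.full(n, np.nan)
    residual_rt = np.full(n, np.nan)

    sub = df.loc[updatable]
    if sub.empty:
        df["updated_pep"] = updated_pep
        df["reference_rt"] = reference_rt
        df["aligned_rt"] = aligned_rt
        df["residual_rt"] = residual_rt
        df["participation"] = "pass-through"
        if settings.compute_qvalues:
            df["updated_qvalue"] = _scoped_qvalues(df, updated_pep, settings)
        return df
    lam = np.clip(sub["spectral_pep"].to_numpy(dtype=float), 0.0, 1.0)
    rho = sub["observed_rt"].to_numpy(dtype=float)
    pep_keys, pep_idx = np.unique(sub["peptide_key"].to_numpy(), return_inverse=True)
    mu_map = np.array([model.reference_rts[k].mu for k in pep_keys])
    reps = np.stack(
        [
            replicates.get(
                k, np.full(settings.bootstrap.n_replicates, model.reference_rts[k].mu)
            )
            for k in pep_keys
        ]
    )  # (n_pep, B); peptides seen only in pass-through rows fall back to the MAP
    exp_ids = sub["experiment_id"].astype(str).to_numpy()
    m = mu_map[pep_idx]
    lap_mean = np.empty(len(sub))
    f0 = np.empty(len(sub))
    g_map = np.empty(len(sub))
    sigma = np.empty(len(sub))
    infl = model.sigma_inflation
    for exp_id in np.unique(exp_ids):
        p = model.experiment_params[exp_id]
        rows = exp_ids == exp_id
        sigma[rows] = infl * residual_sd(p, m[rows])
        g_map[rows] = two_segment_transform(p, m[rows])
        locs = two_segment_transform(p, reps[pep_idx[rows]])  # (n_rows, B)
        dens = np.exp(_laplace_logpdf(rho[rows][:, None], locs, sigma[rows][:, None]))
        lap_mean[rows] = dens.mean(axis=1)
        f0[rows] = np.exp(_normal_logpdf(rho[rows], p.null_mean, p.null_sd))
    num = (1.0 - lam) * lap_mean
    den = num + lam * f0
    if not np.all(np.isfinite(den)):
        bad = sub["psm_id"].to_numpy()[~np.isfinite(den)]
        raise NumericalError(f"non-finite update density for psm_id={bad[:5]}")
    with np.errstate(invalid="ignore"):
        pep_new = np.where(den == 0.0, lam, 1.0 - num / den)
    pep_new = np.clip(pep_new, settings.pep_floor, 1.0)

    idx = np.flatnonzero(updatable)
    updated_pep[idx] = pep_new
    reference_rt[idx] = m
    aligned_rt[idx] = g_map
    residual_rt[idx] = rho - g_map

    df["updated_pep"] = updated_pep
    df["reference_rt"] = reference_rt
    df["aligned_rt"] = aligned_rt
    df["residual_rt"] = residual_rt
    df["participation"] = np.where(updatable, "aligned-and-updated", "pass-through")

    if settings.compute_qvalues:
        df["updated_qvalue"] = _scoped_qvalues(df, updated_pep, settings)
    return df


def _scoped_qvalues(
    df: pd.DataFrame, peps: np.ndarray, settings: UpdateSettings
) -> np.ndarray:
    q = np.full(len(df), np.nan)
    if settings.qvalue_scope == "all":
        scope = np.ones(len(df), dtype=bool)
    elif settings.qvalue_scope == "targets":
        scope = ~df["is_decoy"].to_numpy(dtype=bool)
    else:
        raise ValueError(f"unknown qvalue_scope: {settings.qvalue_scope!r}")
    q[scope] = compute_qvalues(peps[scope])
    return q
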