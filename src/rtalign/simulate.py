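"""Synthetic multi-experiment PSM tables with known ground truth.

The generator inverts the alignment model's generative story so every other
module can be exercised without any external data: reference RTs are drawn
across a 60-minute gradient, each simulated run applies its own two-segment
monotone distortion, correct matches scatter with Laplace residuals whose
scale grows along the gradient, and incorrect matches draw their RT from the
run-wide Normal null. Spectral PEPs come from two Beta distributions —
concentrated near zero for correct PSMs and broad for incorrect ones — so
the generator reproduces the gray zone of ambiguous identifications that RT
evidence can resolve.

Two PEP modes are available. ``conditional`` (default) draws the
correctness label first and then the PEP from the label-conditioned Beta;
the marginal incorrect fraction equals ``incorrect_rate`` but the PEPs are
not calibrated probabilities. ``calibrated`` draws the PEP from the Beta
mixture marginal and then the label as Bernoulli(1 - PEP), making
P(incorrect | PEP) = PEP exactly — the right condition for checking FDR and
PEP calibration of downstream updates (the realized incorrect fraction is
then the mean PEP rather than ``incorrect_rate``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import ExperimentParams, two_segment_transform, residual_sd
from .confidence import compute_qvalues
from .errors import ConfigurationError

_ALPHABET = "ACDEFGHILMNPQSTVW"  # no K/R (reserved for the tryptic terminus)


def _peptide_name(i: int) -> str:
    """Deterministic unique tryptic-looking sequence for peptide index i."""
    letters = []
    x = i
    for _ in range(6):
        letters.append(_ALPHABET[x % len(_ALPHABET)])
        x //= len(_ALPHABET)
    return "PE" + "".join(letters) + "K"


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a staggered set of 60-minute runs on one LC system:
    slopes near identity, split points in the middle third of the gradient,
    residual scales of a few seconds growing along the gradient, and a few
    percent of incorrect matches.
    """

    n_experiments: int = 10
    n_peptides: int = 300
    observation_rate: float = 0.8
    incorrect_rate: float = 0.05
    gradient_length: float = 60.0
    beta0_range: tuple[float, float] = (0.0, 2.0)
    beta1_range: tuple[float, float] = (0.85, 1.15)
    beta2_range: tuple[float, float] = (0.85, 1.15)
    split_range: tuple[float, float] = (20.0, 40.0)
    # minimum |beta1 - beta2|: the emitted distortions are genuinely
    # two-segment, never degenerate-linear (a kink of < ~0.1 would leave the
    # split point unidentifiable at realistic residual scales)
    min_slope_separation: float = 0.1
    sigma_intercept_range: tuple[float, float] = (0.05, 0.15)
    sigma_slope_range: tuple[float, float] = (0.002, 0.008)
    pep_correct_beta: tuple[float, float] = (1.0, 19.0)
    pep_incorrect_beta: tuple[float, float] = (4.0, 4.0)
    pep_mode: str = "conditional"  # or "calibrated"
    decoy_rate: float = 0.0
    quant: bool = False
    n_channels: int = 10
    peptides_per_protein: int = 5
    protein_log_fc_sd: float = 0.5
    quant_noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        probs = (self.observation_rate, self.incorrect_rate, self.decoy_rate)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.observation_rate == 0.0:
            raise ConfigurationError("observation_rate of 0 generates no data")
        if self.n_experiments < 2 or self.n_peptides < 1:
            raise ConfigurationError("need >= 2 experiments and >= 1 peptide")
        if self.pep_mode not in ("conditional", "calibrated"):
            raise ConfigurationError(f"unknown pep_mode: {self.pep_mode!r}")
        for lo, hi in (
            self.beta1_range,
            self.beta2_range,
            self.sigma_intercept_range,
            self.sigma_slope_range,
        ):
            if lo < 0 or hi < lo:
                raise ConfigurationError("parameter ranges must be positive intervals")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset, keyed by psm_id."""

    psm: pd.DataFrame  # psm_id, delta, true_mu, true_sigma, experiment_id
    reference_rts: dict[str, float]
    experiment_params: dict[str, ExperimentParams]
    protein_of_peptide: dict[str, str] = field(default_factory=dict)


def simulate_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate an evidence-dialect PSM table plus its ground truth.

    Deterministic given ``cfg.seed``; the emitted frame is readable by
    :func:`rtalign.io.read_psm_table` after a round trip through
    ``to_csv(sep="\\t")``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.gradient_length
    K, N = cfg.n_experiments, cfg.n_peptides

    peptides = [_peptide_name(i) for i in range(N)]
    mu = rng.uniform(0.05 * G, 0.92 * G, size=N)
    reference_rts = dict(zip(peptides, mu.tolist()))

    exp_ids = [f"run_{k:03d}" for k in range(K)]
    true_params: dict[str, ExperimentParams] = {}
    for k, exp_id in enumerate(exp_ids):
        beta1 = rng.uniform(*cfg.beta1_range)
        beta2 = rng.uniform(*cfg.beta2_range)
        for _ in range(1000):
            if abs(beta1 - beta2) >= cfg.min_slope_separation:
                break
            beta2 = rng.uniform(*cfg.beta2_range)
        true_params[exp_id] = ExperimentParams(
            beta0=rng.uniform(*cfg.beta0_range),
            beta1=beta1,
            beta2=beta2,
            split=rng.uniform(*cfg.split_range),
            sigma_intercept=rng.uniform(*cfg.sigma_intercept_range),
            sigma_slope=rng.uniform(*cfg.sigma_slope_range),
            null_mean=0.0,  # filled from the realized RTs below
            null_sd=1.0,
        )

    obs = rng.random((N, K)) < cfg.observation_rate
    # guarantee each peptide appears somewhere so the table has N peptides
    empty = ~obs.any(axis=1)
    obs[empty, rng.integers(0, K, size=int(empty.sum()))] = True

    rows: list[dict] = []
    truth_rows: list[dict] = []
    protein_of_peptide: dict[str, str] = {}
    if cfg.quant:
        n_prot = max(1, N // cfg.peptides_per_protein)
        prot_ids = [f"P{j:04d}" for j in range(n_prot)]
        prot_of_idx = rng.integers(0, n_prot, size=N)
        protein_of_peptide = {
            peptides[i]: prot_ids[prot_of_idx[i]] for i in range(N)
        }
        # protein-level channel profiles: two cell types with a protein fold change
        half = cfg.n_channels // 2
        type_of_channel = np.array([0] * half + [1] * (cfg.n_channels - half))
        log_fc = rng.normal(0.0, cfg.protein_log_fc_sd, size=n_prot)
        prot_profile = np.exp(np.outer(log_fc, type_of_channel - 0.5))

    for k, exp_id in enumerate(exp_ids):
        p = true_params[exp_id]
        pep_idx = np.flatnonzero(obs[:, k])
        n_k = len(pep_idx)
        m = mu[pep_idx]
        g = two_segment_transform(p, m)
        sigma = residual_sd(p, m)

        if cfg.pep_mode == "conditional":
            delta = rng.random(n_k) >= cfg.incorrect_rate  # True = correct
            lam = np.where(
                delta,
                rng.beta(*cfg.pep_correct_beta, size=n_k),
                rng.beta(*cfg.pep_incorrect_beta, size=n_k),
            )
        else:  # calibrated: lambda first, then delta | lambda
            from_incorrect = rng.random(n_k) < cfg.incorrect_rate
            lam = np.where(
                from_incorrect,
                rng.beta(*cfg.pep_incorrect_beta, size=n_k),
                rng.beta(*cfg.pep_correct_beta, size=n_k),
            )
            delta = rng.random(n_k) >= lam

        rho_correct = g + rng.laplace(0.0, sigma, size=n_k)
        center, spread = float(np.mean(g)), max(float(np.std(g)), 1.0)
        rho_wrong = rng.normal(center, spread, size=n_k)
        rho = np.where(delta, rho_correct, rho_wrong)
        rho = np.maximum(rho, 0.01)  # RT support is positive

        decoy = rng.random(n_k) < cfg.decoy_rate
        delta = delta & ~decoy
        # decoy hits carry no true RT signal: resample from the null
        rho = np.where(decoy, np.maximum(rng.normal(center, spread, size=n_k), 0.01), rho)
        lam = np.where(decoy, rng.beta(*cfg.pep_incorrect_beta, size=n_k), lam)

        true_params[exp_id].null_mean = center
        true_params[exp_id].null_sd = spread

        retlen = rng.uniform(0.1, 0.6, size=n_k)
        for j in range(n_k):
            seq = peptides[pep_idx[j]]
            if cfg.quant:
                prot = protein_of_peptide[seq]
                base = prot_profile[int(prot[1:])]
                inten = base * np.exp(
                    rng.normal(0.0, cfg.quant_noise_sd, size=cfg.n_channels)
                ) * 1e4
            row = {
                "Sequence": seq,
                "Modified sequence": f"_{seq}_",
                "Raw file": exp_id,
                "Retention time": round(float(rho[j]), 4),
                "Retention length": round(float(retlen[j]), 4),
                "PEP": float(lam[j]),
                "Charge": int(rng.integers(2, 4)),
                "Reverse": "+" if decoy[j] else "",
                "Potential contaminant": "",
                "Proteins": (
                    ("REV__" if decoy[j] else "")
                    + (protein_of_peptide.get(seq, f"P{pep_idx[j] // 5:04d}"))
                ),
            }
            if cfg.quant:
                for c in range(cfg.n_channels):
                    row[f"Reporter intensity corrected {c}"] = round(float(inten[c]), 2)
            rows.append(row)
            truth_rows.append(
                {
                    "psm_id": len(rows) - 1,
                    "experiment_id": exp_id,
                    "peptide_key": seq,
                    "delta": bool(delta[j]),
                    "true_mu": float(m[j]),
                    "true_sigma": float(sigma[j]),
                    "is_decoy": bool(decoy[j]),
                }
            )

    table = pd.DataFrame(rows)
    truth = SimTruth(
        psm=pd.DataFrame(truth_rows),
        reference_rts=reference_rts,
        experiment_params=true_params,
        protein_of_peptide=protein_of_peptide,
    )
    return table, truth


def write_simulation(
    table: pd.DataFrame, truth: SimTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write the evidence table and a truth sidecar TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    evidence = outdir / "evidence.txt"
    table.to_csv(evidence, sep="\t", index=False)
    truth_path = outdir / "truth_psms.txt"
    truth.psm.to_csv(truth_path, sep="\t", index=False)
    refs = outdir / "truth_reference_rts.txt"
    pd.Series(truth.reference_rts, name="true_mu").rename_axis("peptide_key").to_csv(
        refs, sep="\t"
    )
    return {"evidence": evidence, "truth_psms": truth_path, "truth_refs": refs}


@dataclass
class TruthMetrics:
    """Summary of an updated PSM set against simulation ground truth."""

    fdr_at_q: dict[float, float]
    n_at_q: dict[float, int]
    pep_calibration: pd.DataFrame
    mu_recovery_r: float
    param_errors: pd.DataFrame
    n_spectral_at_q01: int
    n_updated_at_q01: int


def evaluate_against_truth(
    updated: pd.DataFrame,
    truth: SimTruth,
    model=None,
    q_thresholds: tuple[float, ...] = (0.001, 0.01, 0.05),
    pep_bins: tuple[float, ...] = (0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0),
) -> TruthMetrics:
    """Empirical FDR, PEP calibration, and parameter recovery vs truth.

    ``updated`` must stem from the same simulated table (rows joined on
    ``psm_id``). ``model`` (optional fitted AlignmentModel) enables the
    reference-RT and transform-parameter recovery metrics.
    """
    merged = updated.merge(truth.psm, on="psm_id", suffixes=("", "_truth"))
    if len(merged) != len(updated):
        raise ValueError("psm_id mismatch between updated PSMs and truth")
    wrong = ~merged["delta"].to_numpy(dtype=bool)

    q = merged["updated_qvalue"].to_numpy(dtype=float)
    fdr_at_q, n_at_q = {}, {}
    for t in q_thresholds:
        hit = q <= t
        n_at_q[t] = int(hit.sum())
        fdr_at_q[t] = float(wrong[hit].mean()) if hit.any() else float("nan")

    pep = merged["updated_pep"].to_numpy(dtype=float)
    bins = np.asarray(pep_bins)
    which = np.digitize(pep, bins[1:-1])
    cal_rows = []
    for bidx in range(len(bins) - 1):
        mask = which == bidx
        if mask.sum() == 0:
            continue
        cal_rows.append(
            {
                "bin_lo": bins[bidx],
                "bin_hi": bins[bidx + 1],
                "n": int(mask.sum()),
                "mean_pep": float(pep[mask].mean()),
                "error_rate": float(wrong[mask].mean()),
                "n_wrong": int(wrong[mask].sum()),
            }
        )
    calibration = pd.DataFrame(cal_rows)

    mu_r = float("nan")
    param_errors = pd.DataFrame()
    if model is not None:
        common = [k for k in model.reference_rts if k in truth.reference_rts]
        est = np.array([model.reference_rts[k].mu for k in common])
        tru = np.array([truth.reference_rts[k] for k in common])
        if len(common) >= 2:
            mu_r = float(np.corrcoef(est, tru)[0, 1])
        err_rows = []
        for exp_id, p in model.experiment_params.items():
            tp = truth.experiment_params.get(exp_id)
            if tp is None:
                continue
            err_rows.append(
                {
                    "experiment_id": exp_id,
                    "beta1_rel_err": abs(p.beta1 - tp.beta1) / tp.beta1,
                    "beta2_rel_err": abs(p.beta2 - tp.beta2) / tp.beta2,
                    "split_abs_err": abs(p.split - tp.split),
                    "sigma_intercept_err": p.sigma_intercept - tp.sigma_intercept,
                    "sigma_slope_err": p.sigma_slope - tp.sigma_slope,
                }
            )
        param_errors = pd.DataFrame(err_rows)

    spectral_q = compute_qvalues(
        np.clip(merged["spectral_pep"].to_numpy(dtype=float), 0, 1)
    )
    n_spec = int((spectral_q <= 0.01).sum())
    n_upd = int((q <= 0.01).sum())
    return TruthMetrics(
        fdr_at_q=fdr_at_q,
        n_at_q=n_at_q,
        pep_calibration=calibration,
        mu_recovery_r=mu_r,
        param_errors=param_errors,
        n_spectral_at_q01=n_spec,
        n_updated_at_q01=n_upd,
    )
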