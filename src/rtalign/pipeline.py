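"""Pipeline orchestration: filter -> align -> bootstrap -> update -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import FitOptions, fit_map
from .config import RunConfig, config_to_dict
from .confidence import BootstrapSettings, UpdateSettings, apply_update
from .errors import ConfigurationError
from .io import filter_for_alignment, read_psm_table, write_output_table

log = logging.getLogger("rtalign")


def _config_hash(cfg: RunConfig) -> str:
    doc = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _setup_logging(outdir: Path, verbosity: str) -> None:
    level = getattr(logging, verbosity.upper(), logging.INFO)
    log.setLevel(level)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def residual_summary(updated: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Per-experiment residual-RT summary, overall and binned along the RT axis."""
    rows = []
    part = updated[updated["participation"] == "aligned-and-updated"]
    for exp_id, sub in part.groupby("experiment_id"):
        resid = sub["residual_rt"].to_numpy(dtype=float)
        rt = sub["observed_rt"].to_numpy(dtype=float)
        rows.append(
            {
                "experiment_id": exp_id,
                "rt_bin": "all",
                "n": len(sub),
                "median_abs_residual": float(np.median(np.abs(resid))),
                "mean_abs_residual": float(np.mean(np.abs(resid))),
            }
        )
        if len(sub) >= n_bins:
            edges = np.quantile(rt, np.linspace(0, 1, n_bins + 1))
            which = np.clip(np.searchsorted(edges, rt, side="right") - 1, 0, n_bins - 1)
            for b in range(n_bins):
                mask = which == b
                if not mask.any():
                    continue
                rows.append(
                    {
                        "experiment_id": exp_id,
                        "rt_bin": f"{edges[b]:.1f}-{edges[b + 1]:.1f}",
                        "n": int(mask.sum()),
                        "median_abs_residual": float(np.median(np.abs(resid[mask]))),
                        "mean_abs_residual": float(np.mean(np.abs(resid[mask]))),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write all artifacts into ``cfg.output_dir``.

    Returns the mapping of artifact names to paths. Fully reproducible given
    the configuration and seed.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, cfg.verbosity)
    log.info(
        "rtalign %s | seed=%d | config=%s", __version__, cfg.seed, _config_hash(cfg)
    )
    if not cfg.inputs:
        raise ConfigurationError("no input PSM tables configured")

    frames = []
    original_columns: list[str] | None = None
    for path in cfg.inputs:
        df = read_psm_table(path)
        log.info("read %s: %s", path, df.attrs["parse_report"])
        if original_columns is None:
            original_columns = df.attrs["original_columns"]
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    records["psm_id"] = np.arange(len(records))
    records.attrs["original_columns"] = original_columns

    eligible, passthrough, report = filter_for_alignment(records, cfg.filters)
    log.info("filter report: %s", report.as_dict())

    model = fit_map(
        eligible,
        opts=FitOptions(
            tolerance=cfg.model.tolerance,
            max_iterations=cfg.model.max_iterations,
            segmented=cfg.model.segmented,
        ),
    )
    log.info(
        "alignment: %d experiments, %d peptides, log posterior %.2f, converged=%s "
        "(%d iterations), dropped=%s",
        len(model.experiment_params),
        len(model.reference_rts),
        model.log_posterior,
        model.converged,
        model.iterations,
        model.dropped_experiments,
    )

    all_records = pd.concat([eligible, passthrough]).sort_values("psm_id")
    all_records.attrs["original_columns"] = original_columns
    settings = UpdateSettings(
        bootstrap=BootstrapSettings(
            n_replicates=cfg.bootstrap.n_replicates, seed=cfg.bootstrap_seed()
        ),
        qvalue_scope=cfg.qvalues.scope,
        compute_qvalues=cfg.qvalues.enabled,
    )
    updated = apply_update(all_records, model, settings)
    updated.attrs["original_columns"] = original_columns

    artifacts: dict[str, Path] = {}
    artifacts["psms"] = outdir / "psms_updated.txt"
    write_output_table(updated, artifacts["psms"])
    artifacts["model"] = outdir / "alignment_model.json"
    model.to_json(artifacts["model"])
    artifacts["filter_report"] = outdir / "filter_report.json"
    artifacts["filter_report"].write_text(json.dumps(report.as_dict(), indent=1))
    artifacts["residuals"] = outdir / "residual_summary.txt"
    residual_summary(updated).to_csv(artifacts["residuals"], sep="\t", index=False)

    n_updated = int((updated["participation"] == "aligned-and-updated").sum())
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_psms": len(updated),
        "n_updated": n_updated,
        "n_passthrough": len(updated) - n_updated,
        "log_posterior": model.log_posterior,
        "converged": model.converged,
    }
    artifacts["summary"] = outdir / "summary.json"
    artifacts["summary"].write_text(json.dumps(summary, indent=1))
    artifacts["log"] = outdir / "run.log"
    log.info("summary: %s", summary)
    return artifacts
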