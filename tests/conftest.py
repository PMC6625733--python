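"""Shared fixtures: the reference synthetic study and small helpers.

The expensive session fixtures (one full simulate -> filter -> MAP fit at
the standard study conditions) are shared across alignment, confidence and
acceptance tests to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from rtalign import (
    FilterConfig,
    SimConfig,
    filter_for_alignment,
    fit_map,
    read_psm_table,
    simulate_dataset,
)

hyp_settings.register_profile("suite", derandomize=True, max_examples=50)
hyp_settings.load_profile("suite")

#: standard study conditions: 10 runs x 300 peptides on a 60-min gradient,
#: residual scale 0.1 + 0.005*mu minutes, 5% incorrect matches
STUDY_SEED = 42


def make_study_config(**overrides) -> SimConfig:
    kw = dict(
        n_experiments=10,
        n_peptides=300,
        sigma_intercept_range=(0.1, 0.1),
        sigma_slope_range=(0.005, 0.005),
        incorrect_rate=0.05,
        seed=STUDY_SEED,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def roundtrip_evidence(table: pd.DataFrame, tmp_path) -> pd.DataFrame:
    """Write a simulated table to disk and read it back through psm I/O."""
    path = tmp_path / "evidence.txt"
    table.to_csv(path, sep="\t", index=False)
    return read_psm_table(path)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Simulated study + filtered sets + fitted model (shared, read-only)."""
    cfg = make_study_config()
    table, truth = simulate_dataset(cfg)
    tmp = tmp_path_factory.mktemp("study")
    df = roundtrip_evidence(table, tmp)
    eligible, passthrough, report = filter_for_alignment(df, FilterConfig())
    model = fit_map(eligible)
    return {
        "config": cfg,
        "table": table,
        "truth": truth,
        "records": df,
        "eligible": eligible,
        "passthrough": passthrough,
        "report": report,
        "model": model,
    }


@pytest.fixture()
def toy_evidence(tmp_path):
    """Small handwritten evidence table exercising every filter rule."""
    rows = [
        # sequence, raw file, rt, retlen, pep, reverse, contaminant
        ("AAAAK", "e1", 10.0, 0.5, 0.01, "", ""),
        ("AAAAK", "e2", 10.5, 0.5, 0.02, "", ""),
        ("AAAAK", "e3", 10.2, 0.5, 0.03, "", ""),  # shared in 3 exps: eligible
        ("CCCCK", "e1", 20.0, 0.5, 0.01, "+", ""),  # decoy
        ("DDDDK", "e1", 21.0, 0.5, 0.01, "", "+"),  # contaminant
        ("EEEEK", "e1", 22.0, 0.5, 0.60, "", ""),  # PEP above threshold
        ("FFFFK", "e1", 23.0, 1.5, 0.01, "", ""),  # retention length 1.5 min
        ("GGGGK", "e1", 24.0, 0.5, 0.01, "", ""),  # seen in only 2 experiments
        ("GGGGK", "e2", 24.3, 0.5, 0.02, "", ""),
        ("AAAAK", "e1", 60.0, 0.5, 0.04, "", ""),  # fixes the gradient at 60 min
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "Sequence",
            "Raw file",
            "Retention time",
            "Retention length",
            "PEP",
            "Reverse",
            "Potential contaminant",
        ],
    )
    df.insert(1, "Modified sequence", "_" + df["Sequence"] + "_")
    df["Proteins"] = "P1"
    path = tmp_path / "toy.txt"
    df.to_csv(path, sep="\t", index=False)
    return path
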