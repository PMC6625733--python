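"""Reading, writing and filtering of PSM tables.

The on-disk dialect is the MaxQuant ``evidence.txt`` format: a tab-separated
table with one row per peptide-spectrum match (PSM). Reading canonicalizes a
small set of required columns into lower-snake-case names while preserving
every original column untouched, so that the augmented output table can carry
the input through verbatim.

Canonical columns added by :func:`read_psm_table`:

``psm_id``            stable integer row identifier (input row order)
``experiment_id``     raw-file / run label
``sequence``          bare peptide sequence
``peptide_key``       canonical peptide identity (sequence + modifications,
                      charge excluded)
``observed_rt``       retention time in minutes
``retention_length``  elution-peak width in minutes
``spectral_pep``      search-engine posterior error probability, clamped to [0, 1]
``is_decoy``          reverse-database hit
``is_contaminant``    contaminant-database hit
``proteins``          raw protein-accession string (``;``-separated)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    InvalidRecordError,
    NoAlignableDataError,
)

# Canonical name -> candidate source headers (matched case-insensitively).
# Table-driven so MaxQuant version drift only needs a mapping change.
MAXQUANT_COLUMNS: dict[str, tuple[str, ...]] = {
    "sequence": ("Sequence",),
    "modified_sequence": ("Modified sequence",),
    "experiment_id": ("Raw file",),
    "observed_rt": ("Retention time",),
    "retention_length": ("Retention length",),
    "spectral_pep": ("PEP",),
    "is_decoy": ("Reverse",),
    "is_contaminant": ("Potential contaminant", "Contaminant"),
    "proteins": ("Proteins", "Leading razor protein"),
}

REQUIRED_CANONICAL = (
    "sequence",
    "experiment_id",
    "observed_rt",
    "retention_length",
    "spectral_pep",
)

#: Columns appended by the confidence-update stage, in output order.
OUTPUT_COLUMNS = (
    "updated_pep",
    "updated_qvalue",
    "reference_rt",
    "aligned_rt",
    "residual_rt",
    "participation",
)

_CANONICAL_INTERNAL = (
    "psm_id",
    "sequence",
    "modified_sequence",
    "experiment_id",
    "observed_rt",
    "retention_length",
    "spectral_pep",
    "is_decoy",
    "is_contaminant",
    "proteins",
    "peptide_key",
    "alignment_eligible",
    "filter_reason",
)


def canonical_peptide_key(sequence: str, modifications: str | None = None) -> str:
    """Canonical peptide identity: modified sequence, charge state excluded.

    Two PSMs share a key iff their sequence + modification strings match.
    ``modifications`` is normally the MaxQuant "Modified sequence" string
    (underscores stripped); a bare modification label (no uppercase residues)
    is appended to the sequence instead.
    """
    sequence = (sequence or "").strip().strip("_")
    if not sequence:
        raise InvalidRecordError("empty peptide sequence")
    mods = (modifications or "").strip().strip("_")
    if not mods or mods.lower() == "unmodified" or mods == sequence:
        return sequence
    if re.search(r"[A-Z]", mods):
        # a decorated sequence form, e.g. "PEPT(Oxidation (M))IDEK"
        return mods
    return f"{sequence}[{mods}]"


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lower = {c.lower(): c for c in header}
    resolved: dict[str, str] = {}
    for canonical, candidates in column_map.items():
        for cand in candidates:
            if cand.lower() in lower:
                resolved[canonical] = lower[cand.lower()]
                break
    return resolved


def read_psm_table(
    path: str | Path,
    dialect: str = "maxquant",
    column_map: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Read a PSM table, returning original columns plus canonical ones.

    Rows whose required numeric fields do not parse are kept (they become
    pass-through rows downstream) and tallied in ``df.attrs["parse_report"]``.
    Spectral PEPs outside [0, 1] (MaxQuant emits values > 1) are clamped.

    Raises
    ------
    ConfigurationError
        If a required column is absent (the missing column is named).
    EmptyInputError
        If the file holds no data rows.
    """
    if dialect != "maxquant":
        raise ConfigurationError(f"unknown PSM table dialect: {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise EmptyInputError(f"PSM table {path} contains no rows")

    cmap = dict(MAXQUANT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    resolved = _resolve_columns(df.columns, cmap)
    for canonical in REQUIRED_CANONICAL:
        if canonical not in resolved:
            expected = cmap[canonical][0]
            raise ConfigurationError(
                f"required column {expected!r} (-> {canonical}) missing from {path}"
            )

    original_columns = list(df.columns)
    out = df.copy()
    out["psm_id"] = np.arange(len(out))
    out["sequence"] = df[resolved["sequence"]].str.strip().str.strip("_")
    if "modified_sequence" in resolved:
        out["modified_sequence"] = df[resolved["modified_sequence"]]
    else:
        out["modified_sequence"] = out["sequence"]

    n_unparseable = 0
    for canonical in ("observed_rt", "retention_length", "spectral_pep"):
        vals = pd.to_numeric(df[resolved[canonical]], errors="coerce")
        out[canonical] = vals
    bad = out[["observed_rt", "retention_length", "spectral_pep"]].isna().any(axis=1)
    bad |= out["sequence"] == ""
    n_unparseable = int(bad.sum())

    n_clamped = int(((out["spectral_pep"] > 1) | (out["spectral_pep"] < 0)).sum())
    out["spectral_pep"] = out["spectral_pep"].clip(0.0, 1.0)
    out["experiment_id"] = df[resolved["experiment_id"]].astype(str)

    for canonical, default in (("is_decoy", False), ("is_contaminant", False)):
        if canonical in resolved:
            out[canonical] = df[resolved[canonical]].str.strip() == "+"
        else:
            out[canonical] = default
    out["proteins"] = df[resolved["proteins"]] if "proteins" in resolved else ""

    keys = []
    for seq, mod in zip(out["sequence"], out["modified_sequence"]):
        keys.append(canonical_peptide_key(seq, mod) if seq else "")
    out["peptide_key"] = keys
    out["_unparseable"] = bad.to_numpy()

    out.attrs["original_columns"] = original_columns
    out.attrs["parse_report"] = {
        "n_rows": len(out),
        "n_unparseable": n_unparseable,
        "n_pep_clamped": n_clamped,
        "path": str(path),
    }
    return out


@dataclass
class FilterConfig:
    """Alignment-eligibility filter settings.

    The retention-length ceiling is either an absolute number of minutes or a
    fraction of the gradient length (default 1/60, i.e. 1 min on a 60-min
    run). ``gradient_length`` defaults to the maximum observed RT.
    """

    pep_threshold: float = 0.5
    retention_length_minutes: float | None = None
    retention_length_fraction: float = 1.0 / 60.0
    gradient_length: float | None = None
    min_experiments: int = 3
    exclude_experiments: tuple[str, ...] = ()
    include_decoys: bool = False


_FILTER_RULES = (
    "unparseable",
    "excluded_experiment",
    "decoy",
    "contaminant",
    "pep_threshold",
    "retention_length",
    "min_experiments",
)


@dataclass
class FilterReport:
    """Per-rule removal tallies; removed + eligible == input rows."""

    n_input: int
    n_eligible: int
    n_passthrough: int
    counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "n_passthrough": self.n_passthrough,
            "counts": dict(self.counts),
        }


def filter_for_alignment(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Split PSMs into alignment-eligible and pass-through sets.

    Removal rules, applied in order (each PSM is tallied under the first rule
    that removes it): unparseable fields, excluded experiment, decoy,
    contaminant, spectral PEP >= threshold, retention length above the rule,
    and finally peptides seen in fewer than ``min_experiments`` distinct
    experiments (counted after the per-PSM rules, so low-confidence hits do
    not contribute to the experiment tally).

    Pass-through PSMs still receive output rows; they keep their spectral PEP
    unless their peptide later gains a reference RT.
    """
    cfg = cfg or FilterConfig()
    if records.empty:
        raise EmptyInputError("no PSM records to filter")
    df = records.copy()

    gradient = cfg.gradient_length
    if gradient is None:
        gradient = float(np.nanmax(df["observed_rt"].to_numpy(dtype=float)))
    if cfg.retention_length_minutes is not None:
        max_retlen = float(cfg.retention_length_minutes)
    else:
        max_retlen = cfg.retention_length_fraction * gradient

    reason = pd.Series("", index=df.index, dtype=object)
    unparseable = df.get("_unparseable")
    if unparseable is None:
        unparseable = df[["observed_rt", "retention_length", "spectral_pep"]].isna().any(
            axis=1
        )
    masks = [
        ("unparseable", unparseable.astype(bool)),
        ("excluded_experiment", df["experiment_id"].isin(cfg.exclude_experiments)),
        (
            "decoy",
            df["is_decoy"].astype(bool)
            if not cfg.include_decoys
            else pd.Series(False, index=df.index),
        ),
        ("contaminant", df["is_contaminant"].astype(bool)),
        ("pep_threshold", df["spectral_pep"] >= cfg.pep_threshold),
        ("retention_length", df["retention_length"] > max_retlen),
    ]
    for rule, mask in masks:
        hit = mask.to_numpy(dtype=bool) & (reason == "").to_numpy()
        reason[hit] = rule

    # min-experiments rule on the survivors of the per-PSM filters
    surviving = reason == ""
    n_exp = (
        df.loc[surviving]
        .groupby("peptide_key")["experiment_id"]
        .nunique()
        .reindex(df["peptide_key"])
        .to_numpy()
    )
    too_few = surviving.to_numpy() & (n_exp < cfg.min_experiments)
    reason[too_few] = "min_experiments"

    eligible_mask = (reason == "").to_numpy()
    counts = {rule: int((reason == rule).sum()) for rule in _FILTER_RULES}
    report = FilterReport(
        n_input=len(df),
        n_eligible=int(eligible_mask.sum()),
        n_passthrough=int((~eligible_mask).sum()),
        counts=counts,
    )
    if report.n_eligible == 0:
        raise NoAlignableDataError(
            "no alignable data: every PSM was removed by the eligibility filters"
        )
    eligible = df.loc[eligible_mask].copy()
    eligible["alignment_eligible"] = True
    passthrough = df.loc[~eligible_mask].copy()
    passthrough["alignment_eligible"] = False
    passthrough["filter_reason"] = reason[~eligible_mask]
    return eligible, passthrough, report


def write_output_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a PSM table back to disk in the evidence dialect.

    Original columns are preserved byte-for-byte in their original order;
    confidence-update columns present in ``records`` are appended. Row order
    follows the frame (restore with ``sort_values("psm_id")`` if needed).
    """
    path = Path(path)
    original = records.attrs.get("original_columns")
    if original is None:
        original = [c for c in records.columns if c not in _CANONICAL_INTERNAL]
        original = [c for c in original if c not in OUTPUT_COLUMNS and c != "_unparseable"]
    cols = [c for c in original if c in records.columns]
    cols += [c for c in OUTPUT_COLUMNS if c in records.columns]
    records.loc[:, cols].to_csv(path, sep="\t", index=False)
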