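"""Isobaric reporter-ion normalization and the protein-CV consistency benchmark.

Tandem-mass-tag (TMT) reporter-ion intensities form a matrix of PSMs by
channels. Normalization removes channel-loading differences (divide each
column by its median) and then expresses each PSM relative to its own level
(divide each row by its median), leaving relative enrichment between the
samples in the channels. Peptide and protein intensities are channel-wise
medians of their constituent PSMs and peptides respectively.

The internal-consistency benchmark asks whether PSMs upgraded by the RT
confidence update quantify proteins as reproducibly as PSMs that were
confident from spectra alone. For each protein we compute the coefficient of
variation (sample SD / mean) of normalized intensities across its PSMs,
separately in disjoint PSM subsets:

``spectra``   spectral PEP < threshold
``upgraded``  spectral PEP > threshold and updated PEP < threshold
``decoy``     the spectra+upgraded pool with protein assignments randomly
              permuted (negative control)

A real protein-level signal makes the decoy CV distribution stochastically
dominate the true-assignment distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError


def normalize_ri_matrix(
    matrix: pd.DataFrame,
    empty_channels: tuple[str, ...] = (),
    max_rounds: int = 50,
    tol: float = 1e-13,
) -> pd.DataFrame:
    """Median-normalize a PSM x channel intensity matrix.

    Empty channels are dropped first; rows with any missing value are then
    removed; each column is divided by its median (channel loading) and each
    row of the result by its median (relative enrichment). The column/row
    pair is repeated until both sets of medians are 1, which makes the
    operation idempotent; a single pass leaves the column medians slightly
    off after the row step.
    """
    m = matrix.drop(columns=[c for c in empty_channels if c in matrix.columns])
    m = m.dropna(axis=0, how="any").astype(float)
    if m.empty:
        raise ConfigurationError("no complete reporter-intensity rows to normalize")
    col_med = m.median(axis=0)
    zero = col_med[col_med == 0]
    if not zero.empty:
        raise ConfigurationError(
            f"channel(s) with zero median intensity: {list(zero.index)}"
        )
    for _ in range(max_rounds):
        col_med = m.median(axis=0)
        m = m / col_med
        row_med = m.median(axis=1)
        m = m.div(row_med.replace(0.0, np.nan), axis=0)
        if (np.abs(col_med - 1.0) < tol).all() and (np.abs(row_med - 1.0) < tol).all():
            break
    return m


def collapse_to_protein(
    normalized: pd.DataFrame, peptide_of_psm: pd.Series, protein_of_peptide: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Two-level channel-wise median collapse: PSM -> peptide -> protein.

    ``peptide_of_psm`` maps the matrix's row index to peptide keys;
    ``protein_of_peptide`` maps peptide keys to protein ids. Returns the
    protein x channel table and the count of orphan PSMs (no protein), which
    are excluded.
    """
    peptides = peptide_of_psm.reindex(normalized.index)
    pep_table = normalized.groupby(peptides).median()
    proteins = protein_of_peptide.reindex(pep_table.index)
    orphan_peps = proteins.isna()
    n_orphans = int(
        peptides.isin(pep_table.index[orphan_peps]).sum() + peptides.isna().sum()
    )
    prot_table = pep_table[~orphan_peps.to_numpy()].groupby(
        proteins[~orphan_peps.to_numpy()]
    ).median()
    return prot_table, n_orphans


def protein_cv(values: np.ndarray) -> float:
    """Coefficient of variation across PSMs, averaged over channels.

    ``values`` is an (n_psms, n_channels) array; per channel CV = sample SD
    over mean; channels with zero mean give NaN and are skipped in the mean.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return float(np.nanmean(cv))


@dataclass
class QuantBenchmarkConfig:
    pep_threshold: float = 0.01
    min_psms: int = 3
    empty_channels: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class ProteinCVReport:
    """Per-protein CVs for each PSM subset plus subset bookkeeping."""

    cv: pd.DataFrame  # proteins x subsets
    subset_sizes: dict[str, int]
    psm_counts: pd.DataFrame  # proteins x subsets
    config: QuantBenchmarkConfig = field(default_factory=QuantBenchmarkConfig)


def protein_cv_benchmark(
    updated: pd.DataFrame,
    channel_columns: list[str],
    protein_column: str = "proteins",
    cfg: QuantBenchmarkConfig | None = None,
) -> ProteinCVReport:
    """Protein-CV internal-consistency benchmark on updated PSMs.

    Partitions PSMs into the disjoint ``spectra`` and ``upgraded`` subsets
    (strict thresholds on spectral and updated PEP), builds the
    randomized-assignment ``decoy`` control with a fixed seed, normalizes the
    pooled reporter matrix once, and reports per-protein CVs over proteins
    with at least ``min_psms`` PSMs in both real subsets.
    """
    cfg = cfg or QuantBenchmarkConfig()
    t = cfg.pep_threshold
    spep = updated["spectral_pep"].astype(float)
    upep = updated["updated_pep"].astype(float)
    sets = {
        "spectra": spep < t,
        "upgraded": (spep > t) & (upep < t),
    }
    pool_mask = sets["spectra"] | sets["upgraded"]
    pool = updated.loc[pool_mask]
    if pool.empty:
        raise ConfigurationError("no PSMs pass either PEP threshold")

    matrix = pool[channel_columns].apply(pd.to_numeric, errors="coerce")
    norm = normalize_ri_matrix(matrix, cfg.empty_channels)
    kept = norm.index
    proteins = pool.loc[kept, protein_column].astype(str)
    # a PSM's protein = the first accession in the (;-separated) list
    proteins = proteins.str.split(";").str[0]

    rng = np.random.default_rng(cfg.seed)
    decoy_proteins = pd.Series(
        rng.permutation(proteins.to_numpy()), index=proteins.index
    )

    membership = {
        name: mask.reindex(kept).fillna(False).to_numpy(dtype=bool)
        for name, mask in sets.items()
    }

    def _cvs(assignments: pd.Series, mask: np.ndarray) -> pd.Series:
        vals = norm.loc[mask]
        groups = assignments[mask]
        out = {}
        for prot, sub in vals.groupby(groups):
            if len(sub) >= cfg.min_psms:
                out[prot] = protein_cv(sub.to_numpy())
        return pd.Series(out, dtype=float)

    cv_spectra = _cvs(proteins, membership["spectra"])
    cv_upgraded = _cvs(proteins, membership["upgraded"])
    cv_decoy = _cvs(decoy_proteins, np.ones(len(kept), dtype=bool))

    shared = cv_spectra.index.intersection(cv_upgraded.index)
    if shared.empty:
        import warnings

        warnings.warn("no proteins shared between the spectra and upgraded subsets")
    cv = pd.DataFrame(
        {
            "spectra": cv_spectra,
            "upgraded": cv_upgraded,
            "decoy": cv_decoy,
        }
    )
    counts = pd.DataFrame(
        {
            "spectra": proteins[membership["spectra"]].value_counts(),
            "upgraded": proteins[membership["upgraded"]].value_counts(),
            "decoy": decoy_proteins.value_counts(),
        }
    ).fillna(0).astype(int)
    return ProteinCVReport(
        cv=cv,
        subset_sizes={k: int(v.sum()) for k, v in membership.items()},
        psm_counts=counts,
        config=cfg,
    )
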