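"""Bootstrap of reference RTs, Bayesian PEP update, q-value recomputation."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, strategies as hst

from rtalign import (
    AlignmentModel,
    BootstrapSettings,
    ExperimentParams,
    Hyperpriors,
    ReferenceRT,
    UpdateSettings,
    apply_update,
    bootstrap_reference_rts,
    compute_qvalues,
    update_pep,
)


def _identity_model(peptides, n_exp=5, sigma=0.2, null=(30.0, 12.0)):
    params = {
        f"e{k}": ExperimentParams(0.0, 1.0, 1.0, 30.0, sigma, 0.0, null[0], null[1])
        for k in range(n_exp)
    }
    refs = {k: ReferenceRT(k, mu, n_exp) for k, mu in peptides.items()}
    return AlignmentModel(
        experiment_params=params,
        reference_rts=refs,
        hyperpriors=Hyperpriors(rt_mean=30.0, rt_sd=15.0, rt_max=60.0),
    )


def _observations(peptides, n_exp=5, lam=0.0):
    rows = []
    for key, mu in peptides.items():
        for k in range(n_exp):
            rows.append(
                {
                    "peptide_key": key,
                    "experiment_id": f"e{k}",
                    "observed_rt": mu,
                    "spectral_pep": lam,
                }
            )
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_degenerate_noise_reproduces_the_median(self):
        peptides = {"AAK": 12.0, "CCK": 41.0}
        model = _identity_model(peptides, sigma=1e-6)
        data = _observations(peptides)
        reps = bootstrap_reference_rts(model, data, BootstrapSettings(20, seed=0))
        for key, mu in peptides.items():
            assert np.allclose(reps[key], mu, atol=1e-4)

    def test_single_replicate_cardinality(self):
        peptides = {"AAK": 12.0}
        model = _identity_model(peptides)
        reps = bootstrap_reference_rts(
            model, _observations(peptides), BootstrapSettings(1, seed=0)
        )
        assert reps["AAK"].shape == (1,)

    def test_monte_carlo_mean_matches_truth(self):
        """Identity transforms, lambda=0: replicate mean sits at the true
        location within 3 standard errors (Monte-Carlo oracle)."""
        peptides = {"AAK": 25.0}
        sigma = 0.2
        model = _identity_model(peptides, n_exp=5, sigma=sigma)
        reps = bootstrap_reference_rts(
            model, _observations(peptides), BootstrapSettings(1000, seed=7)
        )["AAK"]
        se = reps.std(ddof=1) / math.sqrt(len(reps))
        assert abs(reps.mean() - 25.0) < 3 * se + 1e-3

    def test_identical_seed_is_bit_identical(self):
        peptides = {"AAK": 12.0, "CCK": 41.0}
        data = _observations(peptides, lam=0.2)
        r1 = bootstrap_reference_rts(
            _identity_model(peptides), data, BootstrapSettings(50, seed=3)
        )
        r2 = bootstrap_reference_rts(
            _identity_model(peptides), data, BootstrapSettings(50, seed=3)
        )
        for key in peptides:
            assert np.array_equal(r1[key], r2[key])

    def test_unknown_peptide_raises(self):
        peptides = {"AAK": 12.0}
        model = _identity_model(peptides)
        data = _observations({"ZZZK": 5.0})
        with pytest.raises(KeyError):
            bootstrap_reference_rts(model, data, BootstrapSettings(5, seed=0))


def _psm(rho, lam, exp="e0", key="AAK"):
    return pd.Series(
        {
            "psm_id": 0,
            "observed_rt": rho,
            "spectral_pep": lam,
            "experiment_id": exp,
            "peptide_key": key,
        }
    )


class TestUpdatePep:
    def test_worked_single_replicate_example(self):
        """Laplace density 2.0, null density 0.1, lambda 0.3:
        P(correct) = 1.4/1.43, so the updated PEP is 0.03/1.43."""
        mu = 25.0
        model = _identity_model({"AAK": mu}, sigma=0.25)  # Laplace at center: 1/(2*0.25) = 2
        null_sd = 1.0 / (0.1 * math.sqrt(2 * math.pi))  # Normal at center: 0.1
        for p in model.experiment_params.values():
            p.null_mean, p.null_sd = mu, null_sd
        out = update_pep(_psm(mu, 0.3), model, np.array([mu]))
        assert out["updated_pep"] == pytest.approx(1.0 - 1.4 / 1.43, rel=1e-12)
        assert out["updated_pep"] == pytest.approx(0.020979, abs=1e-6)

    def test_confident_stays_confident(self):
        model = _identity_model({"AAK": 25.0})
        out = update_pep(_psm(25.0, 0.0), model, np.array([25.0]))
        assert out["updated_pep"] == pytest.approx(1e-16)

    def test_equal_densities_leave_pep_unchanged(self):
        """When the aligned density equals the null density at the observed
        RT, the RT carries no evidence and the PEP must not move."""
        mu, sigma, lam = 25.0, 0.5, 0.37
        model = _identity_model({"AAK": mu}, sigma=sigma)
        laplace_at_center = 1.0 / (2.0 * sigma)
        null_sd = 1.0 / (laplace_at_center * math.sqrt(2 * math.pi))
        for p in model.experiment_params.values():
            p.null_mean, p.null_sd = mu, null_sd
        out = update_pep(_psm(mu, lam), model, np.array([mu]))
        assert out["updated_pep"] == pytest.approx(lam, rel=1e-12)

    def test_monotone_in_absolute_residual(self):
        model = _identity_model({"AAK": 25.0}, sigma=0.3)
        peps = [
            update_pep(_psm(25.0 + r, 0.2), model, np.array([25.0]))["updated_pep"]
            for r in (0.0, 0.5, 1.0, 2.0, 5.0)
        ]
        assert all(a <= b for a, b in zip(peps, peps[1:]))

    def test_empty_replicates_rejected(self):
        model = _identity_model({"AAK": 25.0})
        with pytest.raises(ValueError):
            update_pep(_psm(25.0, 0.2), model, np.array([]))


class TestQvalues:
    def test_worked_prefix_means(self):
        q = compute_qvalues([0.001, 0.01, 0.1])
        assert np.allclose(q, [0.001, 0.011 / 2, 0.111 / 3])

    def test_zeros_and_singleton(self):
        assert np.all(compute_qvalues([0.0, 0.0, 0.0]) == 0.0)
        assert compute_qvalues([0.25]).tolist() == [0.25]
        assert compute_qvalues([]).size == 0

    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, peps):
        got = compute_qvalues(peps)
        # brute force: for every PSM, the mean PEP over all PSMs with a
        # PEP <= its own (ties share the last tied rank)
        arr = np.asarray(peps)
        want = np.array([np.mean(np.sort(arr)[: int((arr <= p).sum())]) for p in arr])
        assert np.allclose(got, want)

    @given(hst.permutations(list(range(8))))
    def test_order_invariance(self, perm):
        base = np.array([0.001, 0.003, 0.003, 0.02, 0.1, 0.4, 0.4, 0.9])
        q_base = compute_qvalues(base)
        q_perm = compute_qvalues(base[perm])
        assert np.allclose(q_perm, q_base[perm])

    def test_ties_share_the_last_tied_rank(self):
        q = compute_qvalues([0.1, 0.1, 0.4])
        assert q[0] == q[1] == pytest.approx(0.1)

    def test_sorted_qvalues_are_non_decreasing(self):
        # recomputing q on the q vector preserves the ranking (idempotent
        # at rank granularity)
        peps = np.linspace(0, 0.9, 20) ** 2
        q1 = compute_qvalues(peps)
        q2 = compute_qvalues(q1)
        assert np.all(np.argsort(q1, kind="stable") == np.argsort(q2, kind="stable"))
        s = np.sort(q1)
        assert np.all(np.diff(s) >= -1e-15)


class TestApplyUpdate:
    def test_all_passthrough_is_identity(self):
        model = _identity_model({"AAK": 25.0})
        df = _observations({"ZZZK": 5.0}, n_exp=2, lam=0.3)
        df["psm_id"] = range(len(df))
        df["is_decoy"] = False
        out = apply_update(df, model)
        assert np.allclose(out["updated_pep"], out["spectral_pep"])
        assert (out["participation"] == "pass-through").all()

    def test_passthrough_peptide_with_reference_is_updated(self):
        model = _identity_model({"AAK": 25.0})
        df = _observations({"AAK": 25.0}, n_exp=2, lam=0.1)
        df["psm_id"] = range(len(df))
        df["is_decoy"] = False
        # mark one row as filtered out of the alignment: it still gets an
        # update because its peptide has a reference RT
        df["alignment_eligible"] = [True, False]
        out = apply_update(df, model)
        assert (out["participation"] == "aligned-and-updated").all()
        assert out["updated_pep"].iloc[1] < 0.1

    def test_decoys_outside_target_qvalue_scope(self):
        model = _identity_model({"AAK": 25.0})
        df = _observations({"AAK": 25.0}, n_exp=4, lam=0.2)
        df["psm_id"] = range(len(df))
        df["is_decoy"] = [False, False, True, False]
        out_t = apply_update(df, model, UpdateSettings(qvalue_scope="targets"))
        assert out_t.loc[df["is_decoy"], "updated_qvalue"].isna().all()
        assert out_t.loc[~df["is_decoy"], "updated_qvalue"].notna().all()
        out_all = apply_update(df, model, UpdateSettings(qvalue_scope="all"))
        assert out_all["updated_qvalue"].notna().all()

    def test_qvalues_non_decreasing_in_pep(self, study):
        from rtalign.confidence import BootstrapSettings as BS

        updated = apply_update(
            pd.concat([study["eligible"], study["passthrough"]]).sort_values("psm_id"),
            study["model"],
            UpdateSettings(bootstrap=BS(25, seed=0)),
        )
        sub = updated.dropna(subset=["updated_qvalue"]).sort_values("updated_pep")
        assert np.all(np.diff(sub["updated_qvalue"].to_numpy()) >= -1e-12)
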