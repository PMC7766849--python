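"""Likelihood evaluation, SAEM fitting, model comparison, bootstrap, covariates."""

import numpy as np
import pandas as pd
import pytest

from buppk import (
    OmegaSpec,
    SAEMSettings,
    SigmaSpec,
    StudyDesign,
    ThetaSet,
    bootstrap,
    compare_models,
    covariate_screen,
    generate_study,
    ofv,
    saem_fit,
)
from buppk.estimation import _prepare_subjects
from buppk.model_core import DoseEvent, simulate_profile
from buppk.population import sample_individuals
from buppk.synthetic_data import Dataset


SMALL_DESIGN = StudyDesign(
    n_subjects=8, dose_allocation={8.0: 8}, times=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
)
FAST = SAEMSettings(n_burnin=40, n_smooth=30, n_chains=1, mcmc_sweeps=1,
                    compute_ofv=False)


@pytest.fixture(scope="module")
def small_study(theta):
    return generate_study(SMALL_DESIGN, theta, seed=42)


def dataset_from_individuals(ind_thetas, covariates, dose_mg, times, sigma, seed):
    """Build a single-dose study dataset from explicit per-subject parameters."""
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    obs_rows, dose_rows = [], []
    for i, th in enumerate(ind_thetas, start=1):
        dose_rows.append({"ID": i, "TIME": 0.0, "AMT": dose_mg})
        prof = simulate_profile(th, [DoseEvent(0.0, dose_mg)], times[times > 0])
        eps = rng.normal(0.0, 1.0, prof.values.shape) * sigma.as_array()
        dv = prof.values * np.exp(eps)
        for j in range(4):
            for t, v in zip(times[times > 0], dv[:, j]):
                obs_rows.append({"ID": i, "TIME": t, "DVID": j + 1, "DV": v,
                                 "BLQ": int(v < 0.05), "MDV": 0})
    subjects = pd.DataFrame(
        {"ID": np.arange(1, len(ind_thetas) + 1), "DOSE": dose_mg} | covariates
    )
    return Dataset(subjects=subjects, doses=pd.DataFrame(dose_rows),
                   observations=pd.DataFrame(obs_rows))


class TestOFV:
    def test_zero_omega_matches_closed_form_gaussian(self, theta, small_study):
        sigma = SigmaSpec()
        res = ofv(small_study, theta, OmegaSpec.none(), sigma, seed=1)
        # independent closed form: sum over records of the log-normal density
        subs = _prepare_subjects(small_study)
        total = 0.0
        for s in subs:
            from buppk.estimation import _predict_log

            r = s.log_dv - _predict_log(s, theta)
            s2 = sigma.as_array()[s.obs_analyte] ** 2
            total += np.sum(np.log(2 * np.pi * s2) + r**2 / s2)
        assert res.value == pytest.approx(total, rel=1e-12)
        assert res.mc_se == 0.0

    def test_invariant_to_subject_order(self, theta, small_study):
        shuffled = Dataset(
            subjects=small_study.subjects.iloc[::-1].reset_index(drop=True),
            doses=small_study.doses.iloc[::-1].reset_index(drop=True),
            observations=small_study.observations.iloc[::-1].reset_index(drop=True),
        )
        a = ofv(small_study, theta, OmegaSpec.none(), SigmaSpec(), seed=1)
        b = ofv(shuffled, theta, OmegaSpec.none(), SigmaSpec(), seed=1)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_monte_carlo_se_shrinks_with_sample_size(self, theta, small_study):
        ses = [
            ofv(small_study, theta, OmegaSpec(), SigmaSpec(),
                n_samples=ns, seed=3).mc_se
            for ns in (200, 3200)
        ]
        assert ses[1] < ses[0]
        # ~1/sqrt(n): a 16-fold sample increase should shrink the SE ~4-fold
        assert 1.5 < ses[0] / ses[1] < 12.0

    def test_seeded_ofv_is_reproducible(self, theta, small_study):
        a = ofv(small_study, theta, OmegaSpec(), SigmaSpec(), n_samples=200, seed=9)
        b = ofv(small_study, theta, OmegaSpec(), SigmaSpec(), n_samples=200, seed=9)
        assert a.value == pytest.approx(b.value, rel=1e-9)


class TestCompareModels:
    def test_boundary_is_significant(self):
        assert compare_models(100.0, 103.84, df=1).significant

    def test_just_below_boundary_is_not(self):
        assert not compare_models(100.0, 103.83, df=1).significant

    def test_df1_threshold_is_chi_square_quantile(self):
        # the 0.95 chi-square quantile for one degree of freedom, quoted to
        # the customary two decimals
        assert compare_models(0.0, 10.0, df=1).threshold == 3.84
        assert compare_models(0.0, 10.0, df=2).threshold == 5.99

    def test_monotone_in_delta(self):
        assert compare_models(100.0, 110.0, df=1).delta_ofv > \
            compare_models(100.0, 105.0, df=1).delta_ofv

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            compare_models(1.0, 2.0, df=0)


class TestSAEM:
    def test_evaluation_only_run_returns_initial_ofv(self, theta, small_study):
        settings = SAEMSettings(n_burnin=0, n_smooth=0, ofv_samples=200)
        fit = saem_fit(small_study, theta, OmegaSpec(), SigmaSpec(),
                       settings=settings, seed=5)
        ref = ofv(small_study, theta, OmegaSpec(), SigmaSpec(),
                  n_samples=200, seed=5)
        assert fit.ofv == pytest.approx(ref.value, rel=1e-12)
        assert fit.n_iterations == 0

    def test_seed_determinism(self, theta, small_study):
        a = saem_fit(small_study, theta, settings=FAST, seed=11)
        b = saem_fit(small_study, theta, settings=FAST, seed=11)
        np.testing.assert_allclose(a.theta.as_array(), b.theta.as_array(),
                                   rtol=1e-6)
        np.testing.assert_allclose(a.omega.as_array(), b.omega.as_array(),
                                   rtol=1e-6, atol=1e-9)

    def test_fit_returns_finite_estimates_and_trace(self, theta, small_study):
        fit = saem_fit(small_study, theta, settings=FAST, seed=2)
        assert np.all(np.isfinite(fit.theta.as_array()))
        assert np.all(fit.omega.as_array() >= 0)
        assert len(fit.trace) == FAST.n_iterations
        assert fit.sigma.bupg > fit.sigma.norbup  # BUP-g is by far the noisiest


class TestBootstrap:
    def test_percentile_ordering_and_determinism(self, theta):
        # fixed-effects data (no IIV) keeps every replicate on the exact
        # NLS path, whose optimum is insensitive to floating-point scheduling
        design = StudyDesign(n_subjects=8, dose_allocation={8.0: 8},
                             times=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                             steady_state=False)
        ds = generate_study(design, theta, OmegaSpec.none(),
                            SigmaSpec(0.1, 0.1, 0.1, 0.1), seed=42)
        a = bootstrap(ds, theta, OmegaSpec.none(), n_reps=3, seed=21)
        b = bootstrap(ds, theta, OmegaSpec.none(), n_reps=3, seed=21)
        t = a.table
        assert (t["p2.5"] <= t["median"] + 1e-12).all()
        assert (t["median"] <= t["p97.5"] + 1e-12).all()
        np.testing.assert_allclose(a.table.to_numpy(), b.table.to_numpy(),
                                   rtol=1e-6)

    def test_too_few_reps_rejected(self, small_study):
        with pytest.raises(ValueError):
            bootstrap(small_study, n_reps=1, seed=1)


class TestCovariateScreen:
    def test_strong_simulated_effect_is_detected(self, theta):
        # k24 driven hard by body weight (power exponent 3): the screen must
        # flag the pair at the 3.84-point rule
        rng = np.random.default_rng(42)
        n = 40
        wt = rng.normal(68, 12, n).clip(42, 100)
        inds = sample_individuals(theta, OmegaSpec(), n, rng)
        ind_thetas = [
            ind.theta.replace(k24=ind.theta.k24 * (wt[i] / 68.0) ** 3.0)
            for i, ind in enumerate(inds)
        ]
        ds = dataset_from_individuals(
            ind_thetas, {"AGE": 45.0, "WT": wt, "SEX": 0},
            dose_mg=8.0, times=(0, 0.5, 1, 2, 4, 8, 24), sigma=SigmaSpec(),
            seed=1,
        )
        settings = SAEMSettings(n_burnin=120, n_smooth=80, n_chains=1,
                                mcmc_sweeps=1, compute_ofv=False)
        base = saem_fit(ds, theta, settings=settings, seed=3)
        table = covariate_screen(
            ds, base, covariates=["WT"], parameters=["k24"],
            settings=settings, seed=4, n_ofv_samples=300,
        )
        row = table.iloc[0]
        assert row["significant"] and row["delta_ofv"] >= 3.84
        assert row["beta"] > 0.8  # right direction, usefully large

    def test_constant_covariate_skipped(self, theta, small_study):
        fit = saem_fit(small_study, theta, settings=FAST, seed=6)
        table = covariate_screen(small_study, fit, covariates=["SEX"],
                                 parameters=["k24"], settings=FAST, seed=7,
                                 n_ofv_samples=100)
        # the generator balances sex 0/1; force a constant column instead
        ds2 = small_study
        ds2.subjects["SEX"] = 0
        table = covariate_screen(ds2, fit, covariates=["SEX"],
                                 parameters=["k24"], settings=FAST, seed=7,
                                 n_ofv_samples=100)
        assert bool(table.iloc[0]["skipped"])

    def test_base_model_against_itself_gives_zero_delta(self, theta, small_study):
        # the seeded OFV is deterministic, so re-evaluating the base model
        # with common random numbers reproduces it exactly
        a = ofv(small_study, theta, OmegaSpec(), SigmaSpec(), n_samples=200,
                seed=13)
        b = ofv(small_study, theta, OmegaSpec(), SigmaSpec(), n_samples=200,
                seed=13)
        assert compare_models(a.value, b.value, df=1).delta_ofv == 0.0
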