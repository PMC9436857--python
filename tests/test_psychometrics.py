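"""Logistic PF fitting, derived indices, deviance goodness of fit, exclusions."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from bisectlab import (
    ObserverParams,
    ResponseSummary,
    apply_exclusions,
    derive_bp_dl_wf,
    fit_pf_mle,
    goodness_of_fit_pdev,
    psi_logistic,
)
from bisectlab.psychometrics import LN3, PsychFit, _fit_logistic_batch, saturated_loglik


class TestPsiLogistic:
    def test_midpoint_and_quantiles(self):
        a, b = 633.0, 0.012
        assert psi_logistic(a, a, b) == pytest.approx(0.5)
        assert psi_logistic(a + LN3 / b, a, b) == pytest.approx(0.75)
        assert psi_logistic(a - LN3 / b, a, b) == pytest.approx(0.25)

    def test_saturation_and_monotonicity(self):
        assert psi_logistic(-1e5, 633.0, 0.012) == pytest.approx(0.0, abs=1e-12)
        assert psi_logistic(1e5, 633.0, 0.012) == pytest.approx(1.0, abs=1e-12)
        # strictly increasing wherever float precision can resolve it
        x = np.linspace(-2000, 3400, 101)
        assert (np.diff(psi_logistic(x, 633.0, 0.012)) > 0).all()

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            psi_logistic(500.0, 633.0, 0.0)


class TestDerivedIndices:
    def test_closed_form_matches_numeric_inversion(self):
        alpha, beta = 600.0, 0.01
        fit = PsychFit(alpha, beta, 0.0, 0.0, True)
        bp, dl, wf = derive_bp_dl_wf(fit)
        assert bp == 600.0
        assert dl == pytest.approx(109.861228866, abs=1e-6)
        assert wf == pytest.approx(0.18310, abs=1e-5)
        # independent oracle: numerically invert psi at 0.75 / 0.25
        x75 = brentq(lambda x: psi_logistic(x, alpha, beta) - 0.75, -1e5, 1e5, xtol=1e-12)
        x25 = brentq(lambda x: psi_logistic(x, alpha, beta) - 0.25, -1e5, 1e5, xtol=1e-12)
        assert dl == pytest.approx((x75 - x25) / 2.0, rel=1e-9)

    def test_wf_scales_inversely_with_beta(self):
        wf1 = PsychFit(600.0, 0.01, 0, 0, True).wf
        wf2 = PsychFit(600.0, 0.02, 0, 0, True).wf
        assert wf1 == pytest.approx(2 * wf2)
        assert PsychFit(600.0, 1e9, 0, 0, True).wf == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            _ = PsychFit(-5.0, 0.01, 0, 0, True).wf


class TestMLEFit:
    def test_self_consistency_on_expected_data(self, expected_summary, standard_observer):
        """On fractional expected-proportion data the MLE sits at the
        generating parameters (the likelihood's unique maximum)."""
        fit = fit_pf_mle(expected_summary)
        assert fit.converged
        assert fit.alpha == pytest.approx(standard_observer.alpha, rel=1e-4)
        assert fit.beta == pytest.approx(standard_observer.beta, rel=1e-4)
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)

    def test_separable_step_data_flagged(self, time_design):
        levels = np.array(time_design.levels)
        n = np.full(6, 30.0)
        k = np.array([0.0, 0.0, 0.0, 30.0, 30.0, 30.0])
        fit = fit_pf_mle(ResponseSummary(levels, n, k))
        assert not fit.converged

    def test_all_identical_responses_flagged(self, time_design):
        levels = np.array(time_design.levels)
        fit = fit_pf_mle(ResponseSummary(levels, np.full(6, 30.0), np.full(6, 30.0)))
        assert not fit.converged

    def test_consistency_large_trials(self, time_design):
        rng = np.random.default_rng(3)
        levels = np.array(time_design.levels)
        obs = ObserverParams(600.0, 0.010)
        n = np.full(6, 10_000)
        k = rng.binomial(n, obs.p_positive(levels))
        fit = fit_pf_mle(ResponseSummary(levels, n.astype(float), k.astype(float)))
        assert fit.alpha == pytest.approx(600.0, rel=0.01)
        assert fit.beta == pytest.approx(0.010, rel=0.03)

    def test_mle_dominates_generating_parameters(self, time_design, design_counts):
        """LL at the fitted maximum >= LL at the truth, for every dataset."""
        from bisectlab.psychometrics import _binom_loglik

        rng = np.random.default_rng(9)
        levels = np.array(time_design.levels)
        for _ in range(100):
            alpha = rng.uniform(450, 850)
            wf = np.exp(rng.normal(np.log(0.15), 0.3))
            obs = ObserverParams(alpha, LN3 / (alpha * wf))
            k = rng.binomial(design_counts.astype(int), obs.p_positive(levels))
            summ = ResponseSummary(levels, design_counts, k.astype(float))
            fit = fit_pf_mle(summ)
            ll_true = _binom_loglik(obs.p_positive(levels), design_counts, k)
            assert fit.loglik >= ll_true - 1e-7

    def test_batch_fitter_agrees_with_mle(self, time_design, design_counts):
        rng = np.random.default_rng(13)
        levels = np.array(time_design.levels)
        ks = []
        for _ in range(50):
            alpha = rng.uniform(480, 820)
            wf = np.exp(rng.normal(np.log(0.15), 0.3))
            obs = ObserverParams(alpha, LN3 / (alpha * wf))
            ks.append(rng.binomial(design_counts.astype(int), obs.p_positive(levels)))
        out = _fit_logistic_batch(levels, design_counts, np.array(ks, dtype=float))
        for i, k in enumerate(ks):
            if not out["converged"][i]:
                continue
            fit = fit_pf_mle(ResponseSummary(levels, design_counts, k.astype(float)))
            if not fit.converged:
                continue
            assert out["alpha"][i] == pytest.approx(fit.alpha, rel=1e-4, abs=1e-3)
            assert out["deviance"][i] == pytest.approx(fit.deviance, abs=1e-5)

    def test_wf_dispersion_shrinks_with_trial_count(self, time_design, design_counts):
        rng = np.random.default_rng(29)
        levels = np.array(time_design.levels)
        obs = ObserverParams(633.0, 0.012)
        spreads = []
        for mult in (1, 4, 16):
            n = design_counts * mult
            wfs = []
            for _ in range(60):
                k = rng.binomial(n.astype(int), obs.p_positive(levels))
                fit = fit_pf_mle(ResponseSummary(levels, n, k.astype(float)))
                if fit.converged:
                    wfs.append(fit.wf)
            spreads.append(np.std(wfs))
        assert spreads[0] > spreads[1] > spreads[2]


class TestPDev:
    def test_perfect_fit_gives_pdev_one(self, expected_summary):
        fit = fit_pf_mle(expected_summary)
        assert goodness_of_fit_pdev(fit, expected_summary, n_sim=100, seed=1) == 1.0

    def test_reproducible_given_seed(self, time_design, design_counts, standard_observer):
        rng = np.random.default_rng(5)
        levels = np.array(time_design.levels)
        k = rng.binomial(design_counts.astype(int), standard_observer.p_positive(levels))
        summ = ResponseSummary(levels, design_counts, k.astype(float))
        fit = fit_pf_mle(summ)
        p1 = goodness_of_fit_pdev(fit, summ, n_sim=200, seed=42)
        p2 = goodness_of_fit_pdev(fit, summ, n_sim=200, seed=42)
        assert p1 == p2

    def test_invariant_to_unit_rescaling(self, time_design, design_counts, standard_observer):
        """pDev is unchanged when stimulus units change ms -> s (beta rescales)."""
        rng = np.random.default_rng(15)
        levels = np.array(time_design.levels)
        k = rng.binomial(design_counts.astype(int), standard_observer.p_positive(levels))
        summ_ms = ResponseSummary(levels, design_counts, k.astype(float))
        summ_s = ResponseSummary(levels / 1000.0, design_counts, k.astype(float))
        fit_ms = fit_pf_mle(summ_ms)
        fit_s = fit_pf_mle(summ_s)
        assert fit_s.beta == pytest.approx(fit_ms.beta * 1000.0, rel=1e-3)
        assert fit_s.deviance == pytest.approx(fit_ms.deviance, abs=1e-5)
        p_ms = goodness_of_fit_pdev(fit_ms, summ_ms, n_sim=300, seed=77)
        p_s = goodness_of_fit_pdev(fit_s, summ_s, n_sim=300, seed=77)
        assert p_s == pytest.approx(p_ms, abs=0.0501)

    def test_misspecified_lapse_inflates_exclusions(self, time_design, design_counts):
        """Data from a 20%-lapse observer, fitted lapse-free, fail the
        deviance check at a rate elevated well above the nominal 5% and
        consistent with an independent noncentral-chi-square oracle for
        the projected model misfit."""
        from scipy import stats as sps

        from bisectlab.psychometrics import _binom_loglik

        rng = np.random.default_rng(19)
        levels = np.array(time_design.levels)
        obs = ObserverParams(633.0, 0.012, lapse_rate=0.2)
        p_true = obs.p_positive(levels)

        # oracle: deviance ~ noncentral chi2(df = levels - 2) with ncp from
        # the KL projection of the lapse model onto the lapse-free logistic
        proj = fit_pf_mle(ResponseSummary(levels, design_counts, design_counts * p_true))
        p_proj = psi_logistic(levels, proj.alpha, proj.beta)
        ncp = 2 * (
            _binom_loglik(p_true, design_counts, design_counts * p_true)
            - _binom_loglik(p_proj, design_counts, design_counts * p_true)
        )
        df = len(levels) - 2
        oracle_power = sps.ncx2.sf(sps.chi2.ppf(0.95, df), df, ncp)

        n_excl = 0
        n_rep = 200
        for _ in range(n_rep):
            k = rng.binomial(design_counts.astype(int), p_true)
            summ = ResponseSummary(levels, design_counts, k.astype(float))
            fit = fit_pf_mle(summ)
            if not fit.converged:
                n_excl += 1
                continue
            if goodness_of_fit_pdev(fit, summ, n_sim=150, rng=rng) < 0.05:
                n_excl += 1
        rate = n_excl / n_rep
        assert oracle_power > 2 * 0.05  # misfit is detectable above nominal
        assert rate == pytest.approx(oracle_power, abs=0.05)


class TestExclusions:
    def _fits(self, pdevs, task="time"):
        return pd.DataFrame(
            {
                "participant_id": [f"p{i:03d}" for i in range(len(pdevs))],
                "task": task,
                "pdev": pdevs,
                "converged": True,
            }
        )

    def test_threshold_count(self):
        retained, log = apply_exclusions(self._fits([0.04, 0.06, 0.50, 0.01, 1.0]))
        assert len(retained) == 3
        assert sorted(log["participant_id"]) == ["p000", "p003"]

    def test_all_retained_empty_log(self):
        retained, log = apply_exclusions(self._fits([0.05, 0.2, 0.9, 1.0]))
        assert len(retained) == 4 and log.empty

    def test_missing_ebr_flagged_but_fit_kept(self):
        fits = self._fits([0.5, 0.5, 0.5])
        ebr = pd.DataFrame({"participant_id": ["p000", "p002"], "ebr": [12.0, np.nan]})
        retained, log = apply_exclusions(fits, ebr)
        assert len(retained) == 3  # still fitted
        assert set(log[log["reason"] == "missing_ebr"]["participant_id"]) == {"p001", "p002"}
        assert retained.set_index("participant_id")["has_ebr"].to_dict() == {
            "p000": True, "p001": False, "p002": False,
        }

    def test_taskwise_independence(self):
        fits = pd.concat(
            [self._fits([0.01, 0.5], task="time"), self._fits([0.5, 0.01], task="color")]
        )
        retained, _ = apply_exclusions(fits)
        by_task = retained.groupby("task")["participant_id"].apply(set).to_dict()
        assert by_task == {"time": {"p001"}, "color": {"p000"}}

    def test_deviance_definition(self, expected_summary):
        fit = fit_pf_mle(expected_summary)
        assert fit.deviance == pytest.approx(
            2 * (saturated_loglik(expected_summary) - fit.loglik), abs=1e-9
        )
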