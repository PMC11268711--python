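"""Hierarchical sampler, HDI, r-hat, and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import costdisc.cohort as ch
from costdisc import models as m
from costdisc import task_design as td
from costdisc.hierfit import (FitResult, PriorSpec, SamplerSettings,
                              fit_hierarchical, hdi, preset, rhat, summarize)


class TestHdi:
    def test_constant_samples(self):
        iv = hdi(np.full(100, 3.5))
        assert iv.lower == iv.upper == 3.5

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        iv = hdi(rng.standard_normal(10**6))
        assert iv.lower == pytest.approx(-1.96, abs=0.02)
        assert iv.upper == pytest.approx(1.96, abs=0.02)

    @pytest.mark.parametrize("n,seed", [(50, 1), (500, 2), (1000, 3)])
    def test_matches_brute_force_window_scan(self, n, seed):
        """Narrowest window over the sorted sample (exhaustive scan)."""
        rng = np.random.default_rng(seed)
        x = np.sort(rng.gamma(2.0, 1.0, n))
        k = int(np.ceil(0.95 * n))
        widths = x[k - 1:] - x[: n - k + 1]
        j = int(np.argmin(widths))
        iv = hdi(x)
        assert iv.lower == pytest.approx(x[j])
        assert iv.upper == pytest.approx(x[j + k - 1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hdi([1.0])


class TestRhat:
    def test_converged_chains_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 4000))
        assert rhat(draws) == pytest.approx(1.0, abs=0.01)

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500))
        draws[1] += 100.0
        assert rhat(draws) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.random.default_rng(0).standard_normal((1, 100)))

    def test_matches_textbook_split_formula(self):
        """Split-chain between/within variance formula, hand-coded."""
        rng = np.random.default_rng(7)
        draws = rng.normal([[0.0], [0.3]], 1.0, (2, 100))
        split = draws.reshape(4, 50)
        w = split.var(axis=1, ddof=1).mean()
        b = 50 * split.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((50 - 1) / 50 * w + b / 50) / w)
        assert rhat(draws, method="split") == pytest.approx(expected, rel=1e-6)


def _placebo_table(params, n_trials, seed, task="effort"):
    if task == "effort":
        spec = td.effort_spec(n_blocks=max(1, n_trials // 25),
                              trials_per_block=min(25, n_trials))
        design = td.build_effort_design(spec, seed)
    else:
        design = td.build_delay_design(td.delay_spec(), 1, seed)
    return ch.simulate_choices(params, "PLC", design, "parabolic", seed + 1)


class TestFitHierarchical:
    def test_prior_only_returns_prior(self):
        """With the likelihood switched off the sampler targets the prior."""
        design = td.build_effort_design(td.effort_spec(), 0, subject_id="s1")
        design2 = td.build_effort_design(td.effort_spec(), 1, subject_id="s2")
        data = pd.concat([design, design2], ignore_index=True)
        priors = PriorSpec.default("effort")
        fit = fit_hierarchical(data, "parabolic", "effort", priors,
                               SamplerSettings(2, 500, 1500, seed=0),
                               prior_only=True)
        for p in ("kappa", "beta"):
            draws = fit.group[p]
            mc_se = draws.std() / np.sqrt(200)  # generous autocorr allowance
            assert abs(draws.mean() - priors.priors[p].mean_loc) < 5 * mc_se

    def test_single_subject_large_data_consistency(self):
        """Subject-level kappa approaches the grid-search ML estimate."""
        true = m.SubjectParams(0.102, 0.667)
        big = pd.concat([_placebo_table(true, 125, s) for s in range(16)],
                        ignore_index=True)  # 2000 trials, one subject
        big["trial_index"] = np.arange(1, len(big) + 1)
        fit = fit_hierarchical(big, "parabolic", "effort",
                               settings=preset("fast", 5))

        def nll(theta):
            return -m.trial_loglik("parabolic",
                                   m.SubjectParams(theta[0], theta[1]),
                                   "PLC", big)

        mle = optimize.minimize(nll, [0.05, 0.5], method="Nelder-Mead").x
        post_kappa = float(fit.subject["kappa"].mean())
        assert post_kappa == pytest.approx(mle[0], rel=0.05)
        assert post_kappa == pytest.approx(true.kappa_plc, rel=0.10)

    def test_shrinkage_toward_group_mean(self):
        """Partial pooling: subject posteriors sit between the no-pooling
        ML estimate and the group mean for most subjects.  Short 25-trial
        sessions keep the likelihood weak enough for pooling to matter."""
        truth = ch.default_effort_truth(10)
        subjects = ch.draw_subjects(truth, seed=31)
        spec = td.effort_spec(n_blocks=1)
        pieces = []
        for i, (sid, sp) in enumerate(subjects.items()):
            design = td.build_effort_design(spec, 100 + i, subject_id=sid)
            pieces.append(ch.simulate_choices(sp, "PLC", design,
                                              "parabolic", 200 + i))
        plc = pd.concat(pieces, ignore_index=True)
        fit = fit_hierarchical(plc, settings=preset("fast", 8))
        group_kappa = float(fit.group["kappa"].mean())
        n_between = 0
        for i, sid in enumerate(fit.subject_ids):
            sub = plc[plc["subject_id"] == sid]

            def nll(theta, sub=sub):
                return -m.trial_loglik(
                    "parabolic", m.SubjectParams(theta[0], theta[1]),
                    "PLC", sub)

            mle_kappa = optimize.minimize(nll, [0.05, 0.5],
                                          method="Nelder-Mead").x[0]
            post = float(fit.subject["kappa"][:, :, i].mean())
            # absolute floor covers subjects whose MLE already sits on the
            # group mean, where "between" is undefined up to jitter
            lo, hi = sorted([mle_kappa, group_kappa])
            tol = 0.15 * (hi - lo) + 5e-3
            n_between += (lo - tol) <= post <= (hi + tol)
        assert n_between >= 0.9 * len(fit.subject_ids)

    def test_missing_condition_column_rejected(self, effort_design):
        data = effort_design.copy()
        data["choice"] = 1.0
        with pytest.raises(ValueError, match="condition"):
            fit_hierarchical(data.drop(columns=["condition"]), "parabolic",
                             "effort")

    def test_save_load_round_trip(self, small_effort_cohort, tmp_path):
        fit = fit_hierarchical(small_effort_cohort.trials,
                               settings=SamplerSettings(2, 100, 100, seed=1))
        fit.save(tmp_path / "fit")
        back = FitResult.load(tmp_path / "fit")
        assert back.subject_ids == fit.subject_ids
        np.testing.assert_allclose(back.group["kappa"], fit.group["kappa"])


class TestSummarize:
    @pytest.fixture(scope="class")
    def fit(self, small_effort_cohort):
        return fit_hierarchical(small_effort_cohort.trials,
                                settings=SamplerSettings(2, 200, 300, seed=2))

    def test_six_primary_rows(self, fit):
        table = summarize(fit)
        assert set(table["param"]) == {"kappa", "beta", "s_kappa_hal",
                                       "s_kappa_bip", "s_beta_hal",
                                       "s_beta_bip"}

    def test_sign_probability_is_direct_count(self, fit):
        table = summarize(fit).set_index("param")
        draws = fit.group["kappa"]
        assert table.loc["kappa", "p_gt_zero"] == \
            pytest.approx(float((draws > 0).mean()))

    def test_symmetric_zero_sample_sign_prob(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((2, 20000))
        assert float((draws > 0).mean()) == pytest.approx(0.5, abs=0.02)
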