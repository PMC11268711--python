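"""Posterior-predictive simulation, recovery reports, Bayesian correlation,
and choice-curve summaries."""

import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import costdisc.cohort as ch
from costdisc import task_design as td
from costdisc.hierfit import fit_hierarchical, preset
from costdisc.validation import (bayesian_correlation, choice_curve_summaries,
                                 posterior_predictive_datasets, recover_group,
                                 recover_subjects)


@pytest.fixture(scope="module")
def effort_fit(small_effort_cohort):
    return fit_hierarchical(small_effort_cohort.trials,
                            settings=preset("fast", 17))


class TestPosteriorPredictive:
    def test_dataset_counts(self, effort_fit, small_effort_cohort):
        sims = posterior_predictive_datasets(
            effort_fit, small_effort_cohort.trials, n_total=50, n_selected=4,
            seed=0)
        assert len(sims) == 4
        for s in sims:
            assert len(s) == len(small_effort_cohort.trials)
            assert set(s["choice"].unique()) <= {0.0, 1.0}
            td.validate_trials(s)

    def test_selection_larger_than_total_rejected(self, effort_fit,
                                                  small_effort_cohort):
        with pytest.raises(ValueError):
            posterior_predictive_datasets(effort_fit,
                                          small_effort_cohort.trials,
                                          n_total=5, n_selected=6, seed=0)

    def test_single_passthrough_dataset(self, effort_fit,
                                        small_effort_cohort):
        sims = posterior_predictive_datasets(
            effort_fit, small_effort_cohort.trials, n_total=1, n_selected=1,
            seed=1)
        assert len(sims) == 1

    def test_observed_rate_covered_by_predictive(self, effort_fit,
                                                 small_effort_cohort):
        """Per subject, the observed HC rate should sit inside the central
        95% of the posterior-predictive HC-rate distribution."""
        sims = posterior_predictive_datasets(
            effort_fit, small_effort_cohort.trials, n_total=60, n_selected=60,
            seed=2)
        obs = small_effort_cohort.trials.groupby("subject_id")["choice"].mean()
        rates = pd.concat([s.groupby("subject_id")["choice"].mean()
                           for s in sims], axis=1)
        n_ok = 0
        for sid in obs.index:
            rank = (rates.loc[sid] < obs[sid]).mean()
            n_ok += 0.025 <= rank <= 0.975 or np.isclose(
                rates.loc[sid].var(), 0)
        assert n_ok >= 0.9 * len(obs)


class TestRecoveryReports:
    def test_infinitely_wide_reference_accepts_everything(self, effort_fit):
        wide = copy.deepcopy(effort_fit)
        for p in wide.active_params:
            wide.group[p] = np.concatenate(
                [wide.group[p], np.full_like(wide.group[p], 1e6),
                 np.full_like(wide.group[p], -1e6)], axis=1)
        report = recover_group([effort_fit], wide)
        assert (report["frac_within_hdi"] == 1.0).all()

    def test_shifted_refits_rejected(self, effort_fit):
        shifted = copy.deepcopy(effort_fit)
        for p in shifted.active_params:
            shifted.group[p] = shifted.group[p] + 100.0
        report = recover_group([shifted], effort_fit)
        assert (report["frac_within_hdi"] == 0.0).all()

    def test_identical_refit_correlates_perfectly(self, effort_fit):
        report = recover_subjects([effort_fit], effort_fit)
        assert (report["pearson_r"] > 0.9999).all()

    def test_noise_refit_uncorrelated(self, effort_fit):
        rng = np.random.default_rng(0)
        noise = copy.deepcopy(effort_fit)
        for p in noise.active_params:
            noise.subject[p] = rng.standard_normal(noise.subject[p].shape)
        report = recover_subjects([noise], effort_fit)
        n = len(effort_fit.subject_ids)
        # 99% CI for a true-zero correlation at this n
        assert (report["pearson_r"].abs() < 2.6 / np.sqrt(n - 3)).all()


class TestBayesianCorrelation:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        post = bayesian_correlation(x, 2 * x + 1, seed=1)
        assert post.mean > 0.97
        assert post.credible

    def test_posterior_mean_matches_sample_r(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        y = 0.5 * x + rng.standard_normal(500)
        post = bayesian_correlation(x, y, seed=2)
        r_sample = stats.pearsonr(x, y)[0]
        assert post.mean == pytest.approx(r_sample, abs=0.05)

    def test_independent_inputs_rarely_credible(self):
        rng = np.random.default_rng(2)
        flags = []
        for rep in range(10):
            x = rng.standard_normal(62)
            y = rng.standard_normal(62)
            flags.append(bayesian_correlation(x, y, seed=rep).credible)
        assert sum(flags) <= 1  # >= 90% of replicates not credible

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bayesian_correlation(np.ones(10), np.arange(10.0))


class TestChoiceCurves:
    def _fixture_table(self):
        rows = []
        for i, (r_hc, c_hc, cond, choice) in enumerate([
                (16, 0.8, "PLC", 1), (16, 0.8, "PLC", 0), (8, 0.4, "PLC", 1),
                (16, 0.8, "HAL", 0), (8, 0.4, "HAL", 0), (8, 0.4, "HAL", 1),
                (16, 0.8, "BIP", 1), (8, 0.4, "BIP", 1), (4, 0.2, "BIP", 0),
                (4, 0.2, "PLC", 1)] * 3):
            rows.append(dict(subject_id="s1", condition=cond,
                             task_kind="effort", block=1, trial_index=i + 1,
                             r_hc=float(r_hc), c_hc=c_hc, r_lc=2.0, c_lc=0.0,
                             choice=float(choice)))
        return pd.DataFrame(rows)

    def test_matches_hand_grouping(self):
        table = self._fixture_table()
        out = choice_curve_summaries(table)
        # PLC rows with reward difference 14 (=16-2): choices 1,0 repeated
        cell = out.query("kind == 'reward' and condition == 'PLC' "
                         "and level == 14.0")
        assert cell["mean"].iloc[0] == pytest.approx(0.5)
        assert cell["n"].iloc[0] == 6
        hal = out.query("kind == 'condition' and condition == 'HAL'")
        assert hal["mean"].iloc[0] == pytest.approx(1 / 3)

    def test_all_ones(self):
        table = self._fixture_table()
        table["choice"] = 1.0
        out = choice_curve_summaries(table)
        assert (out["mean"] == 1.0).all()

    def test_indifferent_simulation_near_half(self, delay_design):
        from costdisc import models as m
        sp = m.SubjectParams(-4.0, 0.0)
        sims = pd.concat(
            [ch.simulate_choices(sp, "PLC", delay_design, "hyperbolic", s)
             for s in range(30)], ignore_index=True)
        out = choice_curve_summaries(sims)
        cond = out.query("kind == 'condition'")
        assert np.allclose(cond["mean"], 0.5, atol=0.02)
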