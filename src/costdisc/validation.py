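"""Posterior-predictive validation, parameter recovery, and the across-task
Bayesian correlation.

The recovery procedure mirrors the modelling pipeline itself: simulate
choice datasets from subject-level posterior draws of a reference fit, refit
them, and check (a) that refit group-level means land inside the reference
95% HDIs and (b) that refit subject-level posterior means correlate strongly
with the reference ones (Pearson r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .hierfit import FitResult, HdiInterval, hdi
from .models import BETA_FLOOR, code_effort, sv_delay, sv_effort

PARAM_KEYS = ("kappa", "beta", "s_kappa_hal", "s_kappa_bip",
              "s_beta_hal", "s_beta_bip")


def _choice_probs(task_kind: str, form: str, effort_coding: str,
                  theta: np.ndarray, block: pd.DataFrame) -> np.ndarray:
    """(n_draws, n_trials) HC-choice probabilities for one subject/condition
    block given a (n_draws, 6) parameter matrix."""
    cond = str(block["condition"].iloc[0])
    ih = 1.0 if cond == "HAL" else 0.0
    ib = 1.0 if cond == "BIP" else 0.0
    kappa = theta[:, 0] + ih * theta[:, 2] + ib * theta[:, 3]
    beta = np.maximum(theta[:, 1] + ih * theta[:, 4] + ib * theta[:, 5],
                      BETA_FLOOR)
    r_hc = block["r_hc"].to_numpy(float)
    r_lc = block["r_lc"].to_numpy(float)
    c_hc = block["c_hc"].to_numpy(float)
    c_lc = block["c_lc"].to_numpy(float)
    if task_kind == "effort":
        c_hc = code_effort(c_hc, effort_coding)
        c_lc = code_effort(c_lc, effort_coding)
        sv = sv_effort
    else:
        sv = sv_delay
    k = kappa[:, None]
    dsv = sv(form, k, r_hc[None, :], c_hc[None, :]) - \
        sv(form, k, r_lc[None, :], c_lc[None, :])
    x = beta[:, None] * dsv
    ax = np.abs(x)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-ax)),
                    np.exp(-ax) / (1.0 + np.exp(-ax)))


def posterior_predictive_datasets(fit: FitResult, design: pd.DataFrame,
                                  n_total: int = 500, n_selected: int = 10,
                                  seed: int = 0) -> List[pd.DataFrame]:
    """Simulate choice datasets from subject-level posterior draws.

    Per subject, ``n_total`` datasets are generated on that subject's design
    rows (one posterior draw each) and a seeded random subset of size
    ``n_selected`` is kept; the k-th kept simulation of every subject is
    assembled into the k-th returned cohort-level trial table.
    """
    if n_selected > n_total:
        raise ValueError("n_selected cannot exceed n_total")
    rng = np.random.default_rng(seed)
    chains, draws = fit.group[fit.active_params[0]].shape
    datasets = [[] for _ in range(n_selected)]
    for si, sid in enumerate(fit.subject_ids):
        sub = design[design["subject_id"].astype(str) == str(sid)]
        if sub.empty:
            raise ValueError(f"design has no rows for subject {sid!r}")
        flat = rng.integers(0, chains * draws, size=n_total)
        theta = np.zeros((n_total, 6))
        for k, p in enumerate(PARAM_KEYS):
            if p in fit.subject:
                theta[:, k] = fit.subject[p][:, :, si].reshape(-1)[flat]
        keep = rng.choice(n_total, size=n_selected, replace=False)
        for cond, block in sub.groupby("condition", sort=True):
            probs = _choice_probs(fit.task_kind, fit.form, fit.effort_coding,
                                  theta[keep], block)
            u = rng.random(probs.shape)
            choices = (u < probs).astype(float)
            for k in range(n_selected):
                piece = block.copy()
                piece["choice"] = choices[k]
                datasets[k].append(piece)
    return [pd.concat(parts, ignore_index=True) for parts in datasets]


def recover_group(refits: Sequence[FitResult],
                  reference: FitResult) -> pd.DataFrame:
    """Fraction of refit group-mean posteriors landing inside the reference
    95% HDI, per parameter."""
    rows = []
    for p in reference.active_params:
        iv = hdi(reference.group[p])
        means = np.array([float(f.group[p].mean()) for f in refits])
        inside = (means >= iv.lower) & (means <= iv.upper)
        rows.append({"param": p, "hdi_lower": iv.lower, "hdi_upper": iv.upper,
                     "n_refits": len(refits),
                     "frac_within_hdi": float(inside.mean())})
    return pd.DataFrame(rows)


def recover_subjects(refits: Sequence[FitResult],
                     reference: FitResult) -> pd.DataFrame:
    """Pearson r between reference subject-level posterior means and the
    refit means averaged across datasets, per parameter.  Per-dataset
    correlations are returned alongside."""
    rows = []
    for p in reference.active_params:
        ref = reference.subject_means(p)
        per_fit = np.array([f.subject_means(p) for f in refits])
        avg = per_fit.mean(axis=0)
        r, _ = stats.pearsonr(ref, avg)
        per_dataset = [float(stats.pearsonr(ref, m)[0]) for m in per_fit]
        rows.append({"param": p, "pearson_r": float(r),
                     "r_per_dataset_min": min(per_dataset),
                     "r_per_dataset_max": max(per_dataset)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationPosterior:
    r_draws: np.ndarray
    mean: float
    interval: HdiInterval

    @property
    def credible(self) -> bool:
        return self.interval.lower > 0 or self.interval.upper < 0


def bayesian_correlation(x, y, n_draws: int = 4000, seed: int = 0,
                         n_walkers: int = 16,
                         warmup: int = 500) -> CorrelationPosterior:
    """Posterior over the correlation of a bivariate normal model.

    Parameters are (mu_x, mu_y, log sd_x, log sd_y, atanh r) sampled with an
    affine-invariant ensemble sampler; the prior on r is uniform on (-1, 1)
    and the location/scale priors are broad around the sample moments.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    mx, my = x.mean(), y.mean()
    lsx, lsy = np.log(x.std(ddof=1)), np.log(y.std(ddof=1))
    n = len(x)

    def logpost(p):
        mu1, mu2, ls1, ls2, z = p
        if abs(z) > 8 or abs(ls1 - lsx) > 8 or abs(ls2 - lsy) > 8:
            return -np.inf
        r = np.tanh(z)
        s1, s2 = np.exp(ls1), np.exp(ls2)
        u = (x - mu1) / s1
        v = (y - mu2) / s2
        q = (u ** 2 - 2 * r * u * v + v ** 2) / (1 - r ** 2)
        loglik = -n * (ls1 + ls2 + 0.5 * np.log1p(-r ** 2)) - 0.5 * q.sum()
        logprior = (-0.5 * ((mu1 - mx) / (5 * np.exp(lsx))) ** 2
                    - 0.5 * ((mu2 - my) / (5 * np.exp(lsy))) ** 2
                    + np.log1p(-r ** 2))  # uniform r via tanh Jacobian
        return loglik + logprior

    rng = np.random.default_rng(seed)
    p0 = np.column_stack([
        mx + 0.1 * np.exp(lsx) * rng.standard_normal(n_walkers),
        my + 0.1 * np.exp(lsy) * rng.standard_normal(n_walkers),
        lsx + 0.1 * rng.standard_normal(n_walkers),
        lsy + 0.1 * rng.standard_normal(n_walkers),
        0.1 * rng.standard_normal(n_walkers),
    ])
    steps = warmup + int(np.ceil(n_draws / n_walkers))
    sampler = emcee.EnsembleSampler(n_walkers, 5, logpost)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, steps, progress=False)
    z = sampler.get_chain(discard=warmup, flat=True)[:, 4]
    r_draws = np.tanh(z[:n_draws])
    return CorrelationPosterior(r_draws, float(r_draws.mean()), hdi(r_draws))


def choice_curve_summaries(data: pd.DataFrame) -> pd.DataFrame:
    """Mean HC-choice rate (with SEM) per condition, per reward level and per
    cost level — reward/cost enter as HC-LC differences for the effort task
    and as absolute HC levels for the delay task."""
    task_kind = str(data["task_kind"].iloc[0])
    df = data.copy()
    if task_kind == "effort":
        df["reward_level"] = df["r_hc"] - df["r_lc"]
        df["cost_level"] = df["c_hc"] - df["c_lc"]
    else:
        df["reward_level"] = df["r_hc"]
        df["cost_level"] = df["c_hc"]
    rows = []

    def emit(kind, level, cond, grp):
        ch = grp["choice"].to_numpy(float)
        rows.append({"kind": kind, "condition": cond, "level": level,
                     "mean": float(ch.mean()),
                     "sem": float(ch.std(ddof=1) / np.sqrt(len(ch)))
                     if len(ch) > 1 else np.nan,
                     "n": len(ch)})

    for cond, g in df.groupby("condition", sort=True):
        emit("condition", np.nan, cond, g)
        for lvl, gg in g.groupby("reward_level", sort=True):
            emit("reward", float(lvl), cond, gg)
        for lvl, gg in g.groupby("cost_level", sort=True):
            emit("cost", float(lvl), cond, gg)
    return pd.DataFrame(rows)
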