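"""Hierarchical logistic regression of choice on drug, reward, cost and their
interactions — the model-agnostic companion to the discounting fits.

Design.  Drug is a 3-level factor with placebo as the reference, entering as
two indicator columns (HAL, BIP).  For the effort task, reward and cost are
high-cost-minus-low-cost differences; for the delay task they are the
absolute levels of the varying high-cost option.  Non-binary predictors are
centred and scaled to SD 0.5; interactions are products of the scaled mains.
Optional extras (trial_number, session) join as scaled mains plus their
two-way drug interactions.

Model.  Bernoulli-logit with weakly informative normal(0, 2.5) priors on
fixed effects; every fixed effect also has a subject-level random slope (plus
a random intercept) with independent half-normal(1) SD priors.  Sampling is
component-wise adaptive Metropolis for fixed and random effects with slice
updates for the random-effect SDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .hierfit import hdi, rhat
from .sampling import adapt_scales, slice_sample, spawn_seeds

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionSpec:
    task_kind: str
    extras: Tuple[str, ...] = ()
    scale_sd: float = 0.5

    def __post_init__(self):
        bad = set(self.extras) - {"trial_number", "session"}
        if bad:
            raise ValueError(f"unknown extras: {sorted(bad)}")


@dataclass
class DesignMatrix:
    X: pd.DataFrame          # one column per fixed effect, intercept first
    y: np.ndarray
    subject_idx: np.ndarray
    subject_ids: List[str]
    spec: RegressionSpec
    scaling: Dict[str, Tuple[float, float]]  # column -> (center, sd)

    @property
    def terms(self) -> List[str]:
        return list(self.X.columns)


def _scale(x: np.ndarray, target_sd: float) -> Tuple[np.ndarray, float, float]:
    sd = x.std(ddof=0)
    if sd <= 1e-10 * max(1.0, float(np.abs(x).max())):
        raise ValueError("constant predictor")
    return (x - x.mean()) / sd * target_sd, float(x.mean()), float(sd)


def build_design(data: pd.DataFrame, spec: RegressionSpec) -> DesignMatrix:
    """Assemble the fixed-effect design matrix from a trial table."""
    if data["choice"].isna().any():
        raise ValueError("trial table has missing choices")
    df = data
    if spec.task_kind == "effort":
        reward_raw = (df["r_hc"] - df["r_lc"]).to_numpy(float)
        cost_raw = (df["c_hc"] - df["c_lc"]).to_numpy(float)
    elif spec.task_kind == "delay":
        reward_raw = df["r_hc"].to_numpy(float)
        cost_raw = df["c_hc"].to_numpy(float)
    else:
        raise ValueError(f"unknown task_kind {spec.task_kind!r}")
    scaling: Dict[str, Tuple[float, float]] = {}
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    cond = df["condition"].to_numpy()
    cols["HAL"] = (cond == "HAL").astype(float)
    cols["BIP"] = (cond == "BIP").astype(float)
    for name, raw in (("reward", reward_raw), ("cost", cost_raw)):
        try:
            scaled, ctr, sd = _scale(raw, spec.scale_sd)
        except ValueError:
            raise ValueError(f"constant predictor: {name}")
        cols[name] = scaled
        scaling[name] = (ctr, sd)
    for drug in ("HAL", "BIP"):
        cols[f"{drug}:reward"] = cols[drug] * cols["reward"]
        cols[f"{drug}:cost"] = cols[drug] * cols["cost"]
    cols["reward:cost"] = cols["reward"] * cols["cost"]
    for drug in ("HAL", "BIP"):
        cols[f"{drug}:reward:cost"] = cols[drug] * cols["reward:cost"]
    for extra in spec.extras:
        if extra == "trial_number":
            raw = df["trial_index"].to_numpy(float)
        else:
            if "session" not in df.columns:
                raise ValueError("data lacks a session column for the "
                                 "session control analysis")
            raw = df["session"].to_numpy(float)
        try:
            scaled, ctr, sd = _scale(raw, spec.scale_sd)
        except ValueError:
            raise ValueError(f"constant predictor: {extra}")
        cols[extra] = scaled
        scaling[extra] = (ctr, sd)
        for drug in ("HAL", "BIP"):
            cols[f"{drug}:{extra}"] = cols[drug] * scaled
    subject_ids = sorted(df["subject_id"].astype(str).unique())
    sid_to_idx = {s: i for i, s in enumerate(subject_ids)}
    subject_idx = df["subject_id"].astype(str).map(sid_to_idx).to_numpy()
    return DesignMatrix(pd.DataFrame(cols), df["choice"].to_numpy(float),
                        subject_idx, subject_ids, spec, scaling)


@dataclass(frozen=True)
class GlmmSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 2000
    seed: int = 0
    fixed_prior_scale: float = 2.5
    sd_prior_scale: float = 1.0


GLMM_PRESETS = {
    "full": dict(chains=4, warmup=1000, draws=2000),
    "fast": dict(chains=2, warmup=400, draws=600),
}


def glmm_preset(name: str, seed: int = 0) -> GlmmSettings:
    return GlmmSettings(seed=seed, **GLMM_PRESETS[name])


@dataclass
class GlmmResult:
    terms: List[str]
    fixed: np.ndarray          # (chain, draw, term)
    sd_random: np.ndarray      # (chain, draw, term)
    subject_ids: List[str]
    settings: GlmmSettings
    separation_warning: bool

    def fixed_draws(self, term: str) -> np.ndarray:
        return self.fixed[:, :, self.terms.index(term)]

    def max_rhat(self) -> float:
        if self.settings.chains < 2:
            return float("nan")
        return max(float(rhat(self.fixed[:, :, j]))
                   for j in range(len(self.terms)))


def _loglik_rows(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    ax = np.abs(eta)
    logp = np.where(eta >= 0, -np.log1p(np.exp(-ax)),
                    eta - np.log1p(np.exp(-ax)))
    log1mp = logp - eta
    return np.where(y == 1, logp, log1mp)


def fit_glmm(design: DesignMatrix,
             settings: Optional[GlmmSettings] = None) -> GlmmResult:
    """Sample the hierarchical Bernoulli-logit model.

    State is (fixed effects b, random effects u, random SDs tau).  b and u
    are updated component-wise by adaptive random-walk Metropolis (u
    vectorised over subjects), tau by slice sampling; the linear predictor is
    maintained incrementally so each update costs one pass over the rows it
    touches.
    """
    settings = settings or GlmmSettings()
    X = design.X.to_numpy(float)
    y = design.y
    s_idx = design.subject_idx
    n, P = X.shape
    S = len(design.subject_ids)
    if S < 2:
        raise ValueError("need at least 2 subjects")
    seeds = spawn_seeds(settings.seed, settings.chains)
    fixed = np.empty((settings.chains, settings.draws, P))
    sd_rand = np.empty((settings.chains, settings.draws, P))
    sep_warn = False

    for c in range(settings.chains):
        rng = np.random.default_rng(seeds[c])
        b = 0.1 * rng.standard_normal(P)
        tau = 0.3 + 0.2 * rng.random(P)
        u = 0.1 * rng.standard_normal((S, P))
        eta = X @ b + np.einsum("np,np->n", X, u[s_idx])
        ll = _loglik_rows(eta, y)
        ll_subj = np.bincount(s_idx, ll, minlength=S)
        log_step_b = np.full(P, np.log(0.1))
        log_step_u = np.full((S, P), np.log(0.3))

        for it in range(settings.warmup + settings.draws):
            warm = it < settings.warmup
            # fixed effects, one scalar at a time
            for j in range(P):
                delta = np.exp(log_step_b[j]) * rng.standard_normal()
                eta_prop = eta + X[:, j] * delta
                ll_prop = _loglik_rows(eta_prop, y)
                bj = b[j] + delta
                dprior = (b[j] ** 2 - bj ** 2) / \
                    (2 * settings.fixed_prior_scale ** 2)
                accept = np.log(rng.random()) < ll_prop.sum() - ll.sum() + dprior
                if accept:
                    b[j] = bj
                    eta = eta_prop
                    ll = ll_prop
                    ll_subj = np.bincount(s_idx, ll, minlength=S)
                if warm:
                    adapt_scales(log_step_b[j:j + 1], np.array([accept]), it)
            # random effects, vectorised over subjects per term
            for j in range(P):
                delta = np.exp(log_step_u[:, j]) * rng.standard_normal(S)
                eta_prop = eta + X[:, j] * delta[s_idx]
                ll_prop_subj = np.bincount(s_idx, _loglik_rows(eta_prop, y),
                                           minlength=S)
                uj = u[:, j]
                dprior = (uj ** 2 - (uj + delta) ** 2) / (2 * tau[j] ** 2)
                accept = np.log(rng.random(S)) < ll_prop_subj - ll_subj + dprior
                if accept.any():
                    u[accept, j] += delta[accept]
                    eta = eta + X[:, j] * np.where(accept[s_idx],
                                                   delta[s_idx], 0.0)
                    ll = _loglik_rows(eta, y)
                    ll_subj = np.bincount(s_idx, ll, minlength=S)
                if warm:
                    adapt_scales(log_step_u[:, j], accept, it)
            # exact Gibbs move along the likelihood-flat direction
            # (b_j + delta, u_.j - delta): eta is unchanged, so delta has a
            # Gaussian full conditional from the priors alone
            for j in range(P):
                prec = 1.0 / settings.fixed_prior_scale ** 2 + S / tau[j] ** 2
                m = (-b[j] / settings.fixed_prior_scale ** 2 +
                     u[:, j].sum() / tau[j] ** 2) / prec
                delta = m + rng.standard_normal() / np.sqrt(prec)
                b[j] += delta
                u[:, j] -= delta
            # joint rescale of (tau_j, u_.j) to cross the funnel
            for j in range(P):
                gamma = 0.3 * rng.standard_normal()
                scale = np.exp(gamma)
                delta_u = u[:, j] * (scale - 1.0)
                eta_prop = eta + X[:, j] * delta_u[s_idx]
                ll_prop = _loglik_rows(eta_prop, y)
                tau_new = tau[j] * scale
                dprior = (tau[j] ** 2 - tau_new ** 2) / \
                    (2 * settings.sd_prior_scale ** 2)
                if np.log(rng.random()) < \
                        ll_prop.sum() - ll.sum() + dprior + gamma:
                    u[:, j] *= scale
                    tau[j] = tau_new
                    eta = eta_prop
                    ll = ll_prop
                    ll_subj = np.bincount(s_idx, ll, minlength=S)
            # random-effect SDs
            for j in range(P):
                ssq = float(np.sum(u[:, j] ** 2))
                hs = settings.sd_prior_scale

                def logpost(t, ssq=ssq, ns=S, hs=hs):
                    s2 = np.exp(2 * t)
                    return (1 - ns) * t - ssq / (2 * s2) - s2 / (2 * hs ** 2)

                tau[j] = float(np.exp(
                    slice_sample(float(np.log(tau[j])), logpost, rng)))
            if not warm:
                k = it - settings.warmup
                fixed[c, k] = b
                sd_rand[c, k] = tau
        if np.mean(np.abs(eta) > 15) > 0.5:
            sep_warn = True
            log.warning("possible separation: most fitted probabilities are "
                        "pinned at the bounds")
    return GlmmResult(design.terms, fixed, sd_rand, design.subject_ids,
                      settings, sep_warn)


def credible_effects(fit: GlmmResult, mass: float = 0.95) -> pd.DataFrame:
    """EffectTable: one row per fixed effect with the HDI-exclusion flag."""
    rows = []
    for j, term in enumerate(fit.terms):
        draws = fit.fixed[:, :, j]
        iv = hdi(draws, mass)
        rows.append({"term": term, "mean": iv.mean,
                     "hdi_lower": iv.lower, "hdi_upper": iv.upper,
                     "credible": bool(iv.lower > 0 or iv.upper < 0)})
    return pd.DataFrame(rows)
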