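"""Hierarchical Bayesian estimation of the discounting model with drug shifts.

Model (per task).  Each subject i has six parameters
``theta_i = (kappa, beta, s_kappa_hal, s_kappa_bip, s_beta_hal, s_beta_bip)``,
drawn from independent normal population distributions with their own group
mean and SD.  On a trial under condition c the resolved parameters are
``kappa_i + I_HAL s_kappa_hal,i + I_BIP s_kappa_bip,i`` (and likewise beta);
the choice is Bernoulli with softmax probability of the high-cost option.
Shift parameters are only included for conditions present in the data, so a
placebo-only table yields the two-parameter (kappa, beta) model used for form
comparison.

Sampling.  Group means are updated by conjugate Gibbs draws, group SDs by
slice sampling, and subject-level parameters by component-wise random-walk
Metropolis whose step sizes are tuned to a 44% acceptance rate during warmup
and frozen afterwards.  Four chains with 4,000 post-warmup draws after 3,000
warmup iterations are the default ("full") setting; "medium" (4 x 1000/1000)
and "fast" (2 x 500/500) presets trade precision for runtime in
simulation studies.  Convergence is reported as split-chain r-hat with 1.01
as the acceptance threshold.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Dict, Optional

import arviz as az
import numpy as np
import pandas as pd

from .models import (BETA_FLOOR, P_CLIP, SubjectParams, WINNING_FORM,
                     code_effort, sv_delay)
from .sampling import adapt_scales, slice_sample, spawn_seeds

PARAMS = SubjectParams.PARAM_NAMES
#: printed row order of the group-level summary tables
PARAM_ORDER = list(PARAMS)


# --------------------------------------------------------------------------
# priors and sampler settings

@dataclass(frozen=True)
class ParamPrior:
    """Normal prior on the group mean and half-normal prior on the group SD."""
    mean_loc: float
    mean_scale: float
    sd_scale: float


@dataclass(frozen=True)
class PriorSpec:
    priors: Dict[str, ParamPrior]

    def __post_init__(self):
        for p in PARAMS:
            if p not in self.priors:
                raise ValueError(f"missing prior for {p!r}")
            pr = self.priors[p]
            if pr.mean_scale <= 0 or pr.sd_scale <= 0:
                raise ValueError(f"prior scales for {p!r} must be positive")

    @classmethod
    def default(cls, task_kind: str) -> "PriorSpec":
        """Weakly informative priors on the scale of each task.

        Effort kappa is a raw quadratic weight near 0.1; delay kappa lives in
        log space near -4.  Group-SD priors are half-normal with half the
        corresponding mean-prior scale.
        """
        if task_kind == "effort":
            kappa = ParamPrior(0.05, 0.1, 0.05)
        elif task_kind == "delay":
            kappa = ParamPrior(-4.0, 2.0, 1.0)
        else:
            raise ValueError(f"unknown task_kind {task_kind!r}")
        beta = ParamPrior(0.5, 0.5, 0.25)
        shift = ParamPrior(0.0, 0.5, 0.25)
        return cls({"kappa": kappa, "beta": beta,
                    "s_kappa_hal": shift, "s_kappa_bip": shift,
                    "s_beta_hal": shift, "s_beta_bip": shift})

    def to_file(self, path) -> str:
        payload = {p: dataclasses.asdict(pr) for p, pr in self.priors.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return str(path)

    @classmethod
    def from_file(cls, path) -> "PriorSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls({p: ParamPrior(**v) for p, v in payload.items()})


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    warmup: int = 3000
    draws: int = 4000
    seed: int = 0


PRESETS = {
    "full": dict(chains=4, warmup=3000, draws=4000),
    "medium": dict(chains=4, warmup=1000, draws=1000),
    "fast": dict(chains=2, warmup=500, draws=500),
}


def preset(name: str, seed: int = 0) -> SamplerSettings:
    return SamplerSettings(seed=seed, **PRESETS[name])


# --------------------------------------------------------------------------
# data preparation and vectorised likelihood

@dataclass
class _TaskData:
    subj_idx: np.ndarray
    ih: np.ndarray
    ib: np.ndarray
    r_hc: np.ndarray
    c_hc: np.ndarray  # model units (coded effort / days)
    r_lc: np.ndarray
    c_lc: np.ndarray
    choice: np.ndarray
    n_subjects: int
    subject_ids: list
    task_kind: str
    form: str
    active: np.ndarray  # bool mask over the 6 parameters
    prior_only: bool = False
    # precomputed pieces of the SV difference (set in __post_init__)
    dr: np.ndarray = field(default=None, repr=False)
    dc: np.ndarray = field(default=None, repr=False)
    dc2: np.ndarray = field(default=None, repr=False)
    c_hc2: np.ndarray = field(default=None, repr=False)
    xsign: np.ndarray = field(default=None, repr=False)
    lc_zero: bool = False

    cell: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.dr = self.r_hc - self.r_lc
        self.dc = self.c_hc - self.c_lc
        self.dc2 = self.c_hc ** 2 - self.c_lc ** 2
        self.c_hc2 = self.c_hc ** 2
        self.xsign = np.where(self.choice == 1, 1.0, -1.0)
        self.lc_zero = bool(np.all(self.c_lc == 0))
        # flat (subject, condition) cell index: 3 cells per subject
        cond_idx = (self.ih + 2 * self.ib).astype(np.intp)
        self.cell = self.subj_idx.astype(np.intp) * 3 + cond_idx


def _prepare(data: pd.DataFrame, form: str, task_kind: str,
             effort_coding: str, prior_only: bool) -> _TaskData:
    if "condition" not in data.columns:
        raise ValueError("trial table lacks a condition column")
    subject_ids = sorted(data["subject_id"].astype(str).unique())
    sid_to_idx = {s: i for i, s in enumerate(subject_ids)}
    subj_idx = data["subject_id"].astype(str).map(sid_to_idx).to_numpy()
    cond = data["condition"].to_numpy()
    ih = (cond == "HAL").astype(float)
    ib = (cond == "BIP").astype(float)
    choice = data["choice"].to_numpy(float)
    if not prior_only and np.any(np.isnan(choice)):
        raise ValueError("trial table has missing choices")
    c_hc = data["c_hc"].to_numpy(float)
    c_lc = data["c_lc"].to_numpy(float)
    if task_kind == "effort":
        c_hc = code_effort(c_hc, effort_coding)
        c_lc = code_effort(c_lc, effort_coding)
    # shifts active only when their condition occurs in the data
    active = np.array([True, True, bool(ih.any()), bool(ib.any()),
                       bool(ih.any()), bool(ib.any())])
    return _TaskData(subj_idx, ih, ib,
                     data["r_hc"].to_numpy(float), c_hc,
                     data["r_lc"].to_numpy(float), c_lc,
                     choice, len(subject_ids), subject_ids, task_kind, form,
                     active, prior_only)


_LOG_CLIP_LO = float(np.log(P_CLIP))
_LOG_CLIP_HI = float(np.log1p(-P_CLIP))


def _pointwise_loglik(d: _TaskData, theta: np.ndarray) -> np.ndarray:
    """Per-trial Bernoulli log-likelihood for a subject-parameter matrix.

    Hot path of the sampler: SV differences use precomputed trial terms
    (the delay task's low-cost option is the fixed immediate reward, so its
    SV is constant), and log sigma(+-x) is one logaddexp.  Equals
    log(clip(p)) from the public softmax rule up to float rounding.
    """
    # resolve per-(subject, condition) parameters on the small S x 3 grid,
    # then gather once per trial
    K = np.column_stack([theta[:, 0], theta[:, 0] + theta[:, 2],
                         theta[:, 0] + theta[:, 3]]).ravel()
    B = np.column_stack([theta[:, 1], theta[:, 1] + theta[:, 4],
                         theta[:, 1] + theta[:, 5]]).ravel()
    kappa = K[d.cell]
    beta = np.maximum(B[d.cell], BETA_FLOOR)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if d.task_kind == "effort":
            if d.form == "parabolic":
                dsv = d.dr - kappa * d.dc2
            elif d.form == "linear":
                dsv = d.dr - kappa * d.dc
            elif d.form == "hyperbolic":
                dsv = d.r_hc / (1.0 + kappa * d.c_hc) - \
                    d.r_lc / (1.0 + kappa * d.c_lc)
            else:
                dsv = d.r_hc * np.exp(-kappa * d.c_hc) - \
                    d.r_lc * np.exp(-kappa * d.c_lc)
        else:
            rate = np.exp(kappa)
            if d.form == "hyperbolic":
                sv_hc = d.r_hc / (1.0 + rate * d.c_hc)
            elif d.form == "linear":
                sv_hc = d.r_hc - rate * d.c_hc
            elif d.form == "exponential":
                sv_hc = d.r_hc * np.exp(-rate * d.c_hc)
            else:
                sv_hc = d.r_hc - rate * d.c_hc2
            if d.lc_zero:
                dsv = sv_hc - d.r_lc
            else:
                dsv = sv_hc - sv_delay(d.form, kappa, d.r_lc, d.c_lc)
        ll = -np.logaddexp(0.0, -d.xsign * beta * dsv)
        ll.clip(_LOG_CLIP_LO, _LOG_CLIP_HI, out=ll)
    return np.where(np.isfinite(ll), ll, -1e12)


def _subject_loglik(d: _TaskData, theta: np.ndarray) -> np.ndarray:
    if d.prior_only:
        return np.zeros(d.n_subjects)
    out = np.bincount(d.subj_idx, _pointwise_loglik(d, theta),
                      minlength=d.n_subjects)
    # a non-finite subject sum (wild proposal) is a sure rejection
    return np.where(np.isfinite(out), out, -np.inf)


# --------------------------------------------------------------------------
# fit result container

@dataclass
class FitResult:
    """Posterior draws and metadata from one hierarchical fit.

    ``group`` maps e.g. ``"kappa"`` -> (chain, draw) group-mean draws and
    ``"sigma_kappa"`` -> group-SD draws; ``subject`` maps parameter name ->
    (chain, draw, subject) arrays.  Inactive shift parameters (conditions
    absent from the data) are omitted.
    """

    task_kind: str
    form: str
    group: Dict[str, np.ndarray]
    subject: Dict[str, np.ndarray]
    subject_ids: list
    settings: SamplerSettings
    priors: PriorSpec
    effort_coding: str
    accept_rate: float
    _data: Optional[_TaskData] = field(default=None, repr=False)

    @property
    def active_params(self) -> list:
        return [p for p in PARAM_ORDER if p in self.group]

    def group_draws(self, param: str) -> np.ndarray:
        return self.group[param]

    def subject_means(self, param: str) -> np.ndarray:
        """Posterior mean per subject, in subject_ids order."""
        return self.subject[param].mean(axis=(0, 1))

    def to_inference_data(self) -> az.InferenceData:
        post = {k: v for k, v in self.group.items()}
        for p, v in self.subject.items():
            post[f"subj_{p}"] = v
        return az.from_dict(posterior=post)

    def pointwise_loglik(self, max_draws: int = 1000) -> np.ndarray:
        """(chain, draw, trial) log-likelihoods on a thinned draw grid."""
        if self._data is None:
            raise ValueError("fit was loaded without trial data attached")
        chains, draws = self.group[self.active_params[0]].shape
        per_chain = max(1, min(draws, max_draws // chains))
        idx = np.linspace(0, draws - 1, per_chain).round().astype(int)
        n_trials = len(self._data.choice)
        out = np.empty((chains, per_chain, n_trials))
        for c in range(chains):
            for j, dr in enumerate(idx):
                theta = np.zeros((len(self.subject_ids), 6))
                for k, p in enumerate(PARAMS):
                    if p in self.subject:
                        theta[:, k] = self.subject[p][c, dr]
                out[c, j] = _pointwise_loglik(self._data, theta)
        return out

    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for p in self.active_params:
            rows.append({"param": p, "rhat": rhat(self.group[p]),
                         "rhat_sd": rhat(self.group[f"sigma_{p}"])})
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        d = self.diagnostics()
        return float(np.nanmax(d[["rhat", "rhat_sd"]].to_numpy()))

    def save(self, directory) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            d / "draws.npz",
            **{f"group__{k}": v for k, v in self.group.items()},
            **{f"subject__{k}": v for k, v in self.subject.items()})
        summarize(self).to_csv(d / "summary.csv", index=False)
        self.diagnostics().to_csv(d / "diagnostics.csv", index=False)
        meta = {"task_kind": self.task_kind, "form": self.form,
                "subject_ids": self.subject_ids,
                "effort_coding": self.effort_coding,
                "accept_rate": self.accept_rate,
                "settings": dataclasses.asdict(self.settings)}
        with open(d / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        self.priors.to_file(d / "priors.json")

    @classmethod
    def load(cls, directory) -> "FitResult":
        d = pathlib.Path(directory)
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        arrs = np.load(d / "draws.npz")
        group = {k.split("__", 1)[1]: arrs[k] for k in arrs.files
                 if k.startswith("group__")}
        subject = {k.split("__", 1)[1]: arrs[k] for k in arrs.files
                   if k.startswith("subject__")}
        return cls(meta["task_kind"], meta["form"], group, subject,
                   meta["subject_ids"],
                   SamplerSettings(**meta["settings"]),
                   PriorSpec.from_file(d / "priors.json"),
                   meta["effort_coding"], meta["accept_rate"])


# --------------------------------------------------------------------------
# the sampler

def fit_hierarchical(data: pd.DataFrame, form: Optional[str] = None,
                     task_kind: Optional[str] = None,
                     priors: Optional[PriorSpec] = None,
                     settings: Optional[SamplerSettings] = None,
                     effort_coding: str = "decile",
                     prior_only: bool = False) -> FitResult:
    """Fit the hierarchical discounting model by Metropolis-within-Gibbs.

    With ``prior_only=True`` the likelihood is switched off and the sampler
    targets the prior, which is useful as a prior-predictive sanity check.
    """
    if task_kind is None:
        task_kind = str(data["task_kind"].iloc[0])
    form = form or WINNING_FORM[task_kind]
    priors = priors or PriorSpec.default(task_kind)
    settings = settings or SamplerSettings()
    d = _prepare(data, form, task_kind, effort_coding, prior_only)

    act = np.flatnonzero(d.active)
    prior_loc = np.array([priors.priors[p].mean_loc for p in PARAMS])
    prior_scale = np.array([priors.priors[p].mean_scale for p in PARAMS])
    sd_scale = np.array([priors.priors[p].sd_scale for p in PARAMS])

    chains = settings.chains
    n_keep = settings.draws
    n_warm = settings.warmup
    seeds = spawn_seeds(settings.seed, chains)

    g_mu = np.empty((chains, n_keep, 6))
    g_sigma = np.empty((chains, n_keep, 6))
    s_theta = np.empty((chains, n_keep, d.n_subjects, 6))
    accepts = []

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        mu = prior_loc + 0.5 * prior_scale * rng.standard_normal(6)
        sigma = sd_scale * (0.5 + 0.5 * rng.random(6))
        mu[~d.active] = 0.0
        sigma[~d.active] = 1.0
        theta = np.tile(mu, (d.n_subjects, 1))
        theta[:, act] += 0.1 * sigma[act] * rng.standard_normal(
            (d.n_subjects, len(act)))
        ll = _subject_loglik(d, theta)
        log_step = np.log(np.maximum(0.3 * sigma, 1e-3))
        log_step = np.tile(log_step, (d.n_subjects, 1))
        # step sizes for the joint translation / rescale moves
        log_tstep = np.log(np.maximum(sd_scale / np.sqrt(d.n_subjects), 1e-4))
        log_sstep = np.full(6, np.log(0.3))
        n_acc = 0
        n_prop = 0

        for it in range(n_warm + n_keep):
            warm = it < n_warm
            # subject-level component-wise Metropolis
            for k in act:
                prop = theta.copy()
                prop[:, k] = theta[:, k] + np.exp(log_step[:, k]) * \
                    rng.standard_normal(d.n_subjects)
                ll_prop = _subject_loglik(d, prop)
                dprior = (-(prop[:, k] - mu[k]) ** 2 +
                          (theta[:, k] - mu[k]) ** 2) / (2 * sigma[k] ** 2)
                log_r = ll_prop - ll + dprior
                accept = np.log(rng.random(d.n_subjects)) < log_r
                theta[accept, k] = prop[accept, k]
                ll = np.where(accept, ll_prop, ll)
                if warm:
                    adapt_scales(log_step[:, k], accept, it)
                else:
                    n_acc += int(accept.sum())
                    n_prop += d.n_subjects
            # group means: conjugate normal draw
            for k in act:
                prec = 1.0 / prior_scale[k] ** 2 + d.n_subjects / sigma[k] ** 2
                m = (prior_loc[k] / prior_scale[k] ** 2 +
                     theta[:, k].sum() / sigma[k] ** 2) / prec
                mu[k] = m + rng.standard_normal() / np.sqrt(prec)
            # joint translation: move the group mean and every subject value
            # together; breaks the mu/theta coupling that stalls centered
            # hierarchies when the group SD is small.  Repeated because these
            # two moves dominate the autocorrelation of the group parameters.
            for _rep in range(2):
                for k in act:
                    delta = np.exp(log_tstep[k]) * rng.standard_normal()
                    prop = theta.copy()
                    prop[:, k] += delta
                    ll_prop = _subject_loglik(d, prop)
                    dprior = (-(mu[k] + delta - prior_loc[k]) ** 2 +
                              (mu[k] - prior_loc[k]) ** 2) / \
                        (2 * prior_scale[k] ** 2)
                    accept = np.log(rng.random()) < \
                        ll_prop.sum() - ll.sum() + dprior
                    if accept:
                        theta, ll = prop, ll_prop
                        mu[k] += delta
                    if warm:
                        adapt_scales(log_tstep[k:k + 1], np.array([accept]),
                                     it)
                # joint rescale: scale the group SD and all subject
                # deviations; the normal-density change cancels the Jacobian
                # exactly, leaving only the likelihood, the half-normal prior
                # and one log-sigma term
                for k in act:
                    gamma = np.exp(log_sstep[k]) * rng.standard_normal()
                    scale = np.exp(gamma)
                    prop = theta.copy()
                    prop[:, k] = mu[k] + (theta[:, k] - mu[k]) * scale
                    ll_prop = _subject_loglik(d, prop)
                    sig_new = sigma[k] * scale
                    dprior = (sigma[k] ** 2 - sig_new ** 2) / \
                        (2 * sd_scale[k] ** 2)
                    accept = np.log(rng.random()) < \
                        ll_prop.sum() - ll.sum() + dprior + gamma
                    if accept:
                        theta, ll = prop, ll_prop
                        sigma[k] = sig_new
                    if warm:
                        adapt_scales(log_sstep[k:k + 1], np.array([accept]),
                                     it)
            # group SDs: slice sample log sigma
            for k in act:
                ssq = float(np.sum((theta[:, k] - mu[k]) ** 2))
                ns, hs = d.n_subjects, sd_scale[k]

                def logpost(t, ssq=ssq, ns=ns, hs=hs):
                    s2 = np.exp(2 * t)
                    return (1 - ns) * t - ssq / (2 * s2) - s2 / (2 * hs ** 2)

                sigma[k] = float(np.exp(
                    slice_sample(float(np.log(sigma[k])), logpost, rng)))
            if not warm:
                j = it - n_warm
                g_mu[c, j] = mu
                g_sigma[c, j] = sigma
                s_theta[c, j] = theta
        accepts.append(n_acc / max(n_prop, 1))

    group = {}
    subject = {}
    for k, p in enumerate(PARAMS):
        if d.active[k]:
            group[p] = g_mu[:, :, k]
            group[f"sigma_{p}"] = g_sigma[:, :, k]
            subject[p] = s_theta[:, :, :, k]
    return FitResult(task_kind, form, group, subject, d.subject_ids,
                     settings, priors, effort_coding,
                     float(np.mean(accepts)), d)


# --------------------------------------------------------------------------
# posterior summaries and diagnostics

@dataclass(frozen=True)
class HdiInterval:
    lower: float
    upper: float
    mass: float
    mean: float


def hdi(samples, mass: float = 0.95) -> HdiInterval:
    """Narrowest contiguous interval holding ``mass`` of the draws."""
    x = np.asarray(samples, float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite samples")
    if np.ptp(x) == 0:
        return HdiInterval(float(x[0]), float(x[0]), mass, float(x[0]))
    x.sort()
    n = x.size
    k = min(n, max(1, int(np.ceil(mass * n))))
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return HdiInterval(float(x[j]), float(x[j + k - 1]), mass,
                       float(x.mean()))


def rhat(draws_by_chain, method: str = "rank") -> float:
    """Split-chain potential scale reduction factor.

    ``method="rank"`` is the rank-normalised split r-hat; ``method="split"``
    is the classic between/within-variance formula on split chains.
    """
    x = np.asarray(draws_by_chain, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need draws shaped (chains >= 2, draws >= 2)")
    return float(az.rhat(az.from_dict(posterior={"x": x}),
                         method=method)["x"].values)


def summarize(fit: FitResult, mass: float = 0.95) -> pd.DataFrame:
    """Group-level parameter table: mean, SD, HDI bounds, r-hat, P(>0)."""
    rows = []
    multi = fit.settings.chains >= 2
    for p in fit.active_params:
        draws = fit.group[p]
        iv = hdi(draws, mass)
        rows.append({
            "param": p,
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)),
            "hdi_2.5%": iv.lower,
            "hdi_97.5%": iv.upper,
            "rhat": rhat(draws) if multi else np.nan,
            "p_gt_zero": float((draws > 0).mean()),
        })
    return pd.DataFrame(rows)
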