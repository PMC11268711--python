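"""Subjective-value discounting models, drug-shift parameterisation, and the
softmax choice rule.

The winning forms in each task are parabolic (effort) and hyperbolic (delay);
linear and exponential alternatives use their standard textbook definitions.
The delay discount rate is parameterised as ``exp(kappa)`` for every form so
that kappa lives in log space and additive drug shifts act uniformly.

Effort enters the model in *decile* units of maximum voluntary contraction by
default (0-80% MVC -> 0-8): with rewards on the 2-16 apple scale this makes a
discounting parameter kappa ~ 0.1 produce devaluations commensurate with the
reward range. Other codings are available via :func:`code_effort`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

FORMS = ("linear", "parabolic", "hyperbolic", "exponential")

#: selected forms per task
WINNING_FORM = {"effort": "parabolic", "delay": "hyperbolic"}

#: floor applied to a condition-resolved inverse temperature
BETA_FLOOR = 1e-6

#: probability clamp before taking logs
P_CLIP = 1e-12

EFFORT_CODINGS = ("fraction", "percent", "decile", "level_index")


def code_effort(effort_fraction, coding: str = "decile"):
    """Convert an effort given as a fraction of MVC into model units."""
    e = np.asarray(effort_fraction, float)
    if coding == "fraction":
        return e
    if coding == "percent":
        return e * 100.0
    if coding == "decile":
        return e * 10.0
    if coding == "level_index":
        # 0, 0.2, ..., 0.8 -> 0..4
        return e * 5.0
    raise ValueError(f"unknown effort coding {coding!r}")


class ResolvedParams(NamedTuple):
    kappa: float
    beta: float
    beta_clipped: bool


@dataclass(frozen=True)
class SubjectParams:
    """One subject's generative parameters.

    ``kappa_plc`` is on the raw scale for the effort task and in log space for
    the delay task; the four shifts are additive on the same scale as their
    placebo parameter.
    """

    kappa_plc: float
    beta_plc: float
    s_kappa_hal: float = 0.0
    s_kappa_bip: float = 0.0
    s_beta_hal: float = 0.0
    s_beta_bip: float = 0.0

    PARAM_NAMES = ("kappa", "beta", "s_kappa_hal", "s_kappa_bip",
                   "s_beta_hal", "s_beta_bip")

    def as_array(self) -> np.ndarray:
        return np.array([self.kappa_plc, self.beta_plc, self.s_kappa_hal,
                         self.s_kappa_bip, self.s_beta_hal, self.s_beta_bip])

    @classmethod
    def from_array(cls, a) -> "SubjectParams":
        return cls(*[float(x) for x in a])


def resolve_condition(params: SubjectParams, condition: str) -> ResolvedParams:
    """Apply the drug-condition shift indicators to kappa and beta.

    Placebo is the reference: under PLC both indicators are zero.  The
    resolved beta is floored at ``BETA_FLOOR`` (flagged) because the additive
    shift is unconstrained but the softmax scale must stay positive.
    """
    if condition not in ("PLC", "HAL", "BIP"):
        raise ValueError(f"unknown condition {condition!r}")
    ih = 1.0 if condition == "HAL" else 0.0
    ib = 1.0 if condition == "BIP" else 0.0
    kappa = params.kappa_plc + ih * params.s_kappa_hal + ib * params.s_kappa_bip
    beta = params.beta_plc + ih * params.s_beta_hal + ib * params.s_beta_bip
    clipped = beta < BETA_FLOOR
    return ResolvedParams(kappa, max(beta, BETA_FLOOR), bool(clipped))


def sv_delay(form: str, kappa, reward, delay):
    """Subjective value of a delayed reward; the rate is exp(kappa).

    hyperbolic: R / (1 + exp(k) * D)      linear:      R - exp(k) * D
    exponential: R * exp(-exp(k) * D)     parabolic:   R - exp(k) * D**2
    """
    reward = np.asarray(reward, float)
    delay = np.asarray(delay, float)
    if np.any(delay < 0):
        raise ValueError("delay must be non-negative")
    rate = np.exp(np.asarray(kappa, float))
    if form == "hyperbolic":
        return reward / (1.0 + rate * delay)
    if form == "linear":
        return reward - rate * delay
    if form == "exponential":
        return reward * np.exp(-rate * delay)
    if form == "parabolic":
        return reward - rate * delay ** 2
    raise ValueError(f"unknown form {form!r}")


def sv_effort(form: str, kappa, reward, effort):
    """Subjective value of an effortful reward; effort in coded units.

    parabolic: R - k * E**2               linear:      R - k * E
    hyperbolic: R / (1 + k * E)           exponential: R * exp(-k * E)
    """
    reward = np.asarray(reward, float)
    effort = np.asarray(effort, float)
    if np.any(effort < 0):
        raise ValueError("effort must be non-negative")
    k = np.asarray(kappa, float)
    if form == "parabolic":
        return reward - k * effort ** 2
    if form == "linear":
        return reward - k * effort
    if form == "hyperbolic":
        return reward / (1.0 + k * effort)
    if form == "exponential":
        return reward * np.exp(-k * effort)
    raise ValueError(f"unknown form {form!r}")


def subjective_values(form: str, task_kind: str, kappa, table: pd.DataFrame,
                      effort_coding: str = "decile"):
    """(sv_hc, sv_lc) for every row of a trial table.

    For the delay task the low-cost option is the fixed immediate reward, so
    its SV equals its face value under every form.
    """
    if task_kind == "delay":
        sv_hc = sv_delay(form, kappa, table["r_hc"].to_numpy(),
                         table["c_hc"].to_numpy())
        sv_lc = sv_delay(form, kappa, table["r_lc"].to_numpy(),
                         table["c_lc"].to_numpy())
    elif task_kind == "effort":
        e_hc = code_effort(table["c_hc"].to_numpy(), effort_coding)
        e_lc = code_effort(table["c_lc"].to_numpy(), effort_coding)
        sv_hc = sv_effort(form, kappa, table["r_hc"].to_numpy(), e_hc)
        sv_lc = sv_effort(form, kappa, table["r_lc"].to_numpy(), e_lc)
    else:
        raise ValueError(f"unknown task_kind {task_kind!r}")
    return sv_hc, sv_lc


def p_choose_hc(sv_hc, sv_lc, beta):
    """Softmax probability of choosing the high-cost option.

    Computed as logistic(beta * (sv_hc - sv_lc)), which is the overflow-safe
    rewrite of exp(b*sv_hc) / (exp(b*sv_hc) + exp(b*sv_lc)).
    """
    sv_hc = np.asarray(sv_hc, float)
    sv_lc = np.asarray(sv_lc, float)
    if not (np.all(np.isfinite(sv_hc)) and np.all(np.isfinite(sv_lc))):
        raise ValueError("subjective values must be finite")
    x = np.asarray(beta, float) * (sv_hc - sv_lc)
    # stable logistic
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return np.clip(out, P_CLIP, 1.0 - P_CLIP)


def trial_loglik(form: str, params: SubjectParams, condition: str,
                 table: pd.DataFrame, task_kind: str | None = None,
                 effort_coding: str = "decile") -> float:
    """Summed Bernoulli log-likelihood of the observed choices in ``table``."""
    if task_kind is None:
        task_kind = str(table["task_kind"].iloc[0])
    choice = table["choice"].to_numpy(float)
    if np.any(np.isnan(choice)):
        raise ValueError("table has missing choices")
    kappa, beta, _ = resolve_condition(params, condition)
    sv_hc, sv_lc = subjective_values(form, task_kind, kappa, table,
                                     effort_coding)
    p = p_choose_hc(sv_hc, sv_lc, beta)
    return float(np.sum(np.where(choice == 1, np.log(p), np.log1p(-p))))
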