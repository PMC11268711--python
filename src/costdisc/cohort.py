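"""Synthetic cohorts with the statistical structure of a within-subject
pharmacological crossover study.

62 subjects each complete an effort session (125 trials) and a delay session
(210 trials) under three drug conditions (placebo, haloperidol, biperiden).
Choices are generated from the winning discounting form (parabolic for effort,
hyperbolic for delay) with softmax stochasticity, subject-level parameter
heterogeneity, and additive condition shifts.

Default population means are literature-reported group-level estimates for
these two tasks; they are estimates adopted as a plausible generative
population, not ground truth.  Between-subject SDs are not available from
the literature, so the defaults are the package's own choices: a moderate
spread for kappa and beta and, for each shift, half the magnitude of its
population mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import task_design as td
from .models import SubjectParams, WINNING_FORM, resolve_condition, \
    subjective_values, p_choose_hc

PARAMS = SubjectParams.PARAM_NAMES


@dataclass(frozen=True)
class GroupTruth:
    """Population means/SDs for the six subject-level parameters."""

    task_kind: str
    mean: Dict[str, float]
    sd: Dict[str, float]
    n_subjects: int = 62
    form: Optional[str] = None

    def __post_init__(self):
        for p in PARAMS:
            if p not in self.mean or p not in self.sd:
                raise ValueError(f"missing mean/sd for parameter {p!r}")
            if self.sd[p] < 0:
                raise ValueError(f"negative SD for parameter {p!r}")
        if self.form is None:
            object.__setattr__(self, "form", WINNING_FORM[self.task_kind])

    def to_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        return str(path)

    @classmethod
    def from_json(cls, path) -> "GroupTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_effort_truth(n_subjects: int = 62) -> GroupTruth:
    """Generative population for the effort task (parabolic form)."""
    mean = {"kappa": 0.102, "beta": 0.667, "s_kappa_hal": 0.013,
            "s_kappa_bip": -0.012, "s_beta_hal": -0.089, "s_beta_bip": 0.127}
    sd = {"kappa": 0.04, "beta": 0.20,
          "s_kappa_hal": abs(mean["s_kappa_hal"]) / 2,
          "s_kappa_bip": abs(mean["s_kappa_bip"]) / 2,
          "s_beta_hal": abs(mean["s_beta_hal"]) / 2,
          "s_beta_bip": abs(mean["s_beta_bip"]) / 2}
    return GroupTruth("effort", mean, sd, n_subjects)


def default_delay_truth(n_subjects: int = 62) -> GroupTruth:
    """Generative population for the delay task (hyperbolic form, log-kappa)."""
    mean = {"kappa": -4.621, "beta": 0.356, "s_kappa_hal": -0.630,
            "s_kappa_bip": -0.125, "s_beta_hal": -0.055, "s_beta_bip": -0.043}
    sd = {"kappa": 1.0, "beta": 0.12,
          "s_kappa_hal": abs(mean["s_kappa_hal"]) / 2,
          "s_kappa_bip": abs(mean["s_kappa_bip"]) / 2,
          "s_beta_hal": abs(mean["s_beta_hal"]) / 2,
          "s_beta_bip": abs(mean["s_beta_bip"]) / 2}
    return GroupTruth("delay", mean, sd, n_subjects)


def draw_subjects(truth: GroupTruth, seed: int) -> Dict[str, SubjectParams]:
    """Independent normal draws per parameter; subject ids s01, s02, ..."""
    if truth.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(truth.n_subjects)))
    out: Dict[str, SubjectParams] = {}
    draws = {p: rng.normal(truth.mean[p], truth.sd[p], truth.n_subjects)
             for p in PARAMS}
    for i in range(truth.n_subjects):
        sid = f"s{i + 1:0{width}d}"
        out[sid] = SubjectParams(*(float(draws[p][i]) for p in PARAMS))
    return out


def simulate_choices(params: SubjectParams, condition: str,
                     design: pd.DataFrame, form: str, seed: int,
                     effort_coding: str = "decile") -> pd.DataFrame:
    """Fill in Bernoulli choices on a design table (which must lack them)."""
    if not design["choice"].isna().all():
        raise ValueError("design table already has choices")
    task_kind = str(design["task_kind"].iloc[0])
    kappa, beta, _ = resolve_condition(params, condition)
    sv_hc, sv_lc = subjective_values(form, task_kind, kappa, design,
                                     effort_coding)
    p = p_choose_hc(sv_hc, sv_lc, beta)
    rng = np.random.default_rng(seed)
    out = design.copy()
    out["condition"] = condition
    out["choice"] = (rng.random(len(design)) < p).astype(float)
    return out


@dataclass
class Cohort:
    """One simulated task: subject parameters plus all-session trial table."""

    task_kind: str
    subjects: Dict[str, SubjectParams]
    trials: pd.DataFrame
    truth: GroupTruth
    seed: int

    def params_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": sid, **dict(zip(PARAMS, sp.as_array()))}
                for sid, sp in self.subjects.items()]
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        td.write_trials(self.trials, d / f"{self.task_kind}_trials.csv")
        self.params_frame().to_csv(d / f"{self.task_kind}_params.csv",
                                   index=False)
        self.truth.to_json(d / f"{self.task_kind}_truth.json")


def simulate_task_cohort(truth: GroupTruth, seed: int,
                         effort_coding: str = "decile",
                         form: Optional[str] = None) -> Cohort:
    """Simulate one task for a whole cohort across all three conditions.

    Session order per subject is a seeded permutation of the conditions;
    session index feeds the delay-task counterbalancing.
    """
    form = form or truth.form
    subjects = draw_subjects(truth, seed)
    master = np.random.default_rng([seed & 0x7FFFFFFF, 1])
    pieces = []
    for i, (sid, sp) in enumerate(subjects.items()):
        order = master.permutation(list(td.CONDITIONS))
        for session_index, condition in enumerate(order, start=1):
            dseed = int(master.integers(0, 2**31 - 1))
            cseed = int(master.integers(0, 2**31 - 1))
            if truth.task_kind == "effort":
                design = td.build_effort_design(td.effort_spec(), dseed,
                                                subject_id=sid)
            else:
                design = td.build_delay_design(td.delay_spec(), session_index,
                                               dseed, subject_id=sid)
            sim = simulate_choices(sp, condition, design, form, cseed,
                                   effort_coding)
            sim["session"] = session_index
            pieces.append(sim)
    trials = pd.concat(pieces, ignore_index=True)
    return Cohort(truth.task_kind, subjects, trials, truth, seed)


def simulate_study(truth_effort: Optional[GroupTruth] = None,
                   truth_delay: Optional[GroupTruth] = None,
                   seed: int = 0) -> Tuple[Cohort, Cohort]:
    """Full two-task study; defaults emulate the 62-subject design."""
    truth_effort = truth_effort or default_effort_truth()
    truth_delay = truth_delay or default_delay_truth()
    eff = simulate_task_cohort(truth_effort, seed)
    del_ = simulate_task_cohort(truth_delay, seed + 1)
    return eff, del_
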