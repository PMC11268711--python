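"""End-to-end orchestration: simulate (or ingest) -> compare forms -> fit the
winning form -> validate and recover -> regress -> correlate, with a
machine-readable manifest of seeds, stages and outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as ch
from . import task_design as td
from .hierfit import (FitResult, PriorSpec, fit_hierarchical,
                      preset, summarize, PARAM_ORDER)
from .models import FORMS, WINNING_FORM
from .regression import (RegressionSpec, build_design, credible_effects,
                         fit_glmm, glmm_preset)
from .sampling import spawn_seeds
from .selection import compare_forms
from .validation import (bayesian_correlation, choice_curve_summaries,
                         posterior_predictive_datasets, recover_group,
                         recover_subjects)

log = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.01


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "costdisc_run"
    n_subjects: int = 62
    tasks: Tuple[str, ...] = ("effort", "delay")
    preset: str = "fast"
    glmm: str = "fast"
    forms: Tuple[str, ...] = FORMS
    n_pp_total: int = 500
    n_pp_selected: int = 10
    trials_effort: Optional[str] = None   # ingest instead of simulating
    trials_delay: Optional[str] = None
    priors_effort: Optional[str] = None
    priors_delay: Optional[str] = None
    regression_extras: Tuple[str, ...] = ()

    def validate(self) -> None:
        if self.preset not in ("full", "medium", "fast"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.glmm not in ("full", "fast"):
            raise ValueError(f"unknown GLMM preset {self.glmm!r}")
        unknown = set(self.tasks) - {"effort", "delay"}
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")
        for f in self.forms:
            if f not in FORMS:
                raise ValueError(f"unknown form {f!r}")

    def to_file(self, path) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)
        return str(path)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("tasks", "forms", "regression_extras"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def render_summary_tables(fits: Dict[str, FitResult], out_dir=None
                          ) -> Dict[str, pd.DataFrame]:
    """Tables in the printed layout: one ordered row per group-level
    parameter (kappa, beta, then the four shifts) with mean, SD and the 95%
    HDI bounds."""
    out = {}
    for task, fit in fits.items():
        if not fit.group:
            raise ValueError(f"empty fit for task {task!r}")
        table = summarize(fit)
        order = {p: i for i, p in enumerate(PARAM_ORDER)}
        table = table.sort_values(by="param",
                                  key=lambda s: s.map(order)).reset_index(drop=True)
        out[task] = table
        if out_dir is not None:
            d = pathlib.Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            table.to_csv(d / f"summary_{task}.csv", index=False)
            with open(d / f"summary_{task}.txt", "w") as fh:
                fh.write(table.to_string(index=False,
                                         float_format=lambda v: f"{v:.3f}"))
                fh.write("\n")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config": dataclasses.asdict(config), "stages": []}

    def _record(stage, t0, **info):
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - t0, 2), **info})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    seeds = spawn_seeds(config.seed, 8)
    trials: Dict[str, pd.DataFrame] = {}
    fits: Dict[str, FitResult] = {}
    try:
        # 1. simulate or ingest
        t0 = time.time()
        for task in config.tasks:
            path = getattr(config, f"trials_{task}")
            if path:
                trials[task] = td.read_trials(path)
            else:
                truth = (ch.default_effort_truth(config.n_subjects)
                         if task == "effort"
                         else ch.default_delay_truth(config.n_subjects))
                task_offset = {"effort": 0, "delay": 1}[task]
                co = ch.simulate_task_cohort(truth, seeds[0] + task_offset)
                co.save(out / "data")
                trials[task] = co.trials
        _record("simulate", t0, tasks=list(config.tasks))

        # 2. form comparison on the placebo subset
        t0 = time.time()
        for task in config.tasks:
            priors = _priors(config, task)
            comp = compare_forms(trials[task], config.forms, priors,
                                 preset(config.preset, seeds[1]),
                                 task_kind=task)
            comp.to_csv(out / f"comparison_{task}.csv", index=False)
        _record("compare", t0, forms=list(config.forms))

        # 3. hierarchical fit of the winning form
        t0 = time.time()
        max_rhats = {}
        for task in config.tasks:
            fit = fit_hierarchical(trials[task], WINNING_FORM[task], task,
                                   _priors(config, task),
                                   preset(config.preset, seeds[2]))
            fit.save(out / f"fit_{task}")
            fits[task] = fit
            max_rhats[task] = fit.max_rhat()
            if max_rhats[task] > RHAT_THRESHOLD:
                log.warning("%s fit: max r-hat %.3f exceeds %.2f",
                            task, max_rhats[task], RHAT_THRESHOLD)
        render_summary_tables(fits, out)
        _record("fit", t0, max_rhat=max_rhats)

        # 4. validation and recovery
        t0 = time.time()
        for task in config.tasks:
            fit = fits[task]
            design = trials[task].copy()
            design["choice"] = np.nan
            sims = posterior_predictive_datasets(
                fit, trials[task], config.n_pp_total, config.n_pp_selected,
                seeds[3])
            refits = [fit_hierarchical(s, fit.form, task,
                                       _priors(config, task),
                                       preset("fast", seeds[4] + i))
                      for i, s in enumerate(sims)]
            recover_group(refits, fit).to_csv(
                out / f"recovery_group_{task}.csv", index=False)
            recover_subjects(refits, fit).to_csv(
                out / f"recovery_subjects_{task}.csv", index=False)
            choice_curve_summaries(trials[task]).to_csv(
                out / f"choice_curves_{task}.csv", index=False)
        _record("validate", t0, n_selected=config.n_pp_selected)

        # 5. regression
        t0 = time.time()
        for task in config.tasks:
            spec = RegressionSpec(task, tuple(config.regression_extras))
            glmm = fit_glmm(build_design(trials[task], spec),
                            glmm_preset(config.glmm, seeds[5]))
            credible_effects(glmm).to_csv(out / f"effects_{task}.csv",
                                          index=False)
        _record("regress", t0)

        # 6. across-task correlation of placebo kappas
        t0 = time.time()
        if set(config.tasks) == {"effort", "delay"}:
            shared = sorted(set(fits["effort"].subject_ids) &
                            set(fits["delay"].subject_ids))
            ke = {s: m for s, m in zip(fits["effort"].subject_ids,
                                       fits["effort"].subject_means("kappa"))}
            kd = {s: m for s, m in zip(fits["delay"].subject_ids,
                                       fits["delay"].subject_means("kappa"))}
            corr = bayesian_correlation([ke[s] for s in shared],
                                        [kd[s] for s in shared],
                                        seed=seeds[6])
            with open(out / "across_task_correlation.json", "w") as fh:
                json.dump({"r_mean": corr.mean,
                           "hdi_lower": corr.interval.lower,
                           "hdi_upper": corr.interval.upper,
                           "credible": corr.credible, "n": len(shared)}, fh,
                          indent=1)
        _record("correlate", t0)
    except Exception as exc:  # persist partial progress, then re-raise
        _record("FAILED", time.time(), error=f"{type(exc).__name__}: {exc}")
        raise
    return manifest


def _priors(config: RunConfig, task: str) -> PriorSpec:
    path = getattr(config, f"priors_{task}")
    return PriorSpec.from_file(path) if path else PriorSpec.default(task)
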