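"""Experimental designs for the effort and delay discounting tasks.

Both tasks present a high-reward/high-cost (HC) against a low-reward/low-cost
(LC) option on every trial.  The effort task varies both options over 5 reward
levels (2-16 apples) and 5 effort levels (0-80% of the subject's maximum
voluntary contraction); the delay task pits a fixed immediate 20 EUR option
against 15 reward levels (20.20-260 EUR) crossed with 7 delays (1-60 days).

Trial tables are plain pandas DataFrames with a fixed column schema
(:data:`TRIAL_COLUMNS`); :func:`validate_trials` enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

EFFORT = "effort"
DELAY = "delay"
CONDITIONS = ("PLC", "HAL", "BIP")

TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "task_kind",
    "block",
    "trial_index",
    "r_hc",
    "c_hc",
    "r_lc",
    "c_lc",
    "choice",
]

DEFAULT_EFFORT_REWARDS = (2.0, 4.0, 8.0, 12.0, 16.0)
DEFAULT_EFFORT_COSTS = (0.0, 0.2, 0.4, 0.6, 0.8)
DEFAULT_DELAY_REWARDS = (
    20.20, 20.40, 21.0, 22.0, 24.0, 30.0, 36.0, 40.0,
    50.0, 60.0, 80.0, 100.0, 140.0, 200.0, 260.0,
)
DEFAULT_DELAY_COSTS = (1.0, 2.0, 3.0, 5.0, 8.0, 30.0, 60.0)


class DesignError(ValueError):
    """Invalid task specification."""


class SchemaError(ValueError):
    """Trial table violates the schema contract."""


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of one experimental design.

    ``low_cost_fixed`` is the constant immediate option of the delay task:
    (reward in EUR, cost in days).
    """

    task_kind: str
    reward_levels: Tuple[float, ...]
    cost_levels: Tuple[float, ...]
    n_blocks: int
    trials_per_block: int
    low_cost_fixed: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.task_kind not in (EFFORT, DELAY):
            raise DesignError(f"unknown task_kind {self.task_kind!r}")
        if len(set(self.reward_levels)) != len(self.reward_levels):
            raise DesignError("duplicate reward levels")
        if len(set(self.cost_levels)) != len(self.cost_levels):
            raise DesignError("duplicate cost levels")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise DesignError("n_blocks and trials_per_block must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def effort_spec(
    reward_levels: Sequence[float] = DEFAULT_EFFORT_REWARDS,
    cost_levels: Sequence[float] = DEFAULT_EFFORT_COSTS,
    n_blocks: int = 5,
    trials_per_block: int = 25,
) -> TaskSpec:
    """Default effort design: 125 trials in 5 blocks of 25."""
    return TaskSpec(EFFORT, tuple(reward_levels), tuple(cost_levels),
                    n_blocks, trials_per_block)


def delay_spec(
    reward_levels: Sequence[float] = DEFAULT_DELAY_REWARDS,
    cost_levels: Sequence[float] = DEFAULT_DELAY_COSTS,
    n_blocks: int = 2,
    low_cost_fixed: Tuple[float, float] = (20.0, 0.0),
) -> TaskSpec:
    """Default delay design: each block enumerates all 105 reward x delay pairs."""
    return TaskSpec(DELAY, tuple(reward_levels), tuple(cost_levels), n_blocks,
                    len(reward_levels) * len(cost_levels), low_cost_fixed)


def _empty_choice(n: int) -> np.ndarray:
    return np.full(n, np.nan)


def build_effort_design(spec: TaskSpec, seed: int,
                        subject_id: str = "s01",
                        condition: str = "PLC") -> pd.DataFrame:
    """Draw an effort-task session.

    Each trial independently draws an ordered reward pair (r_lc < r_hc) and an
    ordered effort pair (c_lc < c_hc) uniformly from the grid of ordered level
    pairs, so the HC option always dominates on reward and on cost.
    """
    if spec.task_kind != EFFORT:
        raise DesignError("spec.task_kind must be 'effort'")
    if len(spec.reward_levels) < 2 or len(spec.cost_levels) < 2:
        raise DesignError("need at least 2 levels on both dimensions")
    r = np.asarray(sorted(spec.reward_levels), float)
    c = np.asarray(sorted(spec.cost_levels), float)
    r_pairs = [(lo, hi) for i, lo in enumerate(r) for hi in r[i + 1:]]
    c_pairs = [(lo, hi) for i, lo in enumerate(c) for hi in c[i + 1:]]
    rng = np.random.default_rng(seed)
    n = spec.n_trials
    ri = rng.integers(0, len(r_pairs), size=n)
    ci = rng.integers(0, len(c_pairs), size=n)
    r_lo, r_hi = np.array(r_pairs)[ri].T
    c_lo, c_hi = np.array(c_pairs)[ci].T
    return pd.DataFrame({
        "subject_id": subject_id,
        "condition": condition,
        "task_kind": EFFORT,
        "block": np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block),
        "trial_index": np.arange(1, n + 1),
        "r_hc": r_hi, "c_hc": c_hi, "r_lc": r_lo, "c_lc": c_lo,
        "choice": _empty_choice(n),
    })[TRIAL_COLUMNS]


def build_delay_design(spec: TaskSpec, session_index: int, seed: int,
                       subject_id: str = "s01",
                       condition: str = "PLC") -> pd.DataFrame:
    """Draw a delay-task session.

    Every block contains each reward x delay combination exactly once; the
    within-block order is a seeded permutation keyed by (seed, session_index,
    block), so sessions share the same trial multiset in different orders.
    """
    if spec.task_kind != DELAY:
        raise DesignError("spec.task_kind must be 'delay'")
    if spec.low_cost_fixed is None:
        raise DesignError("delay spec requires low_cost_fixed")
    r = np.asarray(spec.reward_levels, float)
    d = np.asarray(spec.cost_levels, float)
    grid = np.array([(ri, di) for ri in r for di in d])
    if len(grid) != spec.trials_per_block:
        raise DesignError(
            f"trials_per_block ({spec.trials_per_block}) must equal the number "
            f"of reward x delay combinations ({len(grid)})")
    r_lc, c_lc = spec.low_cost_fixed
    blocks = []
    for b in range(1, spec.n_blocks + 1):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, session_index, b])
        order = rng.permutation(len(grid))
        blocks.append(grid[order])
    trials = np.concatenate(blocks)
    n = len(trials)
    return pd.DataFrame({
        "subject_id": subject_id,
        "condition": condition,
        "task_kind": DELAY,
        "block": np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block),
        "trial_index": np.arange(1, n + 1),
        "r_hc": trials[:, 0], "c_hc": trials[:, 1],
        "r_lc": float(r_lc), "c_lc": float(c_lc),
        "choice": _empty_choice(n),
    })[TRIAL_COLUMNS]


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Check the TrialTable schema; raise :class:`SchemaError` naming the
    offending column or row."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    bad_cond = set(table["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition value(s): {sorted(bad_cond)}")
    choice = table["choice"].to_numpy(float)
    ok = np.isnan(choice) | (choice == 0) | (choice == 1)
    if not ok.all():
        row = int(np.flatnonzero(~ok)[0])
        raise SchemaError(f"non-binary choice value at row {row}")
    dom = (table["r_hc"].to_numpy() > table["r_lc"].to_numpy()) & (
        table["c_hc"].to_numpy() > table["c_lc"].to_numpy())
    if not dom.all():
        row = int(np.flatnonzero(~dom)[0])
        raise SchemaError(
            f"row {row}: high-cost option must dominate on reward and cost")
    return table


def write_trials(table: pd.DataFrame, path) -> str:
    validate_trials(table)
    table.to_csv(path, index=False)
    return str(path)


def read_trials(path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={"subject_id": str, "condition": str, "task_kind": str},
    )
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    keep = TRIAL_COLUMNS + [c for c in ("session",) if c in table.columns]
    table = table[keep]
    table["block"] = table["block"].astype(int)
    table["trial_index"] = table["trial_index"].astype(int)
    for col in ("r_hc", "c_hc", "r_lc", "c_lc", "choice"):
        table[col] = table[col].astype(float)
    return validate_trials(table)
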