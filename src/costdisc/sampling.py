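"""Low-level MCMC building blocks shared by the hierarchical discounting fit
and the Bayesian GLMM: a univariate slice sampler and Robbins-Monro step-size
adaptation for component-wise random-walk Metropolis."""

from __future__ import annotations

from typing import Callable

import numpy as np

TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk proposals


def slice_sample(x0: float, logpdf: Callable[[float], float],
                 rng: np.random.Generator, w: float = 0.5,
                 max_steps: int = 50) -> float:
    """One update of Neal's stepping-out slice sampler on an unbounded axis."""
    f0 = logpdf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice sampler started at a zero-density point")
    log_y = f0 + np.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    steps = max_steps
    while steps > 0 and logpdf(lo) > log_y:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logpdf(hi) > log_y:
        hi += w
        steps -= 1
    while True:
        x1 = lo + rng.random() * (hi - lo)
        if logpdf(x1) > log_y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def adapt_scales(log_scale: np.ndarray, accepted: np.ndarray,
                 iteration: int, target: float = TARGET_ACCEPT) -> None:
    """In-place Robbins-Monro update of log proposal scales during warmup."""
    gamma = (iteration + 1.0) ** -0.6
    log_scale += gamma * (accepted.astype(float) - target)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]
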