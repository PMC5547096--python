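"""Two-limb plasmin crawling as a three-state continuous-time Markov chain.

A plasmin molecule binds fibrin through two lysine-binding kringle "limbs".
Lumping the mirror-symmetric single-bound states gives three states:

* ``S11`` -- both limbs bound;
* ``S10`` -- one limb bound (either one);
* ``S00`` -- both limbs free: absorbing, since solution-phase plasmin is
  immediately inhibited by alpha2-antiplasmin.

From ``S10`` the free limb rebinds at rate ``k_crawl`` (-> ``S11``, counted
as one "step") or the bound limb releases at rate ``k_unbind`` (-> ``S00``).
``S11`` can only reach ``S00`` through ``S10`` (two limbs do not release at
the same instant), relaxing back at rate ``r_11_10``.

The number of steps before absorption, started from ``S10``, is geometric
with success probability ``k_unbind / (k_crawl + k_unbind)``, so the expected
step count is ``k_crawl / k_unbind`` -- independent of ``r_11_10``, which
only stretches the absorption *time*.  A step counts any rebinding event
regardless of where the limb lands, so the ratio overestimates the distance
actually travelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

S00, S10, S11 = 0, 1, 2


@dataclass(frozen=True)
class CrawlChain:
    k_crawl: float = 57.6  # s^-1, S10 -> S11
    k_unbind: float = 0.05  # s^-1, S10 -> S00
    r_11_10: float = 0.1  # s^-1, S11 -> S10; default 2 * k_unbind

    def __post_init__(self) -> None:
        for name in ("k_crawl", "k_unbind", "r_11_10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def expected_steps(chain: CrawlChain) -> float:
    """Closed-form mean number of steps before unbinding: k_crawl/k_unbind."""
    if chain.k_unbind <= 0:
        raise ValueError("k_unbind must be positive (chain never absorbs)")
    return chain.k_crawl / chain.k_unbind


@njit
def _simulate_paths(k_crawl, k_unbind, r_11_10, n_paths, seed, start, steps_out, times_out):
    np.random.seed(seed)
    for i in range(n_paths):
        state = start
        steps = 0
        t = 0.0
        while state != S00:
            if state == S11:
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                t += -np.log(u) / r_11_10
                state = S10
            else:
                tot = k_crawl + k_unbind
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                t += -np.log(u) / tot
                if np.random.random() * tot < k_crawl:
                    state = S11
                    steps += 1
                else:
                    state = S00
        steps_out[i] = steps
        times_out[i] = t


@dataclass
class CrawlSimResult:
    mean_steps: float
    se_steps: float
    mean_absorption_time: float
    steps: np.ndarray
    times: np.ndarray


def simulate_chain(
    chain: CrawlChain,
    start: int = S10,
    seed: int = 0,
    n_paths: int = 10_000,
) -> CrawlSimResult:
    """Exact CTMC simulation to absorption for ``n_paths`` independent paths."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if start not in (S00, S10, S11):
        raise ValueError("start must be one of S00, S10, S11")
    if start != S00:
        if chain.k_unbind <= 0:
            raise ValueError("k_unbind must be positive (chain never absorbs)")
        if start == S11 and chain.r_11_10 <= 0:
            raise ValueError("r_11_10 must be positive when starting from S11")
    steps = np.zeros(n_paths, dtype=np.int64)
    times = np.zeros(n_paths, dtype=np.float64)
    if start != S00:
        _simulate_paths(
            chain.k_crawl, chain.k_unbind, chain.r_11_10,
            n_paths, int(seed), start, steps, times,
        )
    mean = float(steps.mean())
    se = float(steps.std(ddof=1) / np.sqrt(n_paths)) if n_paths > 1 else float("nan")
    return CrawlSimResult(
        mean_steps=mean,
        se_steps=se,
        mean_absorption_time=float(times.mean()),
        steps=steps,
        times=times,
    )
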