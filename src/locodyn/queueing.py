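"""Stochastic priority-queuing model of intermittent behavior.

A fixed-length list holds L demands, each carrying a priority x drawn i.i.d.
uniformly on (priority_floor, 1).  At every discrete time step one demand is
selected for execution with probability proportional to x**alpha, removed,
and replaced by a fresh demand with a new uniform priority.  The waiting time
tau of a demand is the number of steps it spent in the list (demands present
at the start have arrival step 0).

For alpha = 0 the selection is uniform and waiting times are geometric with
mean L.  For alpha > 0 the waiting-time distribution develops a power-law
tail; the cumulative distribution P(>= tau) decays with exponent 1/alpha, so
proportional selection (alpha = 1) reproduces the resting-bout exponent near
1 seen in typical records, and preferential selection (alpha > 1) produces
the fatter tail (smaller exponent) seen in more intermittent phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import CumulativeDistribution

__all__ = [
    "QueueConfig",
    "WaitingTimes",
    "simulate_queue",
    "waiting_time_distribution",
    "onset_sequence",
]


@dataclass(frozen=True)
class QueueConfig:
    """Priority-queue simulation parameters.

    L : list length (number of queued demands).
    alpha : selection exponent; probability of executing priority x is
        proportional to x**alpha.  alpha = 0 is uniform choice, alpha = 1
        proportional choice, large alpha approaches deterministic
        highest-priority choice.
    steps : simulated time steps.
    seed : RNG seed.
    priority_floor : lower support of the uniform priority law; a small
        positive floor prevents zero-probability starvation at large alpha.
    burn_in : executions during the first ``burn_in`` steps are discarded
        from the emitted statistics (stationarity).
    """

    L: int = 10
    alpha: float = 1.0
    steps: int = 100_000
    seed: int | None = None
    priority_floor: float = 1.0e-6
    burn_in: int = 1000

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 <= self.priority_floor < 1):
            raise ValueError("priority_floor must be in [0, 1)")
        if self.burn_in < 0 or self.burn_in >= self.steps:
            raise ValueError("burn_in must be in [0, steps)")


@dataclass(frozen=True)
class WaitingTimes:
    """Waiting times of executed demands (after burn-in) plus censoring info."""

    taus: np.ndarray  # integer steps, one per execution after burn-in
    executed_priorities: np.ndarray
    executed_was_max: np.ndarray  # True when the executed demand held the top priority
    censored_ages: np.ndarray  # steps - arrival for demands still queued
    n_burn_in_executions: int
    taus_burn_in_sum: int  # total waiting time discarded with the burn-in
    config: QueueConfig


def simulate_queue(cfg: QueueConfig) -> WaitingTimes:
    """Run the queue for ``cfg.steps`` steps and collect waiting times.

    Demands still queued at the end are censored: their (truncated) ages are
    reported separately and excluded from ``taus``.
    """
    rng = np.random.default_rng(cfg.seed)
    L, alpha, steps, burn_in = cfg.L, cfg.alpha, cfg.steps, cfg.burn_in
    x = rng.uniform(cfg.priority_floor, 1.0, L).tolist()
    new_p = rng.uniform(cfg.priority_floor, 1.0, steps)
    u = rng.random(steps)

    # weights are kept relative to the current top priority: (x_i/x_max)**alpha
    # stays in [0, 1], so large alpha cannot underflow the whole weight vector
    xmax = max(x)
    w = [(xi / xmax) ** alpha for xi in x]
    total = sum(w)
    arrival = [0] * L
    taus: list[int] = []
    pris: list[float] = []
    was_max: list[bool] = []
    burn_execs = 0
    burn_tau_sum = 0
    last = L - 1
    for t in range(1, steps + 1):
        r = u[t - 1] * total
        acc = 0.0
        i = last  # guard against round-off past the end
        for j in range(L):
            acc += w[j]
            if r < acc:
                i = j
                break
        tau = t - arrival[i]
        if t > burn_in:
            taus.append(tau)
            pris.append(x[i])
            was_max.append(x[i] >= max(x))
        else:
            burn_execs += 1
            burn_tau_sum += tau
        xi = float(new_p[t - 1])
        old = x[i]
        x[i] = xi
        arrival[i] = t
        if xi > xmax or old == xmax:
            # top priority changed: rebase every weight
            xmax = max(x)
            for j in range(L):
                w[j] = (x[j] / xmax) ** alpha
            total = sum(w)
        else:
            total -= w[i]
            wi = (xi / xmax) ** alpha
            w[i] = wi
            total += wi
            if t & 0x3FFF == 0:  # refresh the running sum against drift
                total = sum(w)
    censored = np.array([steps - a for a in arrival], dtype=np.int64)
    return WaitingTimes(
        taus=np.asarray(taus, dtype=np.int64),
        executed_priorities=np.asarray(pris, dtype=float),
        executed_was_max=np.asarray(was_max, dtype=bool),
        censored_ages=censored,
        n_burn_in_executions=burn_execs,
        taus_burn_in_sum=burn_tau_sum,
        config=cfg,
    )


def waiting_time_distribution(
    wt: WaitingTimes, rescale: bool = False, min_count: int = 1000
) -> CumulativeDistribution:
    """Empirical P(>= tau) of the waiting times on the integer tau grid.

    With ``rescale=True`` the waiting times are divided by their mean first
    (for overlay with behavioral rescaled distributions) and tabulated on the
    shared logarithmic grid.
    """
    if wt.taus.size == 0:
        raise ValueError("no waiting times")
    if wt.taus.size < min_count:
        raise ValueError(
            f"need >= {min_count} waiting times, got {wt.taus.size}"
        )
    if rescale:
        from .behavior import rescaled_cumulative

        return rescaled_cumulative(wt.taus.astype(float), dt=1.0)
    taus = np.sort(wt.taus)
    grid = np.arange(1, taus[-1] + 1, dtype=float)
    p = 1.0 - np.searchsorted(taus, grid, side="left") / taus.size
    return CumulativeDistribution(x=grid, P=p, bin_width=1.0, n=int(taus.size))


def onset_sequence(wt: WaitingTimes, step_seconds: float = 0.1, span_s: float | None = None) -> np.ndarray:
    """Burst-onset times: cumulative sums of successive waiting times.

    Each executed demand's waiting time becomes an inter-onset interval;
    onsets are returned in seconds (``step_seconds`` per model step),
    optionally truncated to the first ``span_s`` seconds.
    """
    if step_seconds <= 0:
        raise ValueError("step_seconds must be positive")
    onsets = np.cumsum(wt.taus) * step_seconds
    if span_s is not None:
        onsets = onsets[onsets <= span_s]
    return onsets
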