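"""Synthetic spike-train generation from a latent Langevin model.

Latent trajectories are integrated with the Euler-Maruyama scheme

    x_{k+1} = x_k + D F(x_k) dt + sqrt(2 D dt) eta_k,

started from ``x0 ~ p0`` (inverse-CDF sampling of the nodal density).
For the fixed-duration design, overshoots past +-1 are reflected
elastically and the trial ends at ``trial_duration``; for the
reaction-time design, the trial ends at the first boundary crossing,
with the crossing time located by linear interpolation within the step.
Spikes are generated by time rescaling: a spike is emitted whenever the
running rate integral ``Lambda(t) = int f(x(s)) ds`` (trapezoid per
step) crosses the next unit-mean exponential threshold.

Both the reflection scheme and the crossing interpolation carry an
O(sqrt(dt)) weak bias, controlled by the dt-halving convergence check in
the test suite; the default step is dt = 1e-4 time units.

All trials of a batch advance in lockstep through one vectorized
integrator sharing a single RNG stream, so datasets are bit-reproducible
from ``rng_seed``.

The module also ships the named ground-truth fixture models used in the
examples and recovery experiments ("ramping", "stepping",
"fixed-duration").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ABSORBING,
    FIXED_DURATION,
    REACTION_TIME,
    Dataset,
    LatentModel,
    TrialObservations,
    REFLECTING,
)

__all__ = ["SimConfig", "simulate_trial", "simulate_dataset", "fixture_model"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``trial_duration`` applies to the fixed-duration design only;
    reaction-time trials end at the first boundary passage (a trial not
    absorbed by ``max_time`` is restarted from a fresh draw of p0, which
    is rare for the fixture dynamics).
    """

    n_trials: int = 200
    dt_sim: float = 1e-4
    trial_duration: float = 1.0
    rng_seed: int = 0
    record_latent: bool = False
    max_time: float = 50.0

    def __post_init__(self):
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


def _sample_x0(model: LatentModel, rng: np.random.Generator, size: int) -> np.ndarray:
    """Inverse-CDF draws from the nodal p0 (trapezoid CDF on the grid)."""
    x = model.grid.nodes
    p = np.clip(model.p0, 0.0, None)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x))))
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, x)


def _tables(model: LatentModel, n_fine: int = 2049):
    """Fine uniform tables of F and f for linear interpolation off-grid."""
    xf = np.linspace(-1.0, 1.0, n_fine)
    F = model.grid.interpolate(model.force, xf)
    f = np.clip(model.grid.interpolate(model.rate_fn, xf), 1e-12, None)
    return xf, F, f


def _simulate_batch(model: LatentModel, config: SimConfig,
                    rng: np.random.Generator, n: int):
    """Vectorized lockstep integrator for ``n`` trials.

    Returns (trials, paths) where paths is a list of (times, states)
    per trial if ``config.record_latent`` else None.
    """
    xf, Ftab, ftab = _tables(model)
    absorbing = model.boundary_mode == ABSORBING
    design = REACTION_TIME if absorbing else FIXED_DURATION
    dt = config.dt_sim
    D = model.noise
    sq = np.sqrt(2.0 * D * dt)

    x = _sample_x0(model, rng, n)
    t = np.zeros(n)
    t_end = np.full(n, np.nan)
    lam = np.zeros(n)                      # cumulative rate integral
    thresh = rng.exponential(size=n)       # next cumulative spike threshold
    active = np.ones(n, dtype=bool)
    spike_trials: list[int] = []
    spike_times: list[float] = []
    paths = [[ (0.0, xi) ] for xi in x] if config.record_latent else None
    n_fixed_steps = int(round(config.trial_duration / dt))
    step = 0

    while active.any():
        idx = np.flatnonzero(active)
        xi = x[idx]
        r0 = np.interp(xi, xf, ftab)
        x_new = xi + D * np.interp(xi, xf, Ftab) * dt \
            + sq * rng.standard_normal(idx.size)
        dt_eff = np.full(idx.size, dt)
        done_now = np.zeros(idx.size, dtype=bool)
        if absorbing:
            crossed = np.abs(x_new) >= 1.0
            if crossed.any():
                b = np.sign(x_new[crossed])
                frac = (b - xi[crossed]) / (x_new[crossed] - xi[crossed])
                dt_eff[crossed] = frac * dt
                x_new[crossed] = b
                done_now = crossed
        else:
            over = np.abs(x_new) > 1.0
            x_new[over] = np.sign(x_new[over]) * 2.0 - x_new[over]

        # time-rescaled spike emission (rate treated as its step average)
        rbar = 0.5 * (r0 + np.interp(x_new, xf, ftab))
        lam_new = lam[idx] + rbar * dt_eff
        while True:
            em = lam_new >= thresh[idx]
            if not em.any():
                break
            ei = idx[em]
            t_sp = t[ei] + (thresh[ei] - lam[ei]) / rbar[em]
            # numerical guard: keep spikes strictly inside the step
            t_sp = np.minimum(t_sp, t[ei] + dt_eff[em])
            spike_trials.extend(ei.tolist())
            spike_times.extend(t_sp.tolist())
            thresh[ei] += rng.exponential(size=ei.size)
        lam[idx] = lam_new
        x[idx] = x_new
        t[idx] = t[idx] + dt_eff
        if config.record_latent:
            for k, i in enumerate(idx):
                paths[i].append((t[i], x_new[k]))

        if absorbing:
            fin = idx[done_now]
            t_end[fin] = t[fin]
            active[fin] = False
            # restart trials that exceeded max_time without absorption
            stale = idx[~done_now][t[idx[~done_now]] >= config.max_time]
            if stale.size:
                x[stale] = _sample_x0(model, rng, stale.size)
                t[stale] = 0.0
                lam[stale] = 0.0
                thresh[stale] = rng.exponential(size=stale.size)
                for i in stale:
                    spike_trials_arr = np.asarray(spike_trials)
                    keep = spike_trials_arr != i
                    spike_trials = list(spike_trials_arr[keep])
                    spike_times = list(np.asarray(spike_times)[keep])
                    if config.record_latent:
                        paths[i] = [(0.0, x[i])]
        else:
            step += 1
            if step >= n_fixed_steps:
                t_end[idx] = config.trial_duration
                active[idx] = False

    spike_trials = np.asarray(spike_trials, dtype=int)
    spike_times_arr = np.asarray(spike_times)
    trials = []
    for i in range(n):
        st = np.sort(spike_times_arr[spike_trials == i])
        st = st[(st > 0.0) & (st < t_end[i])]
        st = np.unique(st)
        trials.append(
            TrialObservations(
                t_start=0.0, spike_times=st, t_end=float(t_end[i]),
                design=design, trial_id=i,
            )
        )
    if config.record_latent:
        out_paths = [
            (np.asarray([p[0] for p in pp]), np.asarray([p[1] for p in pp]))
            for pp in paths
        ]
        return trials, out_paths
    return trials, None


def simulate_trial(model: LatentModel, config: SimConfig,
                   rng: np.random.Generator):
    """Simulate a single trial using the supplied generator.

    Returns ``TrialObservations``, or ``(trial, (times, states))`` when
    ``config.record_latent`` is set.
    """
    trials, paths = _simulate_batch(model, config, rng, 1)
    if config.record_latent:
        return trials[0], paths[0]
    return trials[0]


def simulate_dataset(model: LatentModel, config: SimConfig):
    """``config.n_trials`` independent trials, reproducible from ``rng_seed``.

    Returns a :class:`Dataset`, or ``(dataset, paths)`` when
    ``config.record_latent`` is set.
    """
    rng = np.random.default_rng(config.rng_seed)
    trials, paths = _simulate_batch(model, config, rng, config.n_trials)
    data = Dataset.from_trials(trials)
    if config.record_latent:
        return data, paths
    return data


# ---------------------------------------------------------------------------
# named ground-truth fixtures


def fixture_model(name: str, n_points: int = 64) -> LatentModel:
    """Ground-truth models for the recovery experiments.

    - ``ramping``: linear potential Phi = -3x (constant drift toward the
      +1 decision boundary), absorbing boundaries; the drift-diffusion
      account of decision making.
    - ``stepping``: double-barrier potential 12(x^2 - 2x^4) (metastable
      valley at x = 0, barriers near +-0.5), absorbing boundaries;
      decisions as discrete jumps over a barrier.
    - ``fixed-duration``: the ramping potential with reflecting
      boundaries and a fixed trial length.

    All share D = 0.5, a narrow initial density centered at x = 0
    (Gaussian, sigma = 0.15), and a linear firing-rate function rising
    from 10 to 70 spikes per time unit across the domain, matching the
    range of cortical responses recorded during perceptual decisions;
    typical trials last roughly 0.5-2 time units.
    """

    def p0(x):
        return np.exp(-(x**2) / (2 * 0.15**2))

    def rate(x):
        return 10.0 + 30.0 * (1.0 + x)

    if name == "ramping":
        return LatentModel.from_functions(
            n_points, lambda x: -3.0 * x, 0.5, p0, rate, ABSORBING
        )
    if name == "stepping":
        return LatentModel.from_functions(
            n_points, lambda x: 12.0 * (x**2 - 2.0 * x**4), 0.5, p0, rate,
            ABSORBING,
        )
    if name == "fixed-duration":
        return LatentModel.from_functions(
            n_points, lambda x: -3.0 * x, 0.5, p0, rate, REFLECTING
        )
    raise ValueError(f"unknown fixture {name!r}")
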