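"""Core data containers: the latent Langevin model and spike-train trials.

The latent state x(t) evolves on [-1, 1] under

    dx/dt = D F(x) + sqrt(2 D) xi(t),        F(x) = -dPhi/dx,

and is observed only through spikes of an inhomogeneous Poisson process
with rate f(x(t)).  A model bundles the potential Phi(x), the noise
magnitude D, the initial-state density p0(x), the firing-rate function
f(x) (treated as known), and the boundary mode that encodes the
experiment design: reflecting boundaries for fixed-duration trials,
absorbing boundaries for reaction-time trials.

Gauge convention: the additive constant of Phi is fixed so that
``integral exp(-Phi) dx = 1``; p0 integrates to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .grid import Grid, make_grid

__all__ = [
    "REFLECTING",
    "ABSORBING",
    "FIXED_DURATION",
    "REACTION_TIME",
    "LatentModel",
    "TrialObservations",
    "Dataset",
    "gauge_fix",
]

REFLECTING = "reflecting"
ABSORBING = "absorbing"
FIXED_DURATION = "fixed-duration"
REACTION_TIME = "reaction-time"

#: boundary mode consistent with each experiment design
DESIGN_BOUNDARY = {FIXED_DURATION: REFLECTING, REACTION_TIME: ABSORBING}


def gauge_fix(grid: Grid, potential: np.ndarray) -> np.ndarray:
    """Shift ``potential`` so that integral of exp(-Phi) over [-1,1] equals 1."""
    potential = np.asarray(potential, dtype=float)
    # evaluate the normalization in a shift-robust way
    ref = potential.min()
    z = grid.integrate(np.exp(-(potential - ref)))
    return potential + (np.log(z) - ref)


@dataclass(frozen=True)
class LatentModel:
    """A latent Langevin model discretized on a GLL grid.

    All function-valued fields are nodal vectors on ``grid``.
    """

    grid: Grid
    potential: np.ndarray  # Phi(x), dimensionless, gauge-fixed
    noise: float  # D, units x^2 / time
    p0: np.ndarray  # initial density, 1/x units
    rate_fn: np.ndarray  # f(x), spikes / time, > 0
    boundary_mode: str  # REFLECTING or ABSORBING

    def __post_init__(self):
        n = self.grid.n_points
        for name in ("potential", "p0", "rate_fn"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, v)
        if self.boundary_mode not in (REFLECTING, ABSORBING):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.noise < 0:
            raise ValueError("noise magnitude D must be >= 0")
        if np.any(self.rate_fn <= 0):
            raise ValueError("rate_fn must be positive everywhere")
        if np.any(self.p0 < -1e-12):
            raise ValueError("p0 must be non-negative")
        if abs(self.grid.integrate(self.p0) - 1.0) > 1e-6:
            raise ValueError("p0 must integrate to 1")
        if abs(self.grid.integrate(np.exp(-self.potential)) - 1.0) > 1e-6:
            raise ValueError(
                "potential gauge violated: integral exp(-Phi) dx must be 1 "
                "(use LatentModel.from_functions or gauge_fix)"
            )

    @property
    def force(self) -> np.ndarray:
        """Driving force F(x) = -dPhi/dx at the nodes (derived, not stored)."""
        return -self.grid.derivative(self.potential)

    def with_(self, **changes) -> "LatentModel":
        return replace(self, **changes)

    @classmethod
    def from_functions(
        cls,
        grid: Grid | int,
        potential: Callable[[np.ndarray], np.ndarray] | np.ndarray,
        noise: float,
        p0: Callable[[np.ndarray], np.ndarray] | np.ndarray,
        rate_fn: Callable[[np.ndarray], np.ndarray] | np.ndarray,
        boundary_mode: str,
    ) -> "LatentModel":
        """Build a model from callables or nodal arrays.

        The potential is gauge-fixed and p0 is normalized automatically.
        """
        if isinstance(grid, int):
            grid = make_grid(grid)
        x = grid.nodes

        def nodal(v):
            return np.asarray(v(x) if callable(v) else v, dtype=float)

        phi = gauge_fix(grid, nodal(potential))
        p0v = np.clip(nodal(p0), 0.0, None)
        p0v = p0v / grid.integrate(p0v)
        return cls(
            grid=grid,
            potential=phi,
            noise=float(noise),
            p0=p0v,
            rate_fn=nodal(rate_fn),
            boundary_mode=boundary_mode,
        )


@dataclass(frozen=True)
class TrialObservations:
    """One trial: start time, ordered spike times, end time, design flag."""

    t_start: float
    spike_times: np.ndarray
    t_end: float
    design: str = REACTION_TIME
    trial_id: int | None = None

    def __post_init__(self):
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        tid = f" (trial {self.trial_id})" if self.trial_id is not None else ""
        if self.design not in DESIGN_BOUNDARY:
            raise ValueError(f"unknown design {self.design!r}{tid}")
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end must exceed t_start{tid}")
        if st.size:
            if np.any(np.diff(st) <= 0):
                raise ValueError(f"spike times must be strictly increasing{tid}")
            if st[0] <= self.t_start or st[-1] >= self.t_end:
                raise ValueError(
                    f"spike times must lie strictly inside (t_start, t_end){tid}"
                )

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def intervals(self) -> np.ndarray:
        """Durations of the N+1 inter-observation intervals t0..t1..tN..tE."""
        times = np.concatenate(([self.t_start], self.spike_times, [self.t_end]))
        return np.diff(times)


@dataclass(frozen=True)
class Dataset:
    """A homogeneous collection of trials sharing one experiment design."""

    trials: tuple[TrialObservations, ...]
    design: str

    def __post_init__(self):
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        if not trials:
            raise ValueError("dataset contains no trials")
        for t in trials:
            if t.design != self.design:
                raise ValueError(
                    f"trial {t.trial_id} has design {t.design!r}, "
                    f"dataset is {self.design!r}"
                )

    @classmethod
    def from_trials(cls, trials: Sequence[TrialObservations]) -> "Dataset":
        trials = tuple(trials)
        if not trials:
            raise ValueError("dataset contains no trials")
        return cls(trials=trials, design=trials[0].design)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def boundary_mode(self) -> str:
        return DESIGN_BOUNDARY[self.design]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(
            trials=tuple(self.trials[i] for i in indices), design=self.design
        )

    def split_halves(self, rng: np.random.Generator | None = None):
        """Two non-intersecting halves (random permutation if rng given)."""
        n = len(self.trials)
        order = np.arange(n) if rng is None else rng.permutation(n)
        half = n // 2
        return self.subset(order[:half]), self.subset(order[half:])
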