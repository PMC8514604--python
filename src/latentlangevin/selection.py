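"""Feature-consistency model selection and bootstrap uncertainty bounds.

Gradient descent produces a sequence of models of growing structure;
early iterates underfit and late iterates overfit.  Because true
features are shared between independent data samples while overfitting
noise is not, the optimal iterate can be identified by comparing models
fitted to two non-intersecting data halves at matched *feature
complexity*.

Feature complexity is the negative entropy of the model's latent
trajectories relative to a free-diffusion reference (constant potential,
same D, uniform initial density):

    M = KL(p0 || p0_ref) + (D/4) int_0^T dt int F^2(x) p(x, t) dx,

where p(x, t) solves the Fokker-Planck equation from p0.  The time
integral is evaluated in closed form in the eigenbasis of H0 (a
1/lambda-weighted modal sum).  With absorbing boundaries all
eigenvalues are positive and T = infinity; with reflecting boundaries
the zero mode makes the integral grow linearly in T, so complexity is
defined up to the documented horizon ``t_horizon``.

Model overlap is the time-integrated Jensen-Shannon divergence between
the models' latent densities (midpoint rule in time).  The mass lost
through the absorbing boundaries up to time t is re-injected as a
single discrete atom, so each compared object is a proper probability
distribution (continuous part + boundary atom).

The selection rule: for each complexity level of the first trace, find
the closest level of the second trace, take the minimum divergence
within a slack window of ``R`` iterates around it, and select the
maximum complexity M* whose divergence stays below the threshold
(default 0.001).  Bootstrap bounds refit both halves of resampled
datasets and take pointwise percentiles across the 2 x n_bootstrap
selected potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import FitConfig, FitTrace, fit
from .model import ABSORBING, Dataset, LatentModel
from .operators import build_operators

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "feature_complexity",
    "jsd_between_models",
    "select_model",
    "bootstrap_bounds",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection procedure.

    ``jsd_threshold`` is the consistency threshold on the
    time-integrated JSD; ``complexity_slack`` is the window half-width R
    of iterates searched around the complexity-matched index;
    ``time_step`` is the midpoint-rule step of the time integral, which
    is truncated once the surviving continuous mass of both models drops
    below ``mass_cutoff`` (absorbing) or at ``t_horizon`` (reflecting,
    and as an overall safety cap).
    """

    jsd_threshold: float = 0.001
    complexity_slack: int = 5
    time_step: float = 0.05
    mass_cutoff: float = 1e-4
    n_bootstrap: int = 10
    percentiles: tuple[float, float] = (5.0, 95.0)
    t_horizon: float = 10.0
    t_cap: float = 50.0
    eval_stride: int = 1

    def __post_init__(self):
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")
        for name in ("jsd_threshold", "time_step", "mass_cutoff", "t_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.complexity_slack < 0 or self.n_bootstrap < 1:
            raise ValueError("invalid slack or bootstrap count")


@dataclass
class SelectionResult:
    """Outcome of feature-consistency selection (and optional bootstrap)."""

    jsd_curve: np.ndarray  # rows (complexity M_i^1, D_JS)
    optimal_complexity: float
    selected_pair: tuple[LatentModel, LatentModel]
    selected_indices: tuple[int, int]
    threshold_attained: bool  # False -> fell back to the lowest complexity
    point_estimate: np.ndarray | None = None  # average selected potential
    bounds_lower: np.ndarray | None = None
    bounds_upper: np.ndarray | None = None
    pooled_potentials: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# spectral helpers


class _H0Cache:
    """Per-model spectral data for H0 propagation of the latent density."""

    def __init__(self, model: LatentModel):
        b = build_operators(model)
        self.model = model
        self.act = b.active
        lam, U = b.eig_H0
        self.lam = np.clip(lam, 0.0, None)  # reflecting zero mode: clip -eps
        self.U = U
        self.from_sym = b.from_sym
        self.s0_hat = U.T @ (b.to_sym * model.p0[b.active])
        self.w_act = model.grid.quad_weights[b.active]

    def density(self, times: np.ndarray) -> np.ndarray:
        """Continuous latent density at the given times, shape (nt, n_act)."""
        decay = np.exp(-np.outer(times, self.lam))
        return (self.U @ (decay * self.s0_hat).T).T * self.from_sym

    def time_integral(self, coeffs: np.ndarray, t_max: float | None) -> float:
        """integral_0^{t_max} sum_i coeffs_i p_i(t) dt in the eigenbasis."""
        c_hat = self.U.T @ (coeffs * self.from_sym)
        lam = self.lam
        tol = 1e-12 * (1.0 + lam.max())
        if t_max is None:
            if np.any(lam <= tol):
                raise ValueError(
                    "infinite-horizon time integral requires strictly decaying "
                    "modes (absorbing boundaries); pass a finite horizon"
                )
            psi = 1.0 / lam
        else:
            psi = np.where(
                lam > tol, -np.expm1(-lam * t_max) / np.where(lam > tol, lam, 1.0),
                t_max,
            )
        return float(np.sum(c_hat * self.s0_hat * psi))


def feature_complexity(model: LatentModel, config: SelectionConfig) -> float:
    """Negative trajectory entropy M relative to the free-diffusion reference.

    Raises if D = 0 while the force is not identically zero (the
    trajectory-entropy integral is undefined for deterministic drift).
    """
    F = model.force
    if model.noise == 0.0:
        if np.max(np.abs(F)) > 1e-10:
            raise ValueError("feature complexity undefined for D = 0 with F != 0")
        F = np.zeros_like(F)
    grid = model.grid
    p0 = model.p0
    pos = p0 > 0
    kl = grid.integrate(np.where(pos, p0 * np.log(np.where(pos, 2.0 * p0, 1.0)), 0.0))
    if model.noise == 0.0:
        return float(kl)
    cache = _H0Cache(model)
    t_max = None if model.boundary_mode == ABSORBING else config.t_horizon
    coeffs = (cache.w_act * F[cache.act] ** 2)
    integral = cache.time_integral(coeffs, t_max)
    return float(kl + 0.25 * model.noise * integral)


def _jsd_profile(p: np.ndarray, q: np.ndarray, w: np.ndarray,
                 ip: np.ndarray, iq: np.ndarray) -> np.ndarray:
    """Pointwise-in-time JSD of continuous parts (p, q) plus boundary atoms."""
    p = np.clip(p, 0.0, None)
    q = np.clip(q, 0.0, None)
    mix = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(p > 0, p * np.log(p / np.where(mix > 0, mix, 1.0)), 0.0)
        tq = np.where(q > 0, q * np.log(q / np.where(mix > 0, mix, 1.0)), 0.0)
    cont = 0.5 * ((tp @ w) + (tq @ w))
    am = 0.5 * (ip + iq)
    with np.errstate(divide="ignore", invalid="ignore"):
        at = 0.5 * (
            np.where(ip > 0, ip * np.log(ip / np.where(am > 0, am, 1.0)), 0.0)
            + np.where(iq > 0, iq * np.log(iq / np.where(am > 0, am, 1.0)), 0.0)
        )
    return cont + at


def jsd_between_models(
    a: LatentModel,
    b: LatentModel,
    config: SelectionConfig,
    _caches: tuple[_H0Cache, _H0Cache] | None = None,
) -> float:
    """Time-integrated Jensen-Shannon divergence between two models.

    Both models must share the grid and boundary mode; each evolves its
    own p0 under its own Fokker-Planck operator.
    """
    if a.grid is not b.grid and not np.array_equal(a.grid.nodes, b.grid.nodes):
        raise ValueError("models must share the same grid")
    if a.boundary_mode != b.boundary_mode:
        raise ValueError("models must share the boundary mode")
    ca, cb = _caches if _caches is not None else (_H0Cache(a), _H0Cache(b))
    dt = config.time_step
    absorbing = a.boundary_mode == ABSORBING
    t_stop = config.t_cap if absorbing else min(config.t_horizon, config.t_cap)
    w = a.grid.quad_weights[ca.act]
    total = 0.0
    chunk = 128
    t0 = 0.0
    while t0 < t_stop:
        n_t = min(chunk, int(np.ceil((t_stop - t0) / dt)))
        times = t0 + dt * (np.arange(n_t) + 0.5)
        pa = ca.density(times)
        pb = cb.density(times)
        ma = np.clip(pa, 0.0, None) @ w
        mb = np.clip(pb, 0.0, None) @ w
        ia = np.clip(1.0 - ma, 0.0, 1.0)
        ib = np.clip(1.0 - mb, 0.0, 1.0)
        prof = _jsd_profile(pa, pb, w, ia, ib)
        if absorbing:
            alive = (ma >= config.mass_cutoff) | (mb >= config.mass_cutoff)
            if not alive.all():
                k = int(np.argmin(alive))  # first index where both masses died
                total += prof[:k].sum() * dt
                return float(total)
        total += prof.sum() * dt
        t0 = times[-1] + 0.5 * dt
    return float(total)


# ---------------------------------------------------------------------------
# selection over two fit traces


def _trace_complexities(trace: FitTrace, config: SelectionConfig) -> np.ndarray:
    if trace.complexities is None:
        trace.complexities = np.array(
            [feature_complexity(m, config) for m in trace.models]
        )
    return trace.complexities


def select_model(
    trace1: FitTrace, trace2: FitTrace, config: SelectionConfig
) -> SelectionResult:
    """Feature-consistency selection over two traces fitted on data halves.

    Ties in complexity matching break toward the smaller (earlier)
    iterate.  If no level has divergence below the threshold, the
    lowest-complexity pair is returned with ``threshold_attained=False``.
    """
    if not len(trace1) or not len(trace2):
        raise ValueError("empty fit trace")
    M1 = _trace_complexities(trace1, config)
    M2 = _trace_complexities(trace2, config)
    caches1: dict[int, _H0Cache] = {}
    caches2: dict[int, _H0Cache] = {}

    def cache(side, i):
        store, trace = (caches1, trace1) if side == 1 else (caches2, trace2)
        if i not in store:
            store[i] = _H0Cache(trace.models[i])
        return store[i]

    R = config.complexity_slack
    levels = range(0, len(trace1.models), config.eval_stride)
    curve = []
    pair_for_level = {}
    for i in levels:
        j_star = int(np.argmin(np.abs(M1[i] - M2)))  # argmin is first-min: ties -> earlier j
        lo, hi = max(0, j_star - R), min(len(M2) - 1, j_star + R)
        best_j, best_d = None, np.inf
        for j in range(lo, hi + 1):
            d = jsd_between_models(
                trace1.models[i], trace2.models[j], config,
                _caches=(cache(1, i), cache(2, j)),
            )
            if d < best_d:
                best_j, best_d = j, d
        curve.append((M1[i], best_d))
        pair_for_level[i] = (best_j, best_d)
    curve = np.asarray(curve)

    ok = [i for i in levels if pair_for_level[i][1] <= config.jsd_threshold]
    if ok:
        i_sel = max(ok, key=lambda i: M1[i])
        attained = True
    else:
        i_sel = min(levels, key=lambda i: M1[i])
        attained = False
    j_sel = pair_for_level[i_sel][0]
    return SelectionResult(
        jsd_curve=curve,
        optimal_complexity=float(M1[i_sel]),
        selected_pair=(trace1.models[i_sel], trace2.models[j_sel]),
        selected_indices=(i_sel, j_sel),
        threshold_attained=attained,
    )


def bootstrap_bounds(
    data: Dataset,
    fit_config: FitConfig,
    sel_config: SelectionConfig,
) -> SelectionResult:
    """Selection on the original data plus bootstrap confidence bounds.

    Draws ``n_bootstrap`` resamples of the trials (with replacement,
    same size), splits each in half, refits both halves, and runs the
    feature-consistency selection; the pointwise percentile band across
    the 2 x n_bootstrap selected potentials is the confidence bound.
    The point estimate is the average of the two potentials selected on
    the original (non-resampled) split.
    """
    if sel_config.n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(fit_config.rng_seed)

    def fit_select(ds: Dataset) -> SelectionResult:
        h1, h2 = ds.split_halves(rng)
        t1 = fit(h1, fit_config)
        t2 = fit(h2, fit_config)
        return select_model(t1, t2, sel_config)

    base = fit_select(data)
    pooled = []
    n = len(data)
    for _ in range(sel_config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        res = fit_select(data.subset(idx))
        pooled.append(res.selected_pair[0].potential)
        pooled.append(res.selected_pair[1].potential)
    pooled = np.asarray(pooled)
    lo, hi = sel_config.percentiles
    base.point_estimate = 0.5 * (
        base.selected_pair[0].potential + base.selected_pair[1].potential
    )
    base.bounds_lower = np.percentile(pooled, lo, axis=0)
    base.bounds_upper = np.percentile(pooled, hi, axis=0)
    base.pooled_potentials = pooled
    return base
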