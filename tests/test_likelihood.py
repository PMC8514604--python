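import numpy as np
import pytest

from latentlangevin import (
    Dataset,
    LatentModel,
    SimConfig,
    TrialObservations,
    dataset_loglik,
    fixture_model,
    make_grid,
    simulate_dataset,
    trial_loglik,
)
from latentlangevin.model import gauge_fix


def const_rate_model(grid, lam0, boundary="reflecting"):
    return LatentModel.from_functions(
        grid, lambda x: 0 * x, 0.5,
        lambda x: np.exp(-(x**2) / 0.05), lambda x: lam0 + 0 * x, boundary,
    )


class TestClosedForms:
    """With a constant rate and reflecting boundaries the latent dynamics
    integrate out and the homogeneous-Poisson formulas are exact."""

    def test_zero_spikes_void_probability(self, grid32):
        lam0, T = 7.0, 1.3
        m = const_rate_model(grid32, lam0)
        tr = TrialObservations(0.0, np.array([]), T, "fixed-duration")
        assert abs(trial_loglik(m, tr) - (-lam0 * T)) < 1e-8

    def test_one_spike_density(self, grid32):
        lam0, T = 7.0, 1.3
        m = const_rate_model(grid32, lam0)
        tr = TrialObservations(0.0, np.array([0.4]), T, "fixed-duration")
        expected = np.log(lam0) - lam0 * T
        assert abs(trial_loglik(m, tr) - expected) < 1e-8


class TestDatasetLoglik:
    def test_single_trial_dataset_equals_trial(self, grid32):
        m = const_rate_model(grid32, 5.0)
        tr = TrialObservations(0.0, np.array([0.2, 0.5]), 1.0, "fixed-duration")
        data = Dataset.from_trials([tr])
        assert dataset_loglik(m, data) == pytest.approx(trial_loglik(m, tr))

    def test_duplication_doubles_loglik(self, grid32):
        m = const_rate_model(grid32, 5.0)
        tr = TrialObservations(0.0, np.array([0.2, 0.5]), 1.0, "fixed-duration")
        one = dataset_loglik(m, Dataset.from_trials([tr]))
        two = dataset_loglik(m, Dataset.from_trials([tr, tr]))
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_order_invariance(self, grid32):
        data = simulate_dataset(
            fixture_model("ramping", 32), SimConfig(n_trials=10, rng_seed=3)
        )
        m = fixture_model("ramping", 32)
        fwd = dataset_loglik(m, data)
        rev = dataset_loglik(m, data.subset(list(range(len(data) - 1, -1, -1))))
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_mode_mismatch_rejected(self, grid32):
        m = const_rate_model(grid32, 5.0, boundary="absorbing")
        tr = TrialObservations(0.0, np.array([0.2]), 1.0, "fixed-duration")
        with pytest.raises(ValueError, match="inconsistent"):
            trial_loglik(m, tr)

    def test_ground_truth_beats_perturbed_model(self):
        """On repeated datasets, the generating model attains a higher
        per-trial log-likelihood than a sine-perturbed potential."""
        gt = fixture_model("ramping", 32)
        pert = gt.with_(
            potential=gauge_fix(
                gt.grid, gt.potential + 0.5 * np.sin(np.pi * gt.grid.nodes)
            )
        )
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            data = simulate_dataset(
                fixture_model("ramping", 64),
                SimConfig(n_trials=100, rng_seed=1000 + rep),
            )
            if dataset_loglik(gt, data) > dataset_loglik(pert, data):
                wins += 1
        assert wins >= 0.95 * n_rep


class TestNumericalSafety:
    def test_many_spikes_no_underflow(self, grid32):
        m = const_rate_model(grid32, 50.0)
        spikes = np.linspace(1e-4, 100.0 - 1e-4, 10_000)
        tr = TrialObservations(0.0, spikes, 100.0, "fixed-duration")
        ll = trial_loglik(m, tr)
        assert np.isfinite(ll)
        # homogeneous-Poisson closed form still holds
        expected = 10_000 * np.log(50.0) - 50.0 * 100.0
        assert abs(ll - expected) < 1e-6 * abs(expected)

    def test_gauge_invariance(self):
        m = fixture_model("ramping", 32)
        data = simulate_dataset(
            fixture_model("ramping", 32), SimConfig(n_trials=5, rng_seed=9)
        )
        shifted = m.with_(potential=gauge_fix(m.grid, m.potential + 11.0))
        a = dataset_loglik(m, data)
        b = dataset_loglik(shifted, data)
        assert abs(a - b) < 1e-10 * abs(a)


@pytest.fixture(scope="module")
def rt_data():
    return simulate_dataset(
        fixture_model("ramping", 64), SimConfig(n_trials=20, rng_seed=5)
    )


class TestAblationSwitches:
    def test_absorption_term_changes_value(self, rt_data):
        m = fixture_model("ramping", 32)
        full = dataset_loglik(m, rt_data)
        noab = dataset_loglik(m, rt_data, include_absorption=False)
        assert full != pytest.approx(noab)

    def test_boundary_override_changes_value(self, rt_data):
        m = fixture_model("ramping", 32)
        full = dataset_loglik(m, rt_data)
        refl = dataset_loglik(m, rt_data, boundary_override="reflecting")
        assert full != pytest.approx(refl)

    def test_equilibrium_p0_changes_value(self, rt_data):
        m = fixture_model("ramping", 32)
        a = dataset_loglik(m, rt_data, boundary_override="reflecting")
        b = dataset_loglik(
            m, rt_data, boundary_override="reflecting", use_equilibrium_p0=True
        )
        assert a != pytest.approx(b)


def _mc_path_loglik(model, trial, n_paths, dt, delta, seed):
    """Path-sampling estimate of the trial likelihood: average over
    Euler-Maruyama latent paths of the conditional Poisson density times
    an indicator that first passage occurs within +-delta of t_end.
    Brownian-bridge crossing probabilities remove the O(sqrt(dt))
    first-passage bias of the discrete scheme."""
    rng = np.random.default_rng(seed)
    xg = np.linspace(-1, 1, 2001)
    Ftab = model.grid.interpolate(model.force, xg)
    ftab = model.grid.interpolate(model.rate_fn, xg)
    p0tab = np.clip(model.grid.interpolate(model.p0, xg), 0, None)
    cdf = np.concatenate(
        ([0], np.cumsum(0.5 * (p0tab[1:] + p0tab[:-1]) * np.diff(xg)))
    )
    cdf /= cdf[-1]
    tE, spk = trial.t_end, trial.spike_times
    D = model.noise
    sq = np.sqrt(2 * D * dt)
    total_w = total_w2 = 0.0
    chunk = 150_000
    done = 0
    while done < n_paths:
        m_ = min(chunk, n_paths - done)
        done += m_
        x = np.interp(rng.random(m_), cdf, xg)
        alive = np.ones(m_, bool)
        t_abs = np.full(m_, np.nan)
        If = np.zeros(m_)
        fprod = np.ones(m_)
        ks = 0
        t = 0.0
        for _ in range(int(np.ceil((tE + delta) / dt))):
            idx = np.flatnonzero(alive)
            if not idx.size:
                break
            xi = x[idx]
            r0 = np.interp(xi, xg, ftab)
            xn = xi + D * np.interp(xi, xg, Ftab) * dt \
                + sq * rng.standard_normal(idx.size)
            crossed = np.abs(xn) >= 1
            frac = np.ones(idx.size)
            if crossed.any():
                b = np.sign(xn[crossed])
                frac[crossed] = (b - xi[crossed]) / (xn[crossed] - xi[crossed])
            nc = ~crossed
            xin, xnn = xi[nc], xn[nc]
            pU = np.exp(-np.clip((1 - xin) * (1 - xnn), 0, None) / (D * dt))
            pL = np.exp(-np.clip((1 + xin) * (1 + xnn), 0, None) / (D * dt))
            bridge = rng.random(xin.size) < np.clip(pU + pL, 0, 1)
            frac[nc] = np.where(bridge, rng.random(xin.size), 1.0)
            absorbed = crossed.copy()
            absorbed[nc] = bridge
            if absorbed.any():
                t_abs[idx[absorbed]] = t + frac[absorbed] * dt
            r1 = np.interp(np.clip(xn, -1, 1), xg, ftab)
            If[idx] += 0.5 * (r0 + r1) * frac * dt
            while ks < len(spk) and t < spk[ks] <= t + dt:
                xs = xi + (xn - xi) * ((spk[ks] - t) / dt)
                fs = np.interp(np.clip(xs, -1, 1), xg, ftab)
                dead_before = absorbed & (t_abs[idx] <= spk[ks])
                fprod[idx[~dead_before]] *= fs[~dead_before]
                fprod[idx[dead_before]] = 0.0
                ks += 1
            alive[idx[absorbed]] = False
            x[idx[~absorbed]] = xn[~absorbed]
            t += dt
        w = np.where(np.abs(t_abs - tE) <= delta, fprod * np.exp(-If), 0.0)
        w /= 2 * delta
        total_w += w.sum()
        total_w2 += (w**2).sum()
    mean = total_w / n_paths
    se = np.sqrt(max(total_w2 / n_paths - mean**2, 0.0) / n_paths)
    return np.log(mean), se / mean


def test_absorbing_trial_matches_path_sampling_oracle():
    """Operator-chain likelihood of a 3-spike reaction-time trial agrees
    with a direct Monte-Carlo average over latent paths."""
    g = make_grid(64)
    model = LatentModel.from_functions(
        g, lambda x: -3.0 * x, 0.5,
        lambda x: np.exp(-(x**2) / (2 * 0.15**2)),
        lambda x: 4.0 + 2.0 * x, "absorbing",
    )
    trial = TrialObservations(
        0.0, np.array([0.12, 0.28, 0.41]), 0.55, "reaction-time"
    )
    ll = trial_loglik(model, trial)
    log_mc, se_log = _mc_path_loglik(
        model, trial, n_paths=120_000, dt=5e-4, delta=0.03, seed=42
    )
    assert abs(log_mc - ll) < 3 * se_log
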