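import numpy as np
import pytest

from latentlangevin import (
    LatentModel,
    SimConfig,
    absorption_rate,
    build_operators,
    equilibrium_density,
    make_grid,
    propagate,
    simulate_dataset,
)
from latentlangevin.simulate import fixture_model

from conftest import quadratic_model


def free_model(grid, boundary, noise=1.0):
    return LatentModel.from_functions(
        grid, lambda x: 0 * x, noise,
        lambda x: np.exp(-(x**2) / 0.05), lambda x: 10.0 + 0 * x, boundary,
    )


class TestBuildOperators:
    def test_free_diffusion_uniform_is_stationary(self, grid64):
        m = free_model(grid64, "reflecting")
        b = build_operators(m)
        uniform = np.full(64, 0.5)
        assert np.abs(b.H0 @ uniform).max() < 1e-8

    def test_equilibrium_is_null_vector(self, well_reflecting):
        b = build_operators(well_reflecting)
        peq = equilibrium_density(well_reflecting)
        assert np.abs(b.H0 @ peq).max() < 1e-7

    def test_reflecting_mass_conservation_left_null_vector(self, well_reflecting):
        b = build_operators(well_reflecting)
        w = well_reflecting.grid.quad_weights
        assert np.abs(w @ b.H0).max() < 1e-8

    def test_absorbing_spectrum_positive(self, well_absorbing):
        lam, _ = build_operators(well_absorbing).eig_H0
        assert lam.min() > 0

    def test_dirichlet_ground_mode_free_diffusion(self, grid64):
        m = free_model(grid64, "absorbing", noise=1.0)
        lam0 = build_operators(m).eig_H0[0][0]
        exact = (np.pi / 2) ** 2
        assert abs(lam0 - exact) / exact < 1e-4

    def test_H_minus_H0_is_rate_diagonal(self, well_absorbing):
        b = build_operators(well_absorbing)
        f_act = well_absorbing.rate_fn[b.active]
        diff = b.H_sym - b.H0_sym
        # off-diagonal entries are bitwise untouched by the rate sink
        assert np.array_equal(diff - np.diag(np.diag(diff)),
                              np.zeros_like(diff))
        # diagonal equals f up to cancellation against the stiff H0 scale
        scale = 1.0 + np.abs(np.diag(b.H0_sym))
        assert np.abs(np.diag(diff) - f_act).max() / scale.max() < 1e-12

    def test_rejects_negative_noise(self, grid16):
        with pytest.raises(ValueError):
            LatentModel.from_functions(
                grid16, lambda x: 0 * x, -0.1,
                lambda x: np.ones_like(x), lambda x: 1 + 0 * x, "reflecting",
            )


class TestPropagate:
    def test_dt_zero_is_identity(self, well_reflecting):
        b = build_operators(well_reflecting)
        p = well_reflecting.p0
        assert np.abs(propagate(b, p, 0.0) - p).max() < 1e-12

    def test_negative_dt_rejected(self, well_reflecting):
        b = build_operators(well_reflecting)
        with pytest.raises(ValueError):
            propagate(b, well_reflecting.p0, -0.1)

    def test_reflecting_conserves_mass(self, well_reflecting):
        b = build_operators(well_reflecting)
        for dt in (0.05, 0.7, 5.0):
            p = propagate(b, well_reflecting.p0, dt, which="H0")
            assert abs(b.mass(p) - 1.0) < 1e-9

    def test_neumann_heat_kernel_series(self):
        """Free diffusion from a central delta matches the cosine series."""
        g = make_grid(65)  # odd so that x = 0 is a node
        m = free_model(g, "reflecting", noise=1.0)
        b = build_operators(m)
        p = propagate(b, g.delta(0.0), 0.1, which="H0")
        x = g.nodes
        series = np.full_like(x, 0.5)
        for k in range(1, 300):
            series += (np.exp(-((k * np.pi / 2) ** 2) * 0.1)
                       * np.cos(k * np.pi / 2) * np.cos(k * np.pi * (x + 1) / 2))
        assert np.abs(p - series).max() < 1e-5

    def test_semigroup_property(self, well_absorbing):
        b = build_operators(well_absorbing)
        p1 = propagate(b, propagate(b, well_absorbing.p0, 0.3), 0.4)
        p2 = propagate(b, well_absorbing.p0, 0.7)
        assert np.abs(p1 - p2).max() < 1e-9

    def test_positivity_up_to_discretization(self, well_reflecting):
        b = build_operators(well_reflecting)
        p = propagate(b, well_reflecting.p0, 0.2, which="H0")
        assert p.min() > -1e-9

    def test_relaxation_to_equilibrium(self, well_reflecting):
        m = well_reflecting
        b = build_operators(m)
        p = propagate(b, m.p0, 50.0 / m.noise, which="H0")
        peq = equilibrium_density(m)
        assert m.grid.integrate(np.abs(p - peq)) < 1e-6

    def test_absorbing_mass_nonincreasing(self, well_absorbing):
        b = build_operators(well_absorbing)
        masses = [
            b.mass(propagate(b, well_absorbing.p0, dt, which="H0"))
            for dt in (0.0, 0.1, 0.3, 1.0, 3.0)
        ]
        assert np.all(np.diff(masses) <= 1e-12)


class TestEquilibriumDensity:
    def test_constant_potential_uniform(self, grid64):
        m = free_model(grid64, "reflecting")
        assert np.abs(equilibrium_density(m) - 0.5).max() < 1e-12

    def test_symmetric_well_peaks_at_zero(self, well_reflecting):
        peq = equilibrium_density(well_reflecting)
        # unimodal, peaked at one of the two nodes straddling x = 0
        assert abs(well_reflecting.grid.nodes[np.argmax(peq)]) < 0.05
        assert np.all(np.diff(peq[: np.argmax(peq)]) > 0)
        assert np.all(np.diff(peq[np.argmax(peq):]) <= 1e-15)

    def test_normalization(self, well_absorbing):
        m = well_absorbing
        assert abs(m.grid.integrate(equilibrium_density(m)) - 1.0) < 1e-10


class TestAbsorptionRate:
    def test_requires_absorbing_mode(self, well_reflecting):
        b = build_operators(well_reflecting)
        with pytest.raises(ValueError):
            absorption_rate(b, well_reflecting.p0)

    def test_zero_for_interior_density(self, well_absorbing):
        b = build_operators(well_absorbing)
        # narrow bump well away from the boundaries
        x = well_absorbing.grid.nodes
        p = np.exp(-(x**2) / 0.02)
        p /= well_absorbing.grid.integrate(p)
        assert abs(absorption_rate(b, p)) < 1e-6

    def test_matches_mass_decay_rate(self, well_absorbing):
        """integral(A rho) equals -d/dt of total mass under H0."""
        b = build_operators(well_absorbing)
        p = propagate(b, well_absorbing.p0, 0.2, which="H0")
        rate = absorption_rate(b, p)
        eps = 1e-5
        m_plus = b.mass(propagate(b, p, eps, which="H0"))
        m_minus = b.mass(p)
        fd = -(m_plus - m_minus) / eps
        assert abs(rate - fd) / abs(fd) < 1e-4

    def test_integrated_rate_recovers_initial_mass(self, well_absorbing):
        b = build_operators(well_absorbing)
        dt, total, t = 0.01, 0.0, 0.0
        p = well_absorbing.p0
        while b.mass(p) > 1e-4 and t < 50:
            pm = propagate(b, p, dt / 2, which="H0")
            total += absorption_rate(b, pm) * dt
            p = propagate(b, p, dt, which="H0")
            t += dt
        assert abs(total - (1.0 - b.mass(p))) < 1e-3

    def test_profile_matches_first_passage_histogram(self):
        """Absorption-rate time profile vs an Euler-Maruyama first-passage
        histogram (tilted potential, the ramping fixture)."""
        gt = fixture_model("ramping", 64)
        data = simulate_dataset(
            gt, SimConfig(n_trials=20000, dt_sim=2e-4, rng_seed=11)
        )
        durations = np.array([t.duration for t in data])
        b = build_operators(gt)
        edges = np.arange(0.0, 2.0001, 0.1)
        counts, _ = np.histogram(durations, edges)
        n = len(durations)
        # per-bin model probability by Simpson quadrature of the rate
        from scipy.integrate import simpson

        for k in range(len(edges) - 1):
            ts = np.linspace(edges[k], edges[k + 1], 11)
            rates = [
                absorption_rate(b, propagate(b, gt.p0, t, which="H0"))
                for t in ts
            ]
            p_model = simpson(rates, x=ts)
            se = np.sqrt(max(p_model * (1 - p_model), 1e-12) / n)
            assert abs(counts[k] / n - p_model) < 3 * se + 2e-3


def test_gauge_shift_leaves_operators_invariant(grid32):
    m1 = quadratic_model(grid32, "absorbing")
    # same physical model built from a shifted potential (re-gauged)
    m2 = LatentModel.from_functions(
        grid32, lambda x: x**2 + 4.2, m1.noise, m1.p0, m1.rate_fn, "absorbing"
    )
    b1, b2 = build_operators(m1), build_operators(m2)
    assert np.abs(b1.H0_sym - b2.H0_sym).max() < 1e-9
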