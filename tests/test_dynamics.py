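"""Lattice operators, the five-term flux divergence, RK4 and conservation."""

import numpy as np
import pytest
from dataclasses import replace

from barrelmap import dynamics, operators
from barrelmap.dynamics import ModelParams, SimState


class TestLaplacian:
    def test_constant_field_zero(self, lattice500):
        assert np.allclose(operators.laplacian(np.full(lattice500.n_hex, 3.7),
                                               lattice500), 0.0)

    def test_exact_on_quadratics(self, lattice500):
        x, y = lattice500.centres.T
        lap = operators.laplacian(x ** 2 + y ** 2, lattice500)
        interior = lattice500.interior_mask()
        assert np.allclose(lap[interior], 4.0, atol=1e-9)

    def test_total_laplacian_telescopes_to_zero(self, lattice500, rng):
        f = rng.normal(size=lattice500.n_hex)
        total = operators.laplacian(f, lattice500).sum() * lattice500.omega
        scale = np.abs(operators.laplacian(f, lattice500)).sum() * lattice500.omega
        assert abs(total) < 1e-12 * scale


class TestGradient:
    def test_exact_on_linear_fields(self, lattice500):
        x = lattice500.centres[:, 0]
        g = operators.gradient(2.0 * x, lattice500)
        interior = lattice500.interior_mask()
        assert np.allclose(g[interior], [2.0, 0.0], atol=1e-9)

    def test_constant_field_zero(self, lattice500):
        g = operators.gradient(np.full(lattice500.n_hex, 1.23), lattice500)
        assert np.allclose(g, 0.0)

    def test_rotation_equivariance(self, lattice500):
        x, y = lattice500.centres.T
        theta = 0.7
        f0 = 1.5 * x
        f_rot = 1.5 * (np.cos(theta) * x + np.sin(theta) * y)
        interior = lattice500.interior_mask()
        g0 = operators.gradient(f0, lattice500)[interior]
        g_rot = operators.gradient(f_rot, lattice500)[interior]
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert np.allclose(g_rot, g0 @ R.T, atol=1e-9)


class TestADivG:
    def test_constant_vector_field_zero_interior(self, lattice500):
        g = np.tile([1.3, -0.4], (lattice500.n_hex, 1))
        out = operators.a_divg(np.ones(lattice500.n_hex), g, lattice500)
        interior = lattice500.interior_mask()
        assert np.allclose(out[interior], 0.0, atol=1e-9)

    def test_zero_density_gives_zero(self, lattice500, rng):
        g = rng.normal(size=(lattice500.n_hex, 2))
        out = operators.a_divg(np.zeros(lattice500.n_hex), g, lattice500)
        assert np.allclose(out, 0.0)

    def test_linear_vector_field_divergence_two(self, lattice500):
        g = lattice500.centres.copy()   # g = (x, y), div = 2
        out = operators.a_divg(np.ones(lattice500.n_hex), g, lattice500)
        interior = lattice500.interior_mask()
        assert np.allclose(out[interior], 2.0, atol=1e-9)


class TestComputeDivJ:
    def test_reduces_to_pure_diffusion(self, lattice500, rng):
        a = rng.uniform(0.2, 0.4, lattice500.n_hex)
        params = ModelParams(N=2, epsilon=0.0, steps=1)
        zero_g = np.zeros((lattice500.n_hex, 2))
        out = dynamics.compute_divJ(a, a.copy(), zero_g, np.zeros(lattice500.n_hex),
                                    params, lattice500, eps_i=0.0)
        assert np.allclose(out, params.D * operators.laplacian(a, lattice500))

    def test_uniform_state_is_stationary(self, lattice500):
        a = np.full(lattice500.n_hex, 0.3)
        params = ModelParams(N=3, steps=1)
        zero_g = np.zeros((lattice500.n_hex, 2))
        out = dynamics.compute_divJ(a, 2 * a, zero_g, np.zeros(lattice500.n_hex),
                                    params, lattice500)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_global_balance_on_random_states(self, lattice500, guidance500, rng):
        _, _, proj = guidance500
        params = ModelParams(N=5, steps=1)
        a = rng.uniform(0.2, 0.4, (5, lattice500.n_hex))
        total = a.sum(axis=0)
        for i in range(5):
            divJ = dynamics.compute_divJ(a[i], total - a[i], proj.g[i],
                                         proj.div_g[i], params, lattice500)
            imbalance = abs(divJ.sum()) / np.abs(divJ).sum()
            assert imbalance < 1e-12

    def test_competition_without_partner_rejected(self, lattice500):
        a = np.ones(lattice500.n_hex)
        with pytest.raises(ValueError):
            ModelParams(N=1, epsilon=1.2, steps=1)
        params = ModelParams(N=1, epsilon=0.0, steps=1)
        with pytest.raises(ValueError):
            dynamics.compute_divJ(a, a, np.zeros((lattice500.n_hex, 2)),
                                  np.zeros(lattice500.n_hex), params, lattice500,
                                  eps_i=1.0)


class TestDcDt:
    def test_zero_state_zero_rate(self):
        params = ModelParams(N=1, epsilon=0.0, steps=1)
        assert dynamics.dc_dt(np.zeros((1, 4)), np.zeros((1, 4)), params).sum() == 0

    def test_single_projection_fixed_point(self):
        # frozen a = 0.3: c* = beta a^3 / (alpha + beta a^3) = 0.11113
        params = ModelParams(N=1, epsilon=0.0, steps=1)
        a = np.full((1, 8), 0.3)
        c_star = 16.67 * 0.027 / (3.6 + 16.67 * 0.027)
        assert c_star == pytest.approx(0.11113, abs=5e-6)
        rate = dynamics.dc_dt(a, np.full((1, 8), c_star), params)
        assert np.allclose(rate, 0.0, atol=1e-12)

    def test_saturation_forces_decay(self):
        params = ModelParams(N=2, steps=1)
        a = np.full((2, 4), 0.5)
        c = np.full((2, 4), 0.5)   # sum_j c_j = 1 exactly
        rate = dynamics.dc_dt(a, c, params)
        assert (rate < 0).all()
        assert np.allclose(rate, -params.alpha * c)

    def test_symmetric_multiprojection_equilibrium(self, lattice500, guidance500):
        # uniform frozen a for all N: c* = beta a^k / (alpha + N beta a^k)
        params = ModelParams(N=5, steps=1)
        a = np.full((5, lattice500.n_hex), 0.3)
        c_star = 16.67 * 0.027 / (3.6 + 5 * 16.67 * 0.027)
        rate = dynamics.dc_dt(a, np.full_like(a, c_star), params)
        assert np.allclose(rate, 0.0, atol=1e-12)


class TestRk4:
    def test_kernel_matches_reference_operators(self, lattice500, guidance500, rng):
        _, _, proj = guidance500
        params = ModelParams(N=5, steps=1)
        state = dynamics.init_state(lattice500, params, seed=11)
        state.c = rng.uniform(0, 0.05, state.c.shape)
        s_fast = dynamics.rk4_step(state, proj, params, lattice500, use_numba=True)
        s_ref = dynamics.rk4_step(state, proj, params, lattice500, use_numba=False)
        assert np.allclose(s_fast.a, s_ref.a, atol=1e-13)
        assert np.allclose(s_fast.c, s_ref.c, atol=1e-13)

    def test_zero_rate_state_is_fixed_point(self, lattice500, guidance500):
        _, _, proj = guidance500
        params = ModelParams(N=5, epsilon=0.0, alpha=0.0, beta=0.0, D=0.0, steps=1)
        proj0 = replace(proj, g=np.zeros_like(proj.g), div_g=np.zeros_like(proj.div_g))
        state = dynamics.init_state(lattice500, params, seed=2)
        out = dynamics.rk4_step(state, proj0, params, lattice500)
        assert np.array_equal(out.a, state.a)
        assert out.step == state.step + 1

    def test_exponential_decay_to_rk4_order(self, lattice500, guidance500):
        # dc/dt = -alpha c with a frozen at 0: one step vs exp(-alpha dt)
        _, _, proj = guidance500
        dt = 0.01
        params = ModelParams(N=5, alpha=3.6, beta=0.0, D=0.0, epsilon=0.0, dt=dt,
                             steps=1)
        proj0 = replace(proj, g=np.zeros_like(proj.g), div_g=np.zeros_like(proj.div_g))
        state = SimState(a=np.zeros((5, lattice500.n_hex)),
                         c=np.full((5, lattice500.n_hex), 0.8))
        out = dynamics.rk4_step(state, proj0, params, lattice500)
        exact = 0.8 * np.exp(-3.6 * dt)
        lte = (3.6 * dt) ** 5 / 120 * 0.8
        assert np.abs(out.c - exact).max() < 2 * lte

    def test_order_four_convergence(self, ellipse500, guidance500):
        # Richardson: halving dt shrinks the error ~16-fold
        from barrelmap import hexgrid, synthetic

        boundary = ellipse500[0]
        lat = hexgrid.build_lattice(boundary, 0.1)
        import barrelmap.guidance as gd
        import pandas as pd

        coords = pd.DataFrame({"label": list("abc"), "p": [0, 1, 2],
                               "q": [0, 1, 0.5]})
        gamma = gd.scale_interactions(coords)
        fields = [gd.make_linear_field(lat, gd.GuidanceFieldSpec(phi=0.0)),
                  gd.make_linear_field(lat, gd.GuidanceFieldSpec(phi=84.0))]
        proj = gd.compute_projection_guidance(gamma, fields, lat)

        def advance(dt, nsteps):
            params = ModelParams(N=3, dt=dt, steps=nsteps)
            state = dynamics.init_state(lat, params, seed=4)
            for _ in range(nsteps):
                state = dynamics.rk4_step(state, proj, params, lat)
            return state.a

        ref = advance(0.0005, 16)
        err1 = np.abs(advance(0.004, 2) - ref).max()
        err2 = np.abs(advance(0.002, 4) - ref).max()
        order = np.log2(err1 / err2)
        assert 3.3 < order < 5.5

    def test_instability_detected(self, lattice500, guidance500):
        _, _, proj = guidance500
        params = ModelParams(N=5, D=500.0, dt=1e-2, steps=50)
        traj = dynamics.run_simulation(lattice500, proj, params, seed=1,
                                       snapshot_every=50, compute_honda=False)
        assert not traj.stable


class TestInitState:
    def test_deterministic_uniform_control(self, lattice500):
        params = ModelParams(N=4, steps=1)
        st = dynamics.init_state(lattice500, params, seed=1, a_lo=0.3, a_hi=0.3)
        assert (st.a == 0.3).all() and (st.c == 0).all()

    def test_sample_mean_near_band_centre(self, lattice500):
        params = ModelParams(N=8, steps=1)
        st = dynamics.init_state(lattice500, params, seed=6)
        se = (0.4 - 0.2) / np.sqrt(12 * st.a.size)
        assert abs(st.a.mean() - 0.3) < 5 * se

    def test_same_seed_bit_identical(self, lattice500):
        params = ModelParams(N=3, steps=1)
        a = dynamics.init_state(lattice500, params, seed=9)
        b = dynamics.init_state(lattice500, params, seed=9)
        assert np.array_equal(a.a, b.a)


class TestConservation:
    def test_mass_conserved_over_run(self, lattice500, guidance500):
        _, _, proj = guidance500
        params = ModelParams(N=5, steps=500)
        m0 = dynamics.init_state(lattice500, params, seed=3).mass(lattice500)
        traj = dynamics.run_simulation(lattice500, proj, params, seed=3,
                                       snapshot_every=500, compute_honda=False)
        drift = np.abs(traj.state.mass(lattice500) / m0 - 1.0)
        assert drift.max() < 1e-10

    def test_rate_mass_balance_per_projection(self, lattice500, guidance500, rng):
        _, _, proj = guidance500
        params = ModelParams(N=5, steps=1)
        state = dynamics.init_state(lattice500, params, seed=5)
        state.c = rng.uniform(0, 0.1, state.c.shape)
        da, dc = dynamics.da_dt(state, proj, params, lattice500)
        total = (da + dc).sum(axis=1) * lattice500.omega
        scale = np.abs(da + dc).sum(axis=1) * lattice500.omega
        assert (np.abs(total) < 1e-12 * scale).all()

    def test_isolated_projection_migrates_to_guidance_extremum(self, lattice500):
        # chemospecificity contrast: a single projection drifts up its gradient
        import barrelmap.guidance as gd

        f = gd.make_linear_field(lattice500, gd.GuidanceFieldSpec(phi=0.0))
        im = gd.InteractionMatrix(gamma=np.array([[2.0]]), labels=["solo"])
        proj = gd.compute_projection_guidance(im, [f], lattice500)
        params = ModelParams(N=1, epsilon=0.0, alpha=0.0, beta=0.0, dt=4e-4,
                             steps=2500)
        traj = dynamics.run_simulation(lattice500, proj, params, seed=8,
                                       snapshot_every=2500, compute_honda=False)
        x = lattice500.centres[:, 0]
        w0 = dynamics.init_state(lattice500, params, seed=8).a[0]
        x0 = (x * w0).sum() / w0.sum()
        x1 = (x * traj.state.a[0]).sum() / traj.state.a[0].sum()
        assert x1 > x0 + 0.1   # centre of mass moved up-gradient


class TestHeatEquationLimit:
    def test_spike_spreads_and_peak_decays(self, lattice500):
        import barrelmap.guidance as gd

        im = gd.InteractionMatrix(gamma=np.zeros((1, 1)), labels=["h"])
        f = gd.make_linear_field(lattice500, gd.GuidanceFieldSpec(phi=0.0))
        proj = gd.compute_projection_guidance(im, [f], lattice500)
        params = ModelParams(N=1, epsilon=0.0, alpha=0.0, beta=0.0, dt=2e-4,
                             steps=300)
        centre = int(np.argmin(np.linalg.norm(lattice500.centres, axis=1)))
        a = np.zeros((1, lattice500.n_hex))
        a[0, centre] = 1.0
        state = SimState(a=a.copy(), c=np.zeros_like(a))
        peaks = [a.max()]
        for _ in range(3):
            for _ in range(100):
                state = dynamics.rk4_step(state, proj, params, lattice500)
            peaks.append(state.a.max())
        assert all(p1 > p2 for p1, p2 in zip(peaks, peaks[1:]))
        assert state.a.min() > -1e-9   # diffusion keeps the spike non-negative
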