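"""Guidance fields, interaction scaling, boundary fall-off and noise models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from barrelmap import guidance as gd, hexgrid, operators, synthetic
from barrelmap.guidance import GuidanceFieldSpec


class TestLinearField:
    def test_phi0_increases_in_x_constant_in_y(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        x = lattice500.centres[:, 0]
        order = np.argsort(x)
        assert (np.diff(f.rho[order]) >= -1e-12).all()
        assert np.allclose(f.grad_rho[:, 1], 0.0)
        assert f.rho.min() == pytest.approx(0.0) and f.rho.max() == pytest.approx(1.0)

    def test_phi90_swaps_axes(self, lattice500):
        f90 = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=90.0))
        y = lattice500.centres[:, 1]
        order = np.argsort(y)
        assert (np.diff(f90.rho[order]) >= -1e-12).all()
        assert np.allclose(f90.grad_rho[:, 0], 0.0, atol=1e-12)
        # the gradient magnitude is the reciprocal of the y extent
        assert f90.grad_rho[0, 1] == pytest.approx(1.0 / (y.max() - y.min()))

    def test_halving_gain_halves_gradient(self, lattice500):
        f1 = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=30.0, gain=1.0))
        f2 = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=30.0, gain=0.5))
        assert np.allclose(f2.grad_rho, 0.5 * f1.grad_rho)

    def test_gradient_consistent_with_lattice_operator(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=25.0, gain=1.3))
        num = operators.gradient(f.rho, lattice500)
        interior = lattice500.interior_mask()
        assert np.allclose(num[interior], f.grad_rho[interior], atol=1e-9)


class TestFieldNoise:
    def test_zero_noise_is_identity(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        f2 = gd.add_field_noise(f, lattice500, 0.0, 0.05, seed=1)
        assert np.array_equal(f.rho, f2.rho)

    def test_noise_mean_matches_uniform_law(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        nu = 0.3
        f2 = gd.add_field_noise(f, lattice500, nu, 0.0, seed=5)
        added = f2.rho - f.rho
        span = f.rho.max() - f.rho.min()
        expect = span * nu / 2.0
        assert added.mean() == pytest.approx(expect, rel=0.15)
        assert added.min() >= 0.0

    def test_smoothing_reduces_noise_variance_monotonically(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        var_by_sigma = []
        for sigma in (0.0, 0.05, 0.12):
            residuals = []
            for seed in range(20):
                f2 = gd.add_field_noise(f, lattice500, 0.5, sigma, seed=seed)
                residuals.append(np.var(f2.rho - f.rho))
            var_by_sigma.append(np.mean(residuals))
        assert var_by_sigma[0] > var_by_sigma[1] > var_by_sigma[2]

    def test_sigma_zero_smoothing_identity_on_noisy_field(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        a = gd.add_field_noise(f, lattice500, 0.4, 0.0, seed=9)
        b = gd.add_field_noise(f, lattice500, 0.4, 0.0, seed=9)
        assert np.array_equal(a.rho, b.rho)


class TestMirrorField:
    @pytest.fixture(scope="class")
    def mirrored(self):
        base = synthetic.make_barrelfield_boundary(scale=0.5)
        doubled, join_x = synthetic.mirror_boundary(base)
        cen = doubled.polygon.centroid
        lat = hexgrid.build_lattice(doubled, 0.05, anchor=(join_x, cen.y))
        return base, doubled, join_x, lat

    def test_mirrored_field_equal_at_mirror_pairs(self, mirrored):
        _, _, join_x, lat = mirrored
        f = gd.make_mirrored_linear_field(lat, GuidanceFieldSpec(phi=0.0), join_x)
        pair = gd._mirror_pairing(lat, join_x)
        assert np.allclose(f.rho, f.rho[pair], atol=1e-12)

    def test_normal_gradient_antisymmetric_across_join(self, mirrored):
        _, _, join_x, lat = mirrored
        f = gd.make_mirrored_linear_field(lat, GuidanceFieldSpec(phi=0.0), join_x)
        pair = gd._mirror_pairing(lat, join_x)
        off = np.abs(lat.centres[:, 0] - join_x) > lat.d / 2   # exclude the fold ridge
        assert np.allclose(f.grad_rho[off, 0], -f.grad_rho[pair[off], 0], atol=1e-12)
        assert np.allclose(f.grad_rho[off, 1], f.grad_rho[pair[off], 1], atol=1e-12)

    def test_mirror_of_existing_field_restricts_to_original(self, mirrored):
        _, _, join_x, lat = mirrored
        lin = gd.make_linear_field(lat, GuidanceFieldSpec(phi=0.0))
        mir = gd.mirror_field(lin, lat, join_x)
        left = lat.centres[:, 0] <= join_x
        assert np.array_equal(mir.rho[left], lin.rho[left])

    def test_asymmetric_lattice_rejected(self, lattice500):
        lin = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        with pytest.raises(ValueError, match="not symmetric"):
            gd.mirror_field(lin, lattice500, lattice500.centres[:, 0].max() * 0.5)


class TestInteractionScaling:
    def test_extremes_map_to_plus_minus_two(self):
        coords = pd.DataFrame({"label": list("abcd"), "p": [0, 1, 2, 10],
                               "q": [5, 1, 3, 2]})
        im = gd.scale_interactions(coords)
        assert im.gamma[:, 0].min() == pytest.approx(-2.0)
        assert im.gamma[:, 0].max() == pytest.approx(2.0)
        assert im.gamma[:, 1].min() == pytest.approx(-2.0)
        assert im.gamma[:, 1].max() == pytest.approx(2.0)

    def test_rank_order_preserved_and_midpoint_zero(self):
        coords = pd.DataFrame({"label": list("abc"), "p": [0.0, 5.0, 10.0],
                               "q": [1.0, 2.0, 3.0]})
        im = gd.scale_interactions(coords)
        assert im.gamma[1, 0] == pytest.approx(0.0)
        assert (np.diff(im.gamma[:, 0]) > 0).all()

    def test_degenerate_axis_rejected(self):
        coords = pd.DataFrame({"label": ["a", "b"], "p": [0, 1], "q": [2, 2]})
        with pytest.raises(ValueError, match="degenerate axis"):
            gd.scale_interactions(coords)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            gd.InteractionMatrix(gamma=np.zeros((2, 2)), labels=["x", "x"])

    def test_gamma_noise_mean_shift(self):
        coords = pd.DataFrame({"label": [str(i) for i in range(200)],
                               "p": np.linspace(0, 1, 200),
                               "q": np.linspace(3, 4, 200)})
        im = gd.scale_interactions(coords)
        noisy = gd.add_gamma_noise(im, 0.25, seed=3)
        shift = (noisy.gamma - im.gamma).mean(axis=0)
        assert np.allclose(shift, 4.0 * 0.25 / 2.0, rtol=0.15)

    def test_gamma_noise_zero_identity(self):
        coords = pd.DataFrame({"label": ["a", "b"], "p": [0, 1], "q": [0, 1]})
        im = gd.scale_interactions(coords)
        assert np.array_equal(gd.add_gamma_noise(im, 0.0, seed=1).gamma, im.gamma)


class TestBoundaryFalloff:
    def test_reference_values(self):
        assert gd.boundary_falloff(0.1, 0.1) == pytest.approx(0.5)
        assert gd.boundary_falloff(0.2, 0.1) == pytest.approx(0.9999546, abs=1e-7)
        assert gd.boundary_falloff(0.0, 0.1) == pytest.approx(4.53978687e-5, rel=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.25), st.floats(1e-3, 0.05))
    def test_strictly_increasing_in_db(self, d_b, step):
        # range restricted to where the logistic has not saturated to 1.0
        # at double precision
        assert gd.boundary_falloff(d_b + step, 0.1) > gd.boundary_falloff(d_b, 0.1)


class TestProjectionGuidance:
    def test_zero_gamma_row_gives_zero_guidance(self, lattice500, guidance500):
        gamma, fields, _ = guidance500
        im = gd.InteractionMatrix(gamma=np.zeros((2, 2)), labels=["z1", "z2"])
        proj = gd.compute_projection_guidance(im, fields, lattice500)
        assert np.allclose(proj.g, 0.0) and np.allclose(proj.div_g, 0.0)

    def test_interior_magnitude_matches_analytic(self, lattice500):
        f = gd.make_linear_field(lattice500, GuidanceFieldSpec(phi=0.0))
        slope = np.linalg.norm(f.grad_rho[0])
        im = gd.InteractionMatrix(gamma=np.array([[2.0]]), labels=["a"])
        proj = gd.compute_projection_guidance(im, [f], lattice500)
        deep = lattice500.d_b > 0.25   # falloff ~ 1 there
        assert np.allclose(np.linalg.norm(proj.g[0][deep], axis=1), 2.0 * slope,
                           rtol=1e-6)

    def test_divergence_theorem_total_divg_zero(self, lattice500, guidance500):
        _, _, proj = guidance500
        total = proj.div_g.sum(axis=1) * lattice500.omega
        scale = np.abs(proj.div_g).sum(axis=1) * lattice500.omega
        assert (np.abs(total) <= 1e-12 * np.maximum(scale, 1e-300)).all()

    def test_negated_gamma_negates_guidance(self, lattice500, guidance500):
        gamma, fields, proj = guidance500
        im2 = gd.InteractionMatrix(gamma=-gamma.gamma, labels=list(gamma.labels))
        proj2 = gd.compute_projection_guidance(im2, fields, lattice500)
        assert np.allclose(proj2.g, -proj.g)
        assert np.allclose(proj2.div_g, -proj.div_g)

    def test_mismatched_field_count_rejected(self, lattice500, guidance500):
        gamma, fields, _ = guidance500
        with pytest.raises(ValueError, match="columns"):
            gd.compute_projection_guidance(gamma, fields[:1], lattice500)
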