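"""Shared fixtures: small lattices and guidance setups used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from barrelmap import dynamics, guidance as gd, hexgrid, synthetic


def ellipse_lattice_with(n_hex_target: int, semi_major=1.0, semi_minor=0.5):
    """An elliptical lattice with approximately the requested hex count."""
    area = np.pi * semi_major * semi_minor
    d = float(np.sqrt(area / n_hex_target / (np.sqrt(3.0) / 2.0)))
    boundary = synthetic.make_ellipse_boundary(semi_major, semi_minor)
    return boundary, hexgrid.build_lattice(boundary, d)


@pytest.fixture(scope="session")
def ellipse500():
    """Boundary and ~500-hex lattice on a 1.0 x 0.5 mm ellipse."""
    return ellipse_lattice_with(500)


@pytest.fixture(scope="session")
def lattice500(ellipse500):
    return ellipse500[1]


@pytest.fixture(scope="session")
def guidance500(lattice500):
    """Two linear fields and a 5-projection interaction matrix on lattice500."""
    coords = pd.DataFrame({"label": [f"P{i}" for i in range(5)],
                           "p": np.linspace(0.0, 4.0, 5),
                           "q": [0.0, 1.0, 0.3, 0.8, 0.5]})
    gamma = gd.scale_interactions(coords)
    fields = [gd.make_linear_field(lattice500, gd.GuidanceFieldSpec(phi=0.0)),
              gd.make_linear_field(lattice500, gd.GuidanceFieldSpec(phi=84.0))]
    return gamma, fields, gd.compute_projection_guidance(gamma, fields, lattice500)


@pytest.fixture(scope="session")
def params5():
    return dynamics.ModelParams(N=5, steps=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
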