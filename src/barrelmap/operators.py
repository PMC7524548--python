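"""Finite-volume differential operators on the hexagonal lattice.

All operators are derived by applying Gauss's theorem to the mean value over
one hexagonal cell, which reduces each divergence to a sum over the six cell
edges and hence to nearest-neighbour communication only.

No-flux (Neumann) boundaries are enforced with ghost cells: where a neighbour
is missing, scalar fields take the ghost value f(p0) (so the difference, and
the flux through that edge, vanish), while guidance-type vector fields take
the ghost value 0 (they are tailored to vanish at the boundary anyway by the
logistic fall-off).

The Laplacian stencil is exact for polynomials of degree <= 2 and the
gradient stencil for degree <= 1, which the tests verify.
"""

from __future__ import annotations

import numpy as np

_ANG = np.pi * np.arange(6) / 3.0
COS_J = np.cos(_ANG)
SIN_J = np.sin(_ANG)


def neighbour_values(f: np.ndarray, neighbours: np.ndarray, ghost: str = "copy") -> np.ndarray:
    """Gather f at the 6 neighbours of every hex; shape (..., H) -> (..., H, 6).

    ghost='copy' substitutes the centre value at missing neighbours,
    ghost='zero' substitutes 0.
    """
    safe = np.where(neighbours < 0, 0, neighbours)
    vals = f[..., safe]
    if ghost == "copy":
        vals = np.where(neighbours < 0, f[..., :, None], vals)
    elif ghost == "zero":
        vals = np.where(neighbours < 0, 0.0, vals)
    else:
        raise ValueError(f"unknown ghost rule {ghost!r}")
    return vals


def laplacian(f: np.ndarray, lattice) -> np.ndarray:
    """Cell-mean Laplacian: (2 / 3 d^2) * sum_j (f(p_j) - f(p_0))."""
    diff = neighbour_values(f, lattice.neighbours, "copy") - f[..., None]
    return (2.0 / (3.0 * lattice.d ** 2)) * diff.sum(axis=-1)


def gradient(f: np.ndarray, lattice) -> np.ndarray:
    """Cell-mean gradient: (1 / 3 d) * sum_j (f(p_j) - f(p_0)) n_j; shape (..., H, 2)."""
    diff = neighbour_values(f, lattice.neighbours, "copy") - f[..., None]
    inv = 1.0 / (3.0 * lattice.d)
    return np.stack([inv * (diff @ COS_J), inv * (diff @ SIN_J)], axis=-1)


def vector_divergence(g: np.ndarray, lattice, rim: str = "ghost-zero") -> np.ndarray:
    """Flux-sum divergence of a per-hex vector field; shape (..., H, 2) -> (..., H).

    div g(p0) ~ (1 / 3 d) * sum_j [(gx(p_j) + gx(p_0)) cos(pi(j-1)/3)
                                   + (gy(p_j) + gy(p_0)) sin(pi(j-1)/3)]

    rim='ghost-zero' substitutes the ghost vector 0 at missing neighbours
    (the edge then still carries the half-flux g(p_0)/2); rim='no-flux' zeroes
    the whole flux through boundary edges, the discrete form of the zero-flux
    boundary condition, which makes the flux sum telescope exactly:
    sum_hex div*Omega = 0 to machine precision.
    """
    gx, gy = g[..., 0], g[..., 1]
    nx = neighbour_values(gx, lattice.neighbours, "zero")
    ny = neighbour_values(gy, lattice.neighbours, "zero")
    if rim == "ghost-zero":
        sx = nx + gx[..., None]
        sy = ny + gy[..., None]
    elif rim == "no-flux":
        present = lattice.neighbours >= 0
        sx = nx + np.where(present, gx[..., None], 0.0)
        sy = ny + np.where(present, gy[..., None], 0.0)
    else:
        raise ValueError(f"unknown rim rule {rim!r}")
    return (sx @ COS_J + sy @ SIN_J) / (3.0 * lattice.d)


def a_divg(a: np.ndarray, g: np.ndarray, lattice) -> np.ndarray:
    """Advection modulator a(p0) * div g(p0) (flux-sum form of the divergence)."""
    return a * vector_divergence(g, lattice)
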