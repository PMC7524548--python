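"""Molecular guidance fields, thalamic interaction strengths and per-projection
static guidance vector fields.

M scalar concentration fields rho_j (phenomenological stand-ins for graded
guidance cues such as ephrin-A5) cover the cortical sheet.  Each of the N
thalamocortical projections carries an interaction strength gamma_{i,j} with
each field, derived from the projection's barreloid coordinate in the
thalamus, so that relative thalamic position is encoded as relative guidance
sensitivity.  The resulting static vector field

    g_i(x) = falloff(d_b(x)) * sum_j gamma_{i,j} * grad rho_j(x)

advects the projection's axon-branching density; a sharp logistic fall-off
with distance to the boundary makes g_i and its normal derivative vanish at
the rim, which together with ghost cells enforces the no-flux condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import operators
from .hexgrid import HexLattice

DEFAULT_FALLOFF_MM = 0.1       # d_f: fall-off distance, ~3 hexes at d = 0.03 mm
FALLOFF_SHARPNESS = 100.0      # logistic steepness, mm^-1
GAMMA_SPAN = 2.0               # interaction strengths scaled to +/- 2


@dataclass
class GuidanceFieldSpec:
    """Declarative description of one cortical guidance field."""

    kind: str = "linear"             # linear | offset-logistic | mirrored
    phi: float = 0.0                 # gradient orientation, degrees
    gain: float = 1.0                # overall gain G_rho
    noise_mag: float = 0.0           # nu_rho in [0, 1]
    noise_scale: float = 0.0         # sigma_rho, mm (Gaussian smoothing width)
    centre_frac: float = 0.5         # offset-logistic: centre along the axis, in [0,1]
    width_frac: float = 0.1          # offset-logistic: logistic width, fraction of axis
    mirror_x: float | None = None    # mirrored: x of the vertical join line

    def __post_init__(self):
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if self.noise_mag < 0 or self.noise_scale < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GuidanceField:
    """A scalar concentration over the lattice plus its gradient field."""

    rho: np.ndarray        # (H,)
    grad_rho: np.ndarray   # (H, 2), units mm^-1


@dataclass
class InteractionMatrix:
    """N x M interaction strengths gamma with unique projection labels."""

    gamma: np.ndarray           # (N, M)
    labels: list[str]

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("projection labels must be unique")
        if self.gamma.shape[0] != len(self.labels):
            raise ValueError("gamma rows must match labels")

    @property
    def n_projections(self) -> int:
        return self.gamma.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown projection label {label!r}") from None


@dataclass
class ProjectionGuidance:
    """Static per-projection guidance vectors and their lattice divergence."""

    g: np.ndarray        # (N, H, 2)
    div_g: np.ndarray    # (N, H)


# ---------------------------------------------------------------------------
# field construction

def _axis_coordinate(lattice: HexLattice, phi_deg: float) -> np.ndarray:
    phi = np.deg2rad(phi_deg)
    return lattice.centres[:, 0] * np.cos(phi) + lattice.centres[:, 1] * np.sin(phi)


def make_linear_field(lattice: HexLattice, spec: GuidanceFieldSpec) -> GuidanceField:
    """A linear gradient along direction phi, min-max normalized to [0,1], then gained.

    rho(x) = G * (t - t_min) / (t_max - t_min),   t = x cos(phi) + y sin(phi);
    the gradient is constant and computed analytically.
    """
    if lattice.n_hex == 0:
        raise ValueError("empty lattice")
    t = _axis_coordinate(lattice, spec.phi)
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("degenerate lattice: no extent along the field axis")
    rho = spec.gain * (t - t.min()) / span
    phi = np.deg2rad(spec.phi)
    grad = np.broadcast_to(
        spec.gain / span * np.array([np.cos(phi), np.sin(phi)]), (lattice.n_hex, 2)
    ).copy()
    return GuidanceField(rho=rho, grad_rho=grad)


def make_offset_logistic_field(lattice: HexLattice, spec: GuidanceFieldSpec) -> GuidanceField:
    """A logistic (sigmoidal) profile along direction phi, centred at centre_frac.

    rho(u) = G / (1 + exp(-(u - c) / w)) with u the [0,1]-normalized axis
    coordinate; its gradient is the analytic logistic bump.
    """
    if lattice.n_hex == 0:
        raise ValueError("empty lattice")
    t = _axis_coordinate(lattice, spec.phi)
    span = t.max() - t.min()
    u = (t - t.min()) / span
    w = spec.width_frac
    z = (u - spec.centre_frac) / w
    sig = 1.0 / (1.0 + np.exp(-z))
    rho = spec.gain * sig
    dr_du = spec.gain * sig * (1.0 - sig) / w
    phi = np.deg2rad(spec.phi)
    grad = (dr_du / span)[:, None] * np.array([np.cos(phi), np.sin(phi)])
    return GuidanceField(rho=rho, grad_rho=grad)


def make_field(lattice: HexLattice, spec: GuidanceFieldSpec,
               seed: int | None = None) -> GuidanceField:
    """Build a field from its spec, applying noise/smoothing if requested."""
    if spec.kind == "linear":
        fld = make_linear_field(lattice, spec)
    elif spec.kind == "offset-logistic":
        fld = make_offset_logistic_field(lattice, spec)
    elif spec.kind == "mirrored":
        if spec.mirror_x is None:
            raise ValueError("mirrored field requires mirror_x")
        fld = make_mirrored_linear_field(lattice, spec, spec.mirror_x)
    else:
        raise ValueError(f"unknown field kind {spec.kind!r}")
    if spec.noise_mag > 0:
        if seed is None:
            raise ValueError("field noise requested but no seed given")
        fld = add_field_noise(fld, lattice, spec.noise_mag, spec.noise_scale, seed)
    return fld


def _gaussian_smooth(values: np.ndarray, lattice: HexLattice, sigma: float) -> np.ndarray:
    """Convolve per-hex values with a 2D Gaussian of std sigma (mm), kernel
    evaluated at hex-centre offsets and renormalized per hex (no padding bias
    at the irregular rim)."""
    if sigma <= 0:
        return values.copy()
    tree = cKDTree(lattice.centres)
    pairs = tree.sparse_distance_matrix(tree, 3.5 * sigma, output_type="coo_matrix")
    w = np.exp(-0.5 * (pairs.data / sigma) ** 2)
    from scipy.sparse import coo_matrix

    K = coo_matrix((w, (pairs.row, pairs.col)), shape=pairs.shape).tocsr()
    norm = np.asarray(K.sum(axis=1)).ravel()
    return np.asarray(K @ values).ravel() / norm


def add_field_noise(fld: GuidanceField, lattice: HexLattice, nu_rho: float,
                    sigma_rho: float, seed: int) -> GuidanceField:
    """Add per-hex uniform noise (rho_max - rho_min) * U(0, nu_rho), then smooth
    with a Gaussian kernel of width sigma_rho; the gradient is recomputed
    numerically with the lattice gradient operator."""
    if nu_rho < 0 or sigma_rho < 0:
        raise ValueError("noise parameters must be >= 0")
    if nu_rho == 0:
        return GuidanceField(rho=fld.rho.copy(), grad_rho=fld.grad_rho.copy())
    rng = np.random.default_rng(seed)
    span = fld.rho.max() - fld.rho.min()
    rho = fld.rho + span * rng.uniform(0.0, nu_rho, size=fld.rho.shape)
    rho = _gaussian_smooth(rho, lattice, sigma_rho)
    grad = operators.gradient(rho, lattice)
    return GuidanceField(rho=rho, grad_rho=grad)


def _mirror_pairing(lattice: HexLattice, join_x: float) -> np.ndarray:
    """Index of the mirror-image hex of every hex across the line x = join_x.

    Raises if the lattice is not mirror-symmetric about the join.
    """
    reflected = lattice.centres.copy()
    reflected[:, 0] = 2.0 * join_x - reflected[:, 0]
    tree = cKDTree(lattice.centres)
    dist, idx = tree.query(reflected)
    if np.any(dist > 1e-6 * lattice.d + 1e-12):
        raise ValueError("lattice not symmetric about the join line")
    return idx


def make_mirrored_linear_field(lattice: HexLattice, spec: GuidanceFieldSpec,
                               join_x: float) -> GuidanceField:
    """A linear anterior-posterior field reflected at the vertical join line.

    rho is a function of the folded coordinate x' = join_x - |x - join_x|,
    min-max normalized over the lattice and gained; the gradient's x component
    flips sign on the mirrored half.  Models ectopic Fgf8 expression, which
    duplicates the anterior-posterior gradient in mirror image.
    """
    if abs(np.sin(np.deg2rad(spec.phi))) > 1e-9:
        raise ValueError("mirrored fields are defined for phi = 0 (anterior-posterior)")
    x = lattice.centres[:, 0]
    folded = join_x - np.abs(x - join_x)
    span = folded.max() - folded.min()
    if span <= 0:
        raise ValueError("degenerate lattice for mirrored field")
    rho = spec.gain * (folded - folded.min()) / span
    gx = np.where(x <= join_x, spec.gain / span, -spec.gain / span)
    grad = np.column_stack([gx, np.zeros_like(gx)])
    return GuidanceField(rho=rho, grad_rho=grad)


def mirror_field(fld: GuidanceField, lattice: HexLattice, join_x: float) -> GuidanceField:
    """Reflect an existing field's values from the x <= join_x half onto the other.

    The duplicated lattice must be mirror-symmetric about the vertical join
    line; values at x > join_x are replaced by those at the mirror image, and
    the gradient's x component flips sign there.
    """
    pair = _mirror_pairing(lattice, join_x)
    right = lattice.centres[:, 0] > join_x
    rho = fld.rho.copy()
    rho[right] = fld.rho[pair[right]]
    grad = fld.grad_rho.copy()
    grad[right] = fld.grad_rho[pair[right]]
    grad[right, 0] *= -1.0
    return GuidanceField(rho=rho, grad_rho=grad)


# ---------------------------------------------------------------------------
# interaction strengths

def scale_interactions(coords: pd.DataFrame) -> InteractionMatrix:
    """Affinely map labelled thalamic (p, q) coordinates onto gamma in [-2, 2].

    Each axis is scaled independently so its extreme coordinates land exactly
    on -2 and +2; the scaling is arbitrary because the coordinates carry
    relative position information only.
    """
    for col in ("label", "p", "q"):
        if col not in coords.columns:
            raise ValueError(f"coordinate table missing column {col!r}")
    if len(coords) < 2:
        raise ValueError("need at least 2 labelled coordinates")
    gamma = np.empty((len(coords), 2))
    for k, col in enumerate(("p", "q")):
        v = coords[col].to_numpy(float)
        span = v.max() - v.min()
        if span <= 0:
            raise ValueError(f"degenerate axis {col!r}: all coordinates equal")
        gamma[:, k] = GAMMA_SPAN * (2.0 * (v - v.min()) / span - 1.0)
    return InteractionMatrix(gamma=gamma, labels=[str(l) for l in coords["label"]])


def add_gamma_noise(im: InteractionMatrix, nu_gamma: float, seed: int) -> InteractionMatrix:
    """Add (gamma_max - gamma_min) * U(0, nu_gamma) noise per entry (range per column)."""
    if nu_gamma < 0:
        raise ValueError("nu_gamma must be >= 0")
    if nu_gamma == 0:
        return InteractionMatrix(gamma=im.gamma.copy(), labels=list(im.labels))
    rng = np.random.default_rng(seed)
    span = im.gamma.max(axis=0) - im.gamma.min(axis=0)
    noise = span[None, :] * rng.uniform(0.0, nu_gamma, size=im.gamma.shape)
    return InteractionMatrix(gamma=im.gamma + noise, labels=list(im.labels))


def coords_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("label", "p", "q"):
        if col not in df.columns:
            raise ValueError(f"coordinate CSV missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# projection guidance

def boundary_falloff(d_b: np.ndarray | float, d_f: float = DEFAULT_FALLOFF_MM):
    """Sharp logistic fall-off 1 / [1 + exp(100 (d_f - d_b))] (100 in mm^-1).

    Equal to 1/2 at d_b = d_f, ~1 deep in the interior and ~0 at the rim, so
    that guidance vectors and their normal derivatives vanish at the boundary.
    """
    return 1.0 / (1.0 + np.exp(FALLOFF_SHARPNESS * (d_f - np.asarray(d_b, dtype=float))))


def compute_projection_guidance(im: InteractionMatrix, fields: list[GuidanceField],
                                lattice: HexLattice,
                                d_f: float = DEFAULT_FALLOFF_MM) -> ProjectionGuidance:
    """g_i(x) = falloff(d_b) * sum_j gamma_{i,j} grad rho_j(x), with its lattice
    divergence computed numerically (flux-sum form) and cached as static fields."""
    if im.gamma.shape[1] != len(fields):
        raise ValueError(
            f"gamma has {im.gamma.shape[1]} columns but {len(fields)} fields given")
    grads = np.stack([f.grad_rho for f in fields], axis=0)       # (M, H, 2)
    g = np.einsum("im,mhc->ihc", im.gamma, grads)
    g *= boundary_falloff(lattice.d_b, d_f)[None, :, None]
    div_g = operators.vector_divergence(g, lattice, rim="no-flux")
    return ProjectionGuidance(g=g, div_g=div_g)
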