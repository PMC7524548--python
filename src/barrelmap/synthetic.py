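"""Synthetic stand-ins for the external anatomical inputs.

The original study traced its cortical domain from a cytochrome-oxidase
stain and reconstructed barreloid coordinates from published anatomy; neither
is distributed here.  This module generates self-contained substitutes: an
elliptical domain, a barrel-field-shaped boundary polygon, a labelled
row/arc grid of 41 barreloid coordinates, and Voronoi reference
tessellations for the pattern-difference metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

from .hexgrid import BoundaryCurve, HexLattice
from .metrics import LabelMap, labelmap_from_labels

#: default rat macrovibrissae layout: 5 rows A-E plus 4 straddlers = 41 whiskers
DEFAULT_ROWS = ("A", "B", "C", "D", "E")
DEFAULT_ARCS = (4, 4, 8, 10, 11)
DEFAULT_STRADDLERS = ("alpha", "beta", "gamma", "delta")


@dataclass
class BarreloidSpec:
    """Row/arc layout of labelled barreloid centres in the thalamic plane."""

    rows: tuple[str, ...] = DEFAULT_ROWS
    arcs_per_row: tuple[int, ...] = DEFAULT_ARCS
    straddlers: tuple[str, ...] = DEFAULT_STRADDLERS
    pitch: float = 1.0
    jitter: float = 0.0
    straddler_stagger: float = 0.15   # AP offset between straddlers, fraction of pitch

    def __post_init__(self):
        if len(self.rows) != len(self.arcs_per_row):
            raise ValueError("rows and arcs_per_row must match")
        labels = self.labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in barreloid spec")

    def labels(self) -> list[str]:
        out = [f"{r}{a + 1}" for r, n in zip(self.rows, self.arcs_per_row)
               for a in range(n)]
        out.extend(self.straddlers)
        return out

    @property
    def n(self) -> int:
        return sum(self.arcs_per_row) + len(self.straddlers)


def make_ellipse_boundary(semi_major: float, semi_minor: float,
                          n_vertices: int = 128, name: str = "ellipse") -> BoundaryCurve:
    """Inscribed polygonal approximation of an axis-aligned ellipse (mm)."""
    if semi_major <= 0 or semi_minor <= 0:
        raise ValueError("semi-axes must be > 0")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([semi_major * np.cos(t), semi_minor * np.sin(t)])
    return BoundaryCurve(verts, name=name)


def make_barrelfield_boundary(scale: float = 1.0) -> BoundaryCurve:
    """A fixed, deterministic polygon resembling a rat posteromedial barrel
    subfield outline: elongated (~3.9 x 1.8 mm at scale 1, area ~5.4 mm^2,
    matching the ~5.1 mm^2 of the real rat field the model parameters were
    calibrated on), slightly egg-shaped, with a flat posterior (right) edge so
    that the domain can be mirror-duplicated cleanly for the Fgf8
    misexpression experiment.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    t = np.linspace(0.0, 2.0 * np.pi, 160, endpoint=False)
    a, b = 1.95, 0.9
    # mild egg-shaping, then a trapezoidal taper: the dorsal (row A/B) long
    # edge is shorter than the ventral (row E) one, as in the real field
    # where the many-arc rows lie along the longer lateral edge
    r_mod = 1.0 - 0.08 * np.cos(t) - 0.05 * np.cos(2 * t)
    x = a * np.cos(t)
    y = b * r_mod * np.sin(t)
    x = x * (1.0 + 0.28 * y / b)
    poly = Polygon(np.column_stack([x, y]))
    x_cut = 0.92 * a
    minx, miny, maxx, maxy = poly.bounds
    clipped = poly.intersection(box(minx - 1.0, miny - 1.0, x_cut, maxy + 1.0))
    verts = np.asarray(clipped.exterior.coords)[:-1]
    return BoundaryCurve(verts * scale, name="synthetic-barrelfield")


def mirror_boundary(boundary: BoundaryCurve, join_x: float | None = None) -> tuple[BoundaryCurve, float]:
    """The domain plus its mirror image across the vertical line x = join_x
    (default: the boundary's maximum x, i.e. its flat posterior edge).

    Returns the doubled boundary and the join-line x coordinate.  Models the
    mirror-duplicated cortical field induced by ectopic posterior Fgf8.
    """
    poly = boundary.polygon
    if join_x is None:
        join_x = poly.bounds[2]
    mirrored = shapely.affinity.scale(poly, xfact=-1.0, yfact=1.0,
                                      origin=(join_x, 0.0))
    union = poly.union(mirrored)
    if union.geom_type != "Polygon":
        # join was a single point; fuse with a sliver-sized buffer
        union = union.buffer(1e-6).buffer(-1e-6)
        if union.geom_type != "Polygon":
            raise ValueError("mirroring produced a disconnected domain")
    verts = np.asarray(union.exterior.coords)[:-1]
    return BoundaryCurve(verts, name=boundary.name + "+mirror"), float(join_x)


def make_barreloid_coordinates(spec: BarreloidSpec = BarreloidSpec(),
                               seed: int | None = None) -> pd.DataFrame:
    """Labelled (p, q) barreloid centres on a row/arc grid.

    Rows A..E run along the q axis; each row's arcs are spread evenly over
    the common arc axis, so a 4-arc row spans the same anterior-posterior
    extent as an 11-arc row (as the rows of the real barrel field jointly
    span the field's length).  Straddlers (alpha..delta) sit anterior of arc
    1, between consecutive rows, with a slight AP stagger.  Optional Gaussian
    jitter perturbs positions.  The default spec yields the 41 labelled
    macrovibrissae projections.
    """
    pitch = spec.pitch
    arc_span = max(spec.arcs_per_row) - 1
    rows = []
    for r, (row, n_arcs) in enumerate(zip(spec.rows, spec.arcs_per_row)):
        for arc in range(n_arcs):
            frac = arc / max(n_arcs - 1, 1)
            rows.append((f"{row}{arc + 1}", (1.0 + frac * arc_span) * pitch, r * pitch))
    for s, lab in enumerate(spec.straddlers):
        rows.append((lab, spec.straddler_stagger * s * pitch, (s + 0.5) * pitch))
    df = pd.DataFrame(rows, columns=["label", "p", "q"])
    if spec.jitter > 0:
        if seed is None:
            raise ValueError("jitter requested but no seed given")
        rng = np.random.default_rng(seed)
        df[["p", "q"]] += rng.normal(0.0, spec.jitter, size=(len(df), 2))
    return df


def map_coords_to_domain(coords: pd.DataFrame, lattice: HexLattice,
                         margin_frac: float = 0.12) -> np.ndarray:
    """Affinely map thalamic (p, q) coordinates into the cortical domain.

    p spans the x extent and q the y extent of the lattice, shrunk by
    ``margin_frac`` per side, matching the model's convention that a higher
    interaction strength drives a projection further up the corresponding
    cortical gradient.  Points that the rectangular mapping would place
    outside the (non-rectangular) domain are clamped to the nearest hex
    centre.
    """
    pts = coords[["p", "q"]].to_numpy(float)
    out = np.empty_like(pts)
    for k in range(2):
        lo, hi = lattice.centres[:, k].min(), lattice.centres[:, k].max()
        span = hi - lo
        lo += margin_frac * span
        hi -= margin_frac * span
        v = pts[:, k]
        out[:, k] = lo + (v - v.min()) / (v.max() - v.min()) * (hi - lo)
    tree = cKDTree(lattice.centres)
    dist, idx = tree.query(out)
    outside = dist > lattice.d / np.sqrt(3.0)   # beyond any hex circumradius
    out[outside] = lattice.centres[idx[outside]]
    return out


def make_reference_labelmap(points_xy: np.ndarray, lattice: HexLattice,
                            names: list[str] | None = None) -> LabelMap:
    """Voronoi tessellation of generator points rasterized onto the lattice."""
    points_xy = np.asarray(points_xy, float)
    tree = cKDTree(points_xy)
    _, label = tree.query(lattice.centres)
    return labelmap_from_labels(label.astype(int), lattice, len(points_xy), names)
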