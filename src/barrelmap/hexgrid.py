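"""Hexagonal discretization of a 2D cortical domain.

The cortical sheet is modelled as a regular hexagonal lattice clipped to a
closed boundary polygon (in mm).  A hex belongs to the lattice iff its centre
lies strictly inside the polygon.  The triangular grid of centres is anchored
at the polygon centroid (or an explicit anchor point) with lattice axis 1
along +x, so that lattice construction is fully deterministic.

Each hex stores six neighbour indices in fixed angular order, neighbour j
(j = 1..6) lying in direction (cos(pi*(j-1)/3), sin(pi*(j-1)/3)).  Missing
neighbours (outside the boundary) are marked with the sentinel -1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

SENTINEL = -1

#: axial-coordinate offsets of the six neighbours, in angular order j=1..6
AXIAL_OFFSETS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def neighbour_directions() -> np.ndarray:
    """Unit vectors n_j = (cos(pi*(j-1)/3), sin(pi*(j-1)/3)), j = 1..6, shape (6, 2)."""
    ang = np.pi * np.arange(6) / 3.0
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


@dataclass(frozen=True)
class BoundaryCurve:
    """A closed simple polygon (mm) delimiting the cortical domain S."""

    vertices: np.ndarray
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("boundary needs at least 3 (x, y) vertices")
        # drop an explicit closing vertex; shapely closes implicitly
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError(f"boundary polygon is not simple/valid: {self.name!r}")
        if poly.area <= 0:
            raise ValueError("boundary polygon has non-positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class HexLattice:
    """The discretized domain: hex centres, neighbour table and boundary distances."""

    d: float
    centres: np.ndarray          # (H, 2) mm
    neighbours: np.ndarray       # (H, 6) int32, SENTINEL where missing
    d_b: np.ndarray              # (H,) distance from centre to boundary outline, mm
    axial: np.ndarray = field(repr=False, default=None)  # (H, 2) int, internal
    anchor: tuple[float, float] = (0.0, 0.0)

    @property
    def n_hex(self) -> int:
        return self.centres.shape[0]

    @property
    def omega(self) -> float:
        """Area of one hexagonal cell, Omega = (sqrt(3)/2) d^2 (mm^2)."""
        return (np.sqrt(3.0) / 2.0) * self.d ** 2

    @property
    def edge_len(self) -> float:
        """Length of one hex edge, v = d / sqrt(3) (mm)."""
        return self.d / np.sqrt(3.0)

    @property
    def area(self) -> float:
        return self.n_hex * self.omega

    def interior_mask(self) -> np.ndarray:
        """Hexes with a full complement of six neighbours."""
        return (self.neighbours >= 0).all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "index": np.arange(self.n_hex),
            "x_mm": self.centres[:, 0],
            "y_mm": self.centres[:, 1],
            "d_b_mm": self.d_b,
        }
        for j in range(6):
            cols[f"n{j + 1}"] = self.neighbours[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_lattice(boundary: BoundaryCurve, d: float,
                  anchor: tuple[float, float] | None = None) -> HexLattice:
    """Tile the interior of ``boundary`` with hexes of centre spacing ``d`` (mm).

    The triangular grid of centres is anchored at ``anchor`` (default: the
    polygon centroid); a hex centre at position anchor + d*(q + r/2, r*sqrt(3)/2)
    is kept iff it lies strictly inside the polygon.
    """
    if d <= 0:
        raise ValueError("hex spacing d must be > 0")
    poly = boundary.polygon
    omega = (np.sqrt(3.0) / 2.0) * d ** 2
    if poly.area < omega:
        raise ValueError("domain too small")
    if anchor is None:
        cen = poly.centroid
        anchor = (cen.x, cen.y)
    ax, ay = anchor

    minx, miny, maxx, maxy = poly.bounds
    ry = d * np.sqrt(3.0) / 2.0
    r_lo = int(np.floor((miny - ay) / ry)) - 1
    r_hi = int(np.ceil((maxy - ay) / ry)) + 1
    qs, rs = [], []
    for r in range(r_lo, r_hi + 1):
        # x = ax + d*(q + r/2) in [minx, maxx]
        q_lo = int(np.floor((minx - ax) / d - r / 2.0)) - 1
        q_hi = int(np.ceil((maxx - ax) / d - r / 2.0)) + 1
        q = np.arange(q_lo, q_hi + 1)
        qs.append(q)
        rs.append(np.full(q.shape, r))
    q = np.concatenate(qs)
    r = np.concatenate(rs)
    x = ax + d * (q + r / 2.0)
    y = ay + ry * r
    inside = shapely.contains_xy(poly, x, y)
    q, r, x, y = q[inside], r[inside], x[inside], y[inside]
    if q.size == 0:
        raise ValueError("domain too small")

    index = {(int(qi), int(ri)): i for i, (qi, ri) in enumerate(zip(q, r))}
    H = q.size
    nbr = np.full((H, 6), SENTINEL, dtype=np.int32)
    for j, (dq, dr) in enumerate(AXIAL_OFFSETS):
        for i in range(H):
            nbr[i, j] = index.get((int(q[i]) + dq, int(r[i]) + dr), SENTINEL)

    centres = np.column_stack([x, y])
    lat = HexLattice(d=d, centres=centres, neighbours=nbr,
                     d_b=np.zeros(H), axial=np.column_stack([q, r]).astype(np.int64),
                     anchor=(float(ax), float(ay)))
    lat.d_b = distance_to_boundary(lat, boundary)
    return lat


def distance_to_boundary(lattice: HexLattice, boundary: BoundaryCurve) -> np.ndarray:
    """Euclidean distance from each hex centre to the nearest boundary point (mm)."""
    outline = boundary.polygon.exterior
    pts = shapely.points(lattice.centres)
    return shapely.distance(pts, outline)


# ---------------------------------------------------------------------------
# boundary I/O

def boundary_from_csv(path, name: str = "") -> BoundaryCurve:
    """Read a boundary polygon from CSV with header ``x_mm,y_mm``."""
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"boundary CSV missing column {col!r}")
    return BoundaryCurve(df[["x_mm", "y_mm"]].to_numpy(float), name=name or str(path))


def boundary_to_csv(boundary: BoundaryCurve, path) -> None:
    pd.DataFrame(boundary.vertices, columns=["x_mm", "y_mm"]).to_csv(path, index=False)


_PATH_TOKEN = re.compile(r"([MmLlHhVvCcSsQqTtZz])|(-?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def _flatten_bezier(pts: np.ndarray, tol: float) -> np.ndarray:
    """Uniformly sample a Bezier segment finely enough for chord error < tol."""
    ctrl_len = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    n = max(2, int(np.ceil(np.sqrt(ctrl_len / max(tol, 1e-12)))) + 1)
    t = np.linspace(0.0, 1.0, n + 1)[1:]
    # de Casteljau evaluated vectorized over t
    work = [np.repeat(p[None, :], t.size, axis=0) for p in pts]
    while len(work) > 1:
        work = [(1 - t)[:, None] * a + t[:, None] * b for a, b in zip(work[:-1], work[1:])]
    return work[0]


def flatten_svg_path(d_attr: str, tol: float = 0.005) -> np.ndarray:
    """Flatten an SVG path ``d`` attribute to a polyline at chord tolerance ``tol`` mm.

    Supports M/L/H/V/C/S/Q/T/Z in absolute and relative forms (the subset that
    vector-graphics tracings of anatomical outlines use).
    """
    tokens = _PATH_TOKEN.findall(d_attr)
    pts: list[np.ndarray] = []
    cur = np.zeros(2)
    start = np.zeros(2)
    prev_ctrl = None
    i = 0
    vals: list[float] = []
    cmds: list[tuple[str, list[float]]] = []
    cmd = None
    for tk_cmd, tk_num in tokens:
        if tk_cmd:
            if cmd is not None:
                cmds.append((cmd, vals))
            cmd, vals = tk_cmd, []
        else:
            vals.append(float(tk_num))
    if cmd is not None:
        cmds.append((cmd, vals))

    def emit(p):
        pts.append(np.asarray(p, dtype=float))

    for cmd, vals in cmds:
        rel = cmd.islower()
        op = cmd.upper()
        i = 0
        while True:
            if op == "Z":
                cur = start.copy()
                break
            if op == "M":
                if i + 2 > len(vals):
                    break
                p = np.array(vals[i:i + 2])
                cur = cur + p if rel else p
                if i == 0:
                    start = cur.copy()
                    emit(cur)
                else:
                    emit(cur)  # implicit lineto
                prev_ctrl = None
                i += 2
            elif op == "L":
                if i + 2 > len(vals):
                    break
                p = np.array(vals[i:i + 2])
                cur = cur + p if rel else p
                emit(cur)
                prev_ctrl = None
                i += 2
            elif op in ("H", "V"):
                if i + 1 > len(vals):
                    break
                v = vals[i]
                if op == "H":
                    cur = np.array([cur[0] + v if rel else v, cur[1]])
                else:
                    cur = np.array([cur[0], cur[1] + v if rel else v])
                emit(cur)
                prev_ctrl = None
                i += 1
            elif op in ("C", "S", "Q", "T"):
                n_coord = {"C": 6, "S": 4, "Q": 4, "T": 2}[op]
                if i + n_coord > len(vals):
                    break
                raw = np.array(vals[i:i + n_coord]).reshape(-1, 2)
                if rel:
                    raw = raw + cur
                if op in ("S", "T"):
                    first = 2 * cur - prev_ctrl if prev_ctrl is not None else cur.copy()
                    ctrl = np.vstack([cur, first, raw])
                else:
                    ctrl = np.vstack([cur, raw])
                seg = _flatten_bezier(ctrl, tol)
                pts.extend(seg)
                prev_ctrl = ctrl[-2]
                cur = ctrl[-1]
                i += n_coord
            else:  # pragma: no cover - arcs not used by our tracings
                raise ValueError(f"unsupported SVG path command {cmd!r}")
            if i >= len(vals):
                break
    return np.asarray(pts)


def boundary_from_svg(path, tol: float = 0.005, name: str = "") -> BoundaryCurve:
    """Read the first <path>/<polygon>/<polyline> of an SVG file (mm user units)."""
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "path" and el.get("d"):
            return BoundaryCurve(flatten_svg_path(el.get("d"), tol), name=name or str(path))
        if tag in ("polygon", "polyline") and el.get("points"):
            nums = [float(t) for t in re.findall(r"-?\d*\.?\d+(?:[eE][-+]?\d+)?", el.get("points"))]
            return BoundaryCurve(np.asarray(nums).reshape(-1, 2), name=name or str(path))
    raise ValueError(f"no path/polygon element found in {path}")


def read_boundary(path, tol: float = 0.005) -> BoundaryCurve:
    """Dispatch on file extension: .svg or .csv."""
    p = str(path)
    if p.lower().endswith(".svg"):
        return boundary_from_svg(path, tol)
    return boundary_from_csv(path)
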