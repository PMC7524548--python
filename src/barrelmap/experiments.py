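"""Scripted in-silico experiments on the barrel-map model.

Each experiment assembles a full pipeline (domain -> lattice -> guidance ->
solver -> metrics) from a shared setup and is reproducible bit-for-bit under
a fixed seed.  ``scale_down`` trades spatial resolution for speed while
preserving the physics: at factor s the hex spacing becomes 0.03*s mm, the
time step 1e-4*s^2 (the explicit stability limit scales with d^2, so the
margin D*dt/d^2 is unchanged) and the iteration count 30000/s^2, keeping the
total simulated time at 3.0 units.  Cost falls ~s^4-fold.  Scaled-down runs
are used for qualitative assertions (trends, orderings, region counts), not
absolute metric values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import guidance as gd, metrics as mt, synthetic
from .dynamics import ModelParams, Trajectory, run_simulation
from .guidance import GuidanceFieldSpec
from .hexgrid import BoundaryCurve, HexLattice, build_lattice

STANDARD_D_MM = 0.03          # hex spacing of the full-resolution study
STANDARD_DT = 1.0e-4
STANDARD_STEPS = 30000        # total simulated time 3.0 units
PHI_RHO2_DEG = 84.0           # default orientation of the second guidance field


def isotropic_gain(lattice: HexLattice, phi_deg: float, ref_phi_deg: float) -> float:
    """Gain giving the field along ``phi_deg`` the same absolute slope (mm^-1)
    as a unit-gain field along ``ref_phi_deg``.

    Linear fields are min-max normalized over the lattice before gain, so a
    unit-gain gradient is steeper along a short axis than a long one; on an
    elongated domain this would make within-row (anterior-posterior) sorting
    forces much weaker than across-row ones.  A molecular gradient has a
    characteristic slope per mm, not per domain extent, so the standard setup
    equalizes the two slopes.
    """
    def extent(phi):
        t = (lattice.centres[:, 0] * np.cos(np.deg2rad(phi))
             + lattice.centres[:, 1] * np.sin(np.deg2rad(phi)))
        return t.max() - t.min()

    return extent(phi_deg) / extent(ref_phi_deg)


@dataclass
class Setup:
    """A fully assembled simulation context."""

    boundary: BoundaryCurve
    lattice: HexLattice
    coords: pd.DataFrame
    gamma: gd.InteractionMatrix
    fields: list[gd.GuidanceField]
    guidance: gd.ProjectionGuidance
    params: ModelParams
    ref_map: mt.LabelMap | None = None
    join_x: float | None = None   # set for mirrored (Fgf8) domains


def standard_setup(boundary: BoundaryCurve | None = None,
                   coords: pd.DataFrame | None = None,
                   scale_down: float = 1.0,
                   params: ModelParams | None = None,
                   field_specs: list[GuidanceFieldSpec] | None = None,
                   anchor: tuple[float, float] | None = None,
                   with_reference: bool = True,
                   field_seed: int = 0) -> Setup:
    """Assemble the standard 41-projection barrel-field simulation.

    Defaults: synthetic barrel-field boundary, synthetic barreloid grid
    (N=41), two linear guidance fields (phi = 0 and 84 degrees, unit gain),
    gamma scaled to +/-2, and the standard model parameters.
    """
    if boundary is None:
        boundary = synthetic.make_barrelfield_boundary()
    if coords is None:
        coords = synthetic.make_barreloid_coordinates()
    lattice = build_lattice(boundary, STANDARD_D_MM * scale_down, anchor=anchor)
    gamma = gd.scale_interactions(coords)
    if field_specs is None:
        field_specs = [GuidanceFieldSpec(kind="linear", phi=0.0,
                                         gain=isotropic_gain(lattice, 0.0, PHI_RHO2_DEG)),
                       GuidanceFieldSpec(kind="linear", phi=PHI_RHO2_DEG, gain=1.0)]
    fields = [gd.make_field(lattice, s, seed=field_seed + 17 * j)
              for j, s in enumerate(field_specs)]
    proj = gd.compute_projection_guidance(gamma, fields, lattice)
    if params is None:
        params = ModelParams(N=gamma.n_projections,
                             dt=STANDARD_DT * scale_down ** 2,
                             steps=int(round(STANDARD_STEPS / scale_down ** 2)))
    ref_map = None
    if with_reference:
        pts = synthetic.map_coords_to_domain(coords, lattice)
        ref_map = synthetic.make_reference_labelmap(pts, lattice, gamma.labels)
    return Setup(boundary=boundary, lattice=lattice, coords=coords, gamma=gamma,
                 fields=fields, guidance=proj, params=params, ref_map=ref_map)


def run_example(setup: Setup | None = None, seed: int = 0,
                scale_down: float = 1.0, snapshot_every: int = 1000,
                a_init: tuple[float, float] = (0.2, 0.4),
                compute_honda: bool | str = "ends") -> Trajectory:
    """The standard simulation: full pipeline with the example parameters."""
    if setup is None:
        setup = standard_setup(scale_down=scale_down)
    return run_simulation(setup.lattice, setup.guidance, setup.params, seed=seed,
                          a_init=a_init, ref_map=setup.ref_map,
                          snapshot_every=snapshot_every,
                          compute_honda=compute_honda)


# ---------------------------------------------------------------------------
# parameter sweep

@dataclass
class SweepResult:
    """Final metrics and stability flags over a (D, epsilon, alpha/beta) grid."""

    table: pd.DataFrame
    D_grid: np.ndarray
    eps_grid: np.ndarray
    ratio_grid: np.ndarray


def default_sweep_grids(n: int = 6):
    """6 x 6 x 6 = 216 combinations spanning the qualitative ranges of the
    published sweep: D log-spaced and epsilon linear within plots, the ratio
    alpha/beta across five orders of magnitude between plots."""
    D = np.round(np.geomspace(0.05, 1.6, n), 4)
    eps = np.round(np.linspace(0.2, 2.2, n), 4)
    ratio = 0.216 * np.logspace(-2.5, 2.5, n)
    return D, eps, ratio


def parameter_sweep(setup: Setup, D_grid=None, eps_grid=None, ratio_grid=None,
                    seed: int = 0, compute_honda: bool = True) -> SweepResult:
    """Run one simulation per (D, epsilon, alpha/beta) combination, recording
    final Honda-delta, pattern difference, selectivity and stability.

    Cells are independent (fresh state per cell, same seed), so results do
    not depend on execution order; numerically unstable cells are flagged and
    carry no metric values.

    The ratio axis varies alpha/beta at constant turnover alpha*beta
    (alpha = sqrt(AB*r), beta = sqrt(AB/r) with AB from the setup's params):
    this isolates the balance between decay and synaptogenesis from their
    overall speed, so that slow-pruning artefacts of the finite simulated
    time do not masquerade as ratio sensitivity.
    """
    if D_grid is None or eps_grid is None or ratio_grid is None:
        D6, e6, r6 = default_sweep_grids()
        D_grid = D6 if D_grid is None else np.asarray(D_grid, float)
        eps_grid = e6 if eps_grid is None else np.asarray(eps_grid, float)
        ratio_grid = r6 if ratio_grid is None else np.asarray(ratio_grid, float)
    D_grid, eps_grid, ratio_grid = (np.asarray(g, float)
                                    for g in (D_grid, eps_grid, ratio_grid))
    if min(D_grid.size, eps_grid.size, ratio_grid.size) == 0:
        raise ValueError("sweep grids must be non-empty")
    AB = setup.params.alpha * setup.params.beta
    rows = []
    for D, eps, ratio in itertools.product(D_grid, eps_grid, ratio_grid):
        params = replace(setup.params, D=float(D), epsilon=float(eps),
                         alpha=float(np.sqrt(AB * ratio)),
                         beta=float(np.sqrt(AB / ratio)))
        traj = run_simulation(setup.lattice, setup.guidance, params, seed=seed,
                              ref_map=setup.ref_map,
                              snapshot_every=params.steps,
                              compute_honda=compute_honda)
        row = {"D": D, "epsilon": eps, "ratio": ratio, "stable": traj.stable,
               "delta": np.nan, "eta": np.nan, "omega": np.nan}
        if traj.stable:
            row["delta"] = traj.metrics.delta[-1]
            row["eta"] = traj.metrics.eta[-1]
            row["omega"] = traj.metrics.omega[-1]
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), D_grid=D_grid,
                       eps_grid=eps_grid, ratio_grid=ratio_grid)


# ---------------------------------------------------------------------------
# sensitivity analysis

SENSITIVITY_KINDS = ("init-noise", "gamma-noise", "rho-noise", "rho-rotation-gain")


def sensitivity_suite(setup: Setup, kind: str, magnitudes, seeds,
                      sigma_rho: float = 0.0) -> pd.DataFrame:
    """Tabulate final delta/eta/omega under one class of input perturbation.

    kinds: 'init-noise' (magnitude = half-width of the initial uniform band
    around 0.3; 0 gives the noise-free control), 'gamma-noise' (nu_gamma),
    'rho-noise' ((nu_rho, sigma_rho) with sigma via ``sigma_rho``),
    'rho-rotation-gain' (magnitude = (phi_rho1_degrees, G_rho1)).
    """
    if kind not in SENSITIVITY_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    rows = []
    for mag in magnitudes:
        for seed in seeds:
            setup_i = setup
            a_init = (0.2, 0.4)
            if kind == "init-noise":
                half = float(mag)
                a_init = (0.3 - half, 0.3 + half)
            elif kind == "gamma-noise":
                gamma = gd.add_gamma_noise(setup.gamma, float(mag), seed=seed + 991)
                proj = gd.compute_projection_guidance(gamma, setup.fields, setup.lattice)
                setup_i = replace(setup, gamma=gamma, guidance=proj)
            elif kind == "rho-noise":
                fields = [gd.add_field_noise(f, setup.lattice, float(mag), sigma_rho,
                                             seed=seed + 313 * (j + 1))
                          for j, f in enumerate(setup.fields)]
                proj = gd.compute_projection_guidance(setup.gamma, fields, setup.lattice)
                setup_i = replace(setup, fields=fields, guidance=proj)
            elif kind == "rho-rotation-gain":
                phi1, gain1 = mag
                specs = [GuidanceFieldSpec(kind="linear", phi=float(phi1), gain=float(gain1)),
                         GuidanceFieldSpec(kind="linear", phi=PHI_RHO2_DEG, gain=1.0)]
                fields = [gd.make_field(setup.lattice, s) for s in specs]
                proj = gd.compute_projection_guidance(setup.gamma, fields, setup.lattice)
                setup_i = replace(setup, fields=fields, guidance=proj)
            traj = run_simulation(setup_i.lattice, setup_i.guidance, setup_i.params,
                                  seed=seed, a_init=a_init, ref_map=setup_i.ref_map,
                                  snapshot_every=setup_i.params.steps)
            rows.append({"kind": kind, "magnitude": mag if np.isscalar(mag) else str(mag),
                         "seed": seed, "stable": traj.stable,
                         "delta": traj.metrics.delta[-1] if traj.stable else np.nan,
                         "eta": traj.metrics.eta[-1] if traj.stable else np.nan,
                         "omega": traj.metrics.omega[-1] if traj.stable else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fgf8 mirror duplication

@dataclass
class Fgf8Result:
    trajectory: Trajectory
    setup: Setup
    region_count: int              # raw connected components of the label map
    territory_count: int           # half-domain territories: sum over projections
    #                                of (claims left half) + (claims right half);
    #                                2N for a full mirror duplication
    mirror_area_correlation: float
    half_areas: np.ndarray    # (N, 2): per-projection area on each side of the join


def fgf8_duplication(base_boundary: BoundaryCurve | None = None,
                     coords: pd.DataFrame | None = None,
                     scale_down: float = 1.0, seed: int = 0,
                     params: ModelParams | None = None) -> Fgf8Result:
    """Mirror-duplicated barrel field: domain doubled across its posterior
    edge, the anterior-posterior field rho1 reflected at the join, rho2
    extended unreflected; standard model otherwise.

    Reports the number of connected label regions (expected 2N: every
    projection claims mirror-image territory in both halves) and the
    correlation of per-projection areas between the two halves.
    """
    if base_boundary is None:
        base_boundary = synthetic.make_barrelfield_boundary()
    if coords is None:
        coords = synthetic.make_barreloid_coordinates()
    doubled, join_x = synthetic.mirror_boundary(base_boundary)
    cen = doubled.polygon.centroid
    # the mirrored field is normalized over the folded (half-domain) extent;
    # match its absolute slope to the unit-gain field at 84 degrees, as in
    # the standard setup
    v = doubled.vertices
    t84 = (v[:, 0] * np.cos(np.deg2rad(PHI_RHO2_DEG))
           + v[:, 1] * np.sin(np.deg2rad(PHI_RHO2_DEG)))
    gain1 = (np.ptp(v[:, 0]) / 2.0) / np.ptp(t84)
    setup = standard_setup(boundary=doubled, coords=coords, scale_down=scale_down,
                           params=params, anchor=(join_x, cen.y),
                           with_reference=False,
                           field_specs=[GuidanceFieldSpec(kind="mirrored", phi=0.0,
                                                          gain=float(gain1),
                                                          mirror_x=join_x),
                                        GuidanceFieldSpec(kind="linear",
                                                          phi=PHI_RHO2_DEG, gain=1.0)])
    setup.join_x = join_x
    traj = run_simulation(setup.lattice, setup.guidance, setup.params, seed=seed,
                          snapshot_every=setup.params.steps, compute_honda=False)
    lm = traj.label_map
    n_regions = count_regions(lm, setup.lattice)
    left = setup.lattice.centres[:, 0] <= join_x
    N = setup.params.N
    half = np.zeros((N, 2))
    for i in range(N):
        half[i, 0] = np.count_nonzero((lm.label == i) & left) * setup.lattice.omega
        half[i, 1] = np.count_nonzero((lm.label == i) & ~left) * setup.lattice.omega
    with np.errstate(invalid="ignore"):
        corr = float(np.corrcoef(half[:, 0], half[:, 1])[0, 1])
    territories = int((half > 0).sum())
    return Fgf8Result(trajectory=traj, setup=setup, region_count=n_regions,
                      territory_count=territories,
                      mirror_area_correlation=corr, half_areas=half)


def count_regions(lm: mt.LabelMap, lattice: HexLattice,
                  mask: np.ndarray | None = None) -> int:
    """Number of connected same-label components (regions) in a label map."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    H = lattice.n_hex
    label = lm.label
    rows, cols = [], []
    for j in range(6):
        nb = lattice.neighbours[:, j]
        ok = nb >= 0
        h = np.nonzero(ok)[0]
        q = nb[ok]
        same = label[h] == label[q]
        rows.append(h[same])
        cols.append(q[same])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    if mask is not None:
        keep = mask[rows] & mask[cols]
        rows, cols = rows[keep], cols[keep]
    adj = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(H, H))
    n, comp = connected_components(adj, directed=False)
    if mask is not None:
        return len(np.unique(comp[mask]))
    return n


def regions_contiguous(lm: mt.LabelMap, lattice: HexLattice) -> bool:
    """True iff every non-empty label forms a single connected region."""
    occupied = np.count_nonzero(lm.areas > 0)
    return count_regions(lm, lattice) == occupied


# ---------------------------------------------------------------------------
# 1D-reproduction test: few projections, offset gradients on an ellipse

@dataclass
class Reproduction1DResult:
    trajectory: Trajectory
    lattice: HexLattice
    n_fields: int
    contiguous: bool
    ordered: bool           # centroid x order matches the gamma-defined order


def reproduction_1d(seed: int = 0, n_proj: int = 5, n_fields: int = 3,
                    semi_major: float = 1.5, semi_minor: float = 0.65,
                    scale_down: float = 2.0) -> Reproduction1DResult:
    """Topographic ordering along one axis: N projections under M offset
    logistic gradients aligned with the long axis of an ellipse.

    Each projection i targets a fraction f_i = (i + 1/2)/N of the long axis;
    its interaction with the logistic field centred at c_j is graded as
    gamma_{i,j} = 2 tanh(4 (f_i - c_j)), so the localized gradient bumps push
    it towards f_i from either side.  Self-organization should produce N
    distinct, contiguous fields whose left-to-right order matches the order
    of the f_i.
    """
    boundary = synthetic.make_ellipse_boundary(semi_major, semi_minor)
    lattice = build_lattice(boundary, STANDARD_D_MM * scale_down)
    centres = (np.arange(n_fields) + 1.0) / (n_fields + 1.0)
    targets = (np.arange(n_proj) + 0.5) / n_proj
    gamma = 2.0 * np.tanh(4.0 * (targets[:, None] - centres[None, :]))
    im = gd.InteractionMatrix(gamma=gamma, labels=[f"F{i+1}" for i in range(n_proj)])
    fields = [gd.make_offset_logistic_field(
        lattice, GuidanceFieldSpec(kind="offset-logistic", phi=0.0, gain=1.0,
                                   centre_frac=float(c), width_frac=0.12))
        for c in centres]
    proj = gd.compute_projection_guidance(im, fields, lattice)
    params = ModelParams(N=n_proj, dt=STANDARD_DT * scale_down ** 2,
                         steps=int(round(STANDARD_STEPS / scale_down ** 2)))
    traj = run_simulation(lattice, proj, params, seed=seed,
                          snapshot_every=params.steps, compute_honda=False)
    lm = traj.label_map
    n_occupied = int(np.count_nonzero(lm.areas > 0))
    contiguous = regions_contiguous(lm, lattice)
    order = np.argsort(lm.centroids[:, 0])
    ordered = bool(n_occupied == n_proj and np.all(order == np.arange(n_proj)))
    return Reproduction1DResult(trajectory=traj, lattice=lattice,
                                n_fields=n_occupied, contiguous=contiguous,
                                ordered=ordered)


# ---------------------------------------------------------------------------
# whisker trimming

@dataclass
class TrimResult:
    control: Trajectory
    trimmed: Trajectory
    report: pd.DataFrame      # per-label areas and ratios vs the m=1 control
    targets: list[str]
    m: float


def trim_whisker(targets: list[str], m: float, setup: Setup | None = None,
                 seed: int = 0, scale_down: float = 1.0,
                 control: Trajectory | None = None) -> TrimResult:
    """Simulated whisker trimming: multiply epsilon by m for the targeted
    projections (in both competition terms) and compare each barrel's area
    with the m=1 control run at the same seed (pairing cancels the
    initial-condition variance)."""
    if not 0 < m <= 1:
        raise ValueError("trim multiplier m must lie in (0, 1]")
    if setup is None:
        setup = standard_setup(scale_down=scale_down)
    idx = [setup.gamma.index_of(t) for t in targets]
    trim = np.ones(setup.params.N)
    trim[idx] = m
    if control is None:
        control = run_simulation(setup.lattice, setup.guidance, setup.params,
                                 seed=seed, snapshot_every=setup.params.steps,
                                 compute_honda=False)
    params_t = replace(setup.params, trim=trim)
    trimmed = run_simulation(setup.lattice, setup.guidance, params_t, seed=seed,
                             snapshot_every=params_t.steps, compute_honda=False)
    a_ctl = control.label_map.areas
    a_trm = trimmed.label_map.areas
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(a_ctl > 0, a_trm / np.where(a_ctl > 0, a_ctl, 1.0), np.nan)
    report = pd.DataFrame({"label": setup.gamma.labels, "area_control": a_ctl,
                           "area_trimmed": a_trm, "area_ratio": ratio,
                           "trimmed": [l in targets for l in setup.gamma.labels]})
    return TrimResult(control=control, trimmed=trimmed, report=report,
                      targets=list(targets), m=m)


ROW_C_LABELS = [f"C{a}" for a in range(1, 9)] + ["gamma"]
C3_NEIGHBOURS = ["B3", "C2", "C4", "D2", "D3"]


# ---------------------------------------------------------------------------
# statistics

def compare_runs(sample_a, sample_b, paired: bool = True):
    """Two-sample t-test on per-seed metric values (paired by default).

    Returns (t, p); identical paired samples give (0, 1) by convention.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal sample sizes")
        if np.allclose(a, b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
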