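"""The solver: coupled axon-branching / synaptogenesis dynamics on the lattice.

For each of N thalamocortical projections the model evolves a branching
density a_i(x, t) and a connection density c_i(x, t):

    dc_i/dt = -alpha c_i + beta (1 - sum_j c_j) a_i^k
    da_i/dt = div J_i - dc_i/dt

with the flux of axonal branching

    J_i = D grad a_i - a_i g_i + (eps_i / (N-1)) a_i grad a_hat_i,

where a_hat_i = sum_{j != i} a_j and g_i is the static guidance field.  The
divergence is expanded into five locally computable terms:

    div J_i = D lap a_i                        (i)   diffusion
            - a_i div g_i                      (ii)  static advection modulator
            - g_i . grad a_i                   (iii) advection
            + (eps_i/(N-1)) a_i div(grad a_hat_i)     (iv)  competition
            + (eps_i/(N-1)) grad a_hat_i . grad a_i   (v)

each evaluated with the finite-volume lattice operators so that only
nearest-neighbour communication is required.  No-flux boundaries follow from
ghost cells (terms i, iii, v) plus the guidance fall-off and the zero-flux
rim rule (terms ii, iv).

Term (iv) evaluates div(grad a_hat_i) with the same Gauss flux sum used for
div g_i in term (ii) (gradient stencil at the six neighbours, edge-averaged
flux, zero flux through rim edges) rather than with the Laplacian stencil.
The two forms agree to the operators' truncation error, but the flux form
makes the discrete divergence of the competition flux telescope exactly, so
sum_hex div J_i * Omega = 0 to machine precision for every projection and
the per-projection mass sum_hex (a_i + c_i) * Omega is conserved to
round-off over arbitrarily long runs -- branch-density conservation is a
structural requirement of the model, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, operators
from .guidance import ProjectionGuidance
from .hexgrid import HexLattice
from .operators import a_divg, gradient, laplacian  # re-exported lattice operators

__all__ = [
    "ModelParams", "SimState", "NumericalInstability", "Trajectory",
    "laplacian", "gradient", "a_divg", "compute_divJ", "dc_dt", "da_dt",
    "rk4_step", "init_state", "run_simulation",
]

AMAX_ABORT = 1.0e6   # |a| beyond this (or any non-finite) flags instability


class NumericalInstability(RuntimeError):
    """Raised when the explicit integrator produces non-finite or runaway values."""


@dataclass
class ModelParams:
    """Model rates and integration settings (defaults: the standard simulation)."""

    N: int = 41                 # number of thalamocortical projections
    alpha: float = 3.6          # synaptic decay rate
    beta: float = 16.67         # synaptogenesis rate
    k: float = 3.0              # branching nonlinearity exponent (k > 1)
    D: float = 0.5              # diffusion constant
    epsilon: float = 1.2        # competition strength
    trim: np.ndarray | None = None  # per-projection multipliers m_i in (0, 1]
    dt: float = 1.0e-4          # RK4 time step
    steps: int = 30000          # iteration count

    def __post_init__(self):
        if min(self.alpha, self.beta, self.D, self.epsilon) < 0:
            raise ValueError("rates alpha, beta, D, epsilon must be >= 0")
        if self.k < 1:
            raise ValueError("branching exponent k must be >= 1")
        if self.dt <= 0:
            raise ValueError("time step dt must be > 0")
        if self.N < 1:
            raise ValueError("need at least one projection")
        if self.N < 2 and self.epsilon > 0:
            raise ValueError("competition (epsilon > 0) requires N >= 2")
        if self.trim is not None:
            t = np.asarray(self.trim, dtype=float)
            if t.shape != (self.N,):
                raise ValueError("trim must have one multiplier per projection")
            if np.any(t <= 0) or np.any(t > 1):
                raise ValueError("trim multipliers must lie in (0, 1]")
            self.trim = t

    @property
    def epsilon_per_projection(self) -> np.ndarray:
        """eps_i = epsilon * m_i, applied in both competition terms."""
        m = np.ones(self.N) if self.trim is None else self.trim
        return self.epsilon * m


@dataclass
class SimState:
    """Per-projection branching (a) and connection (c) densities over the lattice."""

    a: np.ndarray          # (N, H)
    c: np.ndarray          # (N, H)
    step: int = 0
    seed: int | None = None

    @property
    def n_projections(self) -> int:
        return self.a.shape[0]

    def mass(self, lattice: HexLattice) -> np.ndarray:
        """Per-projection conserved mass sum_hex (a_i + c_i) * Omega."""
        return (self.a + self.c).sum(axis=1) * lattice.omega

    def copy(self) -> "SimState":
        return SimState(a=self.a.copy(), c=self.c.copy(), step=self.step, seed=self.seed)


def compute_divJ(a_i: np.ndarray, a_hat_i: np.ndarray, g_i: np.ndarray,
                 div_g_i: np.ndarray, params: ModelParams, lattice: HexLattice,
                 eps_i: float | None = None) -> np.ndarray:
    """Five-term flux divergence for one projection (numpy reference path)."""
    if eps_i is None:
        eps_i = params.epsilon
    if eps_i > 0 and params.N < 2:
        raise ValueError("competition requires N >= 2")
    grad_a = gradient(a_i, lattice)
    out = params.D * laplacian(a_i, lattice)
    out -= a_i * div_g_i
    out -= (g_i * grad_a).sum(axis=-1)
    if eps_i != 0:
        chi = eps_i / (params.N - 1)
        grad_hat = gradient(a_hat_i, lattice)
        out += chi * a_i * operators.vector_divergence(grad_hat, lattice, rim="no-flux")
        out += chi * (grad_hat * grad_a).sum(axis=-1)
    return out


def dc_dt(a: np.ndarray, c: np.ndarray, params: ModelParams) -> np.ndarray:
    """Synaptogenesis rate -alpha c_i + beta (1 - sum_j c_j) a_i^k, per hex."""
    free = 1.0 - c.sum(axis=0) if c.ndim == 2 else 1.0 - c
    return -params.alpha * c + params.beta * free * a ** params.k


def da_dt(state: SimState, guidance: ProjectionGuidance, params: ModelParams,
          lattice: HexLattice) -> tuple[np.ndarray, np.ndarray]:
    """(da/dt, dc/dt) for all projections via the reference operators."""
    a, c = state.a, state.c
    total = a.sum(axis=0)
    dc = dc_dt(a, c, params)
    eps = params.epsilon_per_projection
    da = np.empty_like(a)
    for i in range(a.shape[0]):
        da[i] = compute_divJ(a[i], total - a[i], guidance.g[i], guidance.div_g[i],
                             params, lattice, eps_i=eps[i])
    da -= dc
    return da, dc


def _kernel_args(guidance: ProjectionGuidance, params: ModelParams, lattice: HexLattice):
    g = np.ascontiguousarray(guidance.g)
    return (np.ascontiguousarray(g[..., 0]), np.ascontiguousarray(g[..., 1]),
            np.ascontiguousarray(guidance.div_g),
            np.ascontiguousarray(lattice.neighbours),
            _kernels.COS_J, _kernels.SIN_J, float(lattice.d), float(params.D),
            params.epsilon_per_projection.astype(float), float(params.alpha),
            float(params.beta), float(params.k))


def rk4_step(state: SimState, guidance: ProjectionGuidance, params: ModelParams,
             lattice: HexLattice, use_numba: bool = True) -> SimState:
    """One classical RK4 step of the full coupled (a, c) system."""
    new = state.copy()
    if use_numba:
        args = _kernel_args(guidance, params, lattice)
        done = _kernels.rk4_steps(new.a, new.c, *args, float(params.dt), 1, AMAX_ABORT)
        if done < 1 or not np.isfinite(new.a).all():
            raise NumericalInstability(f"numerical instability at step {state.step}")
    else:
        dt = params.dt
        k1a, k1c = da_dt(state, guidance, params, lattice)
        s2 = SimState(state.a + 0.5 * dt * k1a, state.c + 0.5 * dt * k1c)
        k2a, k2c = da_dt(s2, guidance, params, lattice)
        s3 = SimState(state.a + 0.5 * dt * k2a, state.c + 0.5 * dt * k2c)
        k3a, k3c = da_dt(s3, guidance, params, lattice)
        s4 = SimState(state.a + dt * k3a, state.c + dt * k3c)
        k4a, k4c = da_dt(s4, guidance, params, lattice)
        new.a = state.a + dt / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a)
        new.c = state.c + dt / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
        if (not np.isfinite(new.a).all() or not np.isfinite(new.c).all()
                or np.abs(new.a).max() > AMAX_ABORT):
            raise NumericalInstability(f"numerical instability at step {state.step}")
    new.step = state.step + 1
    return new


def init_state(lattice: HexLattice, params: ModelParams, seed: int,
               a_lo: float = 0.2, a_hi: float = 0.4) -> SimState:
    """Initial condition a_i ~ U(a_lo, a_hi) i.i.d. per hex and projection, c = 0.

    a_lo == a_hi gives the deterministic noise-free control a = a_lo.
    """
    if a_lo > a_hi:
        raise ValueError("a_lo must be <= a_hi")
    rng = np.random.default_rng(seed)
    if a_lo == a_hi:
        a = np.full((params.N, lattice.n_hex), float(a_lo))
    else:
        a = rng.uniform(a_lo, a_hi, size=(params.N, lattice.n_hex))
    return SimState(a=a, c=np.zeros_like(a), step=0, seed=seed)


@dataclass
class Trajectory:
    """Result of run_simulation: final state, label snapshots and metric series."""

    state: SimState
    stable: bool
    snapshot_steps: list[int] = field(default_factory=list)
    snapshot_labels: list[np.ndarray] = field(default_factory=list)
    metrics: "object" = None            # metrics.MetricSeries
    label_map: "object" = None          # metrics.LabelMap of the final state


def run_simulation(lattice: HexLattice, guidance: ProjectionGuidance,
                   params: ModelParams, seed: int = 0,
                   a_init: tuple[float, float] = (0.2, 0.4),
                   ref_map=None, snapshot_every: int = 1000,
                   compute_honda: bool | str = True,
                   state: SimState | None = None) -> Trajectory:
    """Integrate the model for params.steps RK4 iterations, recording label-map
    snapshots and metric series (Honda-delta, pattern difference eta vs
    ``ref_map`` if given, and selectivity omega) every ``snapshot_every`` steps.

    ``compute_honda`` may be True (every snapshot), False (never) or "ends"
    (first and final snapshot only — the generator fit is the expensive part
    of the metric set).  On numerical instability the partial trajectory is
    returned flagged ``stable=False``.
    """
    from . import metrics as _metrics

    if state is None:
        state = init_state(lattice, params, seed, *a_init)
    args = _kernel_args(guidance, params, lattice)
    traj = Trajectory(state=state, stable=True)
    steps_t, deltas, etas, omegas = [], [], [], []

    def record(st: SimState):
        lm = _metrics.label_map(st.c, lattice, a=st.a)
        traj.snapshot_steps.append(st.step)
        traj.snapshot_labels.append(lm.label.copy())
        steps_t.append(st.step)
        want_delta = (compute_honda is True
                      or (compute_honda == "ends"
                          and (len(steps_t) == 1 or st.step >= params.steps)))
        if want_delta:
            try:
                deltas.append(_metrics.honda_delta(lm, lattice))
            except ValueError:
                deltas.append(np.nan)
        else:
            deltas.append(np.nan)
        etas.append(_metrics.pattern_difference(lm, ref_map) if ref_map is not None
                    else np.nan)
        _, om = _metrics.selectivity(st.c, lattice)
        omegas.append(om)
        traj.label_map = lm

    remaining = params.steps
    while remaining > 0:
        chunk = min(snapshot_every, remaining)
        done = _kernels.rk4_steps(state.a, state.c, *args, float(params.dt),
                                  chunk, AMAX_ABORT)
        state.step += done
        remaining -= done
        if done < chunk or not np.isfinite(state.a).all():
            traj.stable = False
            break
        record(state)
    traj.state = state
    traj.metrics = _metrics.MetricSeries(
        t=np.asarray(steps_t), delta=np.asarray(deltas),
        eta=np.asarray(etas), omega=np.asarray(omegas))
    return traj


def make_params(**kwargs) -> ModelParams:
    """Convenience constructor: standard parameters overridden by kwargs."""
    return ModelParams(**kwargs)
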