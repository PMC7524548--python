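"""HDF5 run containers.

Schema (one file per run):

    /params            attrs: N, alpha, beta, k, D, epsilon, dt, steps, seed
    /params/trim       optional per-projection epsilon multipliers
    /lattice/{centres,neighbours,d_b}   attrs on group: d, omega, edge_len
    /snapshots/<step>/label             winner-take-all labels per snapshot
    /state/{a,c}       final densities, attrs: step
    /metrics/{t,delta,eta,omega}

All length-bearing arrays carry a ``units`` attribute (mm, mm^2, mm^3).
"""

from __future__ import annotations

import numpy as np

from .dynamics import ModelParams, SimState, Trajectory
from .hexgrid import HexLattice
from .metrics import MetricSeries


def save_run(path, lattice: HexLattice, params: ModelParams, traj: Trajectory,
             labels: list[str] | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        p = f.create_group("params")
        for key in ("N", "alpha", "beta", "k", "D", "epsilon", "dt", "steps"):
            p.attrs[key] = getattr(params, key)
        if traj.state.seed is not None:
            p.attrs["seed"] = traj.state.seed
        p.attrs["stable"] = traj.stable
        if params.trim is not None:
            p.create_dataset("trim", data=params.trim)

        g = f.create_group("lattice")
        g.attrs["d"] = lattice.d
        g.attrs["omega"] = lattice.omega
        g.attrs["edge_len"] = lattice.edge_len
        g.create_dataset("centres", data=lattice.centres).attrs["units"] = "mm"
        g.create_dataset("neighbours", data=lattice.neighbours)
        g.create_dataset("d_b", data=lattice.d_b).attrs["units"] = "mm"

        s = f.create_group("state")
        s.attrs["step"] = traj.state.step
        s.create_dataset("a", data=traj.state.a)
        s.create_dataset("c", data=traj.state.c)

        snaps = f.create_group("snapshots")
        for step, lab in zip(traj.snapshot_steps, traj.snapshot_labels):
            snaps.create_group(str(step)).create_dataset("label", data=lab)

        if traj.metrics is not None:
            m = f.create_group("metrics")
            m.create_dataset("t", data=traj.metrics.t)
            m.create_dataset("delta", data=traj.metrics.delta)
            m.create_dataset("eta", data=traj.metrics.eta).attrs["units"] = "mm^3"
            m.create_dataset("omega", data=traj.metrics.omega).attrs["units"] = "mm^2"
        if labels is not None:
            f.create_dataset("labels", data=np.array(labels, dtype="S"))


def load_run(path):
    """Load a saved container; returns (lattice, params, trajectory, labels)."""
    import h5py

    with h5py.File(path, "r") as f:
        p = dict(f["params"].attrs)
        trim = f["params/trim"][()] if "trim" in f["params"] else None
        params = ModelParams(N=int(p["N"]), alpha=float(p["alpha"]), beta=float(p["beta"]),
                             k=float(p["k"]), D=float(p["D"]), epsilon=float(p["epsilon"]),
                             dt=float(p["dt"]), steps=int(p["steps"]), trim=trim)
        g = f["lattice"]
        lattice = HexLattice(d=float(g.attrs["d"]), centres=g["centres"][()],
                             neighbours=g["neighbours"][()], d_b=g["d_b"][()])
        state = SimState(a=f["state/a"][()], c=f["state/c"][()],
                         step=int(f["state"].attrs["step"]),
                         seed=int(p["seed"]) if "seed" in p else None)
        traj = Trajectory(state=state, stable=bool(p.get("stable", True)))
        for step in sorted(f["snapshots"], key=int):
            traj.snapshot_steps.append(int(step))
            traj.snapshot_labels.append(f["snapshots"][step]["label"][()])
        if "metrics" in f:
            m = f["metrics"]
            traj.metrics = MetricSeries(t=m["t"][()], delta=m["delta"][()],
                                        eta=m["eta"][()], omega=m["omega"][()])
        labels = ([s.decode() for s in f["labels"][()]] if "labels" in f else None)
    return lattice, params, traj, labels
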