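"""YAML run configuration.

An empty config resolves to the standard simulation: the synthetic
barrel-field domain at d = 0.03 mm, the synthetic 41-barreloid grid, two
linear guidance fields (anterior-posterior and 84 degrees), and the model
parameters alpha=3.6, beta=16.67, k=3, D=0.5, epsilon=1.2, dt=1e-4,
30000 steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .dynamics import ModelParams
from .guidance import GuidanceFieldSpec

log = logging.getLogger("barrelmap")

_MODEL_DEFAULTS = dict(alpha=3.6, beta=16.67, k=3.0, D=0.5, epsilon=1.2,
                       dt=1.0e-4, steps=30000)
_KNOWN_TOP = {"domain", "lattice", "guidance", "coords", "model", "seeds", "output"}


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled."""

    domain: dict = field(default_factory=lambda: {"source": "synthetic-barrelfield",
                                                  "scale": 1.0, "path": None})
    lattice: dict = field(default_factory=lambda: {"d": 0.03})
    guidance: list[GuidanceFieldSpec] = field(default_factory=list)
    coords: dict = field(default_factory=lambda: {"source": "synthetic", "path": None,
                                                  "jitter": 0.0})
    model: dict = field(default_factory=lambda: dict(_MODEL_DEFAULTS))
    seeds: list[int] = field(default_factory=lambda: [0])
    output: dict = field(default_factory=lambda: {"path": "run.h5",
                                                  "snapshot_cadence": 1000})

    def model_params(self, n_projections: int) -> ModelParams:
        return ModelParams(N=n_projections, **self.model)

    def to_dict(self) -> dict:
        return {
            "domain": dict(self.domain),
            "lattice": dict(self.lattice),
            "guidance": [vars(s).copy() for s in self.guidance],
            "coords": dict(self.coords),
            "model": dict(self.model),
            "seeds": list(self.seeds),
            "output": dict(self.output),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _require(cond: bool, msg: str):
    if not cond:
        raise ValueError(msg)


def load_config(path=None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML config, filling defaults for missing fields.

    Unknown top-level keys produce a warning; invalid values raise ValueError
    naming the offending field.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    for key in data:
        if key not in _KNOWN_TOP:
            log.warning("unknown config key %r ignored", key)

    cfg = RunConfig()
    cfg.domain.update(data.get("domain") or {})
    _require(cfg.domain["source"] in
             ("svg", "csv", "synthetic-ellipse", "synthetic-barrelfield"),
             f"domain.source: unknown source {cfg.domain['source']!r}")
    if cfg.domain["source"] in ("svg", "csv"):
        _require(bool(cfg.domain.get("path")), "domain.path: required for file sources")

    cfg.lattice.update(data.get("lattice") or {})
    _require(cfg.lattice["d"] > 0, "lattice.d: hex spacing must be > 0")

    for spec in data.get("guidance") or []:
        cfg.guidance.append(GuidanceFieldSpec(**spec))

    cfg.coords.update(data.get("coords") or {})
    _require(cfg.coords["source"] in ("csv", "synthetic"),
             f"coords.source: unknown source {cfg.coords['source']!r}")
    if cfg.coords["source"] == "csv":
        _require(bool(cfg.coords.get("path")), "coords.path: required for csv source")

    cfg.model.update(data.get("model") or {})
    for key in cfg.model:
        _require(key in _MODEL_DEFAULTS, f"model.{key}: unknown parameter")
    _require(cfg.model["dt"] > 0, "model.dt: time step must be > 0")
    _require(cfg.model["steps"] > 0, "model.steps: must be > 0")
    for key in ("alpha", "beta", "D", "epsilon"):
        _require(cfg.model[key] >= 0, f"model.{key}: must be >= 0")
    _require(cfg.model["k"] >= 1, "model.k: must be >= 1")

    if "seeds" in data and data["seeds"] is not None:
        seeds = data["seeds"]
        _require(isinstance(seeds, list) and all(isinstance(s, int) for s in seeds),
                 "seeds: must be a list of integers")
        cfg.seeds = seeds

    cfg.output.update(data.get("output") or {})
    _require(cfg.output["snapshot_cadence"] > 0, "output.snapshot_cadence: must be > 0")
    return cfg
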