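"""Run configuration: YAML-backed, fully reproducible simulation recipes.

A config bundles the diffusion model, the PFG sequence conditions (one curve
per (g, delta) combination), the ensemble settings, optional Rician noise
and the validation thresholds. Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .params import (
    GAMMA_PROTON,
    CTRWParams,
    DiffusivityDistribution,
    NormalParams,
    PFGParams,
)

__all__ = ["RunConfig", "load_config", "model_params_from_dict"]


def model_params_from_dict(model: str, d: dict):
    """Build the model parameter bundle from its plain-dict form."""
    if model == "bm":
        return NormalParams(D=float(d["D"]), zeta=float(d["zeta"]))
    if model == "fbm":
        if "K" in d:
            return (float(d["K"]), float(d["H"]))
        return (2.0 * float(d["D_alpha"]), float(d["alpha"]) / 2.0)
    if model == "ss":
        kind = d.get("kind", "gamma")
        if kind == "gamma":
            return DiffusivityDistribution.gamma_dist(float(d["k"]), float(d["theta"]))
        return DiffusivityDistribution.truncated_gaussian(
            float(d["D_star"]), float(d["sigma_D"]))
    if model == "ctrw":
        if "gamma_x" in d:
            return CTRWParams(beta=float(d["beta"]), gamma_t=float(d["gamma_t"]),
                              gamma_x=float(d["gamma_x"]))
        return CTRWParams.from_D_alpha(float(d["beta"]), float(d["gamma_t"]),
                                       float(d["D_alpha"]))
    raise ValueError(f"unknown model {model!r}")


@dataclass
class RunConfig:
    model: str
    model_params: dict
    g: list = field(default_factory=lambda: [0.01])        # T/m, one curve per value
    delta: list = field(default_factory=lambda: [0.01])    # s, crossed with g
    gamma: float = GAMMA_PROTON
    t1: float = 0.005
    Delta_min: float | None = None      # default max(2*delta, 0.01)
    Delta_max: float = 1.0
    Delta_n: int = 48
    n_traj: int = 10_000
    dt: float | None = None             # default per model
    seed: int = 0
    snr: float | None = None            # Rician noise; None = clean
    collapse_threshold: float = 0.05
    drift_threshold: float = 0.1

    def params_object(self):
        return model_params_from_dict(self.model, self.model_params)

    def conditions(self) -> list[PFGParams]:
        """One base PFG condition per (delta, g) pair."""
        out = []
        for d in self.delta:
            for g in self.g:
                out.append(PFGParams(g=float(g), delta=float(d),
                                     Delta=max(2.0 * float(d), 0.01),
                                     gamma=self.gamma, t1=self.t1))
        return out

    def delta_grid(self, delta: float):
        import numpy as np
        lo = self.Delta_min if self.Delta_min is not None else max(2.0 * delta, 0.01)
        return np.linspace(max(lo, 2.0 * delta), self.Delta_max, self.Delta_n)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        """Short content hash identifying the config (for output provenance)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    missing = {"model", "model_params"} - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required fields {sorted(missing)}")
    cfg = RunConfig(**raw)
    cfg.params_object()  # validate model params eagerly
    return cfg
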