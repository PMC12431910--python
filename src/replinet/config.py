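"""Run configuration: a fully-specified simulation as a YAML/JSON document.

A configuration resolves to (model, initial condition, integrator settings,
output requests).  Unknown keys are rejected at every level so that typos
fail loudly rather than silently falling back to defaults.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import ModelSpec
from .games import PayoffMatrix, named_game
from .integrator import IntegratorConfig
from .network import NetworkGraph, named_network
from .transport import TransportSpec

__all__ = ["RunConfig", "load_config", "save_config"]


def _take(d: dict, allowed: set, context: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return d


@dataclass
class RunConfig:
    """Declarative description of one simulation run.

    ``model`` holds ``network`` (builder name or edge-list CSV path, plus
    ``n_nodes``/``directed`` where relevant), ``payoff`` (built-in label, CSV
    path, or inline rows) and ``transport`` (kind, global nu/p/tau, optional
    per-edge overrides).  ``initial_conditions`` holds explicit ``rows``
    and/or ``random: true`` with per-node ``fixed`` overrides.
    """

    model: dict
    initial_conditions: dict
    integrator: dict
    outputs: dict = field(default_factory=dict)
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        _take(self.model, {"network", "n_nodes", "directed", "direction", "payoff", "transport"}, "model")
        _take(self.initial_conditions, {"rows", "random", "fixed"}, "initial_conditions")
        _take(
            self.integrator,
            {"method", "dt", "t_end", "epsilon", "max_corrector_iters", "drift_guard"},
            "integrator",
        )
        _take(self.outputs, {"directory", "trajectory", "report", "plots", "stride"}, "outputs")

    # -- resolution ---------------------------------------------------------

    def build_graph(self) -> NetworkGraph:
        net = self.model["network"]
        if isinstance(net, str) and net.endswith(".csv"):
            return NetworkGraph.from_edgelist_csv(
                net,
                directed=bool(self.model.get("directed", False)),
                direction=self.model.get("direction", "in"),
            )
        kwargs = {}
        if "n_nodes" in self.model:
            kwargs["n_nodes"] = int(self.model["n_nodes"])
        return named_network(net, **kwargs)

    def build_payoff(self) -> PayoffMatrix:
        payoff = self.model["payoff"]
        if isinstance(payoff, str):
            if payoff.endswith(".csv"):
                return PayoffMatrix.from_csv(payoff, label=Path(payoff).stem)
            return named_game(payoff)
        return PayoffMatrix(payoff, label="inline")

    def build_transport(self) -> TransportSpec:
        block = dict(self.model.get("transport") or {"kind": "none"})
        _take(block, {"kind", "nu", "p", "tau", "per_edge", "delayed_form"}, "transport")
        per_edge_raw = block.pop("per_edge", None) or []
        per_edge = {}
        for entry in per_edge_raw:
            entry = dict(entry)
            src, dst = int(entry.pop("src")), int(entry.pop("dst"))
            _take(entry, {"nu", "p", "tau"}, f"per_edge ({src},{dst})")
            per_edge[(src, dst)] = {k: float(v) for k, v in entry.items()}
        return TransportSpec(per_edge=per_edge, **block)

    def build_model(self) -> ModelSpec:
        return ModelSpec(self.build_graph(), self.build_payoff(), self.build_transport())

    def build_integrator(self) -> IntegratorConfig:
        return IntegratorConfig(**self.integrator)

    def build_initial_state(self, model: ModelSpec) -> np.ndarray:
        ic = self.initial_conditions
        N, n = model.N, model.n_species
        if "rows" in ic:
            X = np.asarray(ic["rows"], dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape != (N, n):
                raise ValueError(
                    f"initial_conditions.rows must be {N}x{n}, got {X.shape}"
                )
            X = X.copy()
        elif ic.get("random"):
            rng = np.random.default_rng(self.seed)
            X = rng.dirichlet(np.ones(n), size=N)
        else:
            raise ValueError("initial_conditions needs 'rows' or 'random: true'")
        for node, row in (ic.get("fixed") or {}).items():
            X[int(node) - 1] = np.asarray(row, dtype=float)
        return X

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = _take(dict(data), {f.name for f in cls.__dataclass_fields__.values()}, "run config")
        return cls(**data)


def load_config(path) -> RunConfig:
    """Read a run configuration from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    """Write a run configuration (format chosen by extension)."""
    data = cfg.to_dict()
    # YAML/JSON cannot key mappings by tuples; per-edge overrides are stored
    # as a list of {src, dst, ...} rows, matching the input form.
    transport = (data["model"].get("transport") or {})
    if isinstance(transport.get("per_edge"), dict):
        transport["per_edge"] = [
            {"src": k[0], "dst": k[1], **v} for k, v in transport["per_edge"].items()
        ]
    text = (
        json.dumps(data, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(data, sort_keys=False)
    )
    Path(path).write_text(text)
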