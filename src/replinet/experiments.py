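"""Preset experiments and the run driver.

The presets encode the study conditions used throughout: a single-node
three-species cyclic game (rock-paper-scissors) for validating the
integrator, and two- and three-species games on the prototype networks where
node 1 starts at the mixed equilibrium and the remaining nodes at a pure
state, probing whether transport pulls the pure nodes onto the equilibrium
(moderate coupling) or the whole ensemble onto a synchronized orbit (strong
coupling or delayed exchange).
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .analysis import plot_simplex, plot_timeseries
from .config import RunConfig, save_config
from .integrator import integrate
from .network import named_network

__all__ = [
    "preset_test1",
    "preset_test2_linear",
    "preset_test2_nonlinear",
    "run",
]

log = logging.getLogger("replinet")

#: The four single-node initial conditions used in the validation runs.
TEST1_ICS = {
    "IC1": (0.9, 0.05, 0.05),
    "IC2": (0.4, 0.4, 0.2),
    "IC3": (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
    "IC4": (0.6, 0.1, 0.3),
}

LINEAR_NETWORKS = ("inline", "triangle", "triangle-oriented", "roundabout", "roundabout-oriented")


def preset_test1(ic_label: str, *, t_end: float = 100.0, dt: float = 0.01) -> RunConfig:
    """Single node, rock-paper-scissors, one of the four named starts."""
    if ic_label not in TEST1_ICS:
        raise KeyError(f"unknown initial condition {ic_label!r}; choose from {sorted(TEST1_ICS)}")
    return RunConfig(
        model={"network": "single", "payoff": "RPS", "transport": {"kind": "none"}},
        initial_conditions={"rows": [list(TEST1_ICS[ic_label])]},
        integrator={"method": "gl4pec", "dt": dt, "t_end": t_end},
        label=f"test1-{ic_label}",
    )


def preset_test2_linear(
    network: str,
    nu: float,
    *,
    game: str = "HDG",
    t_end: Optional[float] = None,
    dt: float = 0.01,
) -> RunConfig:
    """Linear transport on a prototype network.

    Two-species runs use the hawk-dove variant with node 1 at (1/2, 1/2) and
    every other node at (0, 1); three-species runs use rock-paper-scissors
    with node 1 at the barycenter and the rest at (0, 1, 0).  A coupling
    above the stability bound 1/Delta is accepted with a warning — that
    regime is part of the study.
    """
    if network not in LINEAR_NETWORKS:
        raise KeyError(f"unknown network {network!r}; choose from {LINEAR_NETWORKS}")
    if nu < 0:
        raise ValueError("transfer velocity nu must be nonnegative")
    game = game.upper()
    if game == "HDG":
        mixed, pure = [0.5, 0.5], [0.0, 1.0]
        horizon = 20.0
    elif game == "RPS":
        third = 1.0 / 3.0
        mixed, pure = [third, third, third], [0.0, 1.0, 0.0]
        horizon = 200.0
    else:
        raise KeyError("linear-transport presets use HDG or RPS")
    if t_end is not None:
        horizon = t_end
    graph = named_network(network, n_nodes=3)
    cfg = RunConfig(
        model={
            "network": network,
            "n_nodes": 3,
            "payoff": game,
            "transport": {"kind": "linear", "nu": float(nu)},
        },
        initial_conditions={"rows": [mixed] + [pure] * (graph.N - 1)},
        integrator={"method": "gl4pec", "dt": dt, "t_end": horizon},
        label=f"test2-{network}-{game.lower()}-nu{nu}",
    )
    bound = graph.stability_bound()
    if nu >= bound:
        warnings.warn(
            f"nu={nu} is at or above the stability bound 1/Delta={bound:.4g} "
            f"for the {network} network; the mixed equilibrium may lose its "
            "attractiveness",
            stacklevel=2,
        )
    return cfg


def preset_test2_nonlinear(
    tau1: float,
    tau2: float,
    seed: int = 0,
    *,
    t_end: float = 75.0,
    dt: float = 0.01,
) -> RunConfig:
    """Delayed transport on the roundabout network.

    Rock-paper-scissors everywhere; survival rate p = 2 on all edges; travel
    time ``tau1`` on the chain ends (1-2 and 5-6) and ``tau2`` inside the
    quadrangle (2-3, 3-5, 5-4, 4-2).  Node 1 starts at the barycenter; nodes
    2-6 at seeded uniform-random simplex points.

    The default horizon covers the synchronization of all nodes onto a common
    cyclic orbit.  Note that the delayed exchange term does not preserve
    positivity: once the synchronized orbit grazes the simplex boundary the
    frequencies can turn slightly negative and, as written, the off-simplex
    replicator dynamics eventually diverges — the integrator then stops with
    a positivity error rather than report non-physical states.
    """
    if tau1 < 0 or tau2 < 0:
        raise ValueError("travel times must be nonnegative")
    third = 1.0 / 3.0
    per_edge = [
        {"src": 1, "dst": 2, "tau": float(tau1)},
        {"src": 5, "dst": 6, "tau": float(tau1)},
        {"src": 2, "dst": 3, "tau": float(tau2)},
        {"src": 3, "dst": 5, "tau": float(tau2)},
        {"src": 5, "dst": 4, "tau": float(tau2)},
        {"src": 4, "dst": 2, "tau": float(tau2)},
    ]
    return RunConfig(
        model={
            "network": "roundabout",
            "payoff": "RPS",
            "transport": {"kind": "delayed", "p": 2.0, "tau": 0.0, "per_edge": per_edge},
        },
        initial_conditions={"random": True, "fixed": {1: [third, third, third]}},
        integrator={"method": "gl4pec", "dt": dt, "t_end": t_end},
        seed=int(seed),
        label=f"test2-nonlinear-tau1={tau1}-tau2={tau2}",
    )


def run(cfg: RunConfig, outdir=None):
    """Execute a configuration and write its artifacts.

    Writes a tidy trajectory CSV, a JSON report (config echo + hash, corrector
    statistics, simplex-drift maxima) and, when requested, simplex/time-series
    figures.  Returns ``(trajectory, artifact paths)``.  Deterministic for a
    fixed configuration and seed.
    """
    outputs = dict(cfg.outputs or {})
    outdir = Path(outdir or outputs.get("directory") or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    model = cfg.build_model()
    x0 = cfg.build_initial_state(model)
    icfg = cfg.build_integrator()
    log.info("running %s: N=%d, n=%d, method=%s, dt=%g, t_end=%g",
             cfg.label or "run", model.N, model.n_species, icfg.method, icfg.dt, icfg.t_end)
    traj = integrate(model, x0, icfg)

    stride = int(outputs.get("stride", 1))
    paths = {}
    traj_path = outdir / outputs.get("trajectory", "trajectory.csv")
    traj.write_csv(traj_path, stride=stride)
    paths["trajectory"] = traj_path

    config_doc = cfg.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_doc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = {
        "label": cfg.label,
        "seed": cfg.seed,
        "config": config_doc,
        "config_hash": config_hash,
        **traj.meta,
    }
    report_path = outdir / outputs.get("report", "report.json")
    report_path.write_text(json.dumps(report, indent=2, default=str))
    paths["report"] = report_path

    if outputs.get("plots"):
        if model.n_species == 3:
            simplex_path = outdir / "simplex.png"
            plot_simplex(traj, simplex_path, stride=max(stride, 1))
            paths["simplex_plot"] = simplex_path
        series_path = outdir / "timeseries.png"
        plot_timeseries(traj, series_path, stride=max(stride, 1))
        paths["timeseries_plot"] = series_path

    log.info("done: max drift %.2e, corrector iters max %d",
             traj.meta["max_simplex_drift"], traj.meta.get("corrector_iterations_max", 0))
    return traj, paths
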