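"""Model configuration files and trajectory I/O.

A model config is a YAML document with three blocks::

    name: my-model            # optional metadata
    seed: 0                   # optional, drives random initial states
    tournament:
      matrix: [[0, 1, -1], [-1, 0, 1], [1, -1, 0]]
      # or: edges: [[winner, loser, rate], ...]   (1-based species)
    dispersal:
      edges:                  # [from, to, rate_fwd, rate_rev], 1-based patches
        - [1, 2, 0.5, 0.25]
      # or: file: path/to/edgelist.txt
    simulation:               # optional, defaults shown
      t_end: 1000.0
      n_samples: 2001
      rtol: 1.0e-10
      atol: 1.0e-12
      initial:
        kind: perturbed       # or "explicit" with proportions: [[...]]
        weight: 0.1

Unknown keys anywhere are rejected with the offending path in the error
message.  Trajectories are written as tidy CSV
(``time,species,patch,proportion``, 1-based indices, 17 significant
digits so the tidy format round-trips losslessly) or as wide CSV with
one ``s<i>_p<j>`` column per state entry; the Lyapunov series is a
two-column ``time,V`` CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dispersal import DispersalGraph, build_graph, read_edge_list
from .generators import perturbed_initial_state
from .models import BalancedModel, Trajectory, assemble
from .tournaments import TournamentMatrix, tournament_from_edges, validate_tournament

__all__ = [
    "ModelConfig",
    "ConfigError",
    "read_config",
    "load_example",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_lyapunov",
]

_SIM_DEFAULTS = {
    "t_end": 1000.0,
    "n_samples": 2001,
    "rtol": 1e-10,
    "atol": 1e-12,
    "initial": {"kind": "perturbed", "weight": 0.1},
}


class ConfigError(ValueError):
    """Raised when a config file violates the schema."""


@dataclass
class ModelConfig:
    """Parsed and validated model configuration."""

    tournament: TournamentMatrix
    graph: DispersalGraph
    simulation: dict = field(default_factory=lambda: dict(_SIM_DEFAULTS))
    name: str = ""
    seed: int | None = None

    def assemble(self) -> BalancedModel:
        return assemble(self.tournament, self.graph)

    def initial_state(self, model: BalancedModel) -> np.ndarray:
        init = self.simulation["initial"]
        if init["kind"] == "explicit":
            x0 = np.asarray(init["proportions"], dtype=float)
            if x0.shape != (model.n, model.m):
                raise ConfigError(
                    f"initial proportions have shape {x0.shape}, "
                    f"expected ({model.n}, {model.m})"
                )
            return x0
        return perturbed_initial_state(model.x_star,
                                       weight=init.get("weight", 0.1),
                                       seed=self.seed)


def _require_keys(block: dict, allowed: set, context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in '{context}'")


def _parse_tournament(block) -> TournamentMatrix:
    if not isinstance(block, dict):
        raise ConfigError("'tournament' must be a mapping")
    _require_keys(block, {"matrix", "edges"}, "tournament")
    if ("matrix" in block) == ("edges" in block):
        raise ConfigError("'tournament' needs exactly one of 'matrix' or 'edges'")
    if "matrix" in block:
        return validate_tournament(np.asarray(block["matrix"], dtype=float))
    return tournament_from_edges(block["edges"])


def _parse_dispersal(block, base_dir) -> DispersalGraph:
    if not isinstance(block, dict):
        raise ConfigError("'dispersal' must be a mapping")
    _require_keys(block, {"edges", "file", "m"}, "dispersal")
    if ("edges" in block) == ("file" in block):
        raise ConfigError("'dispersal' needs exactly one of 'edges' or 'file'")
    m = block.get("m")
    if "file" in block:
        path = base_dir / block["file"] if base_dir is not None else block["file"]
        return read_edge_list(path)
    return build_graph(block["edges"], m=m)


def _parse_simulation(block) -> dict:
    sim = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _SIM_DEFAULTS.items()}
    if block is None:
        return sim
    if not isinstance(block, dict):
        raise ConfigError("'simulation' must be a mapping")
    _require_keys(block, {"t_end", "n_samples", "rtol", "atol", "initial"}, "simulation")
    for key in ("t_end", "rtol", "atol"):
        if key in block:
            sim[key] = float(block[key])
    if "n_samples" in block:
        sim["n_samples"] = int(block["n_samples"])
    if "initial" in block:
        init = block["initial"]
        if not isinstance(init, dict) or "kind" not in init:
            raise ConfigError("'simulation.initial' must be a mapping with a 'kind'")
        kind = init["kind"]
        if kind == "perturbed":
            _require_keys(init, {"kind", "weight"}, "simulation.initial")
        elif kind == "explicit":
            _require_keys(init, {"kind", "proportions"}, "simulation.initial")
            if "proportions" not in init:
                raise ConfigError("'explicit' initial state needs 'proportions'")
        else:
            raise ConfigError(f"unknown initial-state kind {kind!r}")
        sim["initial"] = dict(init)
    return sim


def _parse_document(doc: dict, base_dir=None) -> ModelConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _require_keys(doc, {"name", "seed", "tournament", "dispersal", "simulation"}, "root")
    for key in ("tournament", "dispersal"):
        if key not in doc:
            raise ConfigError(f"missing required block '{key}'")
    seed = doc.get("seed")
    return ModelConfig(
        tournament=_parse_tournament(doc["tournament"]),
        graph=_parse_dispersal(doc["dispersal"], base_dir),
        simulation=_parse_simulation(doc.get("simulation")),
        name=str(doc.get("name", "")),
        seed=None if seed is None else int(seed),
    )


def read_config(path) -> ModelConfig:
    """Read and validate a YAML model config file."""
    from pathlib import Path

    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return _parse_document(doc, base_dir=path.parent)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def load_example(name: str) -> ModelConfig:
    """Load one of the packaged example configs (``example1``, ``example2``).

    ``example1`` is the heterogeneous three-patch migration cycle,
    ``example2`` the homogeneous hub-and-spokes topology; both carry the
    unit-rate three-species cyclic tournament.
    """
    resource = importlib.resources.files("metapopgames") / "examples" / f"{name}.yaml"
    if not resource.is_file():
        raise FileNotFoundError(f"no packaged example named {name!r}")
    doc = yaml.safe_load(resource.read_text())
    return _parse_document(doc)


def write_config(config_dict: dict, path) -> None:
    """Write a config mapping to YAML (used by the generator CLI)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)


def _tidy_frame(traj: Trajectory) -> pd.DataFrame:
    k, n, m = traj.states.shape
    times = np.repeat(traj.times, n * m)
    species = np.tile(np.repeat(np.arange(1, n + 1), m), k)
    patch = np.tile(np.arange(1, m + 1), k * n)
    return pd.DataFrame({
        "time": times,
        "species": species,
        "patch": patch,
        "proportion": traj.states.reshape(-1),
    })


def write_trajectory(traj: Trajectory, path, format: str = "tidy") -> None:
    """Write a trajectory as tidy or wide CSV (17 significant digits)."""
    if format == "tidy":
        _tidy_frame(traj).to_csv(path, index=False, float_format="%.17g")
    elif format == "wide":
        k, n, m = traj.states.shape
        cols = [f"s{i + 1}_p{j + 1}" for i in range(n) for j in range(m)]
        df = pd.DataFrame(traj.states.reshape(k, -1), columns=cols)
        df.insert(0, "time", traj.times)
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path) -> Trajectory:
    """Read a tidy-format trajectory CSV back into a :class:`Trajectory`.

    Lyapunov values are not stored in the CSV and come back as NaN.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", "species", "patch", "proportion"]
    if list(df.columns) != expected:
        raise ValueError(f"expected tidy columns {expected}, got {list(df.columns)}")
    if df.empty:
        return Trajectory(times=np.empty(0), states=np.empty((0, 0, 0)),
                          lyapunov_values=np.empty(0))
    n = int(df["species"].max())
    m = int(df["patch"].max())
    times = df["time"].to_numpy()[:: n * m]
    states = df["proportion"].to_numpy().reshape(-1, n, m)
    return Trajectory(times=times, states=states,
                      lyapunov_values=np.full(len(times), np.nan))


def write_lyapunov(traj: Trajectory, path) -> None:
    """Write the Lyapunov series as a ``time,V`` CSV."""
    pd.DataFrame({"time": traj.times, "V": traj.lyapunov_values}).to_csv(
        path, index=False, float_format="%.17g"
    )
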