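"""Structured configuration: YAML parameter files -> domain objects.

A single YAML document holds the membrane block, the branch geometry, the
boundary parameters, the dwell-time mixtures, the kinetic scheme and the
experiment protocol.  ``default_config()`` returns the packaged defaults;
user files may override any subset (shallow per-section merge).
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cable import DendriteGeometry
from .distributions import MultiExpDistribution
from .kinetic import KineticScheme
from .membrane import MembraneParams
from .transfer import BoundaryParams

__all__ = [
    "default_config",
    "load_config",
    "dump_config",
    "membrane_from_config",
    "geometry_from_config",
    "boundary_from_config",
    "distributions_from_config",
    "kinetic_from_config",
    "stimulus_grid_from_config",
]


def default_config() -> dict:
    """The packaged default parameter set as a plain dict."""
    text = resources.files("dendtf.data").joinpath("default.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unspecified sections from the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            merged = copy.deepcopy(cfg[section])
            merged.update(value)
            cfg[section] = merged
        else:
            cfg[section] = value
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def membrane_from_config(cfg: dict) -> MembraneParams:
    return MembraneParams(**cfg["membrane"])


def geometry_from_config(cfg: dict) -> DendriteGeometry:
    g = cfg["geometry"]
    return DendriteGeometry(
        positions=tuple(g["positions"]),
        lambda_to_soma=g["lambda_to_soma"],
        lambda_back=g.get("lambda_back"),
        spike_lambda_fraction=g.get("spike_lambda_fraction", 0.5),
    )


def boundary_from_config(cfg: dict, section: str = "boundary") -> BoundaryParams:
    b = cfg[section] if isinstance(section, str) else section
    return BoundaryParams(b["b_l"], b["b_u"], b["alpha_l"], b["alpha_u"])


def distributions_from_config(cfg: dict) -> dict[str, MultiExpDistribution]:
    """Opening/burst mixtures, both full and filtered, keyed by name."""
    d = cfg["distributions"]
    opening_full = MultiExpDistribution.from_dict(d["opening_full"])
    burst_full = MultiExpDistribution.from_dict(d["burst_full"])
    return {
        "opening_full": opening_full,
        "opening_filtered": opening_full.filter_and_reweight(d["opening_min_tau_ms"]),
        "burst_full": burst_full,
        "burst_filtered": burst_full.filter_and_reweight(d["burst_min_tau_ms"]),
    }


def kinetic_from_config(cfg: dict) -> KineticScheme:
    k = {key: val for key, val in cfg["kinetic"].items() if key != "t_end"}
    return KineticScheme(**k)


def stimulus_grid_from_config(entry) -> np.ndarray:
    """A stimulus grid given either as a list of levels or start/stop/step."""
    if isinstance(entry, dict):
        grid = np.arange(entry["start"], entry["stop"] + 0.5 * entry["step"],
                         entry["step"])
    else:
        grid = np.asarray(entry, dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("stimulus grid must be nonnegative and increasing")
    return grid
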