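"""Run configuration, YAML round-tripping, and hyperparameter grids."""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__

__all__ = ["RunConfig", "load_config", "echo_config", "grid",
           "mcl_grid", "louvain_grid"]


@dataclass
class RunConfig:
    """Resolved settings for one run; every stochastic step is seeded."""

    method: str = "louvain"
    resistance: float = 0.1
    inflation: float = 2.0
    drop_frac: float = 0.01
    n_iter: int = 100
    alpha: float = 0.85
    eps: float = 1e-5
    max_size: int = 100
    min_size: int = 3
    core_size: int = 60
    size_trigger: int = 100
    threshold: float = 0.5
    pvalue_cutoff: float = 1e-4
    fdr: float = 0.05
    top_frac: float = 0.5
    seed: int = 0
    graph: str | None = None
    out: str | None = None


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; missing keys take defaults, unknown keys fail."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    data.pop("version", None)  # provenance echo, not a setting
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"valid keys: {sorted(_FIELDS)}"
        )
    return RunConfig(**data)


def echo_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config plus library version next to outputs."""
    payload = dataclasses.asdict(cfg)
    payload["version"] = __version__
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def grid(**ranges: list) -> list[RunConfig]:
    """Cartesian expansion of parameter ranges into RunConfigs."""
    if not ranges:
        raise ValueError("no ranges given")
    for name, values in ranges.items():
        if name not in _FIELDS:
            raise ValueError(f"unknown parameter {name!r}")
        if not values:
            raise ValueError(f"empty range for {name!r}")
    names = sorted(ranges)
    return [RunConfig(**dict(zip(names, combo)))
            for combo in itertools.product(*(ranges[n] for n in names))]


def mcl_grid() -> list[RunConfig]:
    """Inflation 2..9 in steps of 1, expansion fixed at 2."""
    return [RunConfig(method="mcl", inflation=float(i)) for i in range(2, 10)]


def louvain_grid() -> list[RunConfig]:
    """Resistance 0.1..1.0 in steps of 0.1."""
    return [RunConfig(method="louvain", resistance=round(0.1 * i, 1))
            for i in range(1, 11)]
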