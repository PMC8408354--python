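"""Scenario-grid configuration files and run manifests.

A configuration is a small YAML document, either a factor grid that is
expanded to its full cross-product::

    grid:
      r2: [0.2, 0.4, 0.6, 0.8, 0.9]
      skewness: [0.1, 1, 1.5, 3]
      linear: [true, false]
      differential: [false]
      val_fraction: [0.40]
    n: 650
    n_reps: 5000
    seed: 20210420

or an explicit ``scenarios:`` list of per-scenario mappings (the form
written by :func:`write_config`, so load(write(grid)) round-trips).
Shipped reproduction configs (``study_main``, ``study_frac10/25/50``,
``study_differential``) live in :mod:`rcsample.configs`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import yaml

from .dgm import InvalidParameterError, ScenarioConfig, scenario_grid

__all__ = [
    "ConfigError",
    "load_config",
    "write_config",
    "shipped_config_path",
    "config_digest",
    "RunManifest",
    "SHIPPED_CONFIGS",
]

SHIPPED_CONFIGS = ("study_main", "study_frac10", "study_frac25",
                   "study_frac50", "study_differential")

_TOP_KEYS = {"grid", "scenarios", "n", "n_reps", "seed"}
_GRID_KEYS = {"r2", "skewness", "linear", "differential", "val_fraction"}
_SCENARIO_KEYS = {"r2", "skewness", "linear", "differential",
                  "val_fraction", "n", "n_reps", "seed"}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def shipped_config_path(name: str) -> Path:
    """Filesystem path of a shipped reproduction config by short name."""
    if name not in SHIPPED_CONFIGS:
        raise ConfigError(
            f"unknown shipped config {name!r}; available: {SHIPPED_CONFIGS}")
    return Path(str(resources.files("rcsample") / "configs" / f"{name}.yaml"))


def load_config(path: str | Path) -> list[ScenarioConfig]:
    """Parse and validate a YAML scenario configuration.

    Returns the expanded list of :class:`ScenarioConfig`; unknown keys and
    out-of-range values raise :class:`ConfigError` naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")

    n = int(raw.get("n", 650))
    n_reps = int(raw.get("n_reps", 5000))
    seed = int(raw.get("seed", 0))

    if "scenarios" in raw:
        entries = raw["scenarios"]
        if not entries:
            raise ConfigError(f"{path}: empty scenario list")
        configs = []
        for i, entry in enumerate(entries):
            unknown = set(entry) - _SCENARIO_KEYS
            if unknown:
                raise ConfigError(
                    f"{path}: scenario {i}: unknown keys {sorted(unknown)}")
            try:
                configs.append(ScenarioConfig(
                    r2_target=float(entry["r2"]),
                    skewness=float(entry["skewness"]),
                    linear=bool(entry.get("linear", True)),
                    differential=bool(entry.get("differential", False)),
                    val_fraction=float(entry.get("val_fraction", 0.40)),
                    n=int(entry.get("n", n)),
                    n_reps=int(entry.get("n_reps", n_reps)),
                    seed=int(entry.get("seed", seed)),
                ))
            except (KeyError, InvalidParameterError) as exc:
                raise ConfigError(f"{path}: scenario {i}: {exc}") from exc
        return configs

    if "grid" not in raw:
        raise ConfigError(f"{path}: needs a 'grid' or 'scenarios' section")
    grid = raw["grid"] or {}
    unknown = set(grid) - _GRID_KEYS
    if unknown:
        raise ConfigError(f"{path}: grid: unknown keys {sorted(unknown)}")

    def levels(key, default):
        v = grid.get(key, default)
        if not isinstance(v, (list, tuple)) or len(v) == 0:
            raise ConfigError(f"{path}: grid.{key}: non-empty list required")
        return tuple(v)

    try:
        return scenario_grid(
            r2=tuple(float(x) for x in levels("r2", [0.8])),
            skewness=tuple(float(x) for x in levels("skewness", [0.1])),
            linear=tuple(bool(x) for x in levels("linear", [True])),
            differential=tuple(
                bool(x) for x in levels("differential", [False])),
            val_fraction=tuple(
                float(x) for x in levels("val_fraction", [0.40])),
            n=n, n_reps=n_reps, seed=seed)
    except InvalidParameterError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_config(configs: list[ScenarioConfig], path: str | Path) -> Path:
    """Write an explicit scenario list; inverse of :func:`load_config`."""
    if not configs:
        raise ConfigError("cannot write an empty scenario list")
    doc = {
        "scenarios": [
            {
                "r2": cfg.r2_target,
                "skewness": cfg.skewness,
                "linear": cfg.linear,
                "differential": cfg.differential,
                "val_fraction": cfg.val_fraction,
                "n": cfg.n,
                "n_reps": cfg.n_reps,
                "seed": cfg.seed,
            }
            for cfg in configs
        ]
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def config_digest(configs: list[ScenarioConfig]) -> str:
    """Content hash (sha256) of a canonical encoding of the scenario list."""
    canon = json.dumps([asdict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one simulation run: identical (digest, seed, version)
    implies bit-identical result tables."""

    config_digest: str
    master_seed: int
    package_version: str
    n_scenarios: int
    outputs: dict = field(default_factory=dict)
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    @classmethod
    def for_run(cls, configs: list[ScenarioConfig], master_seed: int,
                outputs: dict | None = None) -> "RunManifest":
        from . import __version__
        return cls(config_digest=config_digest(configs),
                   master_seed=master_seed,
                   package_version=__version__,
                   n_scenarios=len(configs),
                   outputs=outputs or {})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path
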