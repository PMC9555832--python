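"""Configuration files, trajectory CSV, color palettes and run manifests.

Formats are deliberately plain: YAML/JSON configs, '#'/'.' text barrier
masks, long-format CSV trajectories (diff-able at classroom scale) and JSON
snapshots/manifests.  A manifest plus the input files it names suffices to
reproduce every output byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import GENERATOR_NAME, ParameterError, SimConfig
from .grid import GridSpec
from .stats import AlleleTrajectory


class ConfigError(ValueError):
    """Invalid configuration document (named diagnostics, never a crash)."""


_CONFIG_KEYS = {
    "rows": int,
    "cols": int,
    "init_mu": float,
    "run_mu": float,
    "steps_per_generation": int,
    "seed": int,
    "max_generations": int,
    "barrier_mask": str,
}

_CONFIG_DEFAULTS = {
    "rows": 32,
    "cols": 32,
    "init_mu": 0.001,
    "run_mu": 0.0,
    "steps_per_generation": 2000,
    "seed": 0,
    "max_generations": 100_000,
}


def config_from_dict(doc: dict) -> tuple[SimConfig, str | None]:
    """Resolve a config document: apply defaults, reject unknown keys.

    Returns (config, barrier_mask_path_or_None).
    """
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config document must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    resolved = dict(_CONFIG_DEFAULTS)
    for key, value in doc.items():
        want = _CONFIG_KEYS[key]
        if want is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, want) or isinstance(value, bool):
            raise ConfigError(f"config key {key!r}: expected {want.__name__}, got {value!r}")
        resolved[key] = value
    mask_path = resolved.pop("barrier_mask", None)
    try:
        config = SimConfig(
            grid=GridSpec(resolved["rows"], resolved["cols"]),
            init_mu=resolved["init_mu"],
            run_mu=resolved["run_mu"],
            steps_per_generation=resolved["steps_per_generation"],
            seed=resolved["seed"],
            max_generations=resolved["max_generations"],
        )
    except (ParameterError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return config, mask_path


def load_config(path) -> tuple[SimConfig, str | None]:
    """Load a YAML or JSON config file; missing keys take the defaults
    (32 x 32 grid, init_mu 0.001, run_mu 0, 2000 steps/generation)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        doc = yaml.safe_load(text) if text.strip() else {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(doc)


def config_to_dict(config: SimConfig, barrier_mask: str | None = None) -> dict:
    doc = {
        "rows": config.grid.rows,
        "cols": config.grid.cols,
        "init_mu": config.init_mu,
        "run_mu": config.run_mu,
        "steps_per_generation": config.steps_per_generation,
        "seed": config.seed,
        "max_generations": config.max_generations,
    }
    if barrier_mask is not None:
        doc["barrier_mask"] = barrier_mask
    return doc


def dump_config(config: SimConfig, path, barrier_mask: str | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config, barrier_mask), sort_keys=False))


def validate_config(config: SimConfig) -> list[str]:
    """Diagnostics for a resolved config; empty list means valid.

    SimConfig's constructor already rejects hard errors, so this surfaces
    soft warnings a classroom user would want to see.
    """
    notes = []
    if config.run_mu > 0.1:
        notes.append("run_mu > 0.1: mutation will overwhelm drift; fixation unlikely")
    if config.grid.n_cells > 250_000:
        notes.append("very large grid; runs will be slow")
    return notes


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["generation", "component_id", "allele_id", "count", "frequency"]


def write_trajectory(trajectory: AlleleTrajectory, path) -> None:
    """Long-format CSV with header generation,component_id,allele_id,count,
    frequency; frequencies serialized to 10 significant digits."""
    df = trajectory.to_frame().sort_values(
        ["generation", "component_id", "allele_id"], ignore_index=True
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectory(path) -> AlleleTrajectory:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read trajectory {path}: {exc}") from exc
    if list(df.columns) != _TRAJ_COLUMNS:
        raise IOError(f"trajectory {path}: unexpected columns {list(df.columns)}")
    traj = AlleleTrajectory()
    for row in df.itertuples(index=False):
        traj.records.append(
            (int(row.generation), int(row.component_id), int(row.allele_id),
             int(row.count), float(row.frequency))
        )
    return traj


# ---------------------------------------------------------------------------
# palette
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Palette:
    """18 basic colors for initial (urn) alleles, 6 neon colors for mutant
    alleles; assignment cycles when alleles outnumber the palette."""

    basic_colors: tuple[str, ...] = (
        "red", "green", "blue", "orange", "purple", "brown",
        "pink", "gray", "olive", "cyan", "magenta", "yellow",
        "maroon", "navy", "teal", "lime", "coral", "gold",
    )
    neon_colors: tuple[str, ...] = (
        "neon-green", "neon-pink", "neon-orange",
        "neon-yellow", "neon-blue", "neon-purple",
    )

    def __post_init__(self) -> None:
        if len(self.basic_colors) != 18 or len(self.neon_colors) != 6:
            raise ParameterError("palette needs exactly 18 basic and 6 neon colors")


def assign_colors(
    allele_ids, initial_allele_limit: int, palette: Palette | None = None
) -> dict[int, str]:
    """Map alleles to display colors.

    Alleles with id below *initial_allele_limit* (the allele counter at the
    end of initialization) were created by the urn and take basic colors in
    first-seen order, cycling modulo 18; later ids are mutants and take neon
    colors modulo 6.
    """
    palette = palette or Palette()
    out: dict[int, str] = {}
    n_basic = n_neon = 0
    for a in allele_ids:
        a = int(a)
        if a in out:
            continue
        if a < initial_allele_limit:
            out[a] = palette.basic_colors[n_basic % 18]
            n_basic += 1
        else:
            out[a] = palette.neon_colors[n_neon % 6]
            n_neon += 1
    return out


# ---------------------------------------------------------------------------
# manifests and snapshots
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs byte-identically."""

    config: dict
    seed: int
    generator: str = GENERATOR_NAME
    software_version: str = __version__
    start_generation: int = 0
    end_generation: int = 0
    event_log: str | None = None
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_snapshot(state, path) -> None:
    Path(path).write_text(json.dumps(state.snapshot(), indent=None) + "\n")


def read_snapshot(path) -> dict:
    return json.loads(Path(path).read_text())
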