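"""Run configuration, seeding, and reproducibility plumbing.

A :class:`RunConfig` captures every parameter of a simulated experiment in a
single YAML-serializable structure; re-running a persisted config reproduces
all outputs bit-identically.  All randomness flows from one master seed
through named substreams (:func:`substream`), so independent stages draw from
independent, stable streams.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "OpticsConfig",
    "FieldConfig",
    "CalibConfig",
    "EvalConfig",
    "RunConfig",
    "substream",
]


def substream(master_seed: int, name: str) -> int:
    """Stable named substream seed (< 2³¹) derived from the master seed."""
    h = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return (int(master_seed) * 1_000_003 + h) & 0x7FFFFFFF


@dataclass
class OpticsConfig:
    na: float = 0.5
    wavelength: float = 0.920
    refractive_index: float = 1.33
    grid_size: int = 64
    pad_factor_render: int = 8   # image rendering (fine focal sampling)
    pad_factor_metric: int = 4   # calibration metric (coarser is fine)


@dataclass
class FieldConfig:
    astig_edge: float = 0.12
    coma_edge: float = 0.12
    spherical_edge: float = 0.06
    random_amplitude: float = 0.03
    n_terms: int = 11
    fov_radius: float = 4000.0


@dataclass
class CalibConfig:
    n_terms: int = 11
    rounds_min: int = 4
    rounds_max: int = 8
    cycles_per_term: int = 5
    steps_per_cycle: int = 21
    first_half_range: float = 0.5
    range_decay: float = 0.5
    convergence_threshold: float = 0.01
    metric: str = "sum"
    term_order: str = "defocus_last"


@dataclass
class EvalConfig:
    radii: tuple = (0.0, 2000.0, 3900.0)
    bead_count: int = 6
    bead_diameter: float = 0.5
    movie_cells: int = 5
    movie_duration: float = 60.0
    movie_size_px: int = 64
    scene_size: float = 100.0


@dataclass
class RunConfig:
    """Complete experiment description (see module docstring)."""

    fov_diameter: float = 8000.0
    inclusion_radius: float = 3950.0
    hex_side: float = 577.0
    effective_radius: float = 330.0
    scan_n: int = 4
    seed: int = 0
    outdir: str = "cmatsim_out"
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    field_model: FieldConfig = field(default_factory=FieldConfig)
    calibration: CalibConfig = field(default_factory=CalibConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for key, sub in (
            ("optics", OpticsConfig),
            ("field_model", FieldConfig),
            ("calibration", CalibConfig),
            ("evaluation", EvalConfig),
        ):
            if key in d:
                v = d.pop(key)
                if key == "evaluation" and "radii" in v:
                    v["radii"] = tuple(v["radii"])
                kwargs[key] = sub(**v)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Short stable hash of the canonical YAML dump."""
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
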