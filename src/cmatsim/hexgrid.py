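"""Honeycomb correction-point geometry for multipoint adaptive optics.

The full field of view (FOV) of the mesoscope is tiled with regular hexagons
of side ``s``; the hexagon centers together with the hexagon vertices form a
triangular lattice of pitch ``s``.  Every lattice point inside an inclusion
radius is a *correction point*: a location at which the deformable mirror is
calibrated, and whose compensation is loaded whenever the scanner images
nearby.  Each point is considered effective within a disk of radius
``effective_radius`` (the isoplanatic patch of the correction).

With the reference parameters (side 577 µm, inclusion radius 3950 µm on an
8 mm FOV) the grid contains 163 points, 55 of which are hexagon centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "FOVSpec",
    "HexTilingSpec",
    "CorrectionGrid",
    "OverlapReport",
    "GalvoCalib",
    "CoverageError",
    "build_correction_grid",
    "nearest_point",
    "overlap_report",
    "hex_circumradius",
    "galvo_voltages",
    "check_coverage",
    "save_grid",
    "load_grid",
]

#: Tolerance (µm) used when comparing point coordinates / distances.
_GEOM_TOL = 1e-6


class CoverageError(ValueError):
    """Some FOV location lies farther than the effective radius from every point."""


@dataclass(frozen=True)
class FOVSpec:
    """Circular full field of view.

    Parameters
    ----------
    diameter:
        Diameter of the circular FOV in µm (reference system: 8000).
    inclusion_radius:
        Radius in µm inside which triangular-lattice points are admitted as
        correction points.  The default 3950 reproduces the reference grid
        (163 points / 55 hexagon centers); any value in roughly
        [3790, 3995] gives the same counts for side 577.
    """

    diameter: float = 8000.0
    inclusion_radius: float = 3950.0

    def __post_init__(self) -> None:
        if not (0.0 < self.inclusion_radius <= self.diameter / 2.0):
            raise ValueError(
                f"inclusion_radius must lie in (0, diameter/2]; got "
                f"{self.inclusion_radius} for diameter {self.diameter}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class HexTilingSpec:
    """Regular-hexagon tiling unit.

    ``side`` is the hexagon side length (577 µm in the reference system);
    ``effective_radius`` is the radius of the disk over which one point's
    correction is considered valid (330 µm).  The coverage condition requires
    effective_radius ≥ side/√3 up to a small tolerance: side/√3 is the
    circumradius of the equilateral triangle formed by a hexagon center and
    two adjacent vertices, i.e. the worst-case distance to the nearest
    correction point inside the tiled region.  The reference pair
    (577, 330) sits 0.94 % below that bound — the instrument's own rounding —
    so a 1 % slack is allowed.
    """

    side: float = 577.0
    effective_radius: float = 330.0
    #: fixed orientation convention: the hexagon-center sublattice has a basis
    #: vector (√3·side, 0) along +x; hexagon vertices sit at 30° + k·60° from
    #: each center.
    orientation: str = "center-sublattice-x"

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError(f"hexagon side must be positive; got {self.side}")
        bound = self.side / math.sqrt(3.0)
        if self.effective_radius < bound * (1.0 - 0.01):
            raise ValueError(
                f"effective_radius {self.effective_radius} violates the coverage "
                f"condition (needs ≥ side/√3 = {bound:.2f} µm within 1 %)"
            )


@dataclass(frozen=True)
class CorrectionGrid:
    """Ordered set of correction points.

    ``points`` is an (N, 2) array of FOV-centered coordinates in µm; ``kinds``
    holds ``"center"`` or ``"vertex"`` per point.  Ordering is deterministic:
    sorted by distance from the origin, ties broken by angle from +x
    (smaller angle first).
    """

    points: np.ndarray
    kinds: tuple[str, ...]
    side: float
    effective_radius: float
    inclusion_radius: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def hexagon_centers(self) -> np.ndarray:
        """Indices of the hexagon-center sublattice (pitch √3·side)."""
        return np.flatnonzero([k == "center" for k in self.kinds])

    @property
    def n_centers(self) -> int:
        return len(self.hexagon_centers)


@dataclass(frozen=True)
class OverlapReport:
    """Disk-overlap economics of a correction-point layout.

    ``pairwise_pct`` is the percent of one effective disk's area shared with a
    single adjacent disk; ``total_pct`` multiplies it by the number of nearest
    neighbors (6 in the hexagonal layout, 4 in the square layout).
    """

    scheme: Literal["cmat", "square"]
    pairwise_pct: float
    total_pct: float
    neighbors: int


@dataclass(frozen=True)
class GalvoCalib:
    """Linear slow-axis galvo position→voltage calibration.

    The mechanical response is modeled as a linear, odd map: a position at the
    FOV edge corresponds to ``full_scale_angle`` degrees (45° for the
    reference slow-axis pair), converted to volts with ``volts_per_degree``.
    """

    full_scale_angle: float = 45.0
    volts_per_degree: float = 0.2


def _lattice_basis(side: float) -> tuple[np.ndarray, np.ndarray]:
    # Full triangular lattice of pitch `side`, rotated so that the
    # hexagon-center sublattice (pitch √3·side) has a basis vector along +x.
    a1 = np.array([side * math.sqrt(3.0) / 2.0, side / 2.0])  # 30°
    a2 = np.array([0.0, side])  # 90°
    return a1, a2


def build_correction_grid(
    fov: FOVSpec,
    tiling: HexTilingSpec,
    *,
    coverage_radius: float | None = None,
    coverage_sample_pitch: float = 50.0,
) -> CorrectionGrid:
    """Enumerate all correction points inside the inclusion radius.

    All triangular-lattice points of pitch ``tiling.side`` whose distance from
    the FOV center is at most ``fov.inclusion_radius`` are admitted; the
    sublattice of pitch √3·side containing the origin is flagged as the
    hexagon centers, the rest are hexagon vertices.

    If ``coverage_radius`` is given, verify (on a grid of pitch
    ``coverage_sample_pitch`` µm) that every location of that disk lies within
    ``max(effective_radius, side/√3)`` of some point, raising
    :class:`CoverageError` naming the worst uncovered location otherwise.
    """
    a1, a2 = _lattice_basis(tiling.side)
    kmax = int(math.ceil(fov.inclusion_radius / tiling.side * 2.0)) + 2
    pts: list[np.ndarray] = []
    kinds: list[str] = []
    limit = fov.inclusion_radius * (1.0 + 1e-12)
    for m in range(-kmax, kmax + 1):
        for n in range(-kmax, kmax + 1):
            p = m * a1 + n * a2
            if math.hypot(p[0], p[1]) <= limit:
                pts.append(p)
                kinds.append("center" if (m - n) % 3 == 0 else "vertex")
    points = np.array(pts)
    order = _canonical_order(points)
    grid = CorrectionGrid(
        points=points[order],
        kinds=tuple(kinds[i] for i in order),
        side=tiling.side,
        effective_radius=tiling.effective_radius,
        inclusion_radius=fov.inclusion_radius,
    )
    if coverage_radius is not None:
        worst_d, worst_xy = check_coverage(
            grid, coverage_radius, sample_pitch=coverage_sample_pitch
        )
        bound = max(tiling.effective_radius, tiling.side / math.sqrt(3.0))
        if worst_d > bound * (1.0 + _GEOM_TOL):
            raise CoverageError(
                f"location ({worst_xy[0]:.1f}, {worst_xy[1]:.1f}) µm is "
                f"{worst_d:.1f} µm from the nearest correction point "
                f"(> effective radius {bound:.1f} µm)"
            )
    return grid


def _canonical_order(points: np.ndarray) -> np.ndarray:
    """Sort by distance from origin, then by angle from +x in [0, 2π)."""
    r = np.hypot(points[:, 0], points[:, 1])
    ang = np.mod(np.arctan2(points[:, 1], points[:, 0]), 2.0 * math.pi)
    # quantize distances so symmetric shells compare equal despite round-off
    r_key = np.round(r / _GEOM_TOL) * _GEOM_TOL
    return np.lexsort((ang, r_key))


def check_coverage(
    grid: CorrectionGrid, radius: float, *, sample_pitch: float = 50.0
) -> tuple[float, tuple[float, float]]:
    """Max distance-to-nearest-point over a sampled disk.

    Returns ``(max_min_distance, worst_location)`` for samples on a Cartesian
    grid of the given pitch inside the disk of ``radius`` µm.
    """
    from scipy.spatial import cKDTree

    xs = np.arange(-radius, radius + sample_pitch / 2.0, sample_pitch)
    X, Y = np.meshgrid(xs, xs)
    mask = np.hypot(X, Y) <= radius
    samples = np.column_stack([X[mask], Y[mask]])
    d, _ = cKDTree(grid.points).query(samples)
    i = int(np.argmax(d))
    return float(d[i]), (float(samples[i, 0]), float(samples[i, 1]))


def nearest_point(grid: CorrectionGrid, position) -> int:
    """Index of the correction point nearest to ``position`` (µm).

    Exact distance ties resolve to the lowest index of the grid's canonical
    ordering.
    """
    if len(grid) == 0:
        raise ValueError("correction grid is empty")
    p = np.asarray(position, dtype=float)
    d = np.hypot(grid.points[:, 0] - p[0], grid.points[:, 1] - p[1])
    dmin = d.min()
    tied = np.flatnonzero(d <= dmin + _GEOM_TOL)
    return int(tied[0])


def hex_circumradius(side: float) -> float:
    """Circumradius side/√3 of the center–vertex–vertex equilateral triangle.

    For side 577 µm this is 333.13 µm, i.e. roughly 330 µm — the effective
    compensation radius of the reference system.
    """
    if side <= 0:
        raise ValueError(f"side must be positive; got {side}")
    return side / math.sqrt(3.0)


def _lens_area(r: float, d: float) -> float:
    """Intersection area of two disks of radius r with center separation d."""
    if d >= 2.0 * r:
        return 0.0
    return 2.0 * r * r * math.acos(d / (2.0 * r)) - (d / 2.0) * math.sqrt(
        4.0 * r * r - d * d
    )


def overlap_report(
    scheme: Literal["cmat", "square"], effective_radius: float = 330.0
) -> OverlapReport:
    """Pairwise and total disk-overlap percentages of a layout.

    In the hexagonal (cmat) layout the point spacing is √3·r (side-to-
    circumradius relation s = √3·R_eff), with 6 nearest neighbors; in the
    minimal fully covering square layout the spacing is √2·r with 4
    neighbors.  Percentages are scale-invariant in r.
    """
    r = float(effective_radius)
    if r <= 0:
        raise ValueError(f"effective_radius must be positive; got {r}")
    if scheme == "cmat":
        d, neighbors = math.sqrt(3.0) * r, 6
    elif scheme == "square":
        d, neighbors = math.sqrt(2.0) * r, 4
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    pairwise = 100.0 * _lens_area(r, d) / (math.pi * r * r)
    return OverlapReport(
        scheme=scheme,
        pairwise_pct=pairwise,
        total_pct=neighbors * pairwise,
        neighbors=neighbors,
    )


def galvo_voltages(position, calib: GalvoCalib, fov: FOVSpec) -> np.ndarray:
    """Slow-axis drive voltages for an object-plane position (µm).

    Linear odd map per axis: the FOV edge (|x| = diameter/2) maps to
    ``full_scale_angle · volts_per_degree`` volts.
    """
    p = np.asarray(position, dtype=float)
    half = fov.diameter / 2.0
    for axis, name in zip(p, ("x", "y")):
        if abs(axis) > half * (1.0 + 1e-12):
            raise ValueError(
                f"position {name}={axis} µm outside the ±{half} µm FOV"
            )
    return p / half * calib.full_scale_angle * calib.volts_per_degree


# ---------------------------------------------------------------------------
# text I/O

def save_grid(grid: CorrectionGrid, path) -> None:
    """Write the grid as tab-separated text: index, x_um, y_um, kind."""
    lines = [
        "# cmatsim correction grid",
        f"# side_um\t{grid.side}",
        f"# effective_radius_um\t{grid.effective_radius}",
        f"# inclusion_radius_um\t{grid.inclusion_radius}",
        "# index\tx_um\ty_um\tkind",
    ]
    for i, ((x, y), kind) in enumerate(zip(grid.points, grid.kinds)):
        lines.append(f"{i}\t{x:.9g}\t{y:.9g}\t{kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_grid(path) -> CorrectionGrid:
    """Read a grid written by :func:`save_grid`."""
    meta = {"side_um": 577.0, "effective_radius_um": 330.0,
            "inclusion_radius_um": 3950.0}
    pts, kinds = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2 and parts[0] in meta:
                meta[parts[0]] = float(parts[1])
            continue
        _, x, y, kind = line.split("\t")
        pts.append((float(x), float(y)))
        kinds.append(kind)
    return CorrectionGrid(
        points=np.array(pts),
        kinds=tuple(kinds),
        side=meta["side_um"],
        effective_radius=meta["effective_radius_um"],
        inclusion_radius=meta["inclusion_radius_um"],
    )
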