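"""Tiled full-FOV and ROI scanning with per-tile correction loading.

A full-FOV frame is acquired as N×N square tiles in stripe order (top stripe
first, tiles left-to-right within a stripe).  Before each tile the deformable
mirror loads the calibrated compensation vector of the correction point
nearest to the tile center — N² DM loads per frame — and the galvo jump /
DM load interval is excluded from image formation (logged, no data kept).
ROI scanning applies a single compensation vector, chosen by the ROI
centroid's nearest correction point, for the whole sequence.

Rendering uses a piecewise-constant PSF per tile (evaluated at the tile
center): one DM state, one isoplanatic kernel per subregion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .hexgrid import CorrectionGrid, FOVSpec, nearest_point
from .calibration import CalibrationTable
from .optics import OpticsModel
from .phantoms import CalciumMovie, Volume
from .wavefront import DMState

__all__ = [
    "Tile",
    "ScanPlan",
    "ROIRequest",
    "Frame",
    "plan_full_fov",
    "render_tile",
    "scan_frame",
    "scan_roi",
    "save_plan",
]


@dataclass(frozen=True)
class Tile:
    """One scan subregion: half-open extent [xmin, xmax) × [ymin, ymax) µm."""

    row: int                 # stripe index, 0 = top
    col: int                 # 0 = leftmost
    center: tuple[float, float]
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    point_index: int
    dm_coeffs: np.ndarray


@dataclass(frozen=True)
class ScanPlan:
    """Ordered tiles of a full-FOV scan plus the per-tile DM loads."""

    n: int
    tile_size: float
    fov: FOVSpec
    tiles: tuple[Tile, ...]
    ceao_coeffs: np.ndarray   # compensation of the FOV-center point
    center_point_index: int

    @property
    def dm_load_events(self) -> int:
        return len(self.tiles)


@dataclass(frozen=True)
class ROIRequest:
    """User-selected subfield scan."""

    center: tuple[float, float]
    width: float
    height: float
    pixel_pitch: float | None = None   # None: use the phantom's pitch
    frames: int = 1
    frame_rate: float = 15.0


@dataclass(frozen=True)
class Frame:
    """Assembled image with per-tile provenance and the excluded-sample log."""

    pixels: np.ndarray
    pitch: float
    provenance: tuple
    excluded_log: tuple


def plan_full_fov(
    fov: FOVSpec, n: int, grid: CorrectionGrid, calib: CalibrationTable
) -> ScanPlan:
    """N×N stripe-ordered tiling of the FOV square with DM assignments.

    Each tile's DM vector is the calibrated compensation of the correction
    point nearest to the tile center.  The reference protocol uses n=4 over
    the 8 mm FOV: 16 tiles of 2×2 mm, 16 DM loads per frame.
    """
    if n < 1:
        raise ValueError("grid order n must be ≥ 1")
    D = fov.diameter
    size = D / n
    tiles: list[Tile] = []
    for row in range(n):           # top stripe first
        for col in range(n):       # left to right
            xmin = -D / 2 + col * size
            ymax = D / 2 - row * size
            center = (xmin + size / 2.0, ymax - size / 2.0)
            idx = nearest_point(grid, center)
            try:
                vec = calib.vector(idx)
            except KeyError as exc:
                raise KeyError(
                    f"calibration table has no entry for correction point {idx} "
                    f"(tile row {row}, col {col})"
                ) from exc
            tiles.append(
                Tile(
                    row=row,
                    col=col,
                    center=center,
                    extent=(xmin, xmin + size, ymax - size, ymax),
                    point_index=idx,
                    dm_coeffs=np.asarray(vec, dtype=float),
                )
            )
    center_idx = nearest_point(grid, (0.0, 0.0))
    return ScanPlan(
        n=n,
        tile_size=size,
        fov=fov,
        tiles=tuple(tiles),
        ceao_coeffs=np.asarray(calib.vector(center_idx), dtype=float),
        center_point_index=center_idx,
    )


# ---------------------------------------------------------------------------
# rendering

def _kernel_for_pitch(
    optics: OpticsModel,
    position,
    dm: DMState | None,
    pitch: float,
    *,
    crop_um: float = 6.0,
) -> np.ndarray:
    """Focal-plane two-photon kernel resampled to an image pixel pitch.

    The PSF is computed on the pupil-FFT grid and linearly interpolated onto
    pixel offsets.  The kernel is normalized so the *unaberrated* kernel at
    the same pitch has unit mass: imaging a constant scene through perfect
    optics preserves its level, and residual aberrations attenuate the
    collected signal by the relative two-photon excitation efficiency.
    """
    def _raw(phase_dm):
        psf = optics.psf3d(position, phase_dm, [0.0])
        sl = psf.data[0]
        c0 = sl.shape[0] // 2
        half = int(math.ceil(crop_um / pitch))
        offs = (np.arange(-half, half + 1)) * pitch / psf.lateral_pitch + c0
        O1, O2 = np.meshgrid(offs, offs)
        k = ndimage.map_coordinates(sl, [O2, O1], order=1, mode="constant")
        return k * (pitch / psf.lateral_pitch) ** 2

    cache = getattr(optics, "_kernel_mass_cache", None)
    if cache is None:
        cache = {}
        optics._kernel_mass_cache = cache
    key = (round(pitch, 9), round(crop_um, 9))
    if key not in cache:
        from .wavefront import DMState as _DM

        perfect = _DM(-optics.truth(position))
        cache[key] = float(_raw(perfect).sum())
    return _raw(dm) / cache[key]


def _phantom_plane(phantom: Volume) -> tuple[np.ndarray, float]:
    data = phantom.data
    if data.ndim == 3:
        if data.shape[0] != 1:
            raise ValueError("tile rendering expects a single-plane phantom")
        data = data[0]
    return data, phantom.lateral_pitch


def render_tile(
    optics: OpticsModel,
    phantom: Volume,
    tile: Tile,
    dm: DMState | None,
    *,
    mode: str = "cmat",
    ceao_coeffs: np.ndarray | None = None,
    photon_gain: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one tile through the field aberration at the tile center.

    ``mode="cmat"`` applies the tile's own DM vector (``dm`` or
    ``tile.dm_coeffs``); ``mode="ceao"`` applies the FOV-center compensation
    ``ceao_coeffs`` regardless of tile.  ``photon_gain`` > 0 adds Poisson
    shot noise (photons per intensity unit) from ``rng``.
    """
    plane, pitch = _phantom_plane(phantom)
    H, W = plane.shape
    ext_x = W * pitch
    ext_y = H * pitch
    xmin, xmax, ymin, ymax = tile.extent

    if mode == "cmat":
        use_dm = dm if dm is not None else DMState(tile.dm_coeffs)
    elif mode == "ceao":
        if ceao_coeffs is None:
            raise ValueError("ceao mode needs ceao_coeffs")
        use_dm = DMState(np.asarray(ceao_coeffs, dtype=float))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    kernel = _kernel_for_pitch(optics, tile.center, use_dm, pitch)
    pad = kernel.shape[0] // 2

    # phantom array convention: row 0 at maximum y, pixel centers at
    # (i + 0.5)·pitch − extent/2
    col0 = int(round((xmin + ext_x / 2.0) / pitch))
    col1 = int(round((xmax + ext_x / 2.0) / pitch))
    row0 = int(round((ext_y / 2.0 - ymax) / pitch))
    row1 = int(round((ext_y / 2.0 - ymin) / pitch))
    if not (0 <= col0 < col1 <= W and 0 <= row0 < row1 <= H):
        raise ValueError("phantom does not cover the tile extent")

    sub = np.pad(
        plane, pad, mode="edge"
    )[row0 : row1 + 2 * pad, col0 : col1 + 2 * pad]
    img = signal.fftconvolve(sub, kernel, mode="same")[pad:-pad, pad:-pad]
    img = np.clip(img, 0.0, None)
    if photon_gain > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        img = rng.poisson(img * photon_gain).astype(float) / photon_gain
    return img


def scan_frame(
    optics: OpticsModel,
    phantom: Volume,
    plan: ScanPlan,
    *,
    mode: str = "cmat",
    photon_gain: float = 0.0,
    seed: int = 0,
) -> Frame:
    """Acquire a full-FOV frame: render all tiles, mosaic at half-open
    extents, log one excluded transition interval per DM load."""
    plane, pitch = _phantom_plane(phantom)
    H, W = plane.shape
    out = np.zeros_like(plane, dtype=float)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5CA9])
    provenance = []
    excluded = []
    ext_x, ext_y = W * pitch, H * pitch
    for i, tile in enumerate(plan.tiles):
        img = render_tile(
            optics,
            phantom,
            tile,
            None,
            mode=mode,
            ceao_coeffs=plan.ceao_coeffs,
            photon_gain=photon_gain,
            rng=rng,
        )
        xmin, xmax, ymin, ymax = tile.extent
        col0 = int(round((xmin + ext_x / 2.0) / pitch))
        row0 = int(round((ext_y / 2.0 - ymax) / pitch))
        out[row0 : row0 + img.shape[0], col0 : col0 + img.shape[1]] = img
        provenance.append(
            {
                "tile": i,
                "row": tile.row,
                "col": tile.col,
                "point_index": tile.point_index,
                "extent": tile.extent,
            }
        )
        excluded.append(
            {"tile": i, "event": "galvo jump + DM load", "samples_kept": 0}
        )
    return Frame(
        pixels=out, pitch=pitch, provenance=tuple(provenance),
        excluded_log=tuple(excluded),
    )


def scan_roi(
    optics: OpticsModel,
    phantom,
    roi: ROIRequest,
    grid: CorrectionGrid,
    calib: CalibrationTable,
    *,
    fov: FOVSpec | None = None,
    photon_gain: float = 0.0,
    seed: int = 0,
) -> list[Frame]:
    """Targeted ROI sequence with a single nearest-point compensation.

    The DM vector is the calibrated compensation of the correction point
    nearest the ROI centroid, held constant for the whole sequence.  The
    phantom may be a static :class:`Volume` or a :class:`CalciumMovie`
    (rendered through its template decomposition, one blur per component).
    """
    cx, cy = roi.center
    fov = fov if fov is not None else FOVSpec()
    half = fov.diameter / 2.0
    if max(abs(cx) + roi.width / 2.0, abs(cy) + roi.height / 2.0) > half:
        raise ValueError(
            f"ROI at ({cx}, {cy}) of size {roi.width}×{roi.height} µm "
            f"extends outside the ±{half} µm FOV square"
        )
    idx = nearest_point(grid, (cx, cy))
    dm = DMState(np.asarray(calib.vector(idx), dtype=float))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x9201])
    provenance = ({"roi_center": roi.center, "point_index": idx},)

    if isinstance(phantom, CalciumMovie):
        pitch = phantom.spec.pitch
        kernel = _kernel_for_pitch(
            optics, (cx, cy), dm, pitch
        )
        pad = kernel.shape[0] // 2
        blurred = []
        for tpl in phantom.templates:
            sub = np.pad(tpl, pad, mode="edge")
            blurred.append(
                signal.fftconvolve(sub, kernel, mode="same")[pad:-pad, pad:-pad]
            )
        blurred = np.stack(blurred)
        gain = photon_gain if photon_gain > 0 else phantom.spec.photon_gain
        frames = []
        n_frames = roi.frames if roi.frames > 1 else phantom.temporal.shape[0]
        for t in range(n_frames):
            clean = np.tensordot(phantom.temporal[t], blurred, axes=(0, 0))
            clean = np.clip(clean, 0.0, None)
            if gain > 0:
                img = rng.poisson(clean * gain).astype(float) / gain
            else:
                img = clean
            frames.append(
                Frame(pixels=img, pitch=pitch, provenance=provenance,
                      excluded_log=())
            )
        return frames

    # a static phantom is a local scene centered on the ROI: crop in
    # phantom-local coordinates, evaluate optics at the FOV position
    plane, pitch = _phantom_plane(phantom)
    tile = Tile(
        row=0, col=0, center=(cx, cy),
        extent=(-roi.width / 2, roi.width / 2,
                -roi.height / 2, roi.height / 2),
        point_index=idx, dm_coeffs=dm.coeffs,
    )
    frames = []
    for _t in range(roi.frames):
        img = render_tile(
            optics, phantom, tile, dm, photon_gain=photon_gain, rng=rng
        )
        frames.append(
            Frame(pixels=img, pitch=pitch, provenance=provenance,
                  excluded_log=())
        )
    return frames


def save_plan(plan: ScanPlan, path) -> None:
    """Tab-separated plan: tile, row, col, center, extent, point index."""
    from pathlib import Path

    lines = [
        "# cmatsim scan plan",
        f"# n\t{plan.n}",
        f"# tile_size_um\t{plan.tile_size}",
        "# tile\trow\tcol\tcx_um\tcy_um\txmin\txmax\tymin\tymax\tpoint_index",
    ]
    for i, t in enumerate(plan.tiles):
        lines.append(
            f"{i}\t{t.row}\t{t.col}\t{t.center[0]:.9g}\t{t.center[1]:.9g}\t"
            + "\t".join(f"{v:.9g}" for v in t.extent)
            + f"\t{t.point_index}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
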