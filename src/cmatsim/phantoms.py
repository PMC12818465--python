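"""Seeded synthetic samples: beads, pollen-like calibration targets, neuron
scenes, and GCaMP-like calcium movies.

Every generator is a pure function of its spec (which carries the seed), so
identical specs produce bit-identical phantoms.  Ground truth (bead centers,
ROI masks, spike times) is always emitted alongside the rendered intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BeadFieldSpec",
    "BeadField",
    "NeuronSceneSpec",
    "NeuronScene",
    "CalciumMovieSpec",
    "CalciumMovie",
    "make_beads",
    "make_pollen",
    "make_neuron_scene",
    "make_calcium_movie",
    "save_volume",
]


@dataclass(frozen=True)
class Volume:
    """Intensity volume on an x×y×z grid; ``data`` shape is (nz, ny, nx)."""

    data: np.ndarray
    lateral_pitch: float
    axial_pitch: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("volume intensities must be finite and non-negative")


def save_volume(vol: Volume, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), vol.data.astype(np.float32))


# ---------------------------------------------------------------------------
# fluorescent beads

@dataclass(frozen=True)
class BeadFieldSpec:
    """Field of fluorescent beads in a rectangular volume.

    Bead diameters of 0.5 µm (resolution targets) and 10 µm (brightness
    targets) match the standard characterization samples.  ``amplitude`` is
    the integrated fluorescence per bead (sum over voxels × voxel volume).
    Bead centers are drawn uniformly, rejected until all pairs are at least
    two diameters apart and every bead lies fully inside the volume.
    """

    bead_diameter: float = 0.5
    count: int = 6
    amplitude: float = 1.0
    lateral_size: float = 20.0
    axial_size: float = 12.0
    lateral_pitch: float = 0.0542
    axial_pitch: float = 0.27
    seed: int = 0
    min_separation: float | None = None  # default 2 × diameter

    @property
    def separation(self) -> float:
        return (
            self.min_separation
            if self.min_separation is not None
            else 2.0 * self.bead_diameter
        )


@dataclass(frozen=True)
class BeadField:
    volume: Volume
    centers: np.ndarray  # (count, 3) µm as (x, y, z)
    spec: BeadFieldSpec


def _draw_centers(spec: BeadFieldSpec, rng: np.random.Generator) -> np.ndarray:
    r = spec.bead_diameter / 2.0
    lo = np.array([r, r, r])
    hi = np.array(
        [spec.lateral_size - r, spec.lateral_size - r, spec.axial_size - r]
    )
    if np.any(hi <= lo):
        raise ValueError("bead does not fit inside the volume")
    centers: list[np.ndarray] = []
    for _ in range(spec.count):
        for _attempt in range(10_000):
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - o) >= spec.separation for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError(
                f"could not place {spec.count} beads with separation "
                f"{spec.separation} µm after 10000 attempts"
            )
    return np.array(centers) if centers else np.zeros((0, 3))


def make_beads(spec: BeadFieldSpec) -> BeadField:
    """Rasterize a seeded bead field with anti-aliased sphere edges.

    Each bead's voxel values are an occupancy profile normalized so the
    integrated intensity (Σ value × voxel volume) equals ``amplitude``; a
    bead much smaller than the voxel pitch degenerates to a single-voxel
    impulse carrying the full integrated amplitude.
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0xBEAD])
    nx = max(int(round(spec.lateral_size / spec.lateral_pitch)), 1)
    nz = max(int(round(spec.axial_size / spec.axial_pitch)), 1)
    data = np.zeros((nz, nx, nx))
    voxvol = spec.lateral_pitch**2 * spec.axial_pitch
    centers = _draw_centers(spec, rng)
    xs = (np.arange(nx) + 0.5) * spec.lateral_pitch
    zs = (np.arange(nz) + 0.5) * spec.axial_pitch
    r_b = spec.bead_diameter / 2.0
    w = spec.lateral_pitch  # anti-aliasing edge width
    for cx, cy, cz in centers:
        # local window around the bead
        ix = np.flatnonzero(np.abs(xs - cx) <= r_b + 2 * w)
        iy = np.flatnonzero(np.abs(xs - cy) <= r_b + 2 * w)
        iz = np.flatnonzero(np.abs(zs - cz) <= r_b + 2 * max(w, spec.axial_pitch))
        if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
            ix = np.array([np.argmin(np.abs(xs - cx))])
            iy = np.array([np.argmin(np.abs(xs - cy))])
            iz = np.array([np.argmin(np.abs(zs - cz))])
        Z, Y, X = np.meshgrid(zs[iz], xs[iy], xs[ix], indexing="ij")
        d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        occ = np.clip(0.5 - (d - r_b) / w, 0.0, 1.0)
        total = occ.sum() * voxvol
        if total <= 0.0:
            # sub-voxel bead: deposit everything in the nearest voxel
            kz = int(np.argmin(np.abs(zs - cz)))
            ky = int(np.argmin(np.abs(xs - cy)))
            kx = int(np.argmin(np.abs(xs - cx)))
            data[kz, ky, kx] += spec.amplitude / voxvol
            continue
        block = occ * (spec.amplitude / total)
        data[np.ix_(iz, iy, ix)] += block
    return BeadField(
        volume=Volume(data, spec.lateral_pitch, spec.axial_pitch),
        centers=centers,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# pollen-like calibration target

def make_pollen(
    *,
    radius: float = 10.0,
    n_spikes: int = 14,
    spike_fraction: float = 0.15,
    pitch: float = 0.25,
    amplitude: float = 1.0,
    seed: int = 0,
) -> Volume:
    """Spiky-ball 2-D phantom emulating a pollen grain calibration sample.

    Pollen grains have bright, structured rims; the image is a disk whose rim
    radius is modulated sinusoidally (``n_spikes`` lobes) with extra weight on
    the shell.  Returned as a single-plane Volume.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x90117])
    half = radius * (1.0 + spike_fraction) + 2.0 * pitch
    n = int(math.ceil(2 * half / pitch))
    c = (np.arange(n) + 0.5) * pitch - half
    X, Y = np.meshgrid(c, c)
    r = np.hypot(X, Y)
    th = np.arctan2(Y, X)
    phase = rng.uniform(0, 2 * np.pi)
    edge = radius * (1.0 + spike_fraction * np.cos(n_spikes * th + phase))
    body = np.clip(0.5 - (r - edge) / pitch, 0.0, 1.0)
    shell = np.exp(-((r - edge) ** 2) / (2.0 * (0.08 * radius) ** 2))
    img = amplitude * (0.4 * body + 0.6 * shell * body.clip(max=1.0))
    return Volume(img[None, :, :], pitch, 0.0)


# ---------------------------------------------------------------------------
# neuron scene

@dataclass(frozen=True)
class NeuronSceneSpec:
    """Two-dimensional neural tissue scene: somata, dendrites with spines,
    and diffuse neuropil background, with ground-truth masks."""

    size: float = 100.0          # µm, square field
    pitch: float = 0.5           # µm / pixel
    n_somata: int = 8
    soma_radius: tuple[float, float] = (4.0, 7.0)
    soma_amplitude: tuple[float, float] = (0.8, 1.2)
    n_dendrites: int = 6
    dendrite_width: float = 1.0
    dendrite_amplitude: float = 0.5
    spines_per_dendrite: int = 5
    spine_radius: float = 0.6
    neuropil_level: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class NeuronScene:
    volume: Volume              # single z-plane
    soma_masks: list            # list of boolean (H, W) masks
    dendrite_mask: np.ndarray   # boolean (H, W)
    neuropil_mask: np.ndarray   # boolean (H, W): everything unlabeled
    soma_centers: np.ndarray    # (n, 2) µm


def _soft_disk(X, Y, cx, cy, r, pitch):
    d = np.hypot(X - cx, Y - cy)
    return np.clip(0.5 - (d - r) / pitch, 0.0, 1.0)


def make_neuron_scene(spec: NeuronSceneSpec) -> NeuronScene:
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x5CE9E])
    n = int(round(spec.size / spec.pitch))
    c = (np.arange(n) + 0.5) * spec.pitch - spec.size / 2.0
    X, Y = np.meshgrid(c, c)
    img = np.zeros((n, n))

    # neuropil: smooth low background everywhere
    noise = rng.standard_normal((n, n))
    smooth = ndimage.gaussian_filter(noise, sigma=4.0 / spec.pitch)
    smooth = smooth / (np.abs(smooth).max() + 1e-12)
    img += spec.neuropil_level * (1.0 + 0.3 * smooth)

    # dendrites: straight segments with small spine bumps
    dmask = np.zeros((n, n), dtype=bool)
    for _ in range(spec.n_dendrites):
        p0 = rng.uniform(-spec.size / 2, spec.size / 2, 2)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.4, 0.9) * spec.size
        p1 = p0 + length * np.array([np.cos(ang), np.sin(ang)])
        seg = p1 - p0
        L2 = seg @ seg
        t = np.clip(((X - p0[0]) * seg[0] + (Y - p0[1]) * seg[1]) / L2, 0, 1)
        dx = X - (p0[0] + t * seg[0])
        dy = Y - (p0[1] + t * seg[1])
        d = np.hypot(dx, dy)
        stroke = np.clip(0.5 - (d - spec.dendrite_width / 2) / spec.pitch, 0, 1)
        img += spec.dendrite_amplitude * stroke
        dmask |= stroke > 0.5
        for _s in range(spec.spines_per_dendrite):
            ts = rng.uniform(0.1, 0.9)
            side = rng.choice([-1.0, 1.0])
            normal = np.array([-seg[1], seg[0]]) / math.sqrt(L2)
            sp = p0 + ts * seg + side * normal * (
                spec.dendrite_width / 2 + spec.spine_radius
            )
            bump = _soft_disk(X, Y, sp[0], sp[1], spec.spine_radius, spec.pitch)
            img += spec.dendrite_amplitude * 1.2 * bump
            dmask |= bump > 0.5

    # somata: non-overlapping bright disks
    soma_masks: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for _ in range(spec.n_somata):
        for _attempt in range(10_000):
            r = rng.uniform(*spec.soma_radius)
            margin = r + spec.pitch
            cx, cy = rng.uniform(-spec.size / 2 + margin, spec.size / 2 - margin, 2)
            if all(
                math.hypot(cx - p[0], cy - p[1]) >= r + rr + 1.0
                for p, rr in zip(centers, radii)
            ):
                break
        else:
            raise ValueError("could not place somata without overlap")
        amp = rng.uniform(*spec.soma_amplitude)
        disk = _soft_disk(X, Y, cx, cy, r, spec.pitch)
        img += amp * disk
        soma_masks.append(disk > 0.5)
        centers.append(np.array([cx, cy]))
        radii.append(r)

    labeled = dmask.copy()
    for m in soma_masks:
        labeled |= m
    return NeuronScene(
        volume=Volume(img[None, :, :], spec.pitch, 0.0),
        soma_masks=soma_masks,
        dendrite_mask=dmask,
        neuropil_mask=~labeled,
        soma_centers=np.array(centers) if centers else np.zeros((0, 2)),
    )


# ---------------------------------------------------------------------------
# calcium movie

@dataclass(frozen=True)
class CalciumMovieSpec:
    """GCaMP-like functional movie with known spikes, traces and masks.

    Acquisition defaults mirror the ROI recordings of the reference system:
    15 Hz for 300 s.  Each cell fires a Poisson spike train convolved with a
    single-exponential calcium kernel (GCaMP6s-like decay, τ = 1.5 s).
    Cell pixels carry the cell trace plus a ``neuropil_fraction`` of the
    shared neuropil signal; photon shot noise is Poisson with gain
    ``photon_gain`` photons per intensity unit (0 disables noise).
    """

    n_cells: int = 5
    frame_rate: float = 15.0
    duration: float = 300.0
    spike_rate: float = 0.2
    decay_tau: float = 1.5
    spike_amplitude: float = 0.25   # fractional ΔF per spike
    neuropil_fraction: float = 0.3
    baseline: float = 20.0
    neuropil_baseline: float = 10.0
    photon_gain: float = 0.5
    size_px: int = 64
    pitch: float = 0.5
    cell_radius: float = 3.5
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


@dataclass(frozen=True)
class CalciumMovie:
    """Rendered movie plus its linear decomposition and ground truth.

    ``frames`` (T, H, W) is the noisy movie.  ``templates`` (k, H, W) and
    ``temporal`` (T, k) give the clean movie as temporal @ templates — the
    renderer uses this to apply one optical blur per template instead of per
    frame.  Component 0 is the neuropil background; components 1..n are cells.
    """

    frames: np.ndarray
    templates: np.ndarray
    temporal: np.ndarray
    cell_masks: list
    neuropil_masks: list
    cell_traces: np.ndarray      # (T, n_cells) true somatic fluorescence
    neuropil_trace: np.ndarray   # (T,)
    spike_times: list            # per cell, spike times in s
    spec: CalciumMovieSpec

    @property
    def frame_rate(self) -> float:
        return self.spec.frame_rate


def _exp_kernel(tau: float, dt: float, length: int) -> np.ndarray:
    t = np.arange(length) * dt
    return np.exp(-t / tau)


def make_calcium_movie(spec: CalciumMovieSpec) -> CalciumMovie:
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0xCA1C])
    T = spec.n_frames
    n = spec.size_px
    dt = 1.0 / spec.frame_rate
    c = (np.arange(n) + 0.5) * spec.pitch - n * spec.pitch / 2.0
    X, Y = np.meshgrid(c, c)

    # cell geometry: non-overlapping soft disks
    centers: list[np.ndarray] = []
    for _ in range(spec.n_cells):
        for _attempt in range(10_000):
            margin = spec.cell_radius + 2 * spec.pitch
            half = n * spec.pitch / 2.0
            cx, cy = rng.uniform(-half + margin, half - margin, 2)
            if all(
                math.hypot(cx - p[0], cy - p[1]) >= 2.2 * spec.cell_radius
                for p in centers
            ):
                centers.append(np.array([cx, cy]))
                break
        else:
            raise ValueError("could not place cells without overlap")

    # component 0 is the neuropil spatial map: full strength outside cells,
    # attenuated to `neuropil_fraction` under cell somata, so a cell-mask
    # mean reads F_cell + fraction·F_neuropil (the contamination model the
    # 0.7-subtraction is meant to undo)
    neuropil_map = np.ones((n, n))
    cell_templates = []
    cell_masks, neuropil_masks = [], []
    for cx, cy in centers:
        disk = _soft_disk(X, Y, cx, cy, spec.cell_radius, spec.pitch)
        cell_templates.append(disk)
        cell_masks.append(disk > 0.5)
        neuropil_map -= (1.0 - spec.neuropil_fraction) * disk
        d = np.hypot(X - cx, Y - cy)
        neuropil_masks.append(
            (d > spec.cell_radius + 2 * spec.pitch)
            & (d < spec.cell_radius + 6 * spec.pitch)
        )
    templates = np.stack([neuropil_map] + cell_templates)

    # temporal components
    kernel = _exp_kernel(spec.decay_tau, dt, min(T, int(10 * spec.decay_tau / dt) + 1))
    spike_times: list[np.ndarray] = []
    cell_traces = np.zeros((T, spec.n_cells))
    for i in range(spec.n_cells):
        counts = rng.poisson(spec.spike_rate * dt, size=T)
        idx = np.repeat(np.arange(T), counts)
        spike_times.append(idx * dt)
        train = counts.astype(float)
        dff_true = np.convolve(train, kernel)[:T] * spec.spike_amplitude
        cell_traces[:, i] = spec.baseline * (1.0 + dff_true)
    neuropil_trace = np.full(T, spec.neuropil_baseline)
    if spec.n_cells > 0:
        # neuropil fluctuates with pooled population activity
        pooled = (cell_traces / spec.baseline - 1.0).mean(axis=1)
        neuropil_trace = spec.neuropil_baseline * (1.0 + 0.5 * pooled)

    temporal = np.zeros((T, spec.n_cells + 1))
    temporal[:, 0] = neuropil_trace
    temporal[:, 1:] = cell_traces
    clean = np.tensordot(temporal, templates, axes=(1, 0))

    if spec.photon_gain > 0:
        frames = rng.poisson(
            np.clip(clean, 0, None) * spec.photon_gain
        ).astype(np.float32) / spec.photon_gain
    else:
        frames = clean.astype(np.float32)

    return CalciumMovie(
        frames=frames,
        templates=templates,
        temporal=temporal,
        cell_masks=cell_masks,
        neuropil_masks=neuropil_masks,
        cell_traces=cell_traces,
        neuropil_trace=neuropil_trace,
        spike_times=spike_times,
        spec=spec,
    )
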