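"""Zernike wavefronts and scalar Fourier-optics two-photon PSFs.

Wavefront shapes are parameterized as Noll-indexed, unit-RMS-normalized
Zernike polynomials over the unit-disk pupil.  The two-photon effective PSF
is computed with scalar Fourier optics: the focal-plane field is the far-field
transform of the (aberrated) pupil function, the excitation intensity is its
squared modulus, and two-photon fluorescence generation goes as intensity
squared.  Defocus is applied as the exact high-NA phase
k·z·√(n² − NA²ρ²) rather than the paraxial ρ² term, which matters at NA 0.5.

Units: wavefront coefficients in waves (λ); lengths in µm; phases in radians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ZernikeBasis",
    "PupilSpec",
    "DMState",
    "AberrationField",
    "PSF3D",
    "noll_to_nm",
    "zernike",
    "wavefront_map",
    "pupil_grid",
    "focal_field",
    "psf_2p",
    "truth_coeffs",
    "residual",
    "clip_stroke",
    "save_psf",
]


# ---------------------------------------------------------------------------
# Zernike basis (Noll indexing, unit RMS over the unit disk)

def noll_to_nm(j: int) -> tuple[int, int]:
    """Radial degree n and azimuthal frequency m for Noll index j ≥ 1.

    Noll's convention: even j carry cos(mθ) (m > 0), odd j carry sin(mθ)
    (m < 0); m = 0 terms are purely radial.
    """
    if j < 1:
        raise ValueError(f"Noll index must be ≥ 1; got {j}")
    n = 0
    k = j - 1
    while k > n:
        n += 1
        k -= n
    m = (-1) ** j * ((n % 2) + 2 * ((k + ((n + 1) % 2)) // 2))
    return n, m


@lru_cache(maxsize=512)
def _radial_coeffs(n: int, m: int) -> tuple[tuple[int, float], ...]:
    m = abs(m)
    terms = []
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)) / (
            math.factorial(s)
            * math.factorial((n + m) // 2 - s)
            * math.factorial((n - m) // 2 - s)
        )
        terms.append((n - 2 * s, float(c)))
    return tuple(terms)


def zernike(j: int, rho, theta):
    """Noll-indexed, unit-RMS Zernike polynomial Z_j(ρ, θ).

    ρ must lie in [0, 1] (outside the pupil is an error); arrays broadcast.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho > 1.0 + 1e-12) or np.any(rho < 0.0):
        raise ValueError("rho must lie within the unit pupil [0, 1]")
    n, m = noll_to_nm(j)
    R = np.zeros(np.broadcast(rho, theta).shape)
    for power, c in _radial_coeffs(n, m):
        R = R + c * rho**power
    norm = math.sqrt(n + 1.0) if m == 0 else math.sqrt(2.0 * (n + 1.0))
    if m > 0:
        return norm * R * np.cos(m * theta)
    if m < 0:
        return norm * R * np.sin(-m * theta)
    return norm * R


@dataclass(frozen=True)
class ZernikeBasis:
    """First ``n_terms`` Noll Zernike modes (the reference system uses 200;
    desk-scale simulations default to 15)."""

    n_terms: int = 15

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("need at least one Zernike term")

    def evaluate(self, j: int, rho, theta):
        if not (1 <= j <= self.n_terms):
            raise ValueError(f"Noll index {j} outside basis 1..{self.n_terms}")
        return zernike(j, rho, theta)

    def stack(self, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """(n_terms, ...) array of all basis values at the given pupil points."""
        return np.stack([zernike(j, rho, theta) for j in range(1, self.n_terms + 1)])


# ---------------------------------------------------------------------------
# pupil / PSF

@dataclass(frozen=True)
class PupilSpec:
    """Objective pupil and sampling for the far-field transform.

    The reference objective is a water-immersion NA 0.5 design at
    920 nm excitation.  ``grid_size`` samples span the pupil diameter;
    the FFT is zero-padded by ``pad_factor``, giving a focal-plane pixel of
    λ/(2·NA·pad_factor) µm.
    """

    na: float = 0.5
    wavelength: float = 0.920
    refractive_index: float = 1.33
    grid_size: int = 128
    pad_factor: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.na < self.refractive_index):
            raise ValueError("need 0 < NA < refractive index")
        if self.grid_size < 64:
            raise ValueError("pupil grid_size must be ≥ 64")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be ≥ 2")

    @property
    def focal_pitch(self) -> float:
        """Lateral focal-plane sample pitch in µm."""
        return self.wavelength / (2.0 * self.na * self.pad_factor)


def pupil_grid(pupil: PupilSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, theta, mask) on the pupil sampling grid; mask is ρ ≤ 1."""
    c = np.linspace(-1.0, 1.0, pupil.grid_size, endpoint=False)
    c = c + 1.0 / pupil.grid_size  # symmetric about 0
    U, V = np.meshgrid(c, c)
    rho = np.hypot(U, V)
    theta = np.arctan2(V, U)
    return rho, theta, rho <= 1.0


def wavefront_map(coeffs, pupil: PupilSpec) -> np.ndarray:
    """Pupil phase map (radians) of a coefficient vector in waves.

    phase(u, v) = 2π Σ_j c_j Z_j(u, v) inside the unit disk, 0 outside.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    rho, theta, mask = pupil_grid(pupil)
    phase = np.zeros_like(rho)
    rr, tt = rho[mask], theta[mask]
    acc = np.zeros(rr.shape)
    for j, c in enumerate(coeffs, start=1):
        if c != 0.0:
            acc += c * zernike(j, rr, tt)
    phase[mask] = 2.0 * math.pi * acc
    return phase


def _defocus_phase(pupil: PupilSpec, z: float, rho: np.ndarray) -> np.ndarray:
    """Exact high-NA defocus phase at axial position z (µm)."""
    k = 2.0 * math.pi / pupil.wavelength
    n = pupil.refractive_index
    kz = np.sqrt(np.maximum(n * n - (pupil.na * rho) ** 2, 0.0))
    return k * z * (kz - n)  # constant −n only removes a global phase


def focal_field(pupil: PupilSpec, phase: np.ndarray, z: float = 0.0) -> np.ndarray:
    """Complex focal-plane field h(x, y; z): far-field transform of the pupil.

    Low-level routine without normalization or sampling guards; ``phase`` is
    the aberration phase map (radians) on the pupil grid.
    """
    rho, _, mask = pupil_grid(pupil)
    total = phase + _defocus_phase(pupil, z, rho)
    pup = np.where(mask, np.exp(1j * total), 0.0)
    m = pupil.grid_size * pupil.pad_factor
    return np.fft.fftshift(np.fft.fft2(pup, s=(m, m)))


@dataclass(frozen=True)
class PSF3D:
    """Two-photon effective PSF sampled on a lateral×lateral×axial grid.

    ``data`` has shape (nz, ny, nx); intensities are normalized so that the
    unaberrated PSF peaks at 1.0.
    """

    data: np.ndarray
    lateral_pitch: float
    axial_pitch: float
    z_planes: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("PSF values must be finite and non-negative")


def psf_2p(
    pupil: PupilSpec,
    phase: np.ndarray,
    z_planes,
    *,
    crop: int | None = None,
) -> PSF3D:
    """Two-photon effective PSF = (|h|²)² through the aberrated pupil.

    ``z_planes`` are axial positions in µm (the bead-characterization stacks
    use a 0.27 µm step).  Normalization: the unaberrated PSF at z=0 has unit
    peak.  ``crop`` keeps only the central crop×crop lateral window.
    Raises if the focal sampling is too coarse (< 4 samples across the
    unaberrated lateral FWHM of the two-photon PSF).
    """
    z_planes = np.asarray(z_planes, dtype=float)
    if not np.all(np.isfinite(z_planes)):
        raise ValueError("z_planes must be finite")
    # unaberrated two-photon lateral FWHM ≈ (0.51 λ / NA) / √2
    fwhm_est = 0.51 * pupil.wavelength / pupil.na / math.sqrt(2.0)
    if fwhm_est / pupil.focal_pitch < 4.0:
        raise ValueError(
            f"focal pitch {pupil.focal_pitch:.3f} µm too coarse to sample the "
            f"~{fwhm_est:.2f} µm two-photon focal spot (need ≥ 4 samples; "
            f"increase pad_factor)"
        )
    _, _, mask = pupil_grid(pupil)
    norm = float(mask.sum()) ** 4  # peak |h|⁴ of the unaberrated pupil at z=0
    planes = []
    for z in z_planes:
        h = focal_field(pupil, phase, z)
        I = (h.real**2 + h.imag**2)
        planes.append((I * I) / norm)
    data = np.stack(planes)
    if crop is not None:
        m = data.shape[-1]
        lo = (m - crop) // 2
        data = data[:, lo : lo + crop, lo : lo + crop]
    dz = float(np.diff(z_planes).mean()) if len(z_planes) > 1 else 0.0
    return PSF3D(
        data=data,
        lateral_pitch=pupil.focal_pitch,
        axial_pitch=abs(dz),
        z_planes=z_planes,
    )


# ---------------------------------------------------------------------------
# deformable mirror state

@dataclass(frozen=True)
class DMState:
    """Modal deformable-mirror state: Zernike coefficients in waves.

    ``stroke_limit`` is the peak wavefront amplitude the mirror can produce
    (±30 λ for the reference device).
    """

    coeffs: np.ndarray
    stroke_limit: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))


def residual(truth, dm: DMState) -> np.ndarray:
    """Residual aberration: truth + DM coefficients (zero-padded to match).

    The DM adds to the sample-path phase, so perfect correction is
    dm.coeffs = −truth.
    """
    t = np.asarray(truth, dtype=float)
    d = dm.coeffs
    n = max(len(t), len(d))
    out = np.zeros(n)
    out[: len(t)] += t
    out[: len(d)] += d
    return out


def _surface_max(coeffs: np.ndarray, grid_size: int = 128) -> float:
    """Max |wavefront surface| in waves over the pupil disk."""
    c = np.linspace(-1.0, 1.0, grid_size)
    U, V = np.meshgrid(c, c)
    rho, theta = np.hypot(U, V), np.arctan2(V, U)
    mask = rho <= 1.0
    w = np.zeros(mask.sum())
    rr, tt = rho[mask], theta[mask]
    for j, cj in enumerate(coeffs, start=1):
        if cj != 0.0:
            w += cj * zernike(j, rr, tt)
    return float(np.max(np.abs(w))) if w.size else 0.0


def clip_stroke(dm: DMState, *, grid_size: int = 128) -> DMState:
    """Scale the whole coefficient vector into the stroke range.

    If the synthesized wavefront surface exceeds ``stroke_limit`` waves in
    amplitude, the entire vector is scaled by limit/max — preserving the
    corrected wavefront's shape — and a warning is logged.
    """
    peak = _surface_max(dm.coeffs, grid_size)
    if peak <= dm.stroke_limit or peak == 0.0:
        return dm
    scale = dm.stroke_limit / peak
    logger.warning(
        "DM stroke limit exceeded (peak %.2f λ > %.1f λ); scaling coefficients by %.3f",
        peak, dm.stroke_limit, scale,
    )
    return replace(dm, coeffs=dm.coeffs * scale)


# ---------------------------------------------------------------------------
# ground-truth field-dependent aberrations

@dataclass(frozen=True)
class AberrationField:
    """Field-varying system aberrations the calibration must discover.

    The deterministic part models the classic off-axis growth of a wide-field
    objective — coma linear in field position, astigmatism and spherical
    growing quadratically — each vanishing at the FOV center (the
    best-corrected field point).  ``*_edge`` amplitudes are the coefficient
    magnitudes (waves) reached at ``fov_radius``; the defaults give an edge
    residual of ≈0.19 λ RMS beyond the center correction, the scale at which
    a center-only correction loses most of its two-photon signal and
    measurably broadens the PSF at the field edge while remaining a
    coherent (non-speckled) focus.  A band-limited seeded random component
    (sum of long-period plane waves, per-term amplitude ``random_amplitude``)
    adds realistic irregularity.
    """

    fov_radius: float = 4000.0
    astig_edge: float = 0.12
    coma_edge: float = 0.12
    spherical_edge: float = 0.06
    random_amplitude: float = 0.03
    n_terms: int = 15
    seed: int = 0
    _random_waves: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_terms < 11:
            raise ValueError("field model needs n_terms ≥ 11 (through spherical)")
        rng = np.random.default_rng([int(self.seed) & 0x7FFFFFFF, 0x0AB])
        waves = []
        # 3 plane waves per term, periods ≥ ~2.7 mm so the field is smooth on
        # the correction-point pitch
        for _ in range(4, self.n_terms + 1):
            freq = rng.uniform(0.5, 1.5, size=(3, 1)) / (3.0 * self.fov_radius)
            direc = rng.normal(size=(3, 2))
            direc /= np.linalg.norm(direc, axis=1, keepdims=True)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            weights = rng.normal(size=3) / math.sqrt(3.0)
            waves.append((freq * direc, phases, weights))
        object.__setattr__(self, "_random_waves", tuple(waves))


def truth_coeffs(fld: AberrationField, position) -> np.ndarray:
    """Ground-truth Zernike coefficient vector (waves) at an FOV position.

    Deterministic given (field, position); continuous in position; raises if
    the position lies outside the FOV radius.
    """
    p = np.asarray(position, dtype=float)
    x, y = float(p[0]), float(p[1])
    # valid over the scanned FOV square (the circular field's bounding box,
    # whose corners the tiled scan also visits)
    if max(abs(x), abs(y)) > fld.fov_radius * (1.0 + 1e-9):
        raise ValueError(
            f"position ({x}, {y}) outside the ±{fld.fov_radius} µm FOV square"
        )
    R = fld.fov_radius
    xr, yr = x / R, y / R
    c = np.zeros(fld.n_terms)
    # Noll: j5/j6 astigmatism (sin/cos 2θ), j7/j8 coma (sin/cos θ), j11 spherical
    c[4] = fld.astig_edge * 2.0 * xr * yr            # r² sin 2φ
    c[5] = fld.astig_edge * (xr * xr - yr * yr)      # r² cos 2φ
    c[6] = fld.coma_edge * yr                        # r sin φ
    c[7] = fld.coma_edge * xr                        # r cos φ
    c[10] = fld.spherical_edge * (xr * xr + yr * yr)  # r²
    if fld.random_amplitude > 0.0:
        for idx, (kvecs, phases, weights) in enumerate(fld._random_waves):
            j = idx + 4  # Noll index; vector slot j-1
            val = np.sum(
                weights * np.cos(2.0 * np.pi * (kvecs @ [x, y]) + phases)
            )
            c[j - 1] += fld.random_amplitude * float(val)
    return c


# ---------------------------------------------------------------------------
# PSF export

def save_psf(psf: PSF3D, path) -> None:
    """Write the PSF as a 32-bit multi-page TIFF plus a text sidecar header."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, psf.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".txt")
    sidecar.write_text(
        "# cmatsim PSF3D\n"
        f"lateral_pitch_um\t{psf.lateral_pitch}\n"
        f"axial_pitch_um\t{psf.axial_pitch}\n"
        f"n_planes\t{psf.data.shape[0]}\n"
        "normalization\tunaberrated peak = 1\n"
    )
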