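"""Evaluation statistics: bead-resolution FWHM, intensity profiles, ΔF/F with
neuropil subtraction, calcium SNR, and rank-based group comparisons.

Conventions (stated once, used throughout): percentiles are computed with
linear interpolation between order statistics (rank p·(n−1), 0-based);
standard deviations use the n−1 denominator; FWHM of a Gaussian is
2√(2 ln 2)·σ.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

from .phantoms import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "GAUSS_FWHM_FACTOR",
    "BeadMeasurement",
    "TraceSet",
    "SNRReport",
    "fit_fwhm",
    "line_profile",
    "dff",
    "snr",
    "compare_groups",
    "extract_traces",
    "image_extent_um",
]

#: FWHM of a unit-σ Gaussian.
GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def image_extent_um(n_pixels: int, pixel_pitch: float) -> float:
    """Physical extent of an image axis: n_pixels × pitch (µm).

    E.g. the 1200-pixel bead stacks at 0.0542 µm/pixel span 65 µm (rounded).
    """
    return n_pixels * pixel_pitch


# ---------------------------------------------------------------------------
# bead FWHM

@dataclass(frozen=True)
class BeadMeasurement:
    """Per-bead lateral/axial FWHM (µm) and the per-site mean ± SD summary.

    Beads whose fit failed (non-convergence, or FWHM under 2 pixels) are
    flagged in ``excluded`` and left out of the summary.
    """

    lateral_fwhm: np.ndarray
    axial_fwhm: np.ndarray
    excluded: np.ndarray
    lateral_mean: float
    lateral_sd: float
    axial_mean: float
    axial_sd: float


def _gauss(x, amp, mu, sigma, offset):
    return offset + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_1d(profile: np.ndarray, pitch: float) -> float | None:
    """Gaussian-fit FWHM (µm) of a 1-D intensity profile, or None."""
    x = np.arange(len(profile)) * pitch
    offset = float(profile.min())
    amp = float(profile.max() - offset)
    if amp <= 0:
        return None
    mu = float(x[int(np.argmax(profile))])
    # moment-based σ start
    w = np.clip(profile - offset, 0, None)
    sigma0 = math.sqrt(max(np.sum(w * (x - mu) ** 2) / max(np.sum(w), 1e-12), 1e-6))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _gauss, x, profile, p0=[amp, mu, sigma0, offset], maxfev=5000
            )
    except (RuntimeError, ValueError):
        return None
    fwhm = GAUSS_FWHM_FACTOR * abs(popt[2])
    if not np.isfinite(fwhm) or fwhm < 2.0 * pitch:
        return None
    return float(fwhm)


def fit_fwhm(stack: Volume, centers, *, window_um: float = 3.0,
             axial_window_um: float | None = None) -> BeadMeasurement:
    """Lateral and axial FWHM of isolated beads by 1-D Gaussian fitting.

    For each bead, the intensity maximum is located inside a window around
    the nominal center; 1-D profiles along the two lateral lines (x and y)
    and the axial (z) line through the maximum are fit with a Gaussian
    (amplitude, center, σ, offset), and FWHM = 2√(2 ln 2)·σ.  The lateral
    FWHM is the mean of the x- and y-line values, so an astigmatically
    elongated focus is not measured only along its sharp axis.  Centers are
    (x, y, z) µm in the volume frame (pixel centers at (i+0.5)·pitch).
    """
    data = stack.data
    nz, ny, nx = data.shape
    lp, ap = stack.lateral_pitch, stack.axial_pitch
    wl = int(round(window_um / lp))
    wa = int(round((axial_window_um or max(window_um * 4, 8.0)) / max(ap, 1e-9)))
    lat, axi, excl = [], [], []
    for cx, cy, cz in np.atleast_2d(centers):
        ix = int(cx / lp)
        iy = int(cy / lp)
        iz = int(cz / ap) if ap > 0 else 0
        zlo, zhi = max(iz - wa, 0), min(iz + wa + 1, nz)
        ylo, yhi = max(iy - wl, 0), min(iy + wl + 1, ny)
        xlo, xhi = max(ix - wl, 0), min(ix + wl + 1, nx)
        block = data[zlo:zhi, ylo:yhi, xlo:xhi]
        k = np.unravel_index(int(np.argmax(block)), block.shape)
        pz, py, px = zlo + k[0], ylo + k[1], xlo + k[2]
        f_x = _fit_1d(data[pz, py, xlo:xhi], lp)
        f_y = _fit_1d(data[pz, ylo:yhi, px], lp)
        f_lat = None if (f_x is None or f_y is None) else 0.5 * (f_x + f_y)
        f_axi = _fit_1d(data[zlo:zhi, py, px], ap) if nz > 1 else None
        bad = f_lat is None or (nz > 1 and f_axi is None)
        if bad:
            logger.warning(
                "bead at (%.2f, %.2f, %.2f) µm excluded from FWHM summary "
                "(fit failed or FWHM < 2 px)", cx, cy, cz,
            )
        excl.append(bad)
        lat.append(np.nan if f_lat is None else f_lat)
        axi.append(np.nan if f_axi is None else (f_axi or np.nan))
    lat = np.asarray(lat)
    axi = np.asarray(axi)
    excl = np.asarray(excl, dtype=bool)
    ok = ~excl
    def _mean_sd(v):
        v = v[ok & np.isfinite(v)]
        if len(v) == 0:
            return math.nan, math.nan
        return float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    lm, ls = _mean_sd(lat)
    am, asd = _mean_sd(axi)
    return BeadMeasurement(
        lateral_fwhm=lat, axial_fwhm=axi, excluded=excl,
        lateral_mean=lm, lateral_sd=ls, axial_mean=am, axial_sd=asd,
    )


# ---------------------------------------------------------------------------
# line profiles

def line_profile(image: np.ndarray, p0, p1, *, normalize: bool = False) -> np.ndarray:
    """Bilinear-interpolated profile from p0 to p1 at unit-pixel steps.

    Endpoints are (row, col) pixel coordinates.  ``normalize`` rescales the
    profile min-max to [0, 1].
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0.0:
        raise ValueError("degenerate profile: endpoints coincide")
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError(f"endpoint {tuple(p)} outside the image")
    n = int(math.floor(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    prof = ndimage.map_coordinates(np.asarray(image, float), [rows, cols], order=1)
    if normalize:
        lo, hi = prof.min(), prof.max()
        if hi > lo:
            prof = (prof - lo) / (hi - lo)
        else:
            prof = np.zeros_like(prof)
    return prof


# ---------------------------------------------------------------------------
# calcium traces

@dataclass(frozen=True)
class TraceSet:
    """Per-ROI somatic and neuropil fluorescence time series."""

    cell: np.ndarray       # (T,) or (T, n)
    neuropil: np.ndarray
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.cell, float).T).T
        n = np.atleast_2d(np.asarray(self.neuropil, float).T).T
        if c.shape != n.shape:
            raise ValueError("cell and neuropil traces must have equal shape")
        object.__setattr__(self, "cell", c)
        object.__setattr__(self, "neuropil", n)


def extract_traces(frames, cell_mask, neuropil_mask, frame_rate: float = 15.0,
                   ) -> TraceSet:
    """Mean-pixel-value traces of one ROI from a frame sequence."""
    movie = np.stack([f.pixels if hasattr(f, "pixels") else f for f in frames])
    cell = movie[:, cell_mask].mean(axis=1)
    neu = movie[:, neuropil_mask].mean(axis=1)
    return TraceSet(cell=cell, neuropil=neu, frame_rate=frame_rate)


def dff(traces: TraceSet, r_neuropil: float = 0.7,
        f0_percentile: float = 25.0) -> np.ndarray:
    """Relative fluorescence change ΔF/F = (F − F0)/F0.

    F is the neuropil-corrected signal F_cell − 0.7·F_neuropil; F0 is the
    25th percentile (linear interpolation) of F over the whole recording.
    """
    F = traces.cell - r_neuropil * traces.neuropil
    F0 = np.percentile(F, f0_percentile, axis=0)
    if np.any(F0 <= 0):
        raise ValueError(
            f"degenerate baseline: F0 = {np.atleast_1d(F0)} must be positive "
            "after neuropil subtraction"
        )
    out = (F - F0) / F0
    return out[:, 0] if out.shape[1] == 1 else out


def snr(dff_series, *, top_fraction: float = 0.10,
        interval_based: bool = False) -> float:
    """Calcium signal-to-noise ratio of a ΔF/F series.

    Signal: mean of the samples at or above the (1−top_fraction) percentile
    of ΔF/F (value-based reading of "top 10 % of signal values"); with
    ``interval_based=True`` the contiguous time window of that length with
    the largest mean is used instead.  Noise: SD (n−1) of the samples
    strictly below the percentile.  Raises on zero noise.
    """
    x = np.asarray(dff_series, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 samples for the 90/10 split")
    thresh = np.percentile(x, 100.0 * (1.0 - top_fraction))
    below = x[x < thresh]
    if interval_based:
        w = max(int(round(top_fraction * len(x))), 1)
        csum = np.convolve(x, np.ones(w), mode="valid") / w
        signal_mean = float(csum.max())
    else:
        signal_mean = float(x[x >= thresh].mean())
    if len(below) < 2:
        raise ValueError("degenerate series: no samples below the 90th percentile")
    noise_sd = float(np.std(below, ddof=1))
    if noise_sd == 0.0:
        raise ValueError("zero noise SD: ΔF/F series is degenerate (constant)")
    return signal_mean / noise_sd


# ---------------------------------------------------------------------------
# rank-based comparisons

def _exact_mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann–Whitney by enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return float(u_obs), count / total


def _exact_wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank test by enumeration of sign flips."""
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return float(w_obs), count / 2**n


def compare_groups(a, b, *, paired: bool = False) -> tuple[float, float]:
    """Two-sided rank test: Wilcoxon signed-rank if paired, else Mann–Whitney.

    Exact enumeration for combined n ≤ 12, normal approximation with tie
    correction otherwise.  All-tied inputs return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        if len(a) + len(b) <= 12:
            return _exact_wilcoxon(d)
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             mode="approx")
        return float(res.statistic), float(res.pvalue)
    if len(np.unique(np.concatenate([a, b]))) == 1:
        warnings.warn("all observations tied; p = 1")
        return float(len(a) * len(b) / 2.0), 1.0
    if len(a) + len(b) <= 12:
        return _exact_mannwhitney(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
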