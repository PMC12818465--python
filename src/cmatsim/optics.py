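"""Field-resolved optical model: ties the pupil, the ground-truth aberration
field and the DM state together into renderable PSFs.

One model instance answers, for any FOV position and DM coefficient vector:
what is the residual aberration, the two-photon PSF, the focal-plane imaging
kernel, and the total two-photon signal (the sensorless-calibration metric)?
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wavefront import (
    AberrationField,
    DMState,
    PSF3D,
    PupilSpec,
    focal_field,
    psf_2p,
    pupil_grid,
    residual,
    truth_coeffs,
    zernike,
)

__all__ = ["OpticsModel"]


@dataclass
class OpticsModel:
    """Two-photon mesoscope optics with a field-varying system aberration."""

    pupil: PupilSpec
    field: AberrationField

    def __post_init__(self) -> None:
        rho, theta, mask = pupil_grid(self.pupil)
        self._mask = mask
        self._rr = rho[mask]
        self._tt = theta[mask]
        self._basis = np.stack(
            [zernike(j, self._rr, self._tt) for j in range(1, self.field.n_terms + 1)]
        )
        self._norm_energy = None  # Σ|h|⁴ of the unaberrated pupil (lazy)

    # -- aberrations --------------------------------------------------------

    def truth(self, position) -> np.ndarray:
        return truth_coeffs(self.field, position)

    def residual_coeffs(self, position, dm: DMState | None) -> np.ndarray:
        t = self.truth(position)
        if dm is None:
            return t
        return residual(t, dm)

    def _phase(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.asarray(coeffs, dtype=float)
        nb = self._basis.shape[0]
        if len(c) > nb:
            extra = np.stack(
                [zernike(j, self._rr, self._tt) for j in range(nb + 1, len(c) + 1)]
            )
            self._basis = np.concatenate([self._basis, extra])
        phase = np.zeros(self._mask.shape)
        phase[self._mask] = 2.0 * math.pi * (c @ self._basis[: len(c)])
        return phase

    # -- rendering ----------------------------------------------------------

    def psf3d(
        self, position, dm: DMState | None, z_planes, *, crop: int | None = None
    ) -> PSF3D:
        """Two-photon PSF of the residual aberration at a field position."""
        phase = self._phase(self.residual_coeffs(position, dm))
        return psf_2p(self.pupil, phase, z_planes, crop=crop)

    def kernel2d(self, position, dm: DMState | None, *, crop: int = 128) -> np.ndarray:
        """Focal-plane (z=0) two-photon imaging kernel, central crop window.

        Normalized like the PSF (unaberrated peak = 1), so integrated kernel
        mass reflects the Strehl-dependent excitation efficiency.
        """
        psf = self.psf3d(position, dm, [0.0], crop=crop)
        return psf.data[0]

    # -- scalar figures of merit --------------------------------------------

    def focal_energy(self, coeffs) -> float:
        """Σ|h|⁴ of the focal plane for a residual coefficient vector,
        normalized to 1 for zero aberration.

        This equals (up to the phantom's total brightness) the total
        two-photon fluorescence collected from an extended thin sample — the
        quantity the sensorless calibration maximizes.  Uses the raw far-field
        transform, so it carries no lateral-sampling guard.
        """
        if self._norm_energy is None:
            h0 = focal_field(self.pupil, np.zeros(self._mask.shape), 0.0)
            i0 = h0.real**2 + h0.imag**2
            self._norm_energy = float(np.sum(i0 * i0))
        h = focal_field(self.pupil, self._phase(np.asarray(coeffs, float)), 0.0)
        i = h.real**2 + h.imag**2
        return float(np.sum(i * i)) / self._norm_energy

    def strehl_2p(self, position, dm: DMState | None) -> float:
        """Two-photon Strehl: aberrated over unaberrated peak intensity²."""
        phase = self._phase(self.residual_coeffs(position, dm))
        h = focal_field(self.pupil, phase, 0.0)
        i = h.real**2 + h.imag**2
        return float(i.max() ** 2) / float(self._mask.sum()) ** 4
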