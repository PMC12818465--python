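"""Sensorless modal wavefront calibration.

Per correction point, each Zernike term is swept over an interval of
coefficient values while all other terms are held fixed; the fluorescence
metric is evaluated at 21 equally spaced steps, the sweep is repeated for 5
cycles, and the per-cycle argmax coefficients are averaged into the term's
new value.  One *round* sweeps every optimized term in Noll order
(piston/tip/tilt excluded — piston does not change the two-photon signal and
tip/tilt merely translate the field).  Rounds repeat, with the sweep range
halving each round, until the round-over-round metric gain falls below a
threshold (never fewer than 4 rounds, never more than 8 — the operating range
of the hardware procedure).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .hexgrid import CorrectionGrid
from .optics import OpticsModel
from .wavefront import DMState, clip_stroke

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "CalibrationTable",
    "CalibrationSimulator",
    "sweep_term",
    "calibrate_point",
    "calibrate_grid",
    "save_table",
    "load_table",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Sensorless-calibration protocol parameters.

    The hardware procedure optimizes 200 Zernike terms; desk-scale
    simulations default to 15.  ``first_half_range`` (waves) is the sweep
    half-width of round 1, shrinking by ``range_decay`` each round — the
    hardware's "predetermined coefficient range" per term is not public, so
    a shrinking schedule around the running estimate is used.
    """

    n_terms: int = 15
    start_term: int = 4          # Noll index of the first optimized term
    cycles_per_term: int = 5
    steps_per_cycle: int = 21
    rounds_min: int = 4
    rounds_max: int = 8
    first_half_range: float = 0.5
    range_decay: float = 0.5
    convergence_threshold: float = 0.01
    metric: str = "sum"          # "sum" (total signal) or "peak"
    #: in-round term order: "defocus_last" sweeps the asymmetric terms first
    #: and defocus at the end of each round, avoiding the focal-shift ridge
    #: that traps sequential optimization when defocus is swept against
    #: uncorrected astigmatism/spherical; "noll" sweeps 4..n_terms in order.
    term_order: str = "defocus_last"
    stroke_limit: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_cycle % 2 != 1:
            raise ValueError("steps_per_cycle must be odd (0 must be a grid point)")
        if not (1 <= self.rounds_min <= self.rounds_max):
            raise ValueError("need 1 ≤ rounds_min ≤ rounds_max")
        if self.start_term < 2 or self.start_term > self.n_terms:
            raise ValueError("start_term outside the optimized basis")

    def half_range(self, round_index: int) -> float:
        """Sweep half-range (waves) for round 1, 2, …"""
        return self.first_half_range * self.range_decay ** (round_index - 1)

    def round_order(self) -> list[int]:
        """Noll indices in in-round sweep order."""
        terms = list(range(self.start_term, self.n_terms + 1))
        if self.term_order == "defocus_last" and 4 in terms:
            terms.remove(4)
            terms.append(4)
        elif self.term_order not in ("noll", "defocus_last"):
            raise ValueError(f"unknown term_order {self.term_order!r}")
        return terms


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of calibrating one correction point."""

    coeffs: np.ndarray
    metric_trace: np.ndarray     # best metric at the end of each round
    rounds: int
    converged: bool


class CalibrationSimulator:
    """Fluorescence metric for a calibration phantom at one field position.

    ``metric(dm_coeffs)`` returns the total (or peak) two-photon signal of
    the phantom rendered through the residual aberration at ``position``.
    For the total-signal metric the full-field convolution identity
    Σ(phantom ⊛ PSF) = Σphantom · ΣPSF reduces the render to one focal-plane
    transform per evaluation.  ``noise_sigma`` applies multiplicative
    Gaussian measurement noise (σ relative), drawn from the simulator's
    seeded stream.
    """

    def __init__(
        self,
        optics: OpticsModel,
        position,
        *,
        phantom_total: float = 1.0,
        metric: str = "sum",
        noise_sigma: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.optics = optics
        self.position = np.asarray(position, dtype=float)
        self.phantom_total = float(phantom_total)
        self.metric_kind = metric
        self.noise_sigma = float(noise_sigma)
        self._rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xCA11])
        self._truth = optics.truth(self.position)

    def metric(self, dm_coeffs) -> float:
        c = np.asarray(dm_coeffs, dtype=float)
        n = max(len(c), len(self._truth))
        res = np.zeros(n)
        res[: len(self._truth)] += self._truth
        res[: len(c)] += c
        if self.metric_kind == "peak":
            value = self.optics.strehl_2p(self.position, DMState(c))
        else:
            value = self.phantom_total * self.optics.focal_energy(res)
        if self.noise_sigma > 0.0:
            value *= 1.0 + self.noise_sigma * self._rng.standard_normal()
        return float(value)


def sweep_term(
    metric_fn: Callable[[np.ndarray], float],
    j: int,
    current: np.ndarray,
    half_range: float,
    config: CalibrationConfig,
) -> float:
    """Optimize one Zernike coefficient by repeated grid sweeps.

    For each of ``cycles_per_term`` cycles, evaluate the metric at
    ``steps_per_cycle`` equally spaced values of c_j in
    [c_j − half_range, c_j + half_range] (all other terms fixed) and record
    the argmax coefficient (first grid index on exact ties).  The updated
    coefficient is the mean of the per-cycle argmax values.
    """
    if half_range <= 0:
        raise ValueError("half_range must be positive")
    current = np.asarray(current, dtype=float)
    c0 = current[j - 1]
    grid = np.linspace(c0 - half_range, c0 + half_range, config.steps_per_cycle)
    peaks = []
    trial = current.copy()
    for _cycle in range(config.cycles_per_term):
        values = np.empty(config.steps_per_cycle)
        for k, g in enumerate(grid):
            trial[j - 1] = g
            v = metric_fn(trial)
            if not np.isfinite(v):
                raise ValueError(
                    f"non-finite metric at term {j}, coefficient {g:.4f} λ"
                )
            values[k] = v
        peaks.append(grid[int(np.argmax(values))])  # argmax: first max wins
    return float(np.mean(peaks))


def calibrate_point(
    simulator: CalibrationSimulator,
    position,
    config: CalibrationConfig,
) -> CalibrationResult:
    """Full multi-round sensorless calibration of one correction point.

    Aborts with a diagnostic if the metric degrades by more than 20 % within
    a round (runaway optimization).
    """
    coeffs = np.zeros(config.n_terms)
    metric_trace: list[float] = []
    prev = simulator.metric(coeffs)
    converged = False
    rounds = 0
    for rnd in range(1, config.rounds_max + 1):
        rounds = rnd
        hr = config.half_range(rnd)
        round_start = simulator.metric(coeffs)
        for j in config.round_order():
            coeffs[j - 1] = sweep_term(
                simulator.metric, j, coeffs, hr, config
            )
            now = simulator.metric(coeffs)
            if now < 0.8 * round_start and simulator.noise_sigma == 0.0:
                raise RuntimeError(
                    f"calibration runaway at position {tuple(simulator.position)}: "
                    f"metric fell to {now:.4g} (< 80 % of round-start "
                    f"{round_start:.4g}) after sweeping term {j} in round {rnd}"
                )
        best = simulator.metric(coeffs)
        metric_trace.append(best)
        gain = (best - prev) / abs(prev) if prev != 0 else math.inf
        prev = best
        if rnd >= config.rounds_min and gain < config.convergence_threshold:
            converged = True
            break
    dm = clip_stroke(DMState(coeffs, stroke_limit=config.stroke_limit))
    return CalibrationResult(
        coeffs=dm.coeffs,
        metric_trace=np.asarray(metric_trace),
        rounds=rounds,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# whole-grid calibration and its persisted table

@dataclass
class CalibrationTable:
    """Per-correction-point compensation vectors (waves), index-aligned with
    the grid's canonical ordering."""

    points: np.ndarray        # (N, 2) µm
    coeffs: np.ndarray        # (N, J) waves: the DM *load* (≈ −truth)

    def vector(self, index: int) -> np.ndarray:
        if not (0 <= index < len(self.points)):
            raise KeyError(f"no calibration entry for point {index}")
        return self.coeffs[index]


def calibrate_grid(
    simulator_factory: Callable[[np.ndarray], CalibrationSimulator],
    grid: CorrectionGrid,
    config: CalibrationConfig,
) -> CalibrationTable:
    """Independently calibrate every grid point, in grid-index order.

    ``simulator_factory(position)`` must return the metric simulator with the
    calibration phantom placed at that position.
    """
    vectors = np.zeros((len(grid), config.n_terms))
    for i, p in enumerate(grid.points):
        try:
            result = calibrate_point(simulator_factory(p), p, config)
        except Exception as exc:  # annotate with the failing point
            raise RuntimeError(f"calibration failed at grid point {i}: {exc}") from exc
        vectors[i] = result.coeffs
    return CalibrationTable(points=grid.points.copy(), coeffs=vectors)


def save_table(table: CalibrationTable, path) -> None:
    """Tab-separated text: index, x, y, then c1…cJ in waves."""
    J = table.coeffs.shape[1]
    header = "# index\tx_um\ty_um\t" + "\t".join(f"c{j}" for j in range(1, J + 1))
    lines = [header]
    for i, ((x, y), c) in enumerate(zip(table.points, table.coeffs)):
        lines.append(
            f"{i}\t{x:.9g}\t{y:.9g}\t" + "\t".join(f"{v:.9g}" for v in c)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_table(path) -> CalibrationTable:
    pts, cs = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        pts.append((float(parts[1]), float(parts[2])))
        cs.append([float(v) for v in parts[3:]])
    return CalibrationTable(points=np.array(pts), coeffs=np.array(cs))
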