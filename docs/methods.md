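# Methods

`cmatsim` is a desk-scale digital twin of a large-field two-photon mesoscope
equipped with honeycomb multipoint adaptive optics. It simulates the full
workflow — correction-point layout, sensorless modal calibration of a
deformable mirror (DM), tiled and ROI scanning with per-region correction
loading, and the downstream image-quality and calcium-signal statistics —
entirely on seeded synthetic samples. This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
simulations show.

## Correction-point geometry

The full circular field of view (FOV, Ø8 mm) is tiled with regular hexagons
of side s = 577 µm. Hexagon centers and vertices together form a triangular
lattice of pitch s; every lattice point within an *inclusion radius* of the
FOV center is a correction point. A hexagon center and two adjacent vertices
form an equilateral triangle whose circumradius s/√3 = 333.1 µm ("roughly
330 µm") is the worst-case distance from any tiled location to its nearest
correction point — the effective radius of one point's correction disk.

The inclusion radius defaults to 3950 µm. The reference counts (55 hexagons,
163 correction points) require excluding lattice points at
4·√3·577 ≈ 3997.6 µm even though the FOV nominally extends to 4000 µm; any
inclusion radius in ≈[3790, 3995] µm reproduces both counts, and 3950 was
fixed and documented. Orientation is fixed with the hexagon-center sublattice
basis vector along +x (vertices at 30° + k·60° from each center); point
ordering is by distance from the FOV center, then angle, which makes
nearest-point ties and all downstream assignments deterministic.

**Coverage caveat.** With this admission rule, s/√3-coverage holds over the
disk of radius ≈3.65 mm but *not* all the way to the FOV edge: the outermost
admitted points sit at r = 3784 µm, so locations near r = 3.9–4.0 mm can be
up to ~0.5 mm from the nearest correction point. This is a property of the
printed geometry itself (the outer hexagons' far vertices fall outside the
inclusion radius). `build_correction_grid` therefore treats coverage checking
as an explicit, opt-in validation (`coverage_radius=`) rather than an
invariant; `check_coverage` reports the worst location.

Overlap economics are evaluated analytically from the circular-lens
intersection area: disks of radius r at hexagonal spacing √3·r share 5.77 %
of one disk's area with a single neighbor (34.60 % over 6 neighbors); the
minimal fully covering square layout (spacing √2·r, 4 neighbors) shares
18.17 % / 72.68 %. The percentages are scale-invariant in r.

## Optics

Wavefronts are parameterized by Noll-indexed Zernike polynomials, unit-RMS
normalized over the unit-disk pupil, so a coefficient in waves (λ) is its
RMS wavefront contribution. The point-spread function uses scalar Fourier
optics: the focal field is the far-field transform of the aberrated pupil
(NA 0.5 water immersion, λ = 0.920 µm), with defocus applied as the exact
high-NA phase k·z·√(n² − NA²ρ²); at NA 0.5 the scalar approximation is
validated against an independent Debye-integral oracle to better than 1 % in
lateral FWHM. Two-photon excitation makes the effective PSF the squared
intensity, |h|⁴, normalized to unit peak for the unaberrated system. The
default sampling (pupil grid ≥64, zero-padding ×8) keeps ≥4 samples across
the ~0.68 µm two-photon lateral FWHM; image rendering refuses coarser
sampling.

The DM is modal: its state is a Zernike coefficient vector (in λ) added to
the sample-path phase, so perfect correction is the negative of the truth.
Stroke limiting (±30 λ surface) scales the whole vector rather than clipping
individual terms, preserving the corrected shape; a warning is logged.

**Ground-truth aberration field.** The "system aberrations" the calibration
must discover are a smooth field-dependent coefficient function: coma grows
linearly with field position, astigmatism and spherical quadratically, all
vanishing at the FOV center; a band-limited seeded random component (three
long-period plane waves per term) adds irregularity. Edge amplitudes default
to 0.12 λ (astigmatism), 0.12 λ (coma), 0.06 λ (spherical) and 0.03 λ per
random term — an edge residual of ≈0.19 λ RMS beyond the center correction.
This scale was chosen to match the *observable* consequences the instrument
reports for a center-only correction at the field edge: a severalfold loss
of two-photon signal and a clearly measurable (tens of percent) PSF
broadening, while the focus remains a coherent spot. Much larger amplitudes
shatter the focus into speckle, in which regime a Gaussian "FWHM" measures a
single speckle grain and is no longer a meaningful resolution statistic.

## Sensorless calibration

Calibration of one correction point maximizes the total two-photon
fluorescence of a calibration phantom (a pollen-like spiky ball) by
sequential 1-D sweeps of Zernike coefficients: for each term, the metric is
evaluated at 21 equally spaced coefficient values over a predetermined range,
repeated for 5 cycles, and the per-cycle argmax values are averaged into the
new coefficient. One *round* sweeps every optimized term; rounds repeat with
the sweep half-range halving each round (round 1: ±0.5 λ) until the
round-over-round metric gain drops below 1 %, bounded to 4–8 rounds.
Piston/tip/tilt are excluded (piston does not affect the two-photon signal;
tip/tilt only translate the field). For the total-signal metric the
full-field convolution identity Σ(phantom ⊛ PSF) = Σphantom · Σ|h|⁴ reduces
each metric evaluation to a single focal-plane transform.

**Term order.** Within a round, defocus is swept *after* all asymmetric
terms ("defocus-last"). Sweeping defocus first against still-uncorrected
astigmatism/spherical aberration lets it chase the axially shifted
brightest plane, placing the optimizer on a narrow curved ridge that
sequential 1-D sweeps cannot leave; empirically this single change reduces
the residual on the default edge aberration from ≈0.57 λ to ≈0.10 λ. Plain
Noll order remains available (`term_order="noll"`).

**Capture range.** Sequential modal optimization is a local method. Measured
cold-start behavior (noiseless, terms 4–15, random per-term truth
amplitudes, 8 rounds): ±0.15 λ/term recovers to <0.05 λ residual in 5 of 6
trials; ±0.25 → 2/6; ±0.35 → 1/6; ±0.5 (≈1 λ RMS total) → 0/6, for all
sweep-range schedules tried and for a thick-sample (multi-plane) metric
variant. This matches the ~1 rad RMS capture range generally reported for
image-metric sensorless AO; correcting larger aberrations requires a warm
start (e.g., a neighboring point's solution) or a pre-correction pass. The
default field model keeps per-point truths well inside the capture range.

Metric noise, when enabled, is multiplicative Gaussian from the simulator's
seeded stream; the 5-cycle argmax averaging then demonstrably reduces the
estimator variance relative to a single cycle.

## Scanning

A full-FOV frame is N×N square tiles (default 4×4 over 8 mm, i.e. 16 tiles
of 2×2 mm) in stripe order: top stripe first, left-to-right. Before each
tile the DM loads the calibrated vector of the correction point nearest the
tile center — N² loads per frame — and the galvo-jump/DM-load interval is
logged as excluded with no data retained. Rendering is piecewise-constant
per tile: one residual aberration (truth at the tile center + loaded DM) and
one two-photon kernel per tile, matching the instrument's one-DM-state-per-
subregion physics; intra-tile field variation is deliberately not modeled.
Tiles use half-open extents, so a constant scene under zero aberration scans
seamlessly to machine precision.

Imaging kernels are resampled from the pupil-FFT grid to the image pixel
pitch and normalized so the *unaberrated* kernel has unit mass: perfect
optics preserve scene intensity, and residual aberration attenuates the
collected signal by the relative two-photon excitation efficiency. The
central-AO baseline ("CeAO") applies the FOV-center calibration to every
tile; the multipoint mode applies each tile's own assignment.

ROI scanning selects the single correction point nearest the ROI centroid
and holds it for the whole sequence. A static phantom is interpreted as an
ROI-centered local scene; a calcium movie is rendered through its linear
template decomposition (one blur per spatial component, not per frame).

Galvo drive voltages are a linear odd map: FOV edge ↦ full-scale angle (45°)
× volts/degree.

## Synthetic samples

All generators are pure functions of their spec (including the seed).

- **Beads**: spheres with anti-aliased edges, uniformly placed with ≥2
  diameters center separation, each normalized to a stated integrated
  fluorescence (a sub-voxel bead degenerates to a single-voxel impulse of
  that integrated amplitude). Diameters 0.5 µm (resolution) and 10 µm
  (brightness) mirror the standard characterization samples; bead stacks use
  the instrument's 0.27 µm axial step.
- **Pollen-like target**: a rim-weighted spiky ball for calibration.
- **Neuron scene**: somata (soft disks, 4–7 µm radius), dendrites with spine
  bumps, and a smooth neuropil background, with ground-truth masks.
- **Calcium movie**: per-cell Poisson spike trains (0.2 Hz) convolved with a
  single-exponential kernel (τ = 1.5 s, a standard slow-indicator value),
  riding on a 20-count baseline; cell pixels carry the cell trace plus 0.3×
  the shared neuropil signal (so the conventional 0.7-neuropil subtraction is
  exercised; with a 0.3 contamination it slightly over-subtracts, as real
  pipelines also risk). Photon shot noise is Poisson at 0.5 photons per count
  — a deliberately photon-starved budget in which optical throughput
  differences propagate into the trace SNR. Acquisition defaults are 15 Hz;
  full-length recordings are 300 s (4500 frames), while the end-to-end
  comparisons use 60 s at 64×64 px to keep single-CPU runtimes in seconds.

## Evaluation statistics

- **Bead FWHM**: the bead's intensity maximum is located, 1-D Gaussians
  (amplitude, center, σ, offset) are fit along the x-, y- and z-lines
  through it, and FWHM = 2√(2 ln 2)·σ. The lateral value is the mean of the
  x- and y-line fits — an astigmatic line focus is sharp along one axis, and
  a single-axis fit would systematically miss the broadening. Fits that fail
  or give FWHM < 2 px are flagged, logged and excluded from the mean ± SD
  summary. Recovery bias on noiseless sampled Gaussians is <1 % over
  σ ∈ [0.5, 5] µm at 0.0542 µm lateral / 0.27 µm axial sampling.
- **ΔF/F**: F = F_cell − 0.7·F_neuropil; F0 = 25th percentile of F over the
  whole recording (linear interpolation between order statistics);
  ΔF/F = (F − F0)/F0. F0 ≤ 0 is a hard error.
- **SNR**: mean of the ΔF/F samples at or above the 90th percentile, divided
  by the SD (n−1) of the samples strictly below it. "Top 10 %" is read
  value-based by default; a contiguous best-window reading is available
  (`interval_based=True`).
- **Group comparisons**: two-sided Wilcoxon signed-rank (paired) or
  Mann–Whitney (unpaired); exact p by enumeration for combined n ≤ 12 (the
  enumeration handles ties), normal approximation with tie correction above.

## End-to-end comparison

`compare_modes_at_radius` reproduces the shape of the instrument evaluation
at one field radius: sensorless-calibrate the nearest correction point and
the FOV-center point, then measure (a) bead FWHM from a rendered 3-D bead
stack (6 beads, ±10 µm axial range), (b) mean soma brightness of a rendered
neuron scene, and (c) mean calcium SNR of a rendered movie, under both
corrections. With the default field, at radius 3900 µm the multipoint mode
consistently yields smaller lateral and axial FWHM, severalfold higher soma
signal, and higher calcium SNR (≈4–5 vs ≈3.6–3.9) across seeds. These are
*directional* reproductions at desk scale: the synthetic truth field is not
the instrument's measured aberration map, so the published percentage
improvements are not quantitative targets.

Desk-scale problem sizes used throughout (chosen so the full suite runs on
one CPU in minutes): pupil grid 64 (128 where the calibration protocol is
stress-tested), FFT padding ×4 for calibration metrics and ×8 for image
rendering, 11–15 Zernike terms instead of the instrument's 200, and the
reduced movie/scene sizes above.

## What the synthetic results do and do not show

The simulations demonstrate the *mechanisms*: honeycomb layout economics,
convergence and capture behavior of the sweep protocol, per-tile correction
loading, and the statistical pipeline, with known ground truth throughout.
They do not model: the 97-actuator influence-function DM (modal idealization
instead), resonant-axis timing and bidirectional scanning, depth-dependent
scattering or sample-induced aberrations, motion artifacts, photobleaching,
chromatic or polarization effects, or real segmentation (ROI masks are known
by construction). Conclusions about real tissue imaging therefore rest on
the directional, not the numeric, agreement.
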