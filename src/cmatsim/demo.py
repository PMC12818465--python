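"""End-to-end workflow: tile the FOV, calibrate, scan in both correction
modes, and compare image-quality and calcium-signal statistics.

The central routine :func:`compare_modes_at_radius` reproduces the shape of
the instrument evaluation at one field radius: calibrate the nearest
correction point (multipoint mode) and the FOV-center point (central-AO
baseline), then measure bead FWHM, soma brightness and calcium SNR under
both corrections.  :func:`run_demo` strings the stages together and writes a
deterministic text report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .calibration import (
    CalibrationConfig,
    CalibrationSimulator,
    CalibrationTable,
    calibrate_point,
)
from .config import RunConfig, substream
from .hexgrid import CorrectionGrid, FOVSpec, HexTilingSpec, build_correction_grid, nearest_point
from .metrics import TraceSet, dff, fit_fwhm, snr
from .optics import OpticsModel
from .phantoms import (
    BeadFieldSpec,
    CalciumMovieSpec,
    NeuronSceneSpec,
    Volume,
    make_beads,
    make_calcium_movie,
    make_neuron_scene,
)
from .scanner import _kernel_for_pitch, plan_full_fov, scan_frame
from .wavefront import AberrationField, DMState, PupilSpec

__all__ = ["ModeComparison", "build_models", "calibrate_correction_point",
           "compare_modes_at_radius", "run_demo"]


@dataclass(frozen=True)
class ModeComparison:
    """Paired multipoint-vs-central metrics at one field position."""

    radius: float
    seed: int
    position: tuple[float, float]
    cmat_point: int
    ceao_point: int
    lat_fwhm_cmat: float
    lat_fwhm_ceao: float
    axi_fwhm_cmat: float
    axi_fwhm_ceao: float
    soma_intensity_cmat: float
    soma_intensity_ceao: float
    snr_cmat: float
    snr_ceao: float


def build_models(cfg: RunConfig, seed: int):
    """Grid, truth field, and the render/metric optics for one experiment."""
    grid = build_correction_grid(
        FOVSpec(cfg.fov_diameter, cfg.inclusion_radius),
        HexTilingSpec(cfg.hex_side, cfg.effective_radius),
    )
    fld = AberrationField(
        fov_radius=cfg.field_model.fov_radius,
        astig_edge=cfg.field_model.astig_edge,
        coma_edge=cfg.field_model.coma_edge,
        spherical_edge=cfg.field_model.spherical_edge,
        random_amplitude=cfg.field_model.random_amplitude,
        n_terms=cfg.field_model.n_terms,
        seed=substream(seed, "field"),
    )
    o = cfg.optics
    render = OpticsModel(
        PupilSpec(o.na, o.wavelength, o.refractive_index,
                  o.grid_size, o.pad_factor_render),
        fld,
    )
    metric = OpticsModel(
        PupilSpec(o.na, o.wavelength, o.refractive_index,
                  o.grid_size, o.pad_factor_metric),
        fld,
    )
    return grid, fld, render, metric


def _calib_config(cfg: RunConfig) -> CalibrationConfig:
    c = cfg.calibration
    return CalibrationConfig(
        n_terms=c.n_terms,
        rounds_min=c.rounds_min,
        rounds_max=c.rounds_max,
        cycles_per_term=c.cycles_per_term,
        steps_per_cycle=c.steps_per_cycle,
        first_half_range=c.first_half_range,
        range_decay=c.range_decay,
        convergence_threshold=c.convergence_threshold,
        metric=c.metric,
        term_order=c.term_order,
    )


def calibrate_correction_point(
    metric_optics: OpticsModel,
    position,
    calib_cfg: CalibrationConfig,
    seed: int,
) -> np.ndarray:
    """Sensorless-calibrate one correction point; returns the DM load."""
    sim = CalibrationSimulator(
        metric_optics, position, seed=substream(seed, "calibration")
    )
    return calibrate_point(sim, position, calib_cfg).coeffs


# ---------------------------------------------------------------------------
# per-radius paired evaluation

def _bead_fwhm(optics: OpticsModel, position, dm: DMState, seed: int,
               bead_count: int, bead_diameter: float):
    """Render a bead field through the residual PSF and fit FWHMs."""
    pitch = optics.pupil.focal_pitch
    beads = make_beads(
        BeadFieldSpec(
            bead_diameter=bead_diameter,
            count=bead_count,
            lateral_size=20.0,
            axial_size=10.0,
            lateral_pitch=pitch,
            axial_pitch=0.27,
            min_separation=8.0,
            seed=substream(seed, "beads"),
        )
    )
    z = np.arange(-37, 38) * 0.27  # ±10 µm at the bead-stack axial step
    psf = optics.psf3d(position, dm, z, crop=int(round(12.0 / pitch)) | 1)
    pad_z = len(z) // 2
    vol = np.pad(beads.volume.data, ((pad_z, pad_z), (0, 0), (0, 0)))
    img = signal.fftconvolve(vol, psf.data, mode="same")
    img = np.clip(img, 0.0, None)
    centers = beads.centers + np.array([0.0, 0.0, pad_z * 0.27])
    meas = fit_fwhm(
        Volume(img, pitch, 0.27), centers, window_um=3.5, axial_window_um=10.0
    )
    return meas.lateral_mean, meas.axial_mean


def _soma_intensity(optics: OpticsModel, position, dm: DMState, seed: int,
                    scene_size: float) -> float:
    scene = make_neuron_scene(
        NeuronSceneSpec(size=scene_size, pitch=0.5,
                        seed=substream(seed, "scene"))
    )
    kernel = _kernel_for_pitch(optics, position, dm, 0.5)
    img = signal.fftconvolve(scene.volume.data[0], kernel, mode="same")
    union = np.zeros_like(img, dtype=bool)
    for m in scene.soma_masks:
        union |= m
    return float(img[union].mean())


def _calcium_snr(optics: OpticsModel, position, dm: DMState, seed: int,
                 mode: str, cfg: RunConfig) -> float:
    ev = cfg.evaluation
    movie = make_calcium_movie(
        CalciumMovieSpec(
            n_cells=ev.movie_cells,
            duration=ev.movie_duration,
            size_px=ev.movie_size_px,
            seed=substream(seed, "movie"),
        )
    )
    kernel = _kernel_for_pitch(optics, position, dm, movie.spec.pitch)
    pad = kernel.shape[0] // 2
    blurred = np.stack(
        [
            signal.fftconvolve(np.pad(t, pad, mode="edge"), kernel,
                               mode="same")[pad:-pad, pad:-pad]
            for t in movie.templates
        ]
    )
    clean = np.clip(np.tensordot(movie.temporal, blurred, axes=(1, 0)), 0, None)
    rng = np.random.default_rng(
        [substream(seed, f"shot-noise-{mode}") & 0x7FFFFFFF]
    )
    gain = movie.spec.photon_gain
    frames = rng.poisson(clean * gain).astype(np.float64) / gain
    snrs = []
    for cm, nm in zip(movie.cell_masks, movie.neuropil_masks):
        ts = TraceSet(
            cell=frames[:, cm].mean(axis=1),
            neuropil=frames[:, nm].mean(axis=1),
            frame_rate=movie.spec.frame_rate,
        )
        snrs.append(snr(dff(ts)))
    return float(np.mean(snrs))


def compare_modes_at_radius(
    cfg: RunConfig, radius: float, seed: int, *, angle_deg: float = 90.0
) -> ModeComparison:
    """Calibrate and evaluate both correction modes at one field radius.

    The evaluation position sits at ``radius`` µm from the FOV center along
    ``angle_deg``.  Multipoint mode loads the compensation calibrated at the
    nearest correction point; the central-AO baseline loads the FOV-center
    compensation everywhere.
    """
    grid, fld, render, metric = build_models(cfg, seed)
    calib_cfg = _calib_config(cfg)
    ang = np.deg2rad(angle_deg)
    pos = (radius * np.cos(ang), radius * np.sin(ang))

    i_cmat = nearest_point(grid, pos)
    i_ceao = nearest_point(grid, (0.0, 0.0))
    dm_by_point: dict[int, DMState] = {}
    for idx in {i_cmat, i_ceao}:
        coeffs = calibrate_correction_point(
            metric, grid.points[idx], calib_cfg, seed
        )
        dm_by_point[idx] = DMState(coeffs)
    dm_cmat, dm_ceao = dm_by_point[i_cmat], dm_by_point[i_ceao]

    ev = cfg.evaluation
    lat_c, axi_c = _bead_fwhm(render, pos, dm_cmat, seed,
                              ev.bead_count, ev.bead_diameter)
    lat_o, axi_o = _bead_fwhm(render, pos, dm_ceao, seed,
                              ev.bead_count, ev.bead_diameter)
    soma_c = _soma_intensity(render, pos, dm_cmat, seed, ev.scene_size)
    soma_o = _soma_intensity(render, pos, dm_ceao, seed, ev.scene_size)
    snr_c = _calcium_snr(render, pos, dm_cmat, seed, "cmat", cfg)
    snr_o = _calcium_snr(render, pos, dm_ceao, seed, "ceao", cfg)
    return ModeComparison(
        radius=radius, seed=seed, position=pos,
        cmat_point=i_cmat, ceao_point=i_ceao,
        lat_fwhm_cmat=lat_c, lat_fwhm_ceao=lat_o,
        axi_fwhm_cmat=axi_c, axi_fwhm_ceao=axi_o,
        soma_intensity_cmat=soma_c, soma_intensity_ceao=soma_o,
        snr_cmat=snr_c, snr_ceao=snr_o,
    )


# ---------------------------------------------------------------------------
# full demo

def run_demo(cfg: RunConfig, outdir=None) -> str:
    """Tile → calibrate → scan both modes → metrics; returns the report text.

    Only the correction points actually used (tile assignments plus the
    evaluation points) are calibrated; untouched table rows stay zero.
    Deterministic for a fixed config.
    """
    from pathlib import Path

    stage = "setup"
    try:
        grid, fld, render, metric = build_models(cfg, cfg.seed)
        calib_cfg = _calib_config(cfg)

        stage = "calibrate"
        fov = FOVSpec(cfg.fov_diameter, cfg.inclusion_radius)
        table = CalibrationTable(
            points=grid.points.copy(),
            coeffs=np.zeros((len(grid), calib_cfg.n_terms)),
        )
        # correction points needed by the scan plan
        D, n = cfg.fov_diameter, cfg.scan_n
        size = D / n
        needed = {nearest_point(grid, (0.0, 0.0))}
        for row in range(n):
            for col in range(n):
                cx = -D / 2 + (col + 0.5) * size
                cy = D / 2 - (row + 0.5) * size
                needed.add(nearest_point(grid, (cx, cy)))
        for idx in sorted(needed):
            table.coeffs[idx] = calibrate_correction_point(
                metric, grid.points[idx], calib_cfg, cfg.seed
            )

        stage = "scan"
        plan = plan_full_fov(fov, n, grid, table)
        coarse_pitch = size / 10.0
        npx = int(round(D / coarse_pitch))
        phantom = Volume(
            np.ones((1, npx, npx)), coarse_pitch, 0.0
        )
        frame_cmat = scan_frame(render, phantom, plan, mode="cmat")
        frame_ceao = scan_frame(render, phantom, plan, mode="ceao")

        stage = "metrics"
        comparisons = [
            compare_modes_at_radius(cfg, r, cfg.seed)
            for r in cfg.evaluation.radii
        ]
    except Exception as exc:
        raise RuntimeError(
            f"demo stage '{stage}' failed (config {cfg.config_hash}): {exc}"
        ) from exc

    lines = [
        "cmatsim demo report",
        f"config_hash\t{cfg.config_hash}",
        f"seed\t{cfg.seed}",
        f"grid_points\t{len(grid)}",
        f"hexagon_centers\t{grid.n_centers}",
        f"scan_tiles\t{len(plan.tiles)}",
        f"dm_load_events\t{plan.dm_load_events}",
        "",
        "per-tile mean brightness (multipoint vs central AO)",
        "tile\trow\tcol\tpoint\tcmat\tceao",
    ]
    pitch = frame_cmat.pitch
    W = frame_cmat.pixels.shape[1]
    for i, t in enumerate(plan.tiles):
        xmin, xmax, ymin, ymax = t.extent
        c0 = int(round((xmin + W * pitch / 2) / pitch))
        c1 = int(round((xmax + W * pitch / 2) / pitch))
        r0 = int(round((W * pitch / 2 - ymax) / pitch))
        r1 = int(round((W * pitch / 2 - ymin) / pitch))
        bc = frame_cmat.pixels[r0:r1, c0:c1].mean()
        bo = frame_ceao.pixels[r0:r1, c0:c1].mean()
        lines.append(
            f"{i}\t{t.row}\t{t.col}\t{t.point_index}\t{bc:.5g}\t{bo:.5g}"
        )
    lines += [
        "",
        "per-radius paired comparison (multipoint vs central AO)",
        "radius_um\tlat_fwhm_cmat\tlat_fwhm_ceao\taxi_fwhm_cmat\taxi_fwhm_ceao"
        "\tsoma_cmat\tsoma_ceao\tsnr_cmat\tsnr_ceao",
    ]
    for c in comparisons:
        lines.append(
            f"{c.radius:g}\t{c.lat_fwhm_cmat:.4g}\t{c.lat_fwhm_ceao:.4g}\t"
            f"{c.axi_fwhm_cmat:.4g}\t{c.axi_fwhm_ceao:.4g}\t"
            f"{c.soma_intensity_cmat:.4g}\t{c.soma_intensity_ceao:.4g}\t"
            f"{c.snr_cmat:.4g}\t{c.snr_ceao:.4g}"
        )
    report = "\n".join(lines) + "\n"

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(report)
        cfg.to_yaml(out / "config.yaml")
        from .hexgrid import save_grid
        from .calibration import save_table
        from .scanner import save_plan
        save_grid(grid, out / "grid.tsv")
        save_table(table, out / "calib.tsv")
        save_plan(plan, out / "plan.tsv")
    return report
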