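"""Scan planning, tile rendering, frame mosaicking, and ROI scanning."""

import numpy as np
import pytest

from cmatsim import (
    AberrationField,
    DMState,
    FOVSpec,
    HexTilingSpec,
    OpticsModel,
    PupilSpec,
    ROIRequest,
    build_correction_grid,
    nearest_point,
    plan_full_fov,
    render_tile,
    scan_frame,
    scan_roi,
)
from cmatsim.calibration import CalibrationTable
from cmatsim.phantoms import Volume


@pytest.fixture(scope="module")
def reference_setup(request):
    grid = build_correction_grid(FOVSpec(), HexTilingSpec())
    table = CalibrationTable(
        points=grid.points.copy(), coeffs=np.zeros((len(grid), 11))
    )
    return grid, table


@pytest.fixture(scope="module")
def flat_optics():
    """Optics with zero system aberration."""
    fld = AberrationField(
        n_terms=11, astig_edge=0.0, coma_edge=0.0, spherical_edge=0.0,
        random_amplitude=0.0, seed=0,
    )
    return OpticsModel(PupilSpec(grid_size=64, pad_factor=8), fld)


@pytest.fixture(scope="module")
def radial_optics():
    return OpticsModel(
        PupilSpec(grid_size=64, pad_factor=8), AberrationField(n_terms=11, seed=1)
    )


class TestPlanFullFov:
    def test_reference_protocol_16_tiles(self, reference_setup):
        grid, table = reference_setup
        plan = plan_full_fov(FOVSpec(), 4, grid, table)
        assert len(plan.tiles) == 16
        assert plan.dm_load_events == 16
        for t in plan.tiles:
            xmin, xmax, ymin, ymax = t.extent
            assert xmax - xmin == pytest.approx(2000.0)
            assert ymax - ymin == pytest.approx(2000.0)
        # 4 stripes of full FOV width
        rows = {t.row for t in plan.tiles}
        assert rows == {0, 1, 2, 3}

    def test_single_tile_plan(self, reference_setup):
        grid, table = reference_setup
        plan = plan_full_fov(FOVSpec(), 1, grid, table)
        assert len(plan.tiles) == 1
        assert plan.tiles[0].extent == (-4000.0, 4000.0, -4000.0, 4000.0)

    def test_stripe_order_and_centers_match_meshgrid(self, reference_setup):
        grid, table = reference_setup
        plan = plan_full_fov(FOVSpec(), 4, grid, table)
        size = 2000.0
        expected = []
        for row in range(4):
            for col in range(4):
                expected.append(
                    (-4000 + (col + 0.5) * size, 4000 - (row + 0.5) * size)
                )
        got = [t.center for t in plan.tiles]
        assert np.allclose(got, expected)
        # nearest-point assignment equals the exhaustive oracle
        for t in plan.tiles:
            d = np.hypot(
                grid.points[:, 0] - t.center[0], grid.points[:, 1] - t.center[1]
            )
            assert t.point_index == int(np.argmin(d))

    def test_tiling_partitions_fov_exactly(self, reference_setup):
        grid, table = reference_setup
        plan = plan_full_fov(FOVSpec(), 4, grid, table)
        # half-open extents: no overlaps, full cover
        xs = sorted({t.extent[0] for t in plan.tiles})
        assert xs == [-4000.0, -2000.0, 0.0, 2000.0]
        area = sum(
            (t.extent[1] - t.extent[0]) * (t.extent[3] - t.extent[2])
            for t in plan.tiles
        )
        assert area == pytest.approx(8000.0**2)

    def test_missing_calibration_entry_names_point(self, reference_setup):
        grid, _ = reference_setup
        short = CalibrationTable(points=grid.points[:5].copy(),
                                 coeffs=np.zeros((5, 11)))
        with pytest.raises(KeyError, match="point"):
            plan_full_fov(FOVSpec(), 4, grid, short)


def _small_world(optics, fov_um=800.0, pitch=2.0):
    """Small FOV with a one-point grid for desk-scale render tests."""
    from cmatsim.hexgrid import CorrectionGrid

    grid = CorrectionGrid(
        points=np.array([[0.0, 0.0]]), kinds=("center",),
        side=577.0, effective_radius=330.0, inclusion_radius=400.0,
    )
    table = CalibrationTable(points=grid.points.copy(), coeffs=np.zeros((1, 11)))
    fov = FOVSpec(fov_um, fov_um / 2 - 1)
    plan = plan_full_fov(fov, 2, grid, table)
    n = int(round(fov_um / pitch))
    return grid, table, fov, plan, n


class TestRenderAndFrame:
    def test_modes_identical_without_aberration(self, flat_optics):
        grid, table, fov, plan, n = _small_world(flat_optics)
        phantom = Volume(np.random.default_rng(0).uniform(
            0.5, 1.5, (1, n, n)), 2.0, 0.0)
        a = render_tile(flat_optics, phantom, plan.tiles[0], None, mode="cmat")
        b = render_tile(flat_optics, phantom, plan.tiles[0], None,
                        mode="ceao", ceao_coeffs=plan.ceao_coeffs)
        assert np.allclose(a, b)

    def test_delta_phantom_reproduces_kernel(self, flat_optics):
        grid, table, fov, plan, n = _small_world(flat_optics)
        img = np.zeros((1, n, n))
        img[0, 100, 100] = 1.0
        out = render_tile(flat_optics, Volume(img, 2.0, 0.0),
                          plan.tiles[0], None)
        from cmatsim.scanner import _kernel_for_pitch

        kernel = _kernel_for_pitch(flat_optics, plan.tiles[0].center,
                                   DMState(np.zeros(11)), 2.0)
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert out.max() == pytest.approx(kernel.max(), rel=1e-6)
        assert peak == (100, 100)

    def test_constant_phantom_scans_seamlessly(self, flat_optics):
        grid, table, fov, plan, n = _small_world(flat_optics)
        phantom = Volume(np.full((1, n, n), 2.0), 2.0, 0.0)
        frame = scan_frame(flat_optics, phantom, plan)
        rel = (frame.pixels.max() - frame.pixels.min()) / frame.pixels.mean()
        assert rel < 1e-6

    def test_provenance_and_exclusion_log(self, flat_optics):
        grid, table, fov, plan, n = _small_world(flat_optics)
        phantom = Volume(np.ones((1, n, n)), 2.0, 0.0)
        frame = scan_frame(flat_optics, phantom, plan)
        assert len(frame.provenance) == 4
        assert len(frame.excluded_log) == 4
        assert all(e["samples_kept"] == 0 for e in frame.excluded_log)

    def test_deterministic_with_noise_seed(self, flat_optics):
        grid, table, fov, plan, n = _small_world(flat_optics)
        phantom = Volume(np.full((1, n, n), 50.0), 2.0, 0.0)
        a = scan_frame(flat_optics, phantom, plan, photon_gain=1.0, seed=5)
        b = scan_frame(flat_optics, phantom, plan, photon_gain=1.0, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_edge_tile_multipoint_beats_central(self, radial_optics):
        """With a radially growing aberration, loading the local correction
        gives at least the central correction's peak signal on every tile,
        strictly more beyond the degradation onset."""
        grid = build_correction_grid(FOVSpec(), HexTilingSpec())
        rng = np.random.default_rng(3)
        for _ in range(5):
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(2000.0, 3900.0)
            pos = (r * np.cos(ang), r * np.sin(ang))
            truth_local = radial_optics.truth(pos)
            dm_cmat = DMState(-radial_optics.truth(
                grid.points[nearest_point(grid, pos)]))
            dm_ceao = DMState(-radial_optics.truth((0.0, 0.0)))
            s_cmat = radial_optics.strehl_2p(pos, dm_cmat)
            s_ceao = radial_optics.strehl_2p(pos, dm_ceao)
            assert s_cmat > s_ceao


class TestScanRoi:
    def test_roi_on_correction_point_selects_it(self, flat_optics, reference_setup):
        grid, table = reference_setup
        idx = 42
        roi = ROIRequest(center=tuple(grid.points[idx]), width=100.0,
                         height=100.0, frames=1)
        n = 128
        phantom = Volume(np.ones((1, n, n)), 1.0, 0.0)
        # phantom local to the ROI; FOV check against the full field
        frames = scan_roi(flat_optics, phantom, roi, grid, table,
                          fov=FOVSpec())
        assert frames[0].provenance[0]["point_index"] == idx

    def test_reference_roi_geometry(self):
        # functional recordings: 1000×1000 px at 0.5 µm/px = 500×500 µm
        roi = ROIRequest(center=(0.0, 0.0), width=1000 * 0.5, height=1000 * 0.5)
        assert roi.width == roi.height == 500.0

    def test_voronoi_boundary_splits_assignment(self, flat_optics, reference_setup):
        grid, table = reference_setup
        p0, p1 = grid.points[3], grid.points[4]
        mid = (p0 + p1) / 2
        delta = (p1 - p0) / np.linalg.norm(p1 - p0) * 10.0
        n = 64
        phantom = Volume(np.ones((1, n, n)), 1.0, 0.0)
        f0 = scan_roi(flat_optics, phantom,
                      ROIRequest(center=tuple(mid - delta), width=32, height=32),
                      grid, table, fov=FOVSpec())
        f1 = scan_roi(flat_optics, phantom,
                      ROIRequest(center=tuple(mid + delta), width=32, height=32),
                      grid, table, fov=FOVSpec())
        i0 = f0[0].provenance[0]["point_index"]
        i1 = f1[0].provenance[0]["point_index"]
        assert i0 != i1
        assert {i0, i1} == {3, 4}

    def test_roi_outside_fov_rejected(self, flat_optics, reference_setup):
        grid, table = reference_setup
        roi = ROIRequest(center=(3950.0, 0.0), width=200.0, height=200.0)
        phantom = Volume(np.ones((1, 32, 32)), 1.0, 0.0)
        with pytest.raises(ValueError, match="outside"):
            scan_roi(flat_optics, phantom, roi, grid, table, fov=FOVSpec())

    def test_calcium_movie_rendering(self, flat_optics, reference_setup):
        from cmatsim.phantoms import CalciumMovieSpec, make_calcium_movie

        grid, table = reference_setup
        movie = make_calcium_movie(
            CalciumMovieSpec(duration=2.0, size_px=64, n_cells=2, seed=4)
        )
        roi = ROIRequest(center=(0.0, 0.0), width=32.0, height=32.0)
        frames = scan_roi(flat_optics, movie, roi, grid, table,
                          fov=FOVSpec(), seed=9)
        assert len(frames) == movie.temporal.shape[0]
        assert frames[0].pixels.shape == movie.frames.shape[1:]
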