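"""Geometry catalogue, inlet profile, temporal envelope and flow synthesis."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from jetsr.fixtures import small_jet_geometry, patch_grid
from jetsr.geometry import (
    Direction, GeometryConfig, ShapeClass, VoxelGrid, catalogue,
    geometry_mask, inlet_profile, knn_mask, surface_points, synthesize_flow,
    temporal_envelope,
)


class TestCatalogue:
    def test_twenty_entries_with_unique_ids(self):
        cat = catalogue()
        assert len(cat) == 20
        assert [g.id for g in cat] == list(range(1, 21))

    @pytest.mark.parametrize("idx, v_I, R_I, R_C", [
        (0, 0.30, 5.0, 1.00),
        (4, 0.10, 5.0, 0.60),
        (9, 0.10, 10.0, 1.50),
    ])
    def test_basic_rows(self, idx, v_I, R_I, R_C):
        g = catalogue()[idx]
        assert (g.v_I, g.R_I, g.R_C) == (v_I, R_I, R_C)
        assert g.shape_class is ShapeClass.BASIC

    @pytest.mark.parametrize("idx, theta, delta, direction", [
        (10, 20.0, 0.00, Direction.UPWARD),
        (13, 0.0, 3.00, Direction.NONE),
        (18, 30.0, 2.25, Direction.SIDEWAYS),
        (19, 30.0, 2.25, Direction.DOWNWARD),
    ])
    def test_shaped_rows_inherit_geometry_three(self, idx, theta, delta, direction):
        g = catalogue()[idx]
        assert (g.theta, g.delta, g.direction) == (theta, delta, direction)
        base = catalogue()[2]
        assert (g.v_I, g.R_I, g.R_C) == (base.v_I, base.R_I, base.R_C)

    def test_all_have_71_frames_and_1ms_step(self):
        for g in catalogue():
            assert g.n_frames == 71
            assert g.dt == 0.001

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeometryConfig(id=0, shape_class=ShapeClass.BASIC,
                           v_I=0.3, R_I=1.0, R_C=2.0)
        with pytest.raises(ValueError):
            GeometryConfig(id=0, shape_class=ShapeClass.BASIC,
                           v_I=0.3, R_I=5.0, R_C=1.0, theta=10.0)


class TestInletProfile:
    def test_centre_and_rim(self):
        assert inlet_profile(0, 0, 0.30, 5.0) == pytest.approx(0.30)
        assert inlet_profile(3, 4, 0.77, 5.0) == pytest.approx(0.0)

    def test_interior_value(self):
        # v_I - (x^2+y^2) v_I / R_I^2 at (2.5, 2.5): 0.30 - 12.5*0.30/25
        assert inlet_profile(2.5, 2.5, 0.30, 5.0) == pytest.approx(0.15)

    def test_outside_disc_rejected(self):
        with pytest.raises(ValueError):
            inlet_profile(4.0, 4.0, 0.3, 5.0)

    def test_flux_is_half_peak_times_disc_area(self):
        # parabolic profile integrates to pi R^2 v_I / 2 over the inlet disc
        v_I, R_I, h = 0.30, 5.0, 0.1
        xs = np.arange(-R_I, R_I + h, h)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        inside = X**2 + Y**2 <= R_I**2
        v = np.where(inside, v_I - (X**2 + Y**2) * v_I / R_I**2, 0.0)
        flux = v.sum() * h * h
        assert flux == pytest.approx(np.pi * R_I**2 * v_I / 2, rel=0.01)


class TestTemporalEnvelope:
    def test_boundary_values(self):
        assert temporal_envelope(0.0, 0.02) == 0.0
        assert temporal_envelope(0.02, 0.02) == pytest.approx(1.0)
        assert temporal_envelope(0.04, 0.02) == pytest.approx(2 * np.exp(-1.0))

    def test_unimodal_rise_then_decay(self):
        t = np.linspace(0.0, 0.1, 200)
        g = temporal_envelope(t, 0.015)
        peak = np.argmax(g)
        assert np.all(np.diff(g[:peak + 1]) > 0)
        assert np.all(np.diff(g[peak:]) < 0)
        assert g.max() <= 1.0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            temporal_envelope(0.1, 0.0)


class TestSynthesizeFlow:
    def test_series_has_configured_frames_and_zero_outside_mask(self):
        geom = small_jet_geometry(n_frames=5)
        series = synthesize_flow(geom, patch_grid())
        assert series.n_frames == 5
        outside = ~series.mask
        assert np.all(series.velocity[:, outside] == 0.0)

    def test_peak_speed_in_constriction_and_above_inlet(self):
        geom = small_jet_geometry(n_frames=4)
        series = synthesize_flow(geom, patch_grid())
        speed = np.linalg.norm(series.velocity[-1], axis=-1)
        assert speed.max() > geom.v_I
        ix = np.unravel_index(np.argmax(speed), speed.shape)[0]
        x_mm = series.grid.origin[0] + ix * series.grid.spacing
        x0 = geom.upstream_length
        x1 = x0 + geom.constriction_length
        assert x0 - geom.taper_length <= x_mm <= x1 + geom.taper_length

    def test_deterministic(self):
        geom = small_jet_geometry(n_frames=3)
        a = synthesize_flow(geom, patch_grid()).velocity
        b = synthesize_flow(geom, patch_grid()).velocity
        assert np.array_equal(a, b)

    def test_time_factor_is_separable(self):
        # the envelope peak frame is the same for every voxel
        geom = small_jet_geometry(n_frames=6)
        series = synthesize_flow(geom, patch_grid())
        speed = np.linalg.norm(series.velocity, axis=-1)
        flat = speed.reshape(series.n_frames, -1)
        active = flat[:, flat.max(axis=0) > 0]
        peaks = np.argmax(active, axis=0)
        assert np.unique(peaks).size == 1

    def test_unresolvable_constriction_rejected(self):
        geom = small_jet_geometry(n_frames=2)
        with pytest.raises(ValueError):
            synthesize_flow(geom, VoxelGrid.create((32, 16, 16), spacing=2.0))

    def test_eccentric_jet_is_displaced(self):
        # an offset geometry moves the downstream jet core off the axis
        geom = small_jet_geometry(n_frames=3, shape_class=ShapeClass.OFFSET,
                                  delta=2.0)
        series = synthesize_flow(geom, patch_grid())
        speed = np.linalg.norm(series.velocity[-1], axis=-1)
        x1_vox = int((geom.upstream_length + geom.constriction_length
                      - series.grid.origin[0]) / series.grid.spacing)
        sl = speed[x1_vox]
        iy, iz = np.unravel_index(np.argmax(sl), sl.shape)
        y_mm = series.grid.origin[1] + iy * series.grid.spacing
        assert y_mm > 0.5  # displaced toward +y


class TestKnnMask:
    def test_matches_brute_force_oracle(self, rng):
        fluid = rng.uniform(0, 10, size=(40, 3))
        wall = rng.uniform(0, 10, size=(30, 3))
        grid = VoxelGrid(shape=(5, 5, 4), spacing=2.0, origin=(0.5, 0.5, 0.5))
        for k in (1, 3):
            mask = knn_mask(fluid, wall, grid, k=k)
            pts = np.vstack([fluid, wall])
            labels = np.arange(len(pts)) < len(fluid)
            d = cdist(grid.voxel_centres(), pts)
            nearest = np.argsort(d, axis=1)[:, :k]
            expect = labels[nearest].sum(axis=1) * 2 > k
            assert np.array_equal(mask.ravel(), expect)

    def test_coincident_and_far_points(self):
        grid = VoxelGrid(shape=(1, 1, 2), spacing=1.0, origin=(0.0, 0.0, 0.0))
        fluid = [[0.0, 0.0, 0.0]]
        wall = [[0.0, 0.0, 1.0]]
        mask = knn_mask(fluid, wall, grid, k=1)
        assert bool(mask[0, 0, 0]) is True
        assert bool(mask[0, 0, 1]) is False

    def test_input_validation(self):
        grid = VoxelGrid(shape=(2, 2, 2), spacing=1.0, origin=(0, 0, 0))
        with pytest.raises(ValueError):
            knn_mask(np.empty((0, 3)), [[0, 0, 0]], grid)
        with pytest.raises(ValueError):
            knn_mask([[0, 0, 0]], [[1, 1, 1]], grid, k=2)

    def test_surface_cloud_reconstructs_geometric_mask(self):
        # k-NN labelling of a dense synthetic mesh cloud approximates the
        # analytic channel mask
        geom = small_jet_geometry(n_frames=2)
        grid = VoxelGrid.create((24, 12, 12), spacing=1.0)
        fluid, wall = surface_points(geom, n_axial=160, n_ring=64, x_max=24.0)
        approx = knn_mask(fluid, wall, grid, k=1)
        exact = geometry_mask(geom, grid)
        agree = (approx == exact).mean()
        assert agree > 0.85
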