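"""Beam geometry and the sparse beam's-eye-view projection operator."""

import numpy as np
import pytest
import scipy.sparse as sp

from dosefluence.geometry import (
    BeamGeometry,
    GridSpec,
    bev_target_mask,
    beam_axes,
    build_all_operators,
    build_projection_operator,
    fluence_row_of_slice,
    gantry_source_position,
    load_operators,
    project_volume,
    backproject,
    save_operators,
)


class TestSourcePosition:
    def test_convention_anchors(self):
        # 0 deg anterior, 180 deg posterior, in (left, posterior, superior) mm
        np.testing.assert_allclose(
            gantry_source_position(0, 1000), [0, -1000, 0], atol=1e-9
        )
        np.testing.assert_allclose(
            gantry_source_position(180, 1000), [0, 1000, 0], atol=1e-9
        )

    def test_matches_rotation_matrix_oracle(self):
        th = np.deg2rad(40)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected_xy = rot @ np.array([0.0, -1000.0])
        p = gantry_source_position(40, 1000)
        np.testing.assert_allclose(p[:2], expected_xy, atol=1e-9)
        assert np.isclose(np.linalg.norm(p), 1000.0)

    def test_angle_taken_mod_360(self):
        np.testing.assert_allclose(
            gantry_source_position(400, 1000), gantry_source_position(40, 1000)
        )

    def test_rejects_nonpositive_sad(self):
        with pytest.raises(ValueError):
            gantry_source_position(0, -1.0)


def _brute_force_operator(grid, beam, beam_index):
    """Independent per-voxel ray trace (scalar math, no vectorization)."""
    angle = beam.gantry_angles_deg[beam_index]
    src = gantry_source_position(angle, beam.sad_mm)
    axis, col_ax, row_ax = beam_axes(angle)
    rows_f, cols_f = beam.fluence_shape
    pitch = beam.fluence_pitch_mm
    entries = {}
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.spacing
    ox, oy, oz = grid.origin
    i = 0
    for k in range(nz):
        for r in range(ny):
            for c in range(nx):
                p = np.array([ox + c * dx, oy + r * dy, oz + k * dz])
                d = np.linalg.norm(p - src)
                denom = beam.sad_mm + float(p @ axis)
                if denom > 1e-9:
                    t = beam.sad_mm / denom
                    q = src + t * (p - src)
                    cc = float(q @ col_ax) / pitch + (cols_f - 1) / 2
                    rr = float(q @ row_ax) / pitch + (rows_f - 1) / 2
                    ci = int(np.ceil(cc - 0.5))
                    ri = int(np.ceil(rr - 0.5))
                    if 0 <= ci < cols_f and 0 <= ri < rows_f:
                        entries[(i, ri * cols_f + ci)] = (beam.sad_mm / d) ** 2
                i += 1
    return entries


class TestProjectionOperator:
    @pytest.mark.parametrize("beam_index", [0, 2, 5])
    def test_matches_exhaustive_ray_trace_oracle(self, beam_index):
        grid = GridSpec(shape=(4, 4, 4), spacing=(2.5, 2.5, 2.5))
        beam = BeamGeometry(fluence_shape=(8, 8))
        op = build_projection_operator(grid, beam, beam_index)
        oracle = _brute_force_operator(grid, beam, beam_index)
        coo = op.matrix.tocoo()
        got = {(int(i), int(j)): v for i, j, v in zip(coo.row, coo.col, coo.data)}
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key] == pytest.approx(oracle[key], rel=1e-12)

    def test_isocenter_voxel_unit_weight_at_central_pixel(self):
        # odd-shaped grid so a voxel center sits exactly at the isocenter
        grid = GridSpec(shape=(5, 5, 5), spacing=(2.5, 2.5, 2.5))
        beam = BeamGeometry(fluence_shape=(9, 9))
        op = build_projection_operator(grid, beam, 0)
        center_vox = np.ravel_multi_index((2, 2, 2), grid.shape)
        row = op.matrix.getrow(center_vox)
        assert row.nnz == 1
        assert row.indices[0] == 4 * 9 + 4  # central-axis pixel
        assert row.data[0] == pytest.approx(1.0)

    def test_inverse_square_quarter_weight_at_doubled_distance(self):
        beam = BeamGeometry(fluence_shape=(9, 9))
        # isocenter voxel (distance SAD) vs voxel SAD further along the axis
        grid = GridSpec(
            shape=(1, 2, 1), spacing=(2.5, 1000.0, 2.5), origin=(0.0, 0.0, 0.0)
        )
        op = build_projection_operator(grid, beam, 0)  # beam 0: source anterior
        w_iso = op.matrix[0, :].toarray().max()
        w_far = op.matrix[1, :].toarray().max()
        assert w_iso == pytest.approx(1.0)
        assert w_far == pytest.approx(0.25)

    def test_every_weight_reproduces_inverse_square_from_geometry(self, micro_ops, micro_case):
        op = micro_ops[3]
        pts = micro_case.grid.voxel_centers()
        src = gantry_source_position(op.angle_deg, op.beam.sad_mm)
        coo = op.matrix.tocoo()
        d = np.linalg.norm(pts[coo.row] - src, axis=1)
        np.testing.assert_allclose(coo.data, (op.beam.sad_mm / d) ** 2, rtol=1e-9)

    def test_at_most_one_entry_per_voxel(self, micro_ops):
        counts = np.diff(micro_ops[0].matrix.indptr)
        assert counts.max() <= 1

    def test_axis_parallel_column_lands_in_one_beamlet(self):
        # voxels along the central axis of the anterior beam project to the
        # central-axis pixel only (nearest-neighbor splatting)
        grid = GridSpec(shape=(1, 9, 1), spacing=(2.5, 10.0, 2.5))
        beam = BeamGeometry(fluence_shape=(9, 9))
        op = build_projection_operator(grid, beam, 0)
        coo = op.matrix.tocoo()
        assert coo.nnz == 9
        assert set(coo.col) == {4 * 9 + 4}


class TestProjectVolume:
    def test_zero_volume_projects_to_zero(self, micro_ops, micro_case):
        f = project_volume(micro_ops[0], np.zeros(micro_case.grid.shape))
        assert f.shape == micro_case.beams.fluence_shape
        assert not f.any()

    def test_linearity(self, micro_ops, micro_case, rng):
        op = micro_ops[1]
        v1 = rng.normal(size=micro_case.grid.shape)
        v2 = rng.normal(size=micro_case.grid.shape)
        a = 2.7
        np.testing.assert_allclose(
            project_volume(op, a * v1 + v2),
            a * project_volume(op, v1) + project_volume(op, v2),
            rtol=1e-9, atol=1e-12,
        )

    def test_matches_dense_matrix_oracle(self, rng):
        grid = GridSpec(shape=(4, 6, 6))
        beam = BeamGeometry(fluence_shape=(12, 12))
        op = build_projection_operator(grid, beam, 4)
        v = rng.normal(size=grid.shape)
        dense = op.matrix.toarray()
        expected = (dense.T @ v.ravel()).reshape(12, 12)
        np.testing.assert_allclose(project_volume(op, v), expected, rtol=1e-12)

    def test_adjoint_identity(self, micro_ops, rng):
        # <P^T v, f> == <v, P f> to 1e-6 relative
        for op in micro_ops[:3]:
            v = rng.normal(size=op.grid.shape)
            f = rng.normal(size=op.fluence_shape)
            lhs = float(np.sum(project_volume(op, v) * f))
            rhs = float(np.sum(v * backproject(op, f)))
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_shape_mismatch_raises(self, micro_ops):
        with pytest.raises(ValueError):
            project_volume(micro_ops[0], np.zeros((2, 2, 2)))


class TestBevTargetMask:
    def test_empty_ptv_gives_empty_mask_with_warning(self, micro_ops, micro_case):
        with pytest.warns(UserWarning, match="empty PTV"):
            m = bev_target_mask(np.zeros(micro_case.grid.shape), micro_ops[0])
        assert not m.any()

    def test_single_voxel_matches_dilation_oracle(self):
        grid = GridSpec(shape=(5, 5, 5), spacing=(2.5, 2.5, 2.5))
        beam = BeamGeometry(fluence_shape=(9, 9))
        op = build_projection_operator(grid, beam, 0)
        ptv = np.zeros(grid.shape)
        ptv[2, 2, 2] = 1  # isocenter voxel -> central pixel
        m = bev_target_mask(ptv, op, margin_mm=5.0)
        yy, xx = np.mgrid[0:9, 0:9]
        oracle = (yy - 4) ** 2 + (xx - 4) ** 2 <= 4 + 1e-9  # 2 px radius
        np.testing.assert_array_equal(m, oracle)

    def test_zero_margin_equals_raw_footprint(self, micro_ops, micro_case):
        ptv = micro_case.ptv_dose_mask > 0
        raw = project_volume(micro_ops[2], ptv.astype(float)) > 0
        np.testing.assert_array_equal(bev_target_mask(ptv, micro_ops[2], 0.0), raw)

    def test_monotone_in_margin(self, micro_ops, micro_case):
        ptv = micro_case.ptv_dose_mask > 0
        prev = None
        for margin in (0.0, 2.5, 5.0, 10.0):
            m = bev_target_mask(ptv, micro_ops[0], margin)
            if prev is not None:
                assert np.all(prev <= m)
            prev = m


class TestPatchRestriction:
    def test_restricted_projection_truncates_edges_only(self, rng):
        """Edge fluence rows of a patch lose contributions from voxels
        outside the slab (beam divergence); interior rows agree exactly
        with the full-volume projection."""
        # wide transverse extent so divergence displaces projections by
        # more than a fluence row at the slab edges
        grid = GridSpec(shape=(16, 64, 64), spacing=(2.5, 5.0, 5.0))
        beam = BeamGeometry(fluence_shape=(80, 80))
        op = build_projection_operator(grid, beam, 0)
        s0, s1 = 4, 12  # centered 8-slice slab
        r0 = int(fluence_row_of_slice(grid, beam, s0))
        patch_op = op.restrict(s0, s1, r0, r0 + (s1 - s0))
        v = rng.random(size=grid.shape)
        full = project_volume(op, v)[r0 : r0 + (s1 - s0)]
        patch = project_volume(patch_op, v[s0:s1])
        trim = 3
        np.testing.assert_allclose(patch[trim:-trim], full[trim:-trim], rtol=1e-12)
        assert np.abs(patch[0] - full[0]).max() > 1e-9
        assert np.abs(patch[-1] - full[-1]).max() > 1e-9

    def test_slice_rows_align_with_fluence_rows(self, micro_case):
        rows = fluence_row_of_slice(
            micro_case.grid, micro_case.beams, np.arange(micro_case.grid.shape[0])
        )
        np.testing.assert_allclose(rows, np.round(rows), atol=1e-9)


class TestSerialization:
    def test_hdf5_round_trip_bit_exact(self, micro_ops, tmp_path):
        path = tmp_path / "ops.h5"
        save_operators(path, micro_ops)
        loaded = load_operators(path)
        assert len(loaded) == len(micro_ops)
        for a, b in zip(micro_ops, loaded):
            assert a.angle_deg == b.angle_deg
            assert (a.matrix != b.matrix).nnz == 0
            assert a.grid == b.grid
            assert a.beam == b.beam
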