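"""Grids, beam geometry and the divergent-beam 3D->2D projection operator.

Coordinate conventions (fixed; all other modules rely on them):

* Physical frame: right-handed ``(x, y, z) = (left, posterior, superior)``
  in mm with the origin at the plan isocenter.
* Array axes: volumes are indexed ``[slice, row, col]`` which map to the
  physical axes ``(z, y, x)`` — i.e. axis 0 runs inferior->superior,
  axis 1 anterior->posterior, axis 2 right->left.
* Gantry angle 0 deg puts the source on the anterior side of the patient;
  the angle increases toward patient-left (IEC-like).  The fluence-plane
  row axis is parallel to the superior-inferior (rotation) axis, so at the
  isocenter plane fluence rows align one-to-one with CT slices; columns
  run toward patient-left for the 0 deg beam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

__all__ = [
    "GridSpec",
    "BeamGeometry",
    "ProjectionOperator",
    "gantry_source_position",
    "beam_axes",
    "build_projection_operator",
    "build_all_operators",
    "project_volume",
    "backproject",
    "bev_target_mask",
    "fluence_row_of_slice",
    "save_operators",
    "load_operators",
]

DEFAULT_ANGLES = (0.0, 40.0, 80.0, 120.0, 160.0, 200.0, 240.0, 280.0, 320.0)


@dataclass(frozen=True)
class GridSpec:
    """Volumetric grid: ``shape=(n_slices, height, width)`` voxels.

    ``spacing`` is mm per axis in array order (z, y, x); ``origin`` is the
    physical (x, y, z) mm coordinate of the center of voxel ``[0, 0, 0]``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if len(self.shape) != 3:
            raise ValueError("shape must be (n_slices, height, width)")
        if self.origin is None:
            # center the grid on the isocenter
            nz, ny, nx = self.shape
            dz, dy, dx = self.spacing
            object.__setattr__(
                self,
                "origin",
                (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -(nz - 1) / 2 * dz),
            )
        ox, oy, oz = self.origin
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing
        # isocenter (0,0,0) must lie inside the grid extent
        if not (
            ox - dx / 2 <= 0 <= ox + (nx - 0.5) * dx
            and oy - dy / 2 <= 0 <= oy + (ny - 0.5) * dy
            and oz - dz / 2 <= 0 <= oz + (nz - 0.5) * dz
        ):
            raise ValueError("isocenter must lie inside the grid")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> np.ndarray:
        """Physical (x, y, z) mm coordinates of all voxel centers.

        Returns an array of shape ``(n_voxels, 3)`` in C order over
        ``[slice, row, col]``.
        """
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing
        ox, oy, oz = self.origin
        k, i, j = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        pts = np.empty((self.n_voxels, 3), dtype=np.float64)
        pts[:, 0] = ox + j.ravel() * dx
        pts[:, 1] = oy + i.ravel() * dy
        pts[:, 2] = oz + k.ravel() * dz
        return pts


@dataclass(frozen=True)
class BeamGeometry:
    """Nine-field coplanar beam arrangement and fluence-plane raster.

    The fluence plane sits at the isocenter, perpendicular to each beam's
    central axis, with ``fluence_shape=(rows, cols)`` pixels at
    ``fluence_pitch_mm`` pitch centered on the central axis.
    """

    gantry_angles_deg: tuple[float, ...] = DEFAULT_ANGLES
    sad_mm: float = 1000.0
    fluence_shape: tuple[int, int] = (160, 160)
    fluence_pitch_mm: float = 2.5

    def __post_init__(self):
        ang = [a % 360.0 for a in self.gantry_angles_deg]
        if len(set(ang)) != len(ang):
            raise ValueError("gantry angles must be unique")
        if self.sad_mm <= 0:
            raise ValueError("sad_mm must be positive")
        object.__setattr__(self, "gantry_angles_deg", tuple(ang))

    @property
    def n_beams(self) -> int:
        return len(self.gantry_angles_deg)

    @property
    def n_beamlets(self) -> int:
        return self.fluence_shape[0] * self.fluence_shape[1]


def gantry_source_position(angle_deg: float, sad_mm: float) -> np.ndarray:
    """Source position (x, y, z) mm for a gantry angle.

    Angle 0 deg places the source anteriorly at ``(0, -sad, 0)``; the angle
    increases toward patient-left.  The angle is taken modulo 360.
    """
    if sad_mm <= 0:
        raise ValueError("sad_mm must be positive")
    th = np.deg2rad(angle_deg % 360.0)
    return np.array([sad_mm * np.sin(th), -sad_mm * np.cos(th), 0.0])


def beam_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors ``(axis, col_axis, row_axis)`` of a beam.

    ``axis`` points from source toward isocenter; ``col_axis`` spans fluence
    columns (patient-left for the 0 deg beam); ``row_axis`` is superior.
    """
    th = np.deg2rad(angle_deg % 360.0)
    axis = np.array([-np.sin(th), np.cos(th), 0.0])
    col = np.array([np.cos(th), np.sin(th), 0.0])
    row = np.array([0.0, 0.0, 1.0])
    return axis, col, row


@dataclass
class ProjectionOperator:
    """Sparse voxel->beamlet projection matrix for one beam.

    ``matrix`` has shape ``(n_voxels, n_beamlets)``; entry ``(i, j)`` is the
    inverse-square weight ``(SAD / d_i)**2`` of voxel ``i`` splatted onto
    beamlet ``j`` (nearest-neighbor: at most one entry per voxel row).
    Voxels whose ray misses the fluence plane carry no entry and are counted
    in ``n_truncated``.
    """

    beam_index: int
    angle_deg: float
    matrix: sp.csr_matrix
    grid: GridSpec
    beam: BeamGeometry
    n_truncated: int = 0
    fluence_shape: tuple[int, int] = (160, 160)
    slice_range: tuple[int, int] | None = None  # set on patch restriction
    row_range: tuple[int, int] | None = None

    def restrict(
        self, slice_start: int, slice_stop: int, row_start: int, row_stop: int
    ) -> "ProjectionOperator":
        """Restrict to a slab of slices and a window of fluence rows.

        Rows of ``matrix`` are cut to the voxels of slices
        ``[slice_start, slice_stop)``; columns to fluence rows
        ``[row_start, row_stop)``.  Entries whose beamlet falls outside the
        row window are dropped — this reproduces the truncated-projection
        edge effect of patch-wise training (divergent rays from slab voxels
        can land on fluence rows outside the slab's own row window).
        """
        nz, ny, nx = self.grid.shape
        rows_f, cols_f = self.fluence_shape
        if not (0 <= slice_start < slice_stop <= nz):
            raise ValueError("slice range out of bounds")
        if not (0 <= row_start < row_stop <= rows_f):
            raise ValueError("fluence row range out of bounds")
        v0, v1 = slice_start * ny * nx, slice_stop * ny * nx
        sub = self.matrix[v0:v1, :].tocoo()
        brow, bcol = np.divmod(sub.col, cols_f)
        keep = (brow >= row_start) & (brow < row_stop)
        new_cols = (brow[keep] - row_start) * cols_f + bcol[keep]
        mat = sp.csr_matrix(
            (sub.data[keep], (sub.row[keep], new_cols)),
            shape=(v1 - v0, (row_stop - row_start) * cols_f),
        )
        return ProjectionOperator(
            beam_index=self.beam_index,
            angle_deg=self.angle_deg,
            matrix=mat,
            grid=self.grid,
            beam=self.beam,
            n_truncated=self.n_truncated + int(np.sum(~keep)),
            fluence_shape=(row_stop - row_start, cols_f),
            slice_range=(slice_start, slice_stop),
            row_range=(row_start, row_stop),
        )


def fluence_row_of_slice(grid: GridSpec, beam: BeamGeometry, k) -> np.ndarray:
    """Fluence-plane row index aligned with CT slice ``k`` at the isocenter.

    Fractional in general; integral when slice centers coincide with row
    centers (the case for the isocenter-centered default grids).
    """
    oz = grid.origin[2]
    z = oz + np.asarray(k, dtype=float) * grid.spacing[0]
    return z / beam.fluence_pitch_mm + (beam.fluence_shape[0] - 1) / 2.0


def _nearest_pixel(coord: np.ndarray) -> np.ndarray:
    # ties broken toward the lower index: ceil(x - 0.5)
    return np.ceil(coord - 0.5).astype(np.int64)


def build_projection_operator(
    grid: GridSpec, beam: BeamGeometry, beam_index: int
) -> ProjectionOperator:
    """Ray-trace every voxel through the fluence plane for one beam.

    For voxel center ``p`` the ray from the source ``s`` through ``p`` is
    intersected with the isocenter plane perpendicular to the central axis;
    the intersection is splatted onto the nearest beamlet pixel with weight
    ``(SAD / |p - s|)**2`` (inverse-square only; no attenuation).
    """
    if not (0 <= beam_index < beam.n_beams):
        raise ValueError("beam_index out of range")
    angle = beam.gantry_angles_deg[beam_index]
    sad = beam.sad_mm
    src = gantry_source_position(angle, sad)
    axis, col_ax, row_ax = beam_axes(angle)
    rows_f, cols_f = beam.fluence_shape
    pitch = beam.fluence_pitch_mm

    p = grid.voxel_centers()
    rel = p - src
    d = np.linalg.norm(rel, axis=1)
    denom = sad + p @ axis  # distance from source along the central axis
    ok = denom > 1e-9
    t = np.zeros_like(d)
    t[ok] = sad / denom[ok]
    q = src + t[:, None] * rel  # intersection with the isocenter plane
    col_mm = q @ col_ax
    row_mm = q @ row_ax
    ci = _nearest_pixel(col_mm / pitch + (cols_f - 1) / 2.0)
    ri = _nearest_pixel(row_mm / pitch + (rows_f - 1) / 2.0)
    inside = ok & (ci >= 0) & (ci < cols_f) & (ri >= 0) & (ri < rows_f)

    vox_idx = np.flatnonzero(inside)
    beamlet = ri[inside] * cols_f + ci[inside]
    weight = (sad / d[inside]) ** 2
    mat = sp.csr_matrix(
        (weight, (vox_idx, beamlet)),
        shape=(grid.n_voxels, rows_f * cols_f),
    )
    return ProjectionOperator(
        beam_index=beam_index,
        angle_deg=angle,
        matrix=mat,
        grid=grid,
        beam=beam,
        n_truncated=int(np.sum(~inside)),
        fluence_shape=(rows_f, cols_f),
    )


def build_all_operators(grid: GridSpec, beam: BeamGeometry) -> list[ProjectionOperator]:
    """Projection operators for every beam, ordered by ascending angle."""
    order = np.argsort(beam.gantry_angles_deg)
    if not np.array_equal(order, np.arange(beam.n_beams)):
        raise ValueError("gantry_angles_deg must be sorted ascending")
    return [build_projection_operator(grid, beam, b) for b in range(beam.n_beams)]


def project_volume(op: ProjectionOperator, v: np.ndarray) -> np.ndarray:
    """``f = P^T v``: project a feature volume onto the fluence plane."""
    if v.size != op.matrix.shape[0]:
        raise ValueError(
            f"volume has {v.size} voxels, operator expects {op.matrix.shape[0]}"
        )
    f = op.matrix.T @ np.asarray(v, dtype=np.float64).ravel()
    return f.reshape(op.fluence_shape)


def backproject(op: ProjectionOperator, f: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`project_volume`: ``v = P f`` (gradient propagation)."""
    if f.size != op.matrix.shape[1]:
        raise ValueError("fluence map does not match operator beamlet count")
    v = op.matrix @ np.asarray(f, dtype=np.float64).ravel()
    if op.slice_range is not None:
        nz = op.slice_range[1] - op.slice_range[0]
        return v.reshape((nz,) + op.grid.shape[1:])
    return v.reshape(op.grid.shape)


def _disc(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= radius_px * radius_px + 1e-9


def bev_target_mask(
    ptv_mask: np.ndarray, op: ProjectionOperator, margin_mm: float = 5.0
) -> np.ndarray:
    """Beam's-eye-view footprint of the PTV, dilated by ``margin_mm``.

    Pixels receiving any nonzero projection from PTV voxels, morphologically
    dilated by a Euclidean disc of radius ``margin_mm`` (2 px at 2.5 mm).
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    footprint = project_volume(op, (np.asarray(ptv_mask) > 0).astype(np.float64)) > 0
    if not footprint.any():
        warnings.warn("empty PTV produces an empty BEV mask", stacklevel=2)
        return footprint
    radius_px = margin_mm / op.beam.fluence_pitch_mm
    if radius_px < 1:
        return footprint
    return ndimage.binary_dilation(footprint, structure=_disc(radius_px))


# ---------------------------------------------------------------------------
# HDF5 persistence: COO triplets + geometry metadata, bit-exact round trip.

def save_operators(path, ops: list[ProjectionOperator]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "dosefluence-projection"
        f.attrs["version"] = 1
        g = ops[0]
        f.attrs["grid_shape"] = g.grid.shape
        f.attrs["grid_spacing"] = g.grid.spacing
        f.attrs["grid_origin"] = g.grid.origin
        f.attrs["sad_mm"] = g.beam.sad_mm
        f.attrs["fluence_shape"] = g.beam.fluence_shape
        f.attrs["fluence_pitch_mm"] = g.beam.fluence_pitch_mm
        f.attrs["gantry_angles_deg"] = g.beam.gantry_angles_deg
        for op in ops:
            coo = op.matrix.tocoo()
            grp = f.create_group(f"beam_{op.beam_index:02d}")
            grp.attrs["angle_deg"] = op.angle_deg
            grp.attrs["n_truncated"] = op.n_truncated
            grp.create_dataset("i", data=coo.row)
            grp.create_dataset("j", data=coo.col)
            grp.create_dataset("value", data=coo.data)


def load_operators(path) -> list[ProjectionOperator]:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "dosefluence-projection":
            raise ValueError("not a projection-operator file")
        grid = GridSpec(
            shape=tuple(int(x) for x in f.attrs["grid_shape"]),
            spacing=tuple(float(x) for x in f.attrs["grid_spacing"]),
            origin=tuple(float(x) for x in f.attrs["grid_origin"]),
        )
        beam = BeamGeometry(
            gantry_angles_deg=tuple(float(a) for a in f.attrs["gantry_angles_deg"]),
            sad_mm=float(f.attrs["sad_mm"]),
            fluence_shape=tuple(int(x) for x in f.attrs["fluence_shape"]),
            fluence_pitch_mm=float(f.attrs["fluence_pitch_mm"]),
        )
        ops = []
        for b in range(beam.n_beams):
            grp = f[f"beam_{b:02d}"]
            mat = sp.csr_matrix(
                (grp["value"][:], (grp["i"][:], grp["j"][:])),
                shape=(grid.n_voxels, beam.n_beamlets),
            )
            ops.append(
                ProjectionOperator(
                    beam_index=b,
                    angle_deg=float(grp.attrs["angle_deg"]),
                    matrix=mat,
                    grid=grid,
                    beam=beam,
                    n_truncated=int(grp.attrs["n_truncated"]),
                    fluence_shape=beam.fluence_shape,
                )
            )
    return ops
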