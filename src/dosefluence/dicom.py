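"""Optional DICOM-RT ingest: CT + RTSTRUCT + RTDOSE + RTPLAN -> PatientCase.

Everything is resampled onto the package's isocenter-centered 2.5 mm grid
(trilinear for CT and dose, polygon rasterization for contours); fluence
is reconstructed from the RTPLAN control-point sequences.  DICOM patient
coordinates (LPS) coincide with the package's (left, posterior, superior)
frame.  Requires :mod:`pydicom`; import of this module fails without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

try:
    import pydicom
except ImportError as exc:  # pragma: no cover - guarded optional extra
    raise ImportError(
        "DICOM ingest requires the optional 'pydicom' dependency "
        "(pip install dosefluence[dicom])"
    ) from exc

from .fluence import ControlPoint, MlcModel, fluence_from_control_points, stack_plan_fluence
from .geometry import BeamGeometry, GridSpec
from .phantom import OAR_NAMES, PTV_NAMES, PatientCase

__all__ = ["ingest_dicom", "read_rtplan_fields"]


def _scan(directory):
    found = {"CT": [], "RTSTRUCT": None, "RTDOSE": None, "RTPLAN": None}
    for p in sorted(Path(directory).glob("*.dcm")):
        ds = pydicom.dcmread(p)
        modality = getattr(ds, "Modality", None)
        if modality == "CT":
            found["CT"].append(ds)
        elif modality in ("RTSTRUCT", "RTDOSE", "RTPLAN"):
            found[modality] = ds
    return found


def _ct_volume(slices):
    slices = sorted(slices, key=lambda s: float(s.ImagePositionPatient[2]))
    vol = np.stack(
        [
            s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
            + float(getattr(s, "RescaleIntercept", 0.0))
            for s in slices
        ]
    )
    s0 = slices[0]
    origin = np.array([float(v) for v in s0.ImagePositionPatient])  # (x, y, z) of row0/col0
    dy, dx = (float(v) for v in s0.PixelSpacing)
    dz = (
        float(slices[1].ImagePositionPatient[2]) - origin[2]
        if len(slices) > 1
        else float(getattr(s0, "SliceThickness", 1.0))
    )
    return vol, origin, (dz, dy, dx)


def _resample(vol, origin, spacing, grid: GridSpec, iso, order, cval):
    """Sample a DICOM-gridded volume at the target grid's voxel centers."""
    pts = grid.voxel_centers() + np.asarray(iso)[None, :]  # absolute (x, y, z) mm
    iz = (pts[:, 2] - origin[2]) / spacing[0]
    iy = (pts[:, 1] - origin[1]) / spacing[1]
    ix = (pts[:, 0] - origin[0]) / spacing[2]
    out = ndimage.map_coordinates(
        np.asarray(vol, dtype=np.float64), [iz, iy, ix],
        order=order, mode="constant", cval=cval,
    )
    return out.reshape(grid.shape)


def _rasterize_struct(ds, grid: GridSpec, iso):
    """ROI name -> boolean mask on the target grid."""
    from skimage.draw import polygon as draw_polygon

    roi_names = {
        int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence
    }
    masks = {}
    dz, dy, dx = grid.spacing
    ox, oy, oz = grid.origin
    nz, ny, nx = grid.shape
    for roi in ds.ROIContourSequence:
        name = roi_names[int(roi.ReferencedROINumber)]
        mask = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            rel = data - np.asarray(iso)[None, :]
            k = int(round((rel[0, 2] - oz) / dz))
            if not (0 <= k < nz):
                continue
            rows = (rel[:, 1] - oy) / dy
            cols = (rel[:, 0] - ox) / dx
            rr, cc = draw_polygon(rows, cols, shape=(ny, nx))
            mask[k, rr, cc] = True
        masks[name] = mask
    return masks


def read_rtplan_fields(ds, pitch_mm: float = 2.5):
    """Per-field (gantry_angle, field_mu, [ControlPoint]) from an RTPLAN.

    Supports MLCX leaf banks with ASYMX/ASYMY (or X/Y) jaws; leaf
    boundaries come from the BeamLimitingDeviceSequence.
    """
    metersets = {}
    for fg in ds.FractionGroupSequence:
        for rb in fg.ReferencedBeamSequence:
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    fields = []
    boundaries = None
    for beam in ds.BeamSequence:
        n_pairs = None
        for bld in beam.BeamLimitingDeviceSequence:
            if bld.RTBeamLimitingDeviceType == "MLCX":
                boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
                n_pairs = int(bld.NumberOfLeafJawPairs)
        if n_pairs is None:
            raise ValueError(f"beam {beam.BeamNumber}: no MLCX device")
        angle = None
        jaws = [None, None, None, None]
        cps = []
        for cp in beam.ControlPointSequence:
            if hasattr(cp, "GantryAngle"):
                angle = float(cp.GantryAngle)
            mlc = None
            for pos in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = pos.RTBeamLimitingDeviceType
                vals = np.asarray(pos.LeafJawPositions, dtype=float)
                if kind == "MLCX":
                    mlc = vals
                elif kind in ("ASYMX", "X"):
                    jaws[0], jaws[1] = vals
                elif kind in ("ASYMY", "Y"):
                    jaws[2], jaws[3] = vals
            if mlc is None:
                if not cps:
                    raise ValueError("first control point lacks MLC positions")
                prev = cps[-1]
                left, right = prev.mlc_left, prev.mlc_right
            else:
                left, right = mlc[:n_pairs], mlc[n_pairs:]
            cps.append(
                ControlPoint(
                    cumulative_meterset_weight=float(cp.CumulativeMetersetWeight),
                    mlc_left=left,
                    mlc_right=right,
                    jaws=tuple(float(j) for j in jaws),
                )
            )
        fields.append((angle, metersets[int(beam.BeamNumber)], cps))
    return fields, boundaries


def ingest_dicom(
    directory,
    grid: GridSpec | None = None,
    beams: BeamGeometry | None = None,
    structure_map: dict[str, str] | None = None,
    prescriptions: dict[str, float] | None = None,
    mlc_model: MlcModel | None = None,
):
    """Build a :class:`PatientCase` from a directory of DICOM files.

    ``structure_map`` maps RTSTRUCT ROI names onto the package's canonical
    PTV/OAR names; unmapped ROIs are ignored.  Returns ``(case, info)``;
    ``info['fluence_available']`` is False when no RTPLAN was found, and
    the caller is responsible for final validation (clinical contours may
    violate the synthetic-case invariants).
    """
    found = _scan(directory)
    if not found["CT"]:
        raise ValueError(f"{directory}: no CT series found")
    if found["RTSTRUCT"] is None:
        raise ValueError(f"{directory}: no RTSTRUCT found")
    beams = beams or BeamGeometry()
    vol, ct_origin, ct_spacing = _ct_volume(found["CT"])

    if found["RTPLAN"] is not None and hasattr(found["RTPLAN"], "BeamSequence"):
        iso = np.asarray(
            found["RTPLAN"].BeamSequence[0].ControlPointSequence[0].IsocenterPosition,
            dtype=float,
        )
    else:
        center = ct_origin + np.array(
            [
                (vol.shape[2] - 1) / 2 * ct_spacing[2],
                (vol.shape[1] - 1) / 2 * ct_spacing[1],
                (vol.shape[0] - 1) / 2 * ct_spacing[0],
            ]
        )
        iso = center
    if grid is None:
        grid = GridSpec(shape=(max(16, vol.shape[0]), 224, 224))

    ct = _resample(vol, ct_origin, ct_spacing, grid, iso, order=1, cval=-1000.0)

    raw_masks = _rasterize_struct(found["RTSTRUCT"], grid, iso)
    structure_map = structure_map or {n: n for n in raw_masks}
    ptv_masks = {n: np.zeros(grid.shape, dtype=bool) for n in PTV_NAMES}
    oar_masks = {n: np.zeros(grid.shape, dtype=bool) for n in OAR_NAMES}
    for roi_name, mask in raw_masks.items():
        target = structure_map.get(roi_name)
        if target in ptv_masks:
            ptv_masks[target] |= mask
        elif target in oar_masks:
            oar_masks[target] |= mask

    prescriptions = prescriptions or {}
    pdm = np.zeros(grid.shape)
    for name in PTV_NAMES:
        level = prescriptions.get(name, 0.0)
        m = ptv_masks[name]
        pdm[m] = np.maximum(pdm[m], level)

    dose = None
    if found["RTDOSE"] is not None:
        dd = found["RTDOSE"]
        dvol = dd.pixel_array * float(dd.DoseGridScaling) * 100.0  # Gy -> cGy
        dorigin = np.array([float(v) for v in dd.ImagePositionPatient])
        offs = np.asarray(dd.GridFrameOffsetVector, dtype=float)
        dspacing = (
            float(offs[1] - offs[0]) if len(offs) > 1 else 1.0,
            float(dd.PixelSpacing[0]),
            float(dd.PixelSpacing[1]),
        )
        dorigin = dorigin + np.array([0.0, 0.0, offs[0]])
        dose = _resample(dvol, dorigin, dspacing, grid, iso, order=1, cval=0.0)

    fluence = None
    fluence_available = found["RTPLAN"] is not None
    if fluence_available:
        fields, boundaries = read_rtplan_fields(found["RTPLAN"])
        model = mlc_model or MlcModel(leaf_boundaries_mm=boundaries)
        maps = [
            (
                angle,
                fluence_from_control_points(
                    seq, mu, model, beams.fluence_shape, beams.fluence_pitch_mm
                ),
            )
            for angle, mu, seq in fields
        ]
        fluence = stack_plan_fluence(
            maps, expected_shape=beams.fluence_shape, n_beams=len(maps)
        )

    case = PatientCase(
        grid=grid,
        beams=beams,
        ct=ct,
        ptv_masks=ptv_masks,
        oar_masks=oar_masks,
        prescriptions=prescriptions,
        ptv_dose_mask=pdm,
        dose=dose,
        fluence=fluence,
    )
    info = {
        "isocenter_mm": iso.tolist(),
        "fluence_available": fluence_available,
        "rois": sorted(raw_masks),
    }
    return case, info
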