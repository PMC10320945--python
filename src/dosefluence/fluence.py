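"""Ground-truth fluence reconstruction from MLC control-point sequences.

A delivered IMRT field is a sequence of control points, each a snapshot of
machine state (per-leaf-pair MLC positions, jaw positions, cumulative
meterset weight).  The field's fluence map is the meterset-weighted sum of
aperture transmission masks over the delivery segments, scaled by the field
monitor units.  Rounded leaf ends are modeled by the dosimetric leaf gap
(DLG): each leaf-pair opening is widened by DLG/2 on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControlPoint",
    "MlcModel",
    "aperture_transmission_mask",
    "fluence_from_control_points",
    "stack_plan_fluence",
    "unstack_plan_fluence",
]


@dataclass(frozen=True)
class ControlPoint:
    """Machine-state snapshot within a field's delivery sequence.

    Leaf and jaw positions are mm at the isocenter plane.  ``mlc_left`` /
    ``mlc_right`` are the crossplane (column-axis) positions of the two leaf
    banks, one value per leaf pair ordered by ascending inplane coordinate.
    ``jaws`` is ``(x1, x2, y1, y2)`` with x crossplane and y inplane.
    """

    cumulative_meterset_weight: float
    mlc_left: np.ndarray
    mlc_right: np.ndarray
    jaws: tuple[float, float, float, float]

    def __post_init__(self):
        left = np.asarray(self.mlc_left, dtype=np.float64)
        right = np.asarray(self.mlc_right, dtype=np.float64)
        object.__setattr__(self, "mlc_left", left)
        object.__setattr__(self, "mlc_right", right)
        if left.shape != right.shape or left.ndim != 1:
            raise ValueError("mlc_left/mlc_right must be 1D arrays of equal length")
        if np.any(left > right + 1e-9):
            raise ValueError("mlc_left must not exceed mlc_right")
        x1, x2, y1, y2 = self.jaws
        if not (x1 < x2 and y1 < y2):
            raise ValueError("jaws must satisfy x1 < x2 and y1 < y2")
        if not (0.0 <= self.cumulative_meterset_weight <= 1.0 + 1e-9):
            raise ValueError("cumulative meterset weight must be in [0, 1]")


@dataclass(frozen=True)
class MlcModel:
    """MLC/jaw transmission parameters.

    ``transmission`` and ``dosimetric_leaf_gap_mm`` are machine-commissioning
    values (unpublished for the clinical TPS); the defaults are plausible
    placeholders for a Millennium-style MLC and both are required
    configuration, not constants.
    """

    leaf_boundaries_mm: np.ndarray
    transmission: float = 0.015
    dosimetric_leaf_gap_mm: float = 1.4
    jaw_transmission: float = 0.0

    def __post_init__(self):
        b = np.asarray(self.leaf_boundaries_mm, dtype=np.float64)
        object.__setattr__(self, "leaf_boundaries_mm", b)
        if b.ndim != 1 or b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("leaf_boundaries_mm must be strictly increasing")
        if not (0.0 <= self.transmission < 1.0):
            raise ValueError("transmission must be in [0, 1)")
        if self.dosimetric_leaf_gap_mm < 0:
            raise ValueError("dosimetric leaf gap must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.leaf_boundaries_mm.size - 1

    @classmethod
    def uniform(
        cls,
        n_pairs: int = 80,
        leaf_width_mm: float = 5.0,
        **kwargs,
    ) -> "MlcModel":
        """Uniform-width leaf bank centered on the inplane axis."""
        half = n_pairs * leaf_width_mm / 2.0
        bounds = np.linspace(-half, half, n_pairs + 1)
        return cls(leaf_boundaries_mm=bounds, **kwargs)


def _plane_coords(shape: tuple[int, int], pitch_mm: float):
    rows, cols = shape
    y = (np.arange(rows) - (rows - 1) / 2.0) * pitch_mm  # inplane
    x = (np.arange(cols) - (cols - 1) / 2.0) * pitch_mm  # crossplane
    return y, x


def aperture_transmission_mask(
    cp: ControlPoint,
    model: MlcModel,
    shape: tuple[int, int] = (160, 160),
    pitch_mm: float = 2.5,
    supersample: int = 1,
) -> np.ndarray:
    """Per-pixel transmission of one aperture, in [0, 1].

    Pixel-center sampling: 1 inside the jaw rectangle and within the leaf
    pair's (DLG-widened) opening, ``model.transmission`` under leaves inside
    the jaws, ``model.jaw_transmission`` outside the jaws.  ``supersample``
    > 1 averages an NxN sub-pixel grid for anti-aliased edges.
    """
    if supersample > 1:
        sub = np.linspace(-0.5 + 0.5 / supersample, 0.5 - 0.5 / supersample, supersample)
        acc = np.zeros(shape)
        for dy in sub:
            for dx in sub:
                acc += _aperture_mask_at(cp, model, shape, pitch_mm, dy * pitch_mm, dx * pitch_mm)
        return acc / supersample**2
    return _aperture_mask_at(cp, model, shape, pitch_mm, 0.0, 0.0)


def _aperture_mask_at(cp, model, shape, pitch_mm, off_y, off_x):
    y, x = _plane_coords(shape, pitch_mm)
    y = y + off_y
    x = x + off_x
    b = model.leaf_boundaries_mm
    if y[0] < b[0] or y[-1] >= b[-1]:
        raise ValueError(
            "fluence-plane rows extend beyond the MLC leaf bank: "
            f"rows span [{y[0]:.1f}, {y[-1]:.1f}] mm, leaves [{b[0]:.1f}, {b[-1]:.1f}] mm"
        )
    pair = np.searchsorted(b, y, side="right") - 1  # leaf pair of each row
    half_gap = model.dosimetric_leaf_gap_mm / 2.0
    lo = cp.mlc_left[pair] - half_gap  # (rows,)
    hi = cp.mlc_right[pair] + half_gap
    open_ = (x[None, :] > lo[:, None]) & (x[None, :] < hi[:, None])
    x1, x2, y1, y2 = cp.jaws
    in_jaw = (
        (x[None, :] >= x1) & (x[None, :] <= x2) & (y[:, None] >= y1) & (y[:, None] <= y2)
    )
    out = np.full(shape, model.jaw_transmission, dtype=np.float64)
    out[in_jaw] = model.transmission
    out[in_jaw & open_] = 1.0
    return out


def _interp_cp(a: ControlPoint, b: ControlPoint, frac: float) -> ControlPoint:
    w = (1 - frac) * a.cumulative_meterset_weight + frac * b.cumulative_meterset_weight
    return ControlPoint(
        cumulative_meterset_weight=w,
        mlc_left=(1 - frac) * a.mlc_left + frac * b.mlc_left,
        mlc_right=(1 - frac) * a.mlc_right + frac * b.mlc_right,
        jaws=tuple((1 - frac) * np.array(a.jaws) + frac * np.array(b.jaws)),
    )


def fluence_from_control_points(
    seq: list[ControlPoint],
    field_mu: float,
    model: MlcModel,
    shape: tuple[int, int] = (160, 160),
    pitch_mm: float = 2.5,
    supersample: int = 1,
) -> np.ndarray:
    """Field fluence map (MU) from a control-point sequence.

    For each adjacent control-point pair the leaf/jaw positions are
    interpolated at the segment midpoint, and the resulting aperture mask is
    accumulated with weight ``field_mu * (w_next - w_prev)``.
    """
    if len(seq) < 2:
        raise ValueError("need at least two control points")
    if field_mu < 0:
        raise ValueError("field_mu must be non-negative")
    w = np.array([cp.cumulative_meterset_weight for cp in seq])
    if np.any(np.diff(w) < -1e-9):
        raise ValueError("cumulative meterset weights must be non-decreasing")
    if abs(w[0]) > 1e-9 or abs(w[-1] - 1.0) > 1e-9:
        raise ValueError("meterset weights must start at 0 and end at 1")
    fl = np.zeros(shape, dtype=np.float64)
    for a, b in zip(seq[:-1], seq[1:]):
        dw = b.cumulative_meterset_weight - a.cumulative_meterset_weight
        if dw <= 0:
            continue
        mid = _interp_cp(a, b, 0.5)
        fl += field_mu * dw * aperture_transmission_mask(
            mid, model, shape, pitch_mm, supersample
        )
    return fl


def stack_plan_fluence(
    per_field_maps: dict[float, np.ndarray] | list[tuple[float, np.ndarray]],
    expected_shape: tuple[int, int] = (160, 160),
    n_beams: int = 9,
) -> np.ndarray:
    """Stack per-field maps into the plan fluence array, beams ordered by
    ascending gantry angle from 0 deg.

    Accepts ``{gantry_angle_deg: map}`` or ``[(angle, map), ...]``; returns
    an array of shape ``(n_beams, rows, cols)``.
    """
    items = list(per_field_maps.items()) if isinstance(per_field_maps, dict) else list(per_field_maps)
    if len(items) != n_beams:
        raise ValueError(f"expected {n_beams} fluence maps, got {len(items)}")
    angles = [a % 360.0 for a, _ in items]
    if len(set(angles)) != n_beams:
        raise ValueError("duplicate gantry angles")
    stack = np.empty((n_beams,) + expected_shape, dtype=np.float64)
    for slot, idx in enumerate(np.argsort(angles)):
        m = np.asarray(items[idx][1], dtype=np.float64)
        if m.shape != expected_shape:
            raise ValueError(f"map at {items[idx][0]} deg has shape {m.shape}, expected {expected_shape}")
        stack[slot] = m
    return stack


def plan_from_dict(plan: dict):
    """Parse a JSON-style plan: per-field control points + MLC model.

    Expected layout::

        {"mlc": {"leaf_boundaries_mm": [...] | null, "n_pairs": 80,
                 "leaf_width_mm": 5.0, "transmission": 0.015,
                 "dosimetric_leaf_gap_mm": 1.4},
         "fields": [{"gantry_angle_deg": 0.0, "field_mu": 100.0,
                     "control_points": [{"weight": 0.0,
                                         "mlc_left": [...],
                                         "mlc_right": [...],
                                         "jaws": [x1, x2, y1, y2]}, ...]}]}

    Returns ``(fields, model)`` with fields as
    ``[(angle_deg, field_mu, [ControlPoint, ...]), ...]``.
    """
    mlc = plan["mlc"]
    kwargs = {
        k: mlc[k]
        for k in ("transmission", "dosimetric_leaf_gap_mm", "jaw_transmission")
        if k in mlc
    }
    if mlc.get("leaf_boundaries_mm"):
        model = MlcModel(leaf_boundaries_mm=np.asarray(mlc["leaf_boundaries_mm"]), **kwargs)
    else:
        model = MlcModel.uniform(
            n_pairs=mlc.get("n_pairs", 80),
            leaf_width_mm=mlc.get("leaf_width_mm", 5.0),
            **kwargs,
        )
    fields = []
    for fld in plan["fields"]:
        seq = [
            ControlPoint(
                cumulative_meterset_weight=cp["weight"],
                mlc_left=np.asarray(cp["mlc_left"]),
                mlc_right=np.asarray(cp["mlc_right"]),
                jaws=tuple(cp["jaws"]),
            )
            for cp in fld["control_points"]
        ]
        fields.append((fld["gantry_angle_deg"], fld["field_mu"], seq))
    return fields, model


def unstack_plan_fluence(stack: np.ndarray, angles=None) -> list[tuple[float, np.ndarray]]:
    """Inverse of :func:`stack_plan_fluence` for a known angle list."""
    if angles is None:
        from .geometry import DEFAULT_ANGLES

        angles = DEFAULT_ANGLES
    if len(angles) != stack.shape[0]:
        raise ValueError("angle count does not match stack")
    return [(float(a), stack[i].copy()) for i, a in enumerate(sorted(x % 360 for x in angles))]
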