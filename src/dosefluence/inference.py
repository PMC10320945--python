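"""Whole-volume prediction: sliding windows, overlap blending, scaling.

Volumes longer than one 32-slice patch are covered by windows at stride 24
(8 overlap slices); per-slice outputs from overlapping windows are averaged
with a logarithmic ramp weight profile normalized to a partition of unity,
then denormalized to physical units (cGy / MU).
"""

from __future__ import annotations

import numpy as np

from .geometry import ProjectionOperator
from .model import SharedEncoderModel
from .phantom import PatientCase
from .training import (
    PatchOperatorCache,
    denormalize_dose,
    denormalize_fluence,
    stack_input_channels,
)

__all__ = [
    "plan_windows",
    "log_weight_profile",
    "linear_weight_profile",
    "blend_windows",
    "predict_case",
    "renormalize_to_coverage",
]


def plan_windows(n_slices: int, patch: int = 32, stride: int = 24) -> list[tuple[int, int]]:
    """Half-open slice windows covering ``[0, n_slices)``.

    Regular starts at 0, stride, 2*stride, ...; if the volume tail is not
    covered the final window is end-aligned to ``(n_slices - patch,
    n_slices)``.
    """
    if n_slices < patch:
        raise ValueError(f"need at least {patch} slices, got {n_slices}")
    windows = []
    start = 0
    while start + patch <= n_slices:
        windows.append((start, start + patch))
        start += stride
    if windows[-1][1] < n_slices:
        windows.append((n_slices - patch, n_slices))
    return windows


def log_weight_profile(t: np.ndarray, t_max: int) -> np.ndarray:
    """ln(1+t) / ln(1+t_max) ramp used to smooth overlap regions."""
    t = np.minimum(t, t_max)
    return np.log1p(t) / np.log1p(t_max)


def linear_weight_profile(t: np.ndarray, t_max: int) -> np.ndarray:
    t = np.minimum(t, t_max)
    return t / t_max


def _window_weights(plan, n_slices, overlap, profile):
    """Per-window, per-slice blending weights (n_windows, n_slices)."""
    w = np.zeros((len(plan), n_slices))
    for i, (s0, s1) in enumerate(plan):
        sl = np.arange(s0, s1)
        t = np.minimum(sl - s0, s1 - 1 - sl)  # distance from the nearer edge
        w[i, s0:s1] = profile(t, overlap) if overlap > 0 else 1.0
    return w


def blend_windows(
    patches: list[np.ndarray],
    plan: list[tuple[int, int]],
    n_slices: int,
    slice_axis: int = 0,
    overlap: int | None = None,
    profile=log_weight_profile,
) -> np.ndarray:
    """Combine per-window outputs into a full volume.

    Slices covered by a single window are copied verbatim; in overlap
    regions the contributions are weighted by ``profile`` of the distance
    to the nearer window edge (capped at the overlap width) and normalized
    to sum to one.
    """
    if len(patches) != len(plan):
        raise ValueError("one patch output per planned window required")
    patch_len = plan[0][1] - plan[0][0]
    if overlap is None:
        overlap = patch_len - (plan[1][0] - plan[0][0]) if len(plan) > 1 else 0
    w = _window_weights(plan, n_slices, overlap, profile)
    coverage = np.array([[1.0 if s0 <= s < s1 else 0.0 for s in range(n_slices)]
                         for (s0, s1) in plan])
    n_cover = coverage.sum(axis=0)
    if np.any(n_cover == 0):
        raise ValueError("window plan does not cover all slices")
    # single-coverage slices: verbatim copy (weight 1)
    single = n_cover == 1
    w = np.where(single[None, :], coverage, w)
    tot = w.sum(axis=0)
    if np.any(tot <= 0):  # both windows at zero ramp weight: fall back to mean
        w = np.where((tot <= 0)[None, :], coverage, w)
        tot = w.sum(axis=0)
    w = w / tot

    p0 = np.moveaxis(np.asarray(patches[0], dtype=np.float64), slice_axis, 0)
    out = np.zeros((n_slices,) + p0.shape[1:])
    for patch, (s0, s1), wi in zip(patches, plan, w):
        p = np.moveaxis(np.asarray(patch, dtype=np.float64), slice_axis, 0)
        out[s0:s1] += p * wi[s0:s1, None, None] if p.ndim == 3 else p * wi[s0:s1]
    return np.moveaxis(out, 0, slice_axis)


def predict_case(
    model: SharedEncoderModel,
    case: PatientCase,
    operators: list[ProjectionOperator],
    patch_slices: int = 32,
    stride: int = 24,
    profile=log_weight_profile,
):
    """Predict a case's full dose volume (cGy) and fluence stack (MU).

    Sliding-window forward passes are blended per slice (and per aligned
    fluence row), denormalized, and clamped at zero; the number of clamped
    negative voxels/pixels is reported in the info dict.  Deterministic
    given the checkpoint.
    """
    case.validate()
    n = case.n_slices
    plan = plan_windows(n, patch_slices, stride)
    cache = PatchOperatorCache(operators, patch_slices)
    inputs = stack_input_channels(case)
    dose_patches = []
    flu_patches = []
    for s0, s1 in plan:
        x = inputs[None, :, s0:s1]
        ops = cache.get(s0)
        dose, fl, _ = model.forward(x, ops, train=False)
        dose_patches.append(dose[0, 0])
        flu_patches.append(fl[0])
    overlap = patch_slices - stride
    dose_norm = blend_windows(dose_patches, plan, n, slice_axis=0,
                              overlap=overlap, profile=profile)
    flu_rows = blend_windows(flu_patches, plan, n, slice_axis=1,
                             overlap=overlap, profile=profile)
    dose = denormalize_dose(dose_norm)
    rows_f, cols_f = case.beams.fluence_shape
    fluence = np.zeros((case.beams.n_beams, rows_f, cols_f))
    r0 = cache.row_offset
    fluence[:, r0 : r0 + n, :] = denormalize_fluence(flu_rows)
    info = {
        "n_negative_dose": int((dose < 0).sum()),
        "n_negative_fluence": int((fluence < 0).sum()),
        "windows": plan,
    }
    return np.maximum(dose, 0.0), np.maximum(fluence, 0.0), info


def _coverage(dose, mask, level):
    return float((np.asarray(dose)[mask] >= level).mean())


def renormalize_to_coverage(
    dose: np.ndarray,
    gtv_mask: np.ndarray,
    reference_dose: np.ndarray,
    level: float,
    s_bounds: tuple[float, float] = (0.5, 2.0),
    tol: float = 1e-4,
):
    """Scale ``dose`` so its PTV-GTV coverage at ``level`` matches the
    reference plan's; returns ``(scaled_dose, s)``.

    Coverage(s) = fraction of GTV voxels with ``s * dose >= level`` is
    non-decreasing in ``s``; the scale is found by bisection.
    """
    mask = np.asarray(gtv_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty PTV-GTV mask")
    target = _coverage(reference_dose, mask, level)
    if abs(_coverage(dose, mask, level) - target) <= tol:
        return np.asarray(dose, dtype=np.float64), 1.0
    lo, hi = s_bounds
    c_lo, c_hi = _coverage(dose * lo, mask, level), _coverage(dose * hi, mask, level)
    if not (c_lo - tol <= target <= c_hi + tol):
        raise ValueError(
            f"target coverage {target:.4f} unreachable within scale bounds "
            f"[{lo}, {hi}] (coverage range [{c_lo:.4f}, {c_hi:.4f}])"
        )
    s = 1.0
    for _ in range(60):
        s = 0.5 * (lo + hi)
        c = _coverage(dose * s, mask, level)
        if abs(c - target) <= tol:
            break
        if c < target:
            lo = s
        else:
            hi = s
    return dose * s, s
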