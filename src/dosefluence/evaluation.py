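"""Fluence and dose quality metrics, DVH indices, and cohort statistics.

Fluence accuracy is scored per beam inside the beam's-eye-view PTV(+5 mm)
mask: mean absolute error as a percentage of the ground-truth map maximum,
the structural similarity index, and global gamma passing rates at 3%/3mm
with 0% and 10% low-dose thresholds.  Dose quality uses cumulative DVHs
and the clinical indices D95%, Dmean and Dmax per structure (reported in
Gy), compared three ways — ground truth vs. network-predicted dose vs. the
dose recomputed from the predicted fluence — with paired Wilcoxon
signed-rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import ProjectionOperator, bev_target_mask
from .phantom import OAR_NAMES, PTV_NAMES, PatientCase

__all__ = [
    "masked_mae_percent",
    "ssim_map",
    "gamma_pass_rate",
    "dvh",
    "clinical_indices",
    "paired_wilcoxon",
    "EvalReport",
    "evaluate_cohort",
]


def masked_mae_percent(pred: np.ndarray, gt: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error inside ``mask``, as % of the ground-truth map
    maximum (taken over the whole map, per beam)."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty evaluation mask")
    gmax = gt.max()
    if gmax <= 0:
        raise ValueError("ground-truth maximum must be positive")
    return float(100.0 * np.abs(pred[m] - gt[m]).mean() / gmax)


def _gaussian_blur_11(x: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    # truncate chosen so the kernel radius is 5 (11x11 window)
    return ndimage.gaussian_filter(x, sigma=sigma, truncate=5.0 / sigma, mode="reflect")


def ssim_map(pred: np.ndarray, gt: np.ndarray, k1: float = 0.01, k2: float = 0.03,
             sigma: float = 1.5) -> float:
    """Structural similarity index between two maps.

    Gaussian-weighted 11x11 local statistics (sigma 1.5), data range set by
    the ground-truth maximum, averaged over the interior (window-valid)
    pixels.  Returns a value in [-1, 1].
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("maps must share a shape")
    data_range = gt.max() - 0.0
    if data_range <= 0:
        raise ValueError("SSIM undefined for a constant-zero reference")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    ux = _gaussian_blur_11(pred, sigma)
    uy = _gaussian_blur_11(gt, sigma)
    uxx = _gaussian_blur_11(pred * pred, sigma)
    uyy = _gaussian_blur_11(gt * gt, sigma)
    uxy = _gaussian_blur_11(pred * gt, sigma)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = 5
    return float(s[pad:-pad, pad:-pad].mean())


def gamma_pass_rate(
    ref: np.ndarray,
    eval_map: np.ndarray,
    dd_percent: float = 3.0,
    dta_mm: float = 3.0,
    threshold_percent: float = 0.0,
    pixel_mm: float = 2.5,
    subpixel: float = 0.25,
    search_factor: float = 3.0,
) -> float:
    """Global 2D gamma passing rate (%), criteria ``dd_percent``/``dta_mm``.

    The dose-difference denominator is ``dd_percent`` of the reference map
    maximum (global normalization).  Reference pixels at or above
    ``threshold_percent`` of that maximum are evaluated; for each, gamma is
    minimized over eval positions within ``search_factor * dta_mm``,
    sampled on a ``subpixel``-pitch grid with bilinear interpolation.
    Gamma is asymmetric in (ref, eval) by construction.
    """
    ref = np.asarray(ref, dtype=np.float64)
    ev = np.asarray(eval_map, dtype=np.float64)
    if ref.shape != ev.shape:
        raise ValueError("maps must share a shape")
    rmax = ref.max()
    if rmax <= 0:
        raise ValueError("reference maximum must be positive")
    dd_abs = dd_percent / 100.0 * rmax
    evaluated = ref >= threshold_percent / 100.0 * rmax
    if not evaluated.any():
        raise ValueError("no pixels above the low-dose threshold")

    search_px = search_factor * dta_mm / pixel_mm
    step = subpixel
    offs = np.arange(-np.floor(search_px / step) * step,
                     np.floor(search_px / step) * step + step / 2, step)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    dist_mm = np.hypot(oy, ox) * pixel_mm
    inside = dist_mm <= search_factor * dta_mm
    order = np.argsort(dist_mm[inside])
    offsets = np.column_stack([oy[inside][order], ox[inside][order]])
    dists = dist_mm[inside][order]

    H, W = ref.shape
    iy, ix = np.mgrid[0:H, 0:W]
    iy = iy[evaluated].astype(np.float64)
    ix = ix[evaluated].astype(np.float64)
    rvals = ref[evaluated]
    best = np.full(rvals.shape, np.inf)
    for (dy, dx), dmm in zip(offsets, dists):
        dterm = (dmm / dta_mm) ** 2
        if dterm >= best.max():
            break  # farther offsets cannot improve any pixel
        ev_shift = ndimage.map_coordinates(
            ev, [iy + dy, ix + dx], order=1, mode="nearest"
        )
        g2 = ((ev_shift - rvals) / dd_abs) ** 2 + dterm
        np.minimum(best, g2, out=best)
    return float(100.0 * (np.sqrt(best) <= 1.0).mean())


def dvh(dose_cgy: np.ndarray, mask: np.ndarray, bin_cgy: float = 10.0):
    """Cumulative dose-volume histogram.

    Returns ``(dose_edges_cgy, volume_fraction)`` with
    ``V(d) = fraction of mask voxels receiving >= d``; V(0) = 1 and the
    curve is monotone non-increasing.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty structure mask")
    d = np.asarray(dose_cgy, dtype=np.float64)[m]
    edges = np.arange(0.0, d.max() + 2 * bin_cgy, bin_cgy)
    v = (d[None, :] >= edges[:, None]).mean(axis=1)
    return edges, v


def clinical_indices(dose_cgy: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """D95% / Dmean / Dmax of a structure, in Gy.

    D95% uses the voxel-percentile convention (5th percentile of voxel
    doses, lower interpolation): the largest dose received by at least 95%
    of the structure volume.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty structure mask")
    d = np.asarray(dose_cgy, dtype=np.float64)[m]
    return {
        "D95": float(np.percentile(d, 5.0, method="lower")) / 100.0,
        "Dmean": float(d.mean()) / 100.0,
        "Dmax": float(d.max()) / 100.0,
    }


def paired_wilcoxon(values_a, values_b, alpha: float = 0.05):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Exact null distribution for n <= 25 non-zero differences, normal
    approximation with tie correction above.  Returns
    ``(p_value, significant, defined)``; when every difference is zero the
    test is undefined and ``(nan, False, False)`` is returned.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = b - a
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return float("nan"), False, False
    if nz.size < 6:
        raise ValueError("need at least 6 non-zero differences")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method,
                         alternative="two-sided")
    p = float(res.pvalue)
    return p, p < alpha, True


# ---------------------------------------------------------------------------
# cohort evaluation


@dataclass
class EvalReport:
    """Per-case and cohort metrics in tabular (long) form."""

    fluence_per_case: pd.DataFrame   # case, beam, mae_percent, ssim, gamma_0, gamma_10
    dose_indices: pd.DataFrame       # case, structure, index, gt, predicted, fluence_generated
    fluence_cohort: pd.DataFrame     # metric, mean, sd
    dose_cohort: pd.DataFrame        # structure, index, per-arm mean/sd, p1, p2
    skipped_cases: list = field(default_factory=list)

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.fluence_per_case.to_csv(d / "fluence_per_case.csv", index=False)
        self.dose_indices.to_csv(d / "dose_indices_per_case.csv", index=False)
        self.fluence_cohort.to_csv(d / "fluence_cohort.csv", index=False)
        self.dose_cohort.to_csv(d / "dose_cohort.csv", index=False)
        summary = {
            "fluence": self.fluence_cohort.to_dict(orient="records"),
            "dose": self.dose_cohort.to_dict(orient="records"),
            "skipped_cases": list(self.skipped_cases),
        }
        import json

        (d / "report.json").write_text(json.dumps(summary, indent=2))


ALL_STRUCTURES = PTV_NAMES + OAR_NAMES
INDEX_NAMES = ("D95", "Dmean", "Dmax")


def evaluate_cohort(
    cases: list[PatientCase],
    predicted: list[tuple[np.ndarray, np.ndarray]],
    fluence_generated_doses: list[np.ndarray],
    operators: list[ProjectionOperator],
    bev_margin_mm: float = 5.0,
    gamma_kwargs: dict | None = None,
) -> EvalReport:
    """Full evaluation protocol over a cohort.

    ``predicted`` pairs are (dose_cgy, fluence_mu) per case;
    ``fluence_generated_doses`` are the doses recomputed from the predicted
    fluence by the forward engine.  Fluence metrics are scored within the
    BEV PTV(+margin) masks; dose indices are compared three-way with two
    paired tests per index (ground truth vs. predicted, ground truth vs.
    fluence-generated).  Failing cases are skipped with a log entry.
    """
    gamma_kwargs = dict(gamma_kwargs or {})
    gamma_kwargs.setdefault("pixel_mm", cases[0].beams.fluence_pitch_mm)
    flu_rows = []
    idx_rows = []
    skipped = []
    for ci, (case, (pdose, pflu), fdose) in enumerate(
        zip(cases, predicted, fluence_generated_doses)
    ):
        try:
            ptv_any = case.ptv_dose_mask > 0
            for b, op in enumerate(operators):
                mask = bev_target_mask(ptv_any, op, bev_margin_mm)
                gt = case.fluence[b]
                flu_rows.append(
                    {
                        "case": ci,
                        "beam": b,
                        "angle_deg": op.angle_deg,
                        "mae_percent": masked_mae_percent(pflu[b], gt, mask),
                        "ssim": ssim_map(pflu[b], gt),
                        "gamma_0": gamma_pass_rate(
                            gt, pflu[b], threshold_percent=0.0, **gamma_kwargs
                        ),
                        "gamma_10": gamma_pass_rate(
                            gt, pflu[b], threshold_percent=10.0, **gamma_kwargs
                        ),
                    }
                )
            structures = {**case.ptv_masks, **case.oar_masks}
            for name in ALL_STRUCTURES:
                gt_idx = clinical_indices(case.dose, structures[name])
                pr_idx = clinical_indices(pdose, structures[name])
                fl_idx = clinical_indices(fdose, structures[name])
                for index in INDEX_NAMES:
                    idx_rows.append(
                        {
                            "case": ci,
                            "structure": name,
                            "index": index,
                            "gt": gt_idx[index],
                            "predicted": pr_idx[index],
                            "fluence_generated": fl_idx[index],
                        }
                    )
        except Exception as exc:  # evaluation continues over remaining cases
            skipped.append({"case": ci, "error": str(exc)})
            flu_rows = [r for r in flu_rows if r["case"] != ci]
            idx_rows = [r for r in idx_rows if r["case"] != ci]
    flu = pd.DataFrame(flu_rows)
    idx = pd.DataFrame(idx_rows)

    flu_cohort = pd.DataFrame(
        [
            {"metric": m, "mean": flu[m].mean(), "sd": flu[m].std(ddof=1)}
            for m in ("mae_percent", "ssim", "gamma_0", "gamma_10")
        ]
        if len(flu)
        else []
    )

    rows = []
    for (structure, index), grp in idx.groupby(["structure", "index"], sort=False):
        row = {"structure": structure, "index": index}
        for arm in ("gt", "predicted", "fluence_generated"):
            row[f"{arm}_mean"] = grp[arm].mean()
            row[f"{arm}_sd"] = grp[arm].std(ddof=1)
        for arm, col in (("predicted", "p1"), ("fluence_generated", "p2")):
            try:
                p, sig, defined = paired_wilcoxon(grp["gt"], grp[arm])
                row[col] = p if defined else float("nan")
                row[f"{col}_significant"] = bool(sig)
            except ValueError:
                row[col] = float("nan")
                row[f"{col}_significant"] = False
        rows.append(row)
    dose_cohort = pd.DataFrame(rows)
    return EvalReport(
        fluence_per_case=flu,
        dose_indices=idx,
        fluence_cohort=flu_cohort,
        dose_cohort=dose_cohort,
        skipped_cases=skipped,
    )
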