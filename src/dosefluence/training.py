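"""Dataset assembly, normalization, augmentation, masked losses, training.

Normalization constants follow the clinical protocol: prescription-dose
mask and dose in units of 7000 cGy, fluence in units of 2000 MU, CT
windowed to [-1024, 2000] HU and divided by 2000.  The dual loss is the
sum of a mean-absolute-error dose term inside the patient body and a
mean-absolute-error fluence term inside the beam's-eye-view PTV(+5 mm)
masks, the latter restricted to the middle rows of each fluence patch
(the edge rows of a patch-restricted projection are under-covered by the
patch volume because of beam divergence).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    ProjectionOperator,
    bev_target_mask,
    build_all_operators,
    fluence_row_of_slice,
)
from .model import ModelConfig, SharedEncoderModel, build_model
from .nn.optim import Adam, ReduceLROnPlateau
from .phantom import OAR_NAMES, PatientCase

__all__ = [
    "DOSE_NORM_CGY",
    "FLUENCE_NORM_MU",
    "HU_WINDOW",
    "HU_NORM",
    "FLUENCE_EDGE_TRIM",
    "TrainConfig",
    "TrainingCase",
    "PatchOperatorCache",
    "normalize_dose",
    "denormalize_dose",
    "normalize_fluence",
    "denormalize_fluence",
    "normalize_ct",
    "stack_input_channels",
    "sample_patch",
    "flip_leftright",
    "rotate_axial",
    "augment",
    "dual_loss",
    "dual_loss_and_grad",
    "train",
]

DOSE_NORM_CGY = 7000.0
FLUENCE_NORM_MU = 2000.0
HU_WINDOW = (-1024.0, 2000.0)
HU_NORM = 2000.0
# rows dropped from each edge of a fluence patch in the loss (32 -> 26)
FLUENCE_EDGE_TRIM = 3

ROTATION_ANGLES_DEG = (40, 80, 120, 160, 200, 240, 280, 320)


@dataclass
class TrainConfig:
    patch_slices: int = 32
    batch_size: int = 2
    initial_lr: float = 3e-4
    plateau_factor: float = 0.7  # "reduce the learning rate by 30%"
    plateau_patience: int = 4
    plateau_threshold: float = 1e-4
    epochs: int = 150
    iterations_per_epoch: int = 400
    flip_prob: float = 0.6
    rotation_prob: float = 0.4
    bev_margin_mm: float = 5.0
    fluence_edge_trim: int = FLUENCE_EDGE_TRIM
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)


# ---------------------------------------------------------------------------
# normalization


def normalize_dose(dose_cgy):
    return np.asarray(dose_cgy, dtype=np.float32) / DOSE_NORM_CGY


def denormalize_dose(dose_norm):
    return np.asarray(dose_norm, dtype=np.float64) * DOSE_NORM_CGY


def normalize_fluence(fluence_mu):
    return np.asarray(fluence_mu, dtype=np.float32) / FLUENCE_NORM_MU


def denormalize_fluence(fluence_norm):
    return np.asarray(fluence_norm, dtype=np.float64) * FLUENCE_NORM_MU


def normalize_ct(ct_hu):
    """Window to [-1024, 2000] HU, then divide by 2000 (not invertible for
    values outside the window)."""
    ct = np.clip(np.asarray(ct_hu, dtype=np.float32), *HU_WINDOW)
    return ct / HU_NORM


def stack_input_channels(case: PatientCase) -> np.ndarray:
    """Normalized 19-channel network input for a whole case.

    Channel order: prescription-dose PTV mask, the 17 OAR masks in
    alphabetical order, CT last.
    """
    chans = [normalize_dose(case.ptv_dose_mask)]
    for name in sorted(OAR_NAMES):
        chans.append(case.oar_masks[name].astype(np.float32))
    chans.append(normalize_ct(case.ct))
    return np.stack(chans)


# ---------------------------------------------------------------------------
# prepared cases and patch-restricted operators


class PatchOperatorCache:
    """Patch-restricted projection operators, cached by start slice.

    All cases of a cohort share grid and beam geometry, so one cache serves
    the whole training run.  The fluence-row window of a patch starting at
    slice ``s`` covers the rows aligned (at the isocenter plane) with the
    patch's slices.
    """

    def __init__(self, operators: list[ProjectionOperator], patch_slices: int):
        self.operators = operators
        self.patch_slices = patch_slices
        self._cache: dict[int, list[ProjectionOperator]] = {}
        grid = operators[0].grid
        beam = operators[0].beam
        r0 = fluence_row_of_slice(grid, beam, 0)
        if abs(r0 - round(r0)) > 1e-6:
            raise ValueError(
                "grid slices are not aligned with fluence rows; use an "
                "isocenter-centered grid"
            )
        self.row_offset = int(round(r0))

    def rows_for_start(self, start: int) -> tuple[int, int]:
        return start + self.row_offset, start + self.row_offset + self.patch_slices

    def get(self, start: int) -> list[ProjectionOperator]:
        if start not in self._cache:
            r0, r1 = self.rows_for_start(start)
            self._cache[start] = [
                op.restrict(start, start + self.patch_slices, r0, r1)
                for op in self.operators
            ]
        return self._cache[start]


class TrainingCase:
    """A case with everything precomputed for patch sampling."""

    def __init__(self, case: PatientCase, operators: list[ProjectionOperator],
                 bev_margin_mm: float = 5.0):
        case.validate()
        if case.dose is None or case.fluence is None:
            raise ValueError("training cases need dose and fluence")
        self.case = case
        self.inputs = stack_input_channels(case)
        self.dose = normalize_dose(case.dose)
        self.fluence = normalize_fluence(case.fluence)
        self.body = case.oar_masks["body"].astype(bool)
        ptv_any = case.ptv_dose_mask > 0
        self.ptv_slices = np.flatnonzero(ptv_any.any(axis=(1, 2)))
        self.bev_masks = np.stack(
            [bev_target_mask(ptv_any, op, bev_margin_mm) for op in operators]
        )

    def valid_starts(self, patch_slices: int) -> np.ndarray:
        """Window starts whose 32 slices contain at least one PTV slice."""
        n = self.case.n_slices
        if n < patch_slices:
            raise ValueError("case has fewer slices than the patch length")
        if self.ptv_slices.size == 0:
            raise ValueError("case has an empty PTV mask; rejected for training")
        starts = np.arange(n - patch_slices + 1)
        lo, hi = self.ptv_slices.min(), self.ptv_slices.max()
        ok = (starts + patch_slices - 1 >= lo) & (starts <= hi)
        return starts[ok]


@dataclass
class PatchSample:
    inputs: np.ndarray    # (19, L, H, W) normalized
    dose: np.ndarray      # (L, H, W) normalized
    fluence: np.ndarray   # (n_beams, L, cols) normalized, rows ≡ slices
    body: np.ndarray      # (L, H, W) bool
    bev: np.ndarray       # (n_beams, L, cols) bool, rows ≡ slices
    start: int


def sample_patch(tc: TrainingCase, rng: np.random.Generator,
                 cache: PatchOperatorCache) -> PatchSample:
    """Uniformly sample a contiguous slab of ``patch_slices`` slices whose
    window contains at least one nonzero PTV-mask slice."""
    L = cache.patch_slices
    starts = tc.valid_starts(L)
    start = int(starts[rng.integers(starts.size)])
    return extract_patch(tc, start, cache)


def extract_patch(tc: TrainingCase, start: int, cache: PatchOperatorCache) -> PatchSample:
    L = cache.patch_slices
    r0, r1 = cache.rows_for_start(start)
    sl = slice(start, start + L)
    return PatchSample(
        inputs=tc.inputs[:, sl],
        dose=tc.dose[sl],
        fluence=tc.fluence[:, r0:r1, :],
        body=tc.body[sl],
        bev=tc.bev_masks[:, r0:r1, :],
        start=start,
    )


# ---------------------------------------------------------------------------
# augmentation

_CT_CHANNEL = 18  # CT is the last input channel; all others are masks


def flip_leftright(sample: PatchSample) -> PatchSample:
    """Mirror along the patient left-right axis.

    Volumes flip along the width axis; fluence beams remap
    ``g <-> (360 - g) mod 360`` with each map's column axis reversed.
    """
    n_beams = sample.fluence.shape[0]
    remap = (-np.arange(n_beams)) % n_beams
    return PatchSample(
        inputs=sample.inputs[..., ::-1].copy(),
        dose=sample.dose[..., ::-1].copy(),
        fluence=sample.fluence[remap][..., ::-1].copy(),
        body=sample.body[..., ::-1].copy(),
        bev=sample.bev[remap][..., ::-1].copy(),
        start=sample.start,
    )


def _rot_vol(vol, k, order, cval=0.0):
    # positive k rotates the anatomy in the gantry sense (anterior toward
    # patient-left), carrying the beam-b view onto beam b-1; the ndimage
    # sign below is pinned by the projection-equivalence test
    return ndimage.rotate(
        vol, angle=-40.0 * k, axes=(-2, -1), reshape=False,
        order=order, mode="constant", cval=cval, prefilter=False,
    )


def rotate_axial(sample: PatchSample, k: int) -> PatchSample:
    """Rotate about the superior-inferior axis by ``k * 40`` degrees.

    Masks are resampled nearest-neighbor, CT and dose linearly; fluence
    beam channels shift cyclically by ``k`` (no in-plane resampling needed
    because the beams are equally spaced at 40 degrees).
    """
    inp = np.empty_like(sample.inputs)
    for c in range(sample.inputs.shape[0]):
        if c == _CT_CHANNEL:
            inp[c] = _rot_vol(sample.inputs[c], k, order=1, cval=HU_WINDOW[0] / HU_NORM)
        else:
            inp[c] = _rot_vol(sample.inputs[c], k, order=0)
    return PatchSample(
        inputs=inp,
        dose=_rot_vol(sample.dose, k, order=1),
        fluence=np.roll(sample.fluence, k, axis=0),
        body=_rot_vol(sample.body.astype(np.uint8), k, order=0).astype(bool),
        bev=np.roll(sample.bev, k, axis=0),
        start=sample.start,
    )


def draw_augmentation(rng: np.random.Generator, flip_prob: float = 0.6,
                      rotation_prob: float = 0.4) -> tuple[bool, int]:
    """Independent augmentation draws: ``(do_flip, k)`` with ``k`` the
    rotation multiple of 40 degrees (0 = no rotation, else uniform over
    1..8).  The no-augmentation probability is (1-0.6)(1-0.4) = 0.24."""
    do_flip = rng.random() < flip_prob
    do_rot = rng.random() < rotation_prob
    k = int(rng.integers(1, 9)) if do_rot else 0
    return do_flip, k


def augment(sample: PatchSample, rng: np.random.Generator,
            flip_prob: float = 0.6, rotation_prob: float = 0.4,
            beam_spacing_deg: float = 40.0) -> PatchSample:
    """Random left-right flip (p=0.6) and random axial rotation by one of
    the eight multiples of 40 degrees (p=0.4), drawn independently."""
    if beam_spacing_deg != 40.0:
        raise ValueError("rotation augmentation requires 40-degree beam spacing")
    do_flip, k = draw_augmentation(rng, flip_prob, rotation_prob)
    if do_flip:
        sample = flip_leftright(sample)
    if k:
        sample = rotate_axial(sample, k)
    return sample


# ---------------------------------------------------------------------------
# loss


def _fluence_loss_mask(bev: np.ndarray, edge_trim: int) -> np.ndarray:
    mask = bev.copy()
    if edge_trim > 0:
        mask[:, :edge_trim, :] = False
        mask[:, -edge_trim:, :] = False
    return mask


def dual_loss(pred_dose, pred_fluence, target_dose, target_fluence,
              body_mask, bev_masks, edge_trim: int = FLUENCE_EDGE_TRIM):
    """Masked dual MAE: mean |dose error| over body voxels plus mean
    |fluence error| over BEV-mask pixels in the middle fluence rows,
    pooled across beams.  All on normalized scales."""
    loss, _, _, parts = _dual_loss_impl(
        pred_dose, pred_fluence, target_dose, target_fluence,
        body_mask, bev_masks, edge_trim, want_grad=False,
    )
    return loss, parts


def dual_loss_and_grad(pred_dose, pred_fluence, target_dose, target_fluence,
                       body_mask, bev_masks, edge_trim: int = FLUENCE_EDGE_TRIM):
    loss, g_dose, g_fluence, parts = _dual_loss_impl(
        pred_dose, pred_fluence, target_dose, target_fluence,
        body_mask, bev_masks, edge_trim, want_grad=True,
    )
    return loss, g_dose, g_fluence, parts


def _dual_loss_impl(pred_dose, pred_fluence, target_dose, target_fluence,
                    body_mask, bev_masks, edge_trim, want_grad):
    body = np.asarray(body_mask, dtype=bool)
    fmask = _fluence_loss_mask(np.asarray(bev_masks, dtype=bool), edge_trim)
    nb = int(body.sum())
    nf = int(fmask.sum())
    loss = 0.0
    parts = {}
    g_dose = np.zeros_like(np.asarray(pred_dose)) if want_grad else None
    g_flu = np.zeros_like(np.asarray(pred_fluence)) if want_grad else None
    if nb == 0:
        warnings.warn("empty body mask; dose loss term skipped", stacklevel=2)
    else:
        dd = np.asarray(pred_dose) - np.asarray(target_dose)
        dose_term = float(np.abs(dd[body]).mean())
        loss += dose_term
        parts["dose_mae"] = dose_term
        if want_grad:
            g_dose[body] = np.sign(dd[body]) / nb
    if nf == 0:
        warnings.warn("empty BEV fluence mask; fluence loss term skipped", stacklevel=2)
    else:
        df = np.asarray(pred_fluence) - np.asarray(target_fluence)
        flu_term = float(np.abs(df[fmask]).mean())
        loss += flu_term
        parts["fluence_mae"] = flu_term
        if want_grad:
            g_flu[fmask] = np.sign(df[fmask]) / nf
    return loss, g_dose, g_flu, parts


# ---------------------------------------------------------------------------
# training loop


def _validation_loss(model: SharedEncoderModel, val_cases: list[TrainingCase],
                     cache: PatchOperatorCache, config: TrainConfig) -> float:
    """Deterministic, augmentation-free validation.

    One patch per case, centered on the PTV slice range; the dual loss is
    restricted to PTV-containing slices (the high-dose region the model is
    selected on) and their aligned fluence rows.
    """
    L = cache.patch_slices
    total = 0.0
    for tc in val_cases:
        starts = tc.valid_starts(L)
        center = 0.5 * (tc.ptv_slices.min() + tc.ptv_slices.max())
        start = int(starts[np.argmin(np.abs(starts + L / 2 - center))])
        patch = extract_patch(tc, start, cache)
        ops = cache.get(start)
        dose, fl, _ = model.forward(patch.inputs[None], ops, train=False)
        in_ptv_slice = np.zeros(L, dtype=bool)
        rel = tc.ptv_slices[(tc.ptv_slices >= start) & (tc.ptv_slices < start + L)] - start
        in_ptv_slice[rel] = True
        body = patch.body & in_ptv_slice[:, None, None]
        bev = patch.bev & in_ptv_slice[None, :, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loss, _ = dual_loss(
                dose[0, 0], fl[0], patch.dose, patch.fluence, body, bev,
                edge_trim=config.fluence_edge_trim,
            )
        total += loss
    return total / max(len(val_cases), 1)


def train(
    train_cases: list[TrainingCase],
    val_cases: list[TrainingCase],
    config: TrainConfig,
    operators: list[ProjectionOperator] | None = None,
    model: SharedEncoderModel | None = None,
    log_path=None,
):
    """Train the shared-encoder network; returns (model, history).

    Adam at the configured initial rate, batched patch sampling with
    augmentation, per-epoch validation driving a reduce-on-plateau
    schedule, and best-validation parameter selection.
    """
    if not train_cases:
        raise ValueError("no training cases")
    if operators is None:
        c = train_cases[0].case
        operators = build_all_operators(c.grid, c.beams)
    cache = PatchOperatorCache(operators, config.patch_slices)
    model = model or build_model(config.model)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.initial_lr)
    sched = ReduceLROnPlateau(
        opt, factor=config.plateau_factor, patience=config.plateau_patience,
        threshold=config.plateau_threshold,
    )
    history = []
    best_val = np.inf
    best_params = None
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(config.epochs):
            epoch_loss = 0.0
            for _ in range(config.iterations_per_epoch):
                samples = []
                for _ in range(config.batch_size):
                    tc = train_cases[rng.integers(len(train_cases))]
                    s = sample_patch(tc, rng, cache)
                    samples.append(
                        augment(s, rng, config.flip_prob, config.rotation_prob)
                    )
                x = np.stack([s.inputs for s in samples])
                ops_per_sample = [cache.get(s.start) for s in samples]
                dose, fl, _ = model.forward(x, ops_per_sample, train=True)
                loss = 0.0
                g_dose = np.zeros_like(dose)
                g_fl = np.zeros_like(fl)
                for n, s in enumerate(samples):
                    l, gd, gf, _ = dual_loss_and_grad(
                        dose[n, 0], fl[n], s.dose, s.fluence, s.body, s.bev,
                        edge_trim=config.fluence_edge_trim,
                    )
                    loss += l / len(samples)
                    g_dose[n, 0] = gd / len(samples)
                    g_fl[n] = gf / len(samples)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                opt.zero_grad()
                model.backward(g_dose, g_fl)
                opt.step()
                epoch_loss += loss
            epoch_loss /= config.iterations_per_epoch
            val = (
                _validation_loss(model, val_cases, cache, config)
                if val_cases else epoch_loss
            )
            sched.step(val)
            rec = {
                "epoch": epoch,
                "train_loss": float(epoch_loss),
                "val_loss": float(val),
                "lr": float(opt.lr),
            }
            history.append(rec)
            if log_f:
                log_f.write(json.dumps(rec) + "\n")
                log_f.flush()
            if val < best_val:
                best_val = val
                best_params = {
                    k: p.value.copy() for k, p in model.params().items()
                }
    finally:
        if log_f:
            log_f.close()
    if best_params is not None:
        for k, p in model.params().items():
            p.value[...] = best_params[k]
    return model, history
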