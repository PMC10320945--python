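"""Normalization, patch sampling, augmentation and the masked dual loss."""

import copy

import numpy as np
import pytest
from scipy import stats

from dosefluence.geometry import build_all_operators, project_volume
from dosefluence.nn.layers import Param
from dosefluence.nn.optim import Adam, ReduceLROnPlateau
from dosefluence.phantom import PhantomConfig, generate_anatomy
from dosefluence.profiles import get_profile
from dosefluence.training import (
    PatchOperatorCache,
    TrainingCase,
    _rot_vol,
    augment,
    draw_augmentation,
    dual_loss,
    dual_loss_and_grad,
    extract_patch,
    flip_leftright,
    normalize_ct,
    normalize_dose,
    denormalize_dose,
    rotate_axial,
    sample_patch,
    stack_input_channels,
)


class TestNormalization:
    def test_dose_prescription_scale(self):
        assert normalize_dose(7000.0) == pytest.approx(1.0)
        assert denormalize_dose(normalize_dose(1234.5)) == pytest.approx(1234.5)

    def test_hu_window_and_scale(self):
        assert normalize_ct(3000.0) == pytest.approx(1.0)  # clipped to 2000
        assert normalize_ct(-1024.0) == pytest.approx(-0.512)
        assert normalize_ct(-5000.0) == pytest.approx(-0.512)

    def test_input_stack_is_19_channels_ptv_first_ct_last(self, micro_case):
        x = stack_input_channels(micro_case)
        assert x.shape == (19,) + micro_case.grid.shape
        np.testing.assert_allclose(
            x[0], micro_case.ptv_dose_mask / 7000.0, rtol=1e-6
        )
        np.testing.assert_allclose(x[18], normalize_ct(micro_case.ct), rtol=1e-6)
        assert set(np.unique(x[1])) <= {0.0, 1.0}  # an OAR mask channel


@pytest.fixture(scope="module")
def training_case(micro_case, micro_ops):
    return TrainingCase(micro_case, micro_ops)


@pytest.fixture(scope="module")
def op_cache(micro_ops):
    return PatchOperatorCache(micro_ops, patch_slices=16)


class TestPatchSampling:
    def test_every_window_intersects_the_ptv(self):
        """Enumerated valid starts all overlap the PTV slice range."""
        config = PhantomConfig(grid_shape=(32, 48, 48), fluence_shape=(64, 64))
        case = generate_anatomy(5, config)
        case.dose = np.zeros(case.grid.shape)
        case.fluence = np.zeros((9, 64, 64))
        ops = build_all_operators(case.grid, case.beams)
        tc = TrainingCase(case, ops)
        L = 16
        starts = tc.valid_starts(L)
        lo, hi = tc.ptv_slices.min(), tc.ptv_slices.max()
        for s in range(case.grid.shape[0] - L + 1):
            overlaps = (s + L - 1 >= lo) and (s <= hi)
            assert (s in starts) == overlaps

    def test_start_uniform_when_ptv_covers_all_slices(self):
        """Chi-square uniformity over 10^4 draws at alpha = 0.01."""
        config = PhantomConfig(grid_shape=(32, 48, 48), fluence_shape=(64, 64))
        case = generate_anatomy(5, config)
        case.ptv_dose_mask[:, 24, 24] = 7000.0  # PTV touches every slice
        case.dose = np.zeros(case.grid.shape)
        case.fluence = np.zeros((9, 64, 64))
        ops = build_all_operators(case.grid, case.beams)
        tc = TrainingCase(case, ops)
        cache = PatchOperatorCache(ops, patch_slices=16)
        n_starts = 32 - 16 + 1
        assert tc.valid_starts(16).size == n_starts
        rng = np.random.default_rng(7)
        counts = np.zeros(n_starts)
        for _ in range(10_000):
            counts[sample_patch(tc, rng, cache).start] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=n_starts - 1)
        assert p > 0.01

    def test_fixed_seed_reproduces_patch_sequence(self, training_case, op_cache):
        seq1 = [sample_patch(training_case, np.random.default_rng(3), op_cache).start
                for _ in range(5)]
        seq2 = [sample_patch(training_case, np.random.default_rng(3), op_cache).start
                for _ in range(5)]
        assert seq1 == seq2

    def test_fluence_rows_align_with_patch_slices(self, training_case, op_cache):
        patch = extract_patch(training_case, 0, op_cache)
        assert patch.fluence.shape == (9, 16, 32)
        r0, r1 = op_cache.rows_for_start(0)
        np.testing.assert_array_equal(
            patch.fluence, training_case.fluence[:, r0:r1, :]
        )


class TestAugmentation:
    def test_no_augmentation_probability(self):
        """Monte-Carlo estimate of the untouched-case probability over
        10^6 seeded draws matches (1-0.6)(1-0.4) = 0.24 within 0.002."""
        rng = np.random.default_rng(123)
        none = sum(
            1 for _ in range(1_000_000)
            if draw_augmentation(rng) == (False, 0)
        )
        assert none / 1e6 == pytest.approx(0.24, abs=0.002)

    def test_rotation_draw_uniform_over_eight_angles(self):
        rng = np.random.default_rng(5)
        ks = [draw_augmentation(rng)[1] for _ in range(200_000)]
        ks = [k for k in ks if k > 0]
        counts = np.bincount(ks, minlength=9)[1:]
        assert counts.min() > 0.9 * counts.mean()

    def test_flip_twice_is_identity(self, training_case, op_cache):
        patch = extract_patch(training_case, 0, op_cache)
        twice = flip_leftright(flip_leftright(patch))
        np.testing.assert_array_equal(twice.inputs, patch.inputs)
        np.testing.assert_array_equal(twice.dose, patch.dose)
        np.testing.assert_array_equal(twice.fluence, patch.fluence)
        np.testing.assert_array_equal(twice.bev, patch.bev)

    def test_rotation_matches_beam_shift_oracle(self, micro_case, micro_ops):
        """Projecting the rotated anatomy through beam b agrees with
        projecting the original through beam b-k (mod 9), up to
        nearest-neighbor resampling error — and disagrees strongly with
        the opposite shift."""
        vol = (micro_case.ptv_dose_mask > 0).astype(float)
        for k in (1, 3):
            rot = _rot_vol(vol, k, order=0)
            for b in (0, 4):
                got = project_volume(micro_ops[b], rot)
                want = project_volume(micro_ops[(b - k) % 9], vol)
                wrong = project_volume(micro_ops[(b + k) % 9], vol)
                rel = np.abs(got - want).sum() / (np.abs(got) + np.abs(want)).sum()
                rel_wrong = np.abs(got - wrong).sum() / (np.abs(got) + np.abs(wrong)).sum()
                assert rel < 0.15
                assert rel_wrong > 2 * rel

    def test_fluence_channels_roll_with_rotation(self, training_case, op_cache):
        patch = extract_patch(training_case, 0, op_cache)
        rot = rotate_axial(patch, 2)
        np.testing.assert_array_equal(rot.fluence, np.roll(patch.fluence, 2, axis=0))

    def test_flip_remaps_mirror_beams_and_columns(self, training_case, op_cache):
        patch = extract_patch(training_case, 0, op_cache)
        fl = flip_leftright(patch)
        # beam 0 (gantry 0) is self-mirror: columns reversed only
        np.testing.assert_array_equal(fl.fluence[0], patch.fluence[0][:, ::-1])
        # beam 1 (40 deg) takes the map of beam 8 (320 deg)
        np.testing.assert_array_equal(fl.fluence[1], patch.fluence[8][:, ::-1])


class TestDualLoss:
    def test_zero_for_perfect_prediction(self, training_case, op_cache):
        p = extract_patch(training_case, 0, op_cache)
        loss, parts = dual_loss(p.dose, p.fluence, p.dose, p.fluence, p.body, p.bev)
        assert loss == 0.0

    def test_hand_computed_toy(self):
        """dose diffs {0.1, 0.3} in body, fluence diff {0.2} in mask:
        loss = mean(0.1,0.3) + 0.2 = 0.4."""
        pred_d = np.array([[[0.1, 0.3]], [[0.0, 9.9]]])
        targ_d = np.zeros_like(pred_d)
        body = np.array([[[True, True]], [[False, False]]])
        pred_f = np.full((1, 8, 2), 0.2)
        targ_f = np.zeros_like(pred_f)
        bev = np.zeros((1, 8, 2), dtype=bool)
        bev[0, 4, 1] = True
        loss, parts = dual_loss(pred_d, pred_f, targ_d, targ_f, body, bev, edge_trim=3)
        assert loss == pytest.approx(0.4)
        assert parts["dose_mae"] == pytest.approx(0.2)
        assert parts["fluence_mae"] == pytest.approx(0.2)

    def test_edge_rows_excluded_from_fluence_term(self, training_case, op_cache, rng):
        p = extract_patch(training_case, 0, op_cache)
        pred = p.fluence.copy()
        pred[:, :3, :] += rng.random((9, 3, 32))  # perturb excluded rows only
        pred[:, -3:, :] += rng.random((9, 3, 32))
        loss, _ = dual_loss(p.dose, pred, p.dose, p.fluence, p.body, p.bev)
        assert loss == 0.0

    def test_loss_mask_uses_middle_rows_only(self, training_case, op_cache):
        from dosefluence.training import _fluence_loss_mask

        mask = _fluence_loss_mask(np.ones((9, 32, 160), dtype=bool), edge_trim=3)
        rows_used = np.unique(np.where(mask)[1])
        assert rows_used.size == 26
        np.testing.assert_array_equal(rows_used, np.arange(3, 29))

    def test_gradient_matches_sign_structure(self, training_case, op_cache):
        p = extract_patch(training_case, 0, op_cache)
        pred_d = p.dose + 0.5
        loss, gd, gf, _ = dual_loss_and_grad(
            pred_d, p.fluence, p.dose, p.fluence, p.body, p.bev
        )
        nb = p.body.sum()
        np.testing.assert_allclose(gd[p.body], 1.0 / nb)
        assert not gd[~p.body].any()

    def test_empty_masks_warn_and_skip(self, training_case, op_cache):
        p = extract_patch(training_case, 0, op_cache)
        with pytest.warns(UserWarning, match="body"):
            loss, parts = dual_loss(
                p.dose + 1, p.fluence, p.dose, p.fluence,
                np.zeros_like(p.body), p.bev,
            )
        assert "dose_mae" not in parts

    def test_augmentation_consistency(self, training_case, op_cache):
        """The masked loss is invariant under a joint flip of predictions
        and targets (exact: flipping permutes masked elements)."""
        p = extract_patch(training_case, 0, op_cache)
        rng = np.random.default_rng(0)
        pred_d = p.dose + rng.normal(0, 0.01, p.dose.shape)
        pred_f = p.fluence + rng.normal(0, 0.01, p.fluence.shape)
        base, _ = dual_loss(pred_d, pred_f, p.dose, p.fluence, p.body, p.bev)
        fp = flip_leftright(p)
        fake = copy.copy(p)
        fake.dose, fake.fluence = pred_d, pred_f
        ffake = flip_leftright(fake)
        flipped, _ = dual_loss(
            ffake.dose, ffake.fluence, fp.dose, fp.fluence, fp.body, fp.bev
        )
        assert flipped == pytest.approx(base, rel=1e-9)


class TestScheduler:
    def test_plateau_reduces_lr_by_exactly_30_percent(self):
        p = {"w": Param(np.zeros(1))}
        opt = Adam(p, lr=3e-4)
        sched = ReduceLROnPlateau(opt, factor=0.7, patience=4)
        sched.step(1.0)  # initial best
        reductions = 0
        for _ in range(20):
            if sched.step(1.0):  # never improves
                reductions += 1
            if reductions == 2:
                break
        assert opt.lr == pytest.approx(3e-4 * 0.7**2)

    def test_improvement_resets_patience(self):
        p = {"w": Param(np.zeros(1))}
        opt = Adam(p, lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.7, patience=4)
        vals = [1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.8]
        for v in vals:
            sched.step(v)
        assert opt.lr == 1e-3  # never more than 4 bad epochs in a row
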