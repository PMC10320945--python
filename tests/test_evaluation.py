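"""Fluence/dose metrics: MAE%, SSIM, gamma, DVH indices, paired tests."""

import numpy as np
import pytest
from scipy import ndimage

from dosefluence.evaluation import (
    clinical_indices,
    dvh,
    evaluate_cohort,
    gamma_pass_rate,
    masked_mae_percent,
    paired_wilcoxon,
    ssim_map,
)


class TestMaskedMae:
    def test_perfect_prediction_is_zero(self, rng):
        gt = rng.random((8, 8))
        mask = np.ones_like(gt, dtype=bool)
        assert masked_mae_percent(gt, gt, mask) == 0.0

    def test_forced_by_formula(self):
        gt = np.zeros((4, 4))
        gt[0, 0] = 10.0
        pred = gt + 0.5
        assert masked_mae_percent(pred, gt, np.ones_like(gt, bool)) == pytest.approx(5.0)

    def test_random_instance_vs_elementwise_oracle(self, rng):
        gt = rng.random((8, 8)) * 100
        pred = gt + rng.normal(0, 5, (8, 8))
        mask = rng.random((8, 8)) > 0.4
        oracle = 0.0
        n = 0
        for i in range(8):
            for j in range(8):
                if mask[i, j]:
                    oracle += abs(pred[i, j] - gt[i, j])
                    n += 1
        oracle = 100 * oracle / n / gt.max()
        assert masked_mae_percent(pred, gt, mask) == pytest.approx(oracle, rel=1e-12)

    def test_scale_invariance(self, rng):
        gt = rng.random((8, 8)) + 0.1
        pred = gt + rng.normal(0, 0.05, (8, 8))
        mask = np.ones_like(gt, bool)
        a = masked_mae_percent(pred, gt, mask)
        b = masked_mae_percent(3.7 * pred, 3.7 * gt, mask)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_mask_and_zero_max_rejected(self, rng):
        gt = rng.random((4, 4))
        with pytest.raises(ValueError, match="mask"):
            masked_mae_percent(gt, gt, np.zeros_like(gt, bool))
        with pytest.raises(ValueError, match="maximum"):
            masked_mae_percent(gt, np.zeros((4, 4)), np.ones((4, 4), bool))


class TestSsim:
    def test_identical_maps_give_one(self, rng):
        gt = rng.random((32, 32))
        assert ssim_map(gt, gt) == pytest.approx(1.0)

    def test_constant_shift_equals_luminance_closed_form(self):
        """On constant images a constant offset leaves only the luminance
        term: (2*ux*uy + C1) / (ux^2 + uy^2 + C1)."""
        gt = np.full((32, 32), 10.0)
        pred = gt + 50.0
        c1 = (0.01 * 10.0) ** 2
        expected = (2 * 60.0 * 10.0 + c1) / (60.0**2 + 10.0**2 + c1)
        got = ssim_map(pred, gt)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got < 1.0

    def test_matches_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        for _ in range(3):
            gt = rng.random((24, 24)) * 100
            pred = gt + rng.normal(0, 10, (24, 24))
            ref = structural_similarity(
                pred, gt, win_size=11, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=gt.max(),
            )
            assert ssim_map(pred, gt) == pytest.approx(ref, abs=1e-6)

    def test_constant_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ssim_map(np.ones((16, 16)), np.zeros((16, 16)))


def _gamma_oracle(ref, ev, dd=3.0, dta=3.0, thr=0.0, pixel=2.5, fine=0.1):
    """Exhaustive fine-grid gamma: bilinear upsampling of the eval map at
    0.1 px pitch over the full search disc."""
    rmax = ref.max()
    dd_abs = dd / 100 * rmax
    H, W = ref.shape
    search = 3.0 * dta
    offs = np.arange(-search / pixel, search / pixel + fine / 2, fine)
    passes = []
    for i in range(H):
        for j in range(W):
            if ref[i, j] < thr / 100 * rmax:
                continue
            best = np.inf
            for dy in offs:
                for dx in offs:
                    dist = np.hypot(dy, dx) * pixel
                    if dist > search or dist**2 / dta**2 >= best:
                        continue
                    val = ndimage.map_coordinates(
                        ev, [[i + dy], [j + dx]], order=1, mode="nearest"
                    )[0]
                    g2 = ((val - ref[i, j]) / dd_abs) ** 2 + dist**2 / dta**2
                    best = min(best, g2)
            passes.append(np.sqrt(best) <= 1.0)
    return 100.0 * np.mean(passes)


class TestGamma:
    def test_identical_maps_pass_fully(self, rng):
        ref = rng.random((16, 16)) * 100
        assert gamma_pass_rate(ref, ref) == 100.0

    def test_within_one_point_of_exhaustive_oracle(self, rng):
        ref = ndimage.gaussian_filter(rng.random((16, 16)), 1.0)
        ref = ref / ref.max() * 100
        ev = ref * (1 + rng.normal(0, 0.04, ref.shape))
        got = gamma_pass_rate(ref, ev, pixel_mm=2.5)
        oracle = _gamma_oracle(ref, ev)
        assert abs(got - oracle) <= 1.0

    def test_low_dose_threshold_changes_denominator(self):
        """Hand-built map: one low-dose pixel fails (its whole 9 mm search
        neighborhood reads 50 while the reference reads 5); at a 10%
        threshold it leaves the evaluated set, changing the rate by a hand
        count: 255/256 -> 256/256."""
        ref = np.full((16, 16), 50.0)
        ref[8, 8] = 100.0  # map maximum
        ref[0, 0] = 5.0  # 5% of max: excluded at the 10% threshold
        ev = ref.copy()
        ev[0:4, 0:4] = 50.0  # uniform 50 across the corner search disc
        all_rate = gamma_pass_rate(ref, ev, threshold_percent=0.0)
        thr_rate = gamma_pass_rate(ref, ev, threshold_percent=10.0)
        assert all_rate == pytest.approx(100 * 255 / 256)
        assert thr_rate == 100.0

    def test_asymmetric_in_arguments(self):
        ref = np.zeros((9, 9))
        ref[4, 4] = 100.0
        ev = np.zeros((9, 9))
        ev[4, 4] = 100.0
        ev[0, 0] = 50.0  # extra hot spot far from any reference dose
        # ref -> ev: the zero reference pixel at (0,0) sees 50 nearby: fails
        a = gamma_pass_rate(ref, ev)
        b = gamma_pass_rate(ev, ref)
        assert a != b

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            gamma_pass_rate(np.zeros((4, 4)), np.ones((4, 4)))


class TestDvh:
    def test_uniform_dose_step_curve(self):
        dose = np.full((4, 4, 4), 7000.0)
        mask = np.ones_like(dose, bool)
        edges, v = dvh(dose, mask, bin_cgy=10.0)
        assert v[0] == 1.0
        np.testing.assert_array_equal(v[edges <= 7000.0], 1.0)
        np.testing.assert_array_equal(v[edges > 7000.0], 0.0)

    def test_linear_ramp_matches_analytic_line(self):
        n = 10000
        dose = np.linspace(0, 7000, n).reshape(1, 1, -1)
        mask = np.ones_like(dose, bool)
        edges, v = dvh(dose, mask, bin_cgy=10.0)
        analytic = np.clip(1 - edges / 7000.0, 0, 1)
        assert np.abs(v - analytic).max() <= 10.0 / 7000.0 + 1e-6

    def test_monotone_non_increasing(self, rng):
        dose = rng.random((6, 6, 6)) * 8000
        _, v = dvh(dose, np.ones_like(dose, bool))
        assert np.all(np.diff(v) <= 0)


class TestClinicalIndices:
    def test_uniform_dose(self):
        dose = np.full((3, 3, 3), 6400.0)
        idx = clinical_indices(dose, np.ones_like(dose, bool))
        assert idx == {"D95": 64.0, "Dmean": 64.0, "Dmax": 64.0}

    def test_percentile_convention_on_1_to_100(self):
        dose = (np.arange(1, 101, dtype=float) * 100).reshape(4, 5, 5)  # 1..100 Gy
        idx = clinical_indices(dose, np.ones_like(dose, bool))
        assert idx["D95"] == 5.0  # 5th percentile, lower interpolation
        assert idx["Dmean"] == pytest.approx(50.5)
        assert idx["Dmax"] == 100.0

    def test_ordering_property(self, rng):
        for _ in range(5):
            dose = rng.random((5, 5, 5)) * 7000
            mask = rng.random((5, 5, 5)) > 0.3
            idx = clinical_indices(dose, mask)
            assert idx["D95"] <= idx["Dmean"] <= idx["Dmax"]


class TestWilcoxon:
    def test_constant_shift_gives_minimal_exact_p(self):
        """b = a + c, n = 10: the most extreme signed-rank statistic has
        two-sided exact p = 2/2^10."""
        a = np.arange(10, dtype=float)
        b = a + 3.0
        p, sig, defined = paired_wilcoxon(a, b)
        assert defined
        assert p == pytest.approx(2 / 2**10)
        assert sig

    def test_symmetric_differences_not_significant(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        b = np.array([2.0, 1, 4, 3, 6, 5, 8, 7])  # +-1 alternating
        p, sig, defined = paired_wilcoxon(a, b)
        assert defined
        assert p > 0.05
        assert not sig

    def test_identical_vectors_flagged_undefined(self):
        a = np.ones(10)
        p, sig, defined = paired_wilcoxon(a, a)
        assert not defined
        assert np.isnan(p)
        assert not sig

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact p for small n agrees with explicit enumeration of all
        sign assignments of the rank sum."""
        from itertools import product

        a = rng.random(8)
        b = a + rng.normal(0, 1, 8)
        d = b - a
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_plus = ranks[d > 0].sum()
        n = len(d)
        stats_all = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in product([0, 1], repeat=n)
        ]
        w = min(w_plus, n * (n + 1) / 2 - w_plus)
        count = sum(1 for t in stats_all if min(t, n * (n + 1) / 2 - t) <= w)
        p_oracle = count / 2**n
        p, _, _ = paired_wilcoxon(a, b)
        assert p == pytest.approx(p_oracle, rel=1e-9)


@pytest.fixture(scope="module")
def perfect_report(micro_case, micro_ops):
    import copy

    cases = []
    for shift in (0.0, 10.0, 20.0):
        c = copy.copy(micro_case)
        c.dose = micro_case.dose + shift  # distinct but consistent cases
        cases.append(c)
    predicted = [(c.dose.copy(), c.fluence.copy()) for c in cases]
    flugen = [c.dose.copy() for c in cases]
    return evaluate_cohort(cases, predicted, flugen, micro_ops)


class TestCohortEvaluation:
    def test_ground_truth_predictions_score_perfectly(self, perfect_report):
        rep = perfect_report
        assert (rep.fluence_per_case["mae_percent"] == 0).all()
        np.testing.assert_allclose(rep.fluence_per_case["ssim"], 1.0, rtol=1e-9)
        assert (rep.fluence_per_case["gamma_0"] == 100.0).all()
        assert (rep.fluence_per_case["gamma_10"] == 100.0).all()
        assert (rep.dose_indices["gt"] == rep.dose_indices["predicted"]).all()

    def test_report_schema_covers_all_structures(self, perfect_report):
        rep = perfect_report
        assert set(rep.dose_indices["structure"]) == set(
            ("ptv_gtv", "ptv_1", "ptv_2", "ptv_ln_l", "ptv_ln_r")
        ) | {
            "body", "brainstem", "spinal_cord", "chiasm", "tongue",
            "optic_nerve_l", "optic_nerve_r", "lens_l", "lens_r",
            "temporal_lobe_l", "temporal_lobe_r", "mandible_l", "mandible_r",
            "tmj_l", "tmj_r", "parotid_l", "parotid_r",
        }
        assert set(rep.dose_indices["index"]) == {"D95", "Dmean", "Dmax"}
        assert len(rep.dose_cohort) == 22 * 3
        for col in ("gt_mean", "predicted_mean", "fluence_generated_mean",
                    "p1", "p2"):
            assert col in rep.dose_cohort.columns
        assert rep.fluence_per_case["beam"].nunique() == 9

    def test_cohort_mean_sd_matches_aggregation_oracle(self, perfect_report):
        rep = perfect_report
        grp = rep.dose_indices[
            (rep.dose_indices["structure"] == "ptv_gtv")
            & (rep.dose_indices["index"] == "Dmean")
        ]
        row = rep.dose_cohort[
            (rep.dose_cohort["structure"] == "ptv_gtv")
            & (rep.dose_cohort["index"] == "Dmean")
        ].iloc[0]
        vals = grp["gt"].to_numpy()
        assert row["gt_mean"] == pytest.approx(vals.mean())
        assert row["gt_sd"] == pytest.approx(vals.std(ddof=1))

    def test_report_round_trips_to_disk(self, perfect_report, tmp_path):
        perfect_report.save(tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "dose_cohort.csv").exists()
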