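"""Validation statistics: agreement, error, reproducibility estimators."""

import numpy as np
import pytest

from slovasc import evalstats as ev
from slovasc.errors import ParameterError


def _pairs(m1, m2):
    return ev.PairedMeasurements(list(range(len(m1))), np.asarray(m1), np.asarray(m2))


class TestDice:
    def test_identical_nonempty_is_one(self, rng):
        m = rng.random((20, 20)) > 0.5
        assert ev.dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert ev.dice(a, b) == 0.0

    def test_subset_counting_oracle(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.ravel()[:50] = True
        b.ravel()[:100] = True
        assert ev.dice(a, b) == pytest.approx(2 * 50 / 150)

    def test_symmetric_and_empty_convention(self, rng):
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        assert ev.dice(a, b) == ev.dice(b, a)
        assert ev.dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0


class TestAUC:
    def test_perfect_and_constant(self):
        t = np.array([[1, 1], [0, 0]], bool)
        assert ev.auc(t.astype(float), t) == 1.0
        assert ev.auc(np.full((2, 2), 0.5), t) == 0.5

    def test_four_pixel_case_exhaustive(self):
        p = np.array([0.9, 0.8, 0.3, 0.1]).reshape(2, 2)
        t = np.array([1, 1, 0, 0], bool).reshape(2, 2)
        assert ev.auc(p, t) == 1.0

    def test_matches_sklearn_oracle(self, rng):
        p = rng.random((30, 30))
        t = rng.random((30, 30)) > 0.7
        from sklearn.metrics import roc_auc_score

        assert ev.auc(p, t) == pytest.approx(roc_auc_score(t.ravel(), p.ravel()))

    def test_complement_invariance(self, rng):
        p = rng.random((20, 20))
        t = rng.random((20, 20)) > 0.5
        assert ev.auc(1 - p, ~t) == pytest.approx(ev.auc(p, t))


class TestMAE:
    def test_trivial_cases(self):
        assert ev.mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert ev.mae([2.0, 0.0], [1.0, 3.0]) == 2.0

    def test_diagonal_combination(self):
        assert ev.combine_axis_mae(6.28, 4.78) == pytest.approx(7.9, abs=0.05)
        assert ev.combine_axis_mae(3.0, 4.0) == 5.0
        assert ev.combine_axis_mae(0.0, 2.5) == 2.5


class TestUnitConversions:
    def test_posterior_pole_field_scale(self):
        scale = ev.field_scale_um_per_px(9.0, 768)
        assert scale == pytest.approx(11.71875)
        assert np.floor(scale * 100) / 100 == 11.71

    def test_area_conversion(self):
        assert ev.px2_to_mm2(638.17, 11.71875) == pytest.approx(0.0876, abs=0.0002)
        assert ev.px_to_um(5.0, 11.71) == pytest.approx(58.55)
        assert ev.px_to_um(0.0, 11.71) == 0.0


class TestBlandAltman:
    def test_identical_pairs(self):
        md, lo, hi = ev.bland_altman(_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert (md, lo, hi) == (0.0, 0.0, 0.0)

    def test_plus_minus_one_closed_form(self):
        md, lo, hi = ev.bland_altman(_pairs([1.0, 0.0], [0.0, 1.0]))
        assert md == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2))
        assert lo == pytest.approx(-1.96 * np.sqrt(2))

    def test_injected_bias_recovered(self, rng):
        base = rng.normal(0, 5, 500)
        m1 = base + 0.7 + rng.normal(0, 0.3, 500)
        md, lo, hi = ev.bland_altman(_pairs(m1, base))
        assert md == pytest.approx(0.7, abs=0.06)
        assert lo < md < hi


class TestICC:
    def test_exact_repeat_is_one(self):
        m = np.array([1.0, 5.0, 9.0, 2.0])
        icc, ci = ev.icc31(_pairs(m, m))
        assert icc == pytest.approx(1.0)

    def test_constant_offset_keeps_consistency_at_one(self):
        m = np.array([1.0, 5.0, 9.0, 2.0])
        icc, _ = ev.icc31(_pairs(m, m + 3.0))
        assert icc == pytest.approx(1.0)

    def test_variance_components_closed_form(self, rng):
        n, sb, sw = 500, 10.0, 1.0
        b = rng.normal(0, sb, n)
        icc, ci = ev.icc31(_pairs(b + rng.normal(0, sw, n), b + rng.normal(0, sw, n)))
        assert icc == pytest.approx(sb**2 / (sb**2 + sw**2), abs=0.01)
        assert ci[0] < icc < ci[1]

    def test_matches_pingouin_oracle(self, rng):
        import pandas as pd
        import pingouin as pg

        m1 = rng.normal(0, 3, 20)
        m2 = m1 + rng.normal(0, 1, 20)
        icc, ci = ev.icc31(_pairs(m1, m2))
        frame = pd.DataFrame({
            "targets": np.repeat(np.arange(20), 2),
            "raters": np.tile(["a", "b"], 20),
            "scores": np.column_stack([m1, m2]).ravel(),
        })
        ref = pg.intraclass_corr(frame, targets="targets", raters="raters",
                                 ratings="scores")
        # two-way mixed, single measure, consistency: labeled ICC(C,1)
        row = ref[ref.Type.isin(["ICC3", "ICC(C,1)"])].iloc[0]
        ref_ci = row[[c for c in ref.columns if c.startswith("CI95")][0]]
        assert icc == pytest.approx(row.ICC, abs=1e-9)
        assert ci[0] == pytest.approx(ref_ci[0], abs=0.01)
        assert ci[1] == pytest.approx(ref_ci[1], abs=0.01)


class TestLambda:
    def test_identical_repeats_give_zero(self):
        m = np.array([1.0, 5.0, 9.0])
        assert np.all(ev.lambda_noise(_pairs(m, m)) == 0.0)

    def test_single_eye_worked_example(self):
        # one eye measured {9, 11}: within-eye sd = sqrt(2); choose the other
        # eyes so the sd of eye means is exactly 10
        m1 = np.array([9.0, 0.0, 10.0, 20.0])
        m2 = np.array([11.0, 0.0, 10.0, 20.0])
        means = (m1 + m2) / 2
        lam = ev.lambda_noise(_pairs(m1, m2))
        expect = 100 * np.sqrt(2) / np.std(means, ddof=1)
        assert lam[0] == pytest.approx(expect)
        assert np.std(means, ddof=1) == pytest.approx(np.std([10, 0, 10, 20], ddof=1))

    def test_scale_invariance(self, rng):
        m1 = rng.normal(10, 2, 30)
        m2 = m1 + rng.normal(0, 0.5, 30)
        lam = ev.lambda_noise(_pairs(m1, m2))
        lam_scaled = ev.lambda_noise(_pairs(7.3 * m1, 7.3 * m2))
        assert np.allclose(lam, lam_scaled)

    def test_half_normal_median_closed_form(self, rng):
        # with k = 2 repeats the per-eye sd is sigma_w * |z|, half-normal;
        # median lambda -> 100 * rho * 0.6745 / sqrt(1 + rho^2 / 2)
        n, sb, rho = 4000, 10.0, 0.25
        sw = rho * sb
        b = rng.normal(0, sb, n)
        lam = ev.lambda_noise(_pairs(b + rng.normal(0, sw, n),
                                     b + rng.normal(0, sw, n)))
        expect = 100 * rho * 0.674490 / np.sqrt(1 + rho**2 / 2)
        assert np.median(lam) == pytest.approx(expect, rel=0.05)

    def test_zero_between_variability_rejected(self):
        with pytest.raises(ParameterError):
            ev.lambda_noise(_pairs([1.0, 1.0], [1.0, 1.0]))


class TestReproReport:
    def test_report_internal_consistency(self, rng):
        b = rng.normal(50, 8, 60)
        pairs = _pairs(b + rng.normal(0, 1, 60), b + rng.normal(0, 1, 60))
        rep = ev.repro_report(pairs)
        assert rep.loa_low <= rep.mean_difference <= rep.loa_high
        assert -1 <= rep.pearson_r <= 1 and -1 <= rep.spearman_rho <= 1
        assert rep.lambda_iqr_pct[0] <= rep.lambda_median_pct <= rep.lambda_iqr_pct[1]
        assert np.all(rep.lambda_per_eye_pct >= 0)
        row = rep.to_row()
        assert row["n_eyes"] == 60 and "ICC31" in row
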