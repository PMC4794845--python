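import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dpmquant.errors import DesignError, DpmQuantError
from dpmquant.protein_quant import (
    GTestResult,
    RatioStats,
    bh_correct,
    call_regulation,
    estimate_log_bias,
    g_test,
    protein_log_ratio,
    ratio_cv_profile,
    weighted_ratio_stats,
)


class TestProteinLogRatio:
    def test_null_case_all_ratios_one(self):
        rs = protein_log_ratio([(100.0, 100.0, 1.0)] * 3, log_bias=0.0)
        assert rs.weighted_log_ratio == 0.0
        assert rs.t_stat == 0.0
        assert rs.p_value == 1.0
        assert rs.ratio == 1.0

    def test_hand_computed_t_test(self):
        # Four equal-weight peptides with log10 ratios 0.30/0.28/0.32/0.30.
        # Oracle arithmetic: mean 0.30, s = sqrt(8e-4/3), SE = s/2,
        # t = 0.30/SE, p = 2*sf(t, 3).
        xs = [0.30, 0.28, 0.32, 0.30]
        areas = [(10.0**x, 1.0, 1.0) for x in xs]
        rs = protein_log_ratio(areas, log_bias=0.0)
        s = math.sqrt(sum((x - 0.30) ** 2 for x in xs) / 3)
        t_expected = 0.30 / (s / 2.0)
        assert rs.weighted_log_ratio == pytest.approx(0.30, abs=1e-12)
        assert rs.t_stat == pytest.approx(t_expected, rel=1e-9)
        assert rs.p_value == pytest.approx(2 * sps.t.sf(t_expected, 3), rel=1e-9)
        assert rs.p_value < 0.05

    def test_single_peptide_undefined_markers(self):
        rs = protein_log_ratio([(200.0, 100.0, 1.0)])
        assert rs.ratio == pytest.approx(2.0)
        assert math.isnan(rs.p_value)
        assert math.isnan(rs.error_factor)
        assert rs.n_peptides == 1

    def test_error_factor_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            xs = rng.normal(0, 0.2, size=5)
            rs = weighted_ratio_stats(xs, rng.uniform(1, 10, size=5))
            assert rs.error_factor >= 1.0

    def test_zero_area_rejected(self):
        with pytest.raises(DpmQuantError):
            protein_log_ratio([(0.0, 100.0, 1.0)])

    def test_weights_shift_mean_toward_heavy_peptides(self):
        rs = weighted_ratio_stats([0.0, 1.0], weights=[1.0, 9.0])
        assert rs.weighted_log_ratio == pytest.approx(0.9)


class TestLogBias:
    def test_symmetric_ratios_give_zero(self):
        assert estimate_log_bias([-0.2, 0.0, 0.2]) == 0.0

    def test_constant_ratios(self):
        assert estimate_log_bias([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(DpmQuantError):
            estimate_log_bias([])

    def test_recovers_systematic_offset_with_minority_changes(self):
        # 90 % null peptides around a 0.05 offset, 10 % true 2-fold changes.
        rng = np.random.default_rng(42)
        null = rng.normal(0.05, 0.08, size=900)
        changed = rng.normal(0.05 + math.log10(2), 0.08, size=100)
        bias = estimate_log_bias(np.concatenate([null, changed]))
        assert bias == pytest.approx(0.05, abs=0.02)


def _oracle_g(a: float, b: float) -> float:
    """Independent two-cell log-likelihood-ratio: 2 sum obs*ln(obs/exp)."""
    exp = (a + b) / 2.0
    total = 0.0
    for obs in (a, b):
        if obs > 0:
            total += obs * math.log(obs / exp)
    return 2.0 * total


class TestGTest:
    def test_equal_areas_null(self):
        res = g_test(100.0, 100.0)
        assert res.g_value == 0.0
        assert res.p_raw == 1.0

    def test_worked_example(self):
        # 2*(100*ln(1/2) + 300*ln(3/2)) = 104.64963...
        res = g_test(100.0, 300.0)
        assert res.g_value == pytest.approx(104.6496281, abs=1e-6)
        assert res.g_value == pytest.approx(_oracle_g(100, 300), abs=1e-9)

    def test_zero_cell_convention(self):
        res = g_test(0.0, 50.0)
        assert res.g_value == pytest.approx(2 * 50 * math.log(2), abs=1e-9)

    def test_both_zero_rejected(self):
        with pytest.raises(DpmQuantError):
            g_test(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(DpmQuantError):
            g_test(-1.0, 10.0)

    @given(
        a=st.one_of(st.just(0.0), st.floats(1e-6, 1e6, allow_nan=False)),
        b=st.floats(1e-3, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_is_symmetric(self, a, b):
        res = g_test(a, b)
        assert res.g_value == pytest.approx(_oracle_g(a, b), abs=1e-9, rel=1e-9)
        assert g_test(b, a).g_value == pytest.approx(res.g_value, abs=1e-9, rel=1e-9)
        assert res.g_value >= 0.0

    def test_monotone_in_imbalance_at_fixed_total(self):
        total = 1000.0
        gs = [g_test(total / 2 - d, total / 2 + d).g_value for d in (0, 50, 150, 300)]
        assert gs[0] == 0.0
        assert all(g1 < g2 for g1, g2 in zip(gs, gs[1:]))


class TestBhCorrect:
    def test_single_p_value(self):
        adj, threshold = bh_correct([0.03], alpha=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert threshold == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        adj, threshold = bh_correct([0.01, 0.02, 0.04, 0.8], alpha=0.05)
        assert adj == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])
        # Largest raw p still rejected: 0.02 (0.04's adjusted 0.0533 > 0.05).
        assert threshold == pytest.approx(0.02)

    def test_all_ones_no_discoveries(self):
        adj, threshold = bh_correct([1.0, 1.0, 1.0], alpha=0.05)
        assert (adj == 1.0).all()
        assert math.isnan(threshold)

    def test_out_of_range_rejected(self):
        with pytest.raises(DpmQuantError):
            bh_correct([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_dominates_bonferroni(self, p):
        adj, _ = bh_correct(p, alpha=0.05)
        order = np.argsort(p)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0 + 1e-12)).all()
        # Every Bonferroni discovery is also a BH discovery.
        m = len(p)
        for pi, ai in zip(p, adj):
            if pi <= 0.05 / m:
                assert ai <= 0.05 + 1e-12


def _stats(acc, group, ratio, n=4):
    return RatioStats(acc, group, math.log10(ratio), 0.01, n, 1.05, 10.0, 1e-4)


def _gtest(acc, p_bh):
    return GTestResult(acc, 1000.0, 2000.0, 50.0, p_bh / 2, p_bh)


class TestCallRegulation:
    def test_female_up_male_unchanged_gender_differential(self):
        call = call_regulation(
            {"female": _stats("NADPH1", "female", 2.09),
             "male": _stats("NADPH1", "male", 0.89)},
            {"female": _gtest("NADPH1", 1e-5), "male": _gtest("NADPH1", 1e-5)},
        )
        assert call.call_vs_control == {"female": "up", "male": "unchanged"}
        assert call.modulated == {"female": True, "male": False}
        assert call.gender_difference == pytest.approx(1.20)
        assert call.gender_quotient == pytest.approx(2.09 / 0.89)
        assert call.is_gender_differential
        assert call.significance_tier == "p<0.001 & diff>=0.9"

    def test_unchanged_both_groups(self):
        call = call_regulation(
            {"female": _stats("P1", "female", 1.0), "male": _stats("P1", "male", 1.0)},
            {"female": _gtest("P1", 0.5), "male": _gtest("P1", 0.5)},
        )
        assert call.call_vs_control == {"female": "unchanged", "male": "unchanged"}
        assert not call.is_gender_differential
        assert call.significance_tier == "none"

    def test_half_ratio_called_down(self):
        call = call_regulation(
            {"female": _stats("GS", "female", 0.5), "male": _stats("GS", "male", 0.9)},
            {"female": _gtest("GS", 0.002), "male": _gtest("GS", 0.5)},
        )
        assert call.call_vs_control["female"] == "down"
        assert call.modulated["female"]

    def test_down_cutoff_is_rounded_to_067(self):
        call = call_regulation(
            {"female": _stats("P1", "female", 0.665),
             "male": _stats("P1", "male", 0.68)},
            {},
        )
        assert call.call_vs_control == {"female": "down", "male": "unchanged"}

    def test_missing_group_is_design_error(self):
        with pytest.raises(DesignError):
            call_regulation({"female": _stats("P1", "female", 1.0)}, {})


class TestRatioCvProfile:
    def test_identical_replicates_zero_cv(self):
        df, summary = ratio_cv_profile({"P1": [1.2, 1.2, 1.2]})
        assert df["cv_pct"].iloc[0] == pytest.approx(0.0)
        assert summary["frac_below"][50.0] == 1.0

    def test_two_replicate_hand_value(self):
        # mean 1.25, sd 0.35355..., CV = 28.2843 %
        df, _ = ratio_cv_profile({"P1": [1.0, 1.5]})
        assert df["cv_pct"].iloc[0] == pytest.approx(28.2842712, abs=1e-4)

    def test_zero_mean_gets_undefined_marker(self):
        df, _ = ratio_cv_profile({"P1": [1.0, -1.0]})
        assert math.isnan(df["cv_pct"].iloc[0])

    def test_recovers_generating_cv(self):
        # Log-normal replicate ratios with CV 20 %: median %CV near 20.
        rng = np.random.default_rng(5)
        sigma = math.sqrt(math.log(1 + 0.2**2))
        ratios = {
            f"P{i}": rng.lognormal(0.0, sigma, size=6) for i in range(300)
        }
        _, summary = ratio_cv_profile(ratios)
        assert summary["median_cv_pct"] == pytest.approx(20.0, abs=5.0)
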