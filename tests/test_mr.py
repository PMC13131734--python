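import numpy as np
import pandas as pd
import pytest

from pleiomr import mr, simulate
from pleiomr.sumstats_io import LDMatrix, SummaryStats
from conftest import make_sumstats_df
from oracles import bh_stepup, wls_through_origin


def _pair(bx, by, sy, sx=0.01):
    k = len(bx)
    return mr.HarmonizedPair(
        pd.DataFrame(
            {
                "variant_id": [f"iv{i}" for i in range(k)],
                "beta_exposure": bx,
                "se_exposure": sx,
                "beta_outcome": by,
                "se_outcome": sy,
            }
        )
    )


class TestSelectInstruments:
    def _stats(self, pvals):
        rows = [
            (f"rs{i}", "1", (i + 1) * 1000, "A", "G", 0.4, 0.1, 0.02, p, 1000)
            for i, p in enumerate(pvals)
        ]
        return SummaryStats(make_sumstats_df(rows), trait_label="exp")

    def test_filter_then_count(self):
        pvals = [1e-9, 1e-10, 4e-8, 1e-7, 0.01, 0.5, 0.9, 0.2]
        stats = self._stats(pvals)
        ld = LDMatrix([f"rs{i}" for i in range(8)], np.eye(8))
        got = mr.select_instruments(stats, ld)
        assert sorted(got) == ["rs0", "rs1", "rs2"]

    def test_correlated_pair_keeps_smaller_p(self):
        pvals = [1e-9, 1e-12, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        r = np.eye(8)
        r[0, 1] = r[1, 0] = np.sqrt(0.9)
        stats = self._stats(pvals)
        ld = LDMatrix([f"rs{i}" for i in range(8)], r)
        got = mr.select_instruments(stats, ld)
        assert got == ["rs1"]

    def test_no_significant_variant_is_fatal(self):
        stats = self._stats([0.1] * 8)
        ld = LDMatrix([f"rs{i}" for i in range(8)], np.eye(8))
        with pytest.raises(ValueError, match="exp"):
            mr.select_instruments(stats, ld)


class TestHarmonizePair:
    def _sumstats(self, rows, label):
        return SummaryStats(make_sumstats_df(rows), trait_label=label)

    def test_opposite_allele_coding_negates_outcome_beta(self):
        exp = self._sumstats(
            [("rs1", "1", 100, "A", "G", 0.3, 0.5, 0.02, 1e-9, 1000)], "exp"
        )
        out = self._sumstats(
            [("rs1", "1", 100, "G", "A", 0.7, 0.1, 0.02, 1e-4, 1000)], "out"
        )
        pair = mr.harmonize_pair(exp, out, ["rs1"])
        assert pair.table["beta_outcome"].iloc[0] == pytest.approx(-0.1)

    def test_palindromic_instrument_dropped(self):
        rows_e = [
            ("rs1", "1", 100, "A", "T", 0.3, 0.5, 0.02, 1e-9, 1000),
            ("rs2", "1", 200, "A", "G", 0.3, 0.4, 0.02, 1e-9, 1000),
        ]
        rows_o = [
            ("rs1", "1", 100, "A", "T", 0.3, 0.1, 0.02, 1e-3, 1000),
            ("rs2", "1", 200, "A", "G", 0.3, 0.1, 0.02, 1e-3, 1000),
        ]
        pair = mr.harmonize_pair(
            self._sumstats(rows_e, "e"), self._sumstats(rows_o, "o"), ["rs1", "rs2"]
        )
        assert pair.table["variant_id"].tolist() == ["rs2"]

    def test_all_lost_is_fatal(self):
        rows_e = [("rs1", "1", 100, "A", "T", 0.3, 0.5, 0.02, 1e-9, 1000)]
        rows_o = [("rs1", "1", 100, "A", "T", 0.3, 0.1, 0.02, 1e-3, 1000)]
        with pytest.raises(ValueError, match="all instruments"):
            mr.harmonize_pair(
                self._sumstats(rows_e, "e"), self._sumstats(rows_o, "o"), ["rs1"]
            )


class TestIvw:
    def test_single_instrument_reduces_to_wald_ratio(self):
        pair = _pair([0.5], [0.1], [0.02])
        res = mr.mr_ivw(pair)
        assert res.beta_causal == pytest.approx(0.2)
        assert res.se == pytest.approx(0.04)
        assert res.method == "Wald ratio"

    def test_homogeneous_ratios_give_q_zero(self):
        bx = np.array([0.2, 0.4, 0.6])
        pair = _pair(bx, 0.3 * bx, [0.02, 0.03, 0.01])
        res = mr.mr_ivw(pair)
        assert res.beta_causal == pytest.approx(0.3)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-20)

    def test_three_instrument_wls_oracle(self):
        bx = [0.31, 0.18, 0.44]
        by = [0.07, 0.031, 0.092]
        sy = [0.021, 0.017, 0.03]
        res = mr.mr_ivw(_pair(bx, by, sy))
        w = [1.0 / s**2 for s in sy]
        slope, se_fixed = wls_through_origin(bx, by, w)
        assert res.beta_causal == pytest.approx(slope, abs=1e-10)
        q = sum(wi * (yi - slope * xi) ** 2 for wi, xi, yi in zip(w, bx, by))
        assert res.se == pytest.approx(se_fixed * max(q / 2, 1) ** 0.5, abs=1e-10)

    def test_zero_exposure_betas_rejected(self):
        with pytest.raises(ValueError, match="identification"):
            mr.mr_ivw(_pair([0.0, 0.0], [0.1, 0.1], [0.02, 0.02]))


class TestEgger:
    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            mr.mr_egger(_pair([0.1, 0.2], [0.02, 0.04], [0.02, 0.02]))

    def test_collinear_constant_ratio_gives_zero_intercept(self):
        bx = np.array([0.1, 0.3, 0.5, 0.7])
        pair = _pair(bx, 0.25 * bx, np.full(4, 0.02))
        res = mr.mr_egger(pair)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert res.beta_causal == pytest.approx(0.25, abs=1e-12)

    def test_orientation_invariance(self):
        # flipping an instrument's allele coding must not change the fit
        bx = np.array([0.1, -0.3, 0.5, 0.7])
        by = 0.25 * bx + np.array([0.001, -0.002, 0.0, 0.001])
        a = mr.mr_egger(_pair(bx, by, np.full(4, 0.02)))
        bx2, by2 = bx.copy(), by.copy()
        bx2[1], by2[1] = -bx2[1], -by2[1]
        b = mr.mr_egger(_pair(bx2, by2, np.full(4, 0.02)))
        assert a.beta_causal == pytest.approx(b.beta_causal)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)


class TestMedianAndMode:
    def test_equal_weight_median(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.3])
        res = mr.mr_weighted_median(_pair(bx, by, np.full(3, 0.02)), n_boot=200, seed=0)
        assert res.beta_causal == pytest.approx(0.2)

    def test_same_seed_reproduces_se(self):
        pair = simulate.simulate_mr_instruments(k=10, seed=3)
        a = mr.mr_weighted_median(pair, n_boot=300, seed=7)
        b = mr.mr_weighted_median(pair, n_boot=300, seed=7)
        assert a.se == b.se

    def test_mode_point_mass(self):
        bx = np.array([0.2, 0.5, 0.9])
        pair = _pair(bx, 0.3 * bx, np.full(3, 0.02))
        res = mr.mr_weighted_mode(pair, n_boot=100, seed=0)
        assert res.beta_causal == pytest.approx(0.3, abs=1e-9)

    def test_mode_bandwidth_smoke(self):
        pair = simulate.simulate_mr_instruments(k=15, seed=4)
        a = mr.mr_weighted_mode(pair, bandwidth_factor=1.0, n_boot=100, seed=1)
        b = mr.mr_weighted_mode(pair, bandwidth_factor=2.0, n_boot=100, seed=1)
        assert np.isfinite(a.beta_causal) and np.isfinite(b.beta_causal)
        assert abs(a.beta_causal - b.beta_causal) < 0.05


class TestCochranQ:
    def test_identical_ratios(self):
        bx = np.array([0.2, 0.4, 0.6])
        q, df, p = mr.cochran_q(_pair(bx, 0.3 * bx, np.full(3, 0.02)), "ivw")
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_instrument_hand_computation(self):
        # equal weights, ratios 0 and 2r: slope r, Q = 2 w r^2
        r = 0.15
        pair = _pair([1.0, 1.0], [0.0, 2 * r], [0.1, 0.1])
        q, df, p = mr.cochran_q(pair, "ivw")
        w = 1.0 / 0.1**2
        assert q == pytest.approx(2 * w * r**2, rel=1e-12)
        assert df == 1

    def test_null_calibration(self):
        qs = []
        for s in range(200):
            pair = simulate.simulate_mr_instruments(k=20, seed=7000 + s)
            q, df, _ = mr.cochran_q(pair, "ivw")
            qs.append(q / df)
        # Q/df approximately 1 on average; exposure-side noise inflates mildly
        assert np.mean(qs) == pytest.approx(1.0, abs=0.15)

    def test_df_guard(self):
        q, df, p = mr.cochran_q(_pair([0.5], [0.1], [0.02]), "ivw")
        assert p is None


class TestLeaveOneOut:
    def test_homogeneous_estimates_equal_full(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        pair = _pair(bx, 0.3 * bx, np.full(4, 0.02))
        table = mr.leave_one_out(pair)
        assert len(table) == 4
        assert np.allclose(table["beta_causal"], 0.3)
        assert not table["flagged"].any()

    def test_planted_outlier_is_flagged(self):
        pair = simulate.simulate_mr_instruments(k=12, seed=8)
        t = pair.table.copy()
        t.loc[0, "beta_outcome"] += 20 * t.loc[0, "se_outcome"]
        table = mr.leave_one_out(mr.HarmonizedPair(t))
        assert table.loc[table["excluded"] == "iv001", "flagged"].iloc[0]


class TestPressoGlobal:
    def test_needs_four_instruments(self):
        with pytest.raises(ValueError):
            mr.presso_global(_pair([0.1] * 3, [0.02] * 3, [0.02] * 3))

    def test_same_seed_same_p(self):
        pair = simulate.simulate_mr_instruments(k=15, seed=9)
        p1 = mr.presso_global(pair, n_sim=200, seed=5)[2]
        p2 = mr.presso_global(pair, n_sim=200, seed=5)[2]
        assert p1 == p2

    def test_displaced_instrument_detected(self):
        pair = simulate.simulate_mr_instruments(k=20, seed=10)
        t = pair.table.copy()
        t.loc[0, "beta_outcome"] += 10 * t.loc[0, "se_outcome"]
        p = mr.presso_global(mr.HarmonizedPair(t), n_sim=300, seed=1)[2]
        assert p < 0.05


class TestOverlapAdjustment:
    def test_zero_overlap_identical_to_ivw(self):
        pair = simulate.simulate_mr_instruments(k=20, seed=11)
        base = mr.mr_ivw(pair)
        adj = mr.overlap_adjusted_ivw(pair, 0.0)
        assert adj.beta_causal == base.beta_causal
        assert adj.se == base.se

    def test_se_monotone_in_overlap(self):
        pair = simulate.simulate_mr_instruments(k=20, seed=12)
        ses = [
            mr.overlap_adjusted_ivw(pair, f, phenotype_corr=0.2).se
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b >= a - 1e-15 for a, b in zip(ses, ses[1:]))
        assert ses[-1] > ses[0]

    def test_point_estimate_unchanged(self):
        pair = simulate.simulate_mr_instruments(k=20, seed=13)
        base = mr.mr_ivw(pair)
        adj = mr.overlap_adjusted_ivw(pair, 1.0, phenotype_corr=0.3)
        assert adj.beta_causal == base.beta_causal


class TestMvmr:
    def test_zero_effect_exposure_reduces_to_univariable(self):
        pair = simulate.simulate_mr_instruments(k=20, seed=14)
        bx, _, by, sy = pair.arrays()
        uni = mr.mr_ivw(pair)
        res = mr.mvmr_ivw(by, sy, np.column_stack([bx, np.zeros_like(bx)]), ["x1", "x2"])
        assert res[0].beta_causal == pytest.approx(uni.beta_causal, abs=1e-12)
        assert np.isnan(res[1].beta_causal)

    def test_joint_recovery(self):
        rng = np.random.default_rng(15)
        k = 40
        g1 = rng.normal(0.1, 0.03, k)
        g2 = rng.normal(0.1, 0.03, k)
        sy = np.full(k, 0.005)
        by = 0.2 * g1 + 0.0 * g2 + rng.normal(0, sy)
        res = mr.mvmr_ivw(by, sy, np.column_stack([g1, g2]), ["a", "b"])
        assert res[0].beta_causal == pytest.approx(0.2, abs=3 * res[0].se)
        assert abs(res[1].beta_causal) <= 3 * res[1].se

    def test_duplicated_exposures_rejected(self):
        rng = np.random.default_rng(16)
        g = rng.normal(0.1, 0.03, 10)
        with pytest.raises(ValueError, match="collinear"):
            mr.mvmr_ivw(0.2 * g, np.full(10, 0.01), np.column_stack([g, g]))


class TestBhFdr:
    def test_stepup_hand_example(self):
        got = mr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, bh_stepup([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert mr.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.allclose(mr.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mr.bh_fdr([0.5, 0.0])


class TestModelInterface:
    def test_fit_all_battery(self):
        pair = simulate.simulate_mr_instruments(k=15, seed=17)
        battery = mr.MRModel(pair).fit_all(seed=0, n_boot=100)
        methods = battery.table()["method"].tolist()
        assert methods[0].startswith("IVW")
        assert {"MR-Egger", "Weighted median", "Weighted mode"} <= set(methods)
        assert "presso" in battery.extras
        assert "leave_one_out" in battery.extras
        assert battery.summary()

    def test_allele_relabel_invariance(self):
        pair = simulate.simulate_mr_instruments(k=10, seed=18)
        t = pair.table.copy()
        t.loc[3, ["beta_exposure", "beta_outcome"]] *= -1
        flipped = mr.HarmonizedPair(t)
        for fn in (mr.mr_ivw, mr.mr_egger):
            assert fn(pair).beta_causal == pytest.approx(fn(flipped).beta_causal)
        a = mr.mr_weighted_median(pair, n_boot=100, seed=2)
        b = mr.mr_weighted_median(flipped, n_boot=100, seed=2)
        assert a.beta_causal == pytest.approx(b.beta_causal)
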