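import numpy as np
import pandas as pd
import pytest

from pleiomr import pleiofdr, simulate
from pleiomr.sumstats_io import SummaryStats
from conftest import make_sumstats_df


def _stats_from_p(pvals, trait="t", start_pos=1):
    rows = [
        (f"rs{i}", "1", (start_pos + i) * 1000, "A", "G", 0.4, 0.1, 0.02, p, 1000)
        for i, p in enumerate(pvals)
    ]
    return SummaryStats(make_sumstats_df(rows), trait_label=trait)


class TestEnrichmentConfig:
    def test_default_cutoffs(self):
        assert pleiofdr.EnrichmentConfig().secondary_cutoffs == [0.1, 0.01, 0.001]

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError):
            pleiofdr.EnrichmentConfig(secondary_cutoffs=[0.01, 0.1])


class TestFoldEnrichment:
    def test_independent_traits_give_flat_curves(self):
        cfg = simulate.SimConfig(
            n_variants=100_000, pi_null=1.0, pi_A=0, pi_B=0, pi_shared=0, seed=21
        )
        a, b, _ = simulate.simulate_gwas_pair(cfg)
        curves = pleiofdr.fold_enrichment(a, b)
        for cutoff, grp in curves.groupby("cutoff"):
            if grp["n_stratum"].iloc[0] >= 500:
                assert grp["enrichment"].mean() == pytest.approx(1.0, abs=0.15)

    def test_planted_sharing_orders_curves_by_cutoff(self):
        # direct counting on repeated simulations: stricter secondary cutoff
        # concentrates shared signal, so enrichment must increase
        vals = {0.1: [], 0.001: []}
        for s in range(20):
            cfg = simulate.SimConfig(
                n_variants=30_000, pi_null=0.99, pi_A=0.0, pi_B=0.0,
                pi_shared=0.01, seed=500 + s,
            )
            a, b, _ = simulate.simulate_gwas_pair(cfg)
            curves = pleiofdr.fold_enrichment(a, b)
            at_t = curves[curves["neglog10_p"] == 2.0].set_index("cutoff")
            for c in vals:
                vals[c].append(at_t.loc[c, "enrichment"])
        assert np.mean(vals[0.001]) > np.mean(vals[0.1]) > 1.0

    def test_too_few_shared_variants_rejected(self):
        a = _stats_from_p(np.linspace(0.01, 1, 100))
        with pytest.raises(ValueError, match="1000"):
            pleiofdr.fold_enrichment(a, a)


class TestFitFdrGrid:
    def test_stratum_one_matches_unconditional_ecdf(self):
        # conditioning on everything is no conditioning: condFDR from the
        # cutoff-1.0 stratum equals p / ECDF(p), enumerated by hand
        # (p values sit on the lookup grid so the step ECDF is hit exactly)
        pvals = list(10.0 ** -np.array([3.0, 2.0, 1.5, 1.2, 1.0, 0.8, 0.6, 0.4, 0.2, 0.0]))
        a = _stats_from_p(pvals)
        b = _stats_from_p([1.0] * 10, trait="sec")
        grid = pleiofdr.fit_fdr_grid(a, b, ld=None, min_stratum=1, seed=0)
        for i, p in enumerate(pvals):
            ecdf = sum(q <= p for q in pvals) / len(pvals)
            expected = min(p / ecdf, 1.0)
            got = pleiofdr.condfdr_lookup(grid, p, 1.0)
            assert got == pytest.approx(expected, rel=0.02)

    def test_hand_computed_stratified_ecdf_two_strata(self):
        # 10 variants, secondary p splits them into a conditioned stratum of
        # 4; expected condFDR enumerated directly from the definition
        p1 = [1e-4, 1e-3, 0.01, 0.1, 0.3, 0.5, 0.01, 1e-3, 0.2, 1.0]
        p2 = [0.05, 0.5, 0.02, 0.9, 0.6, 0.7, 0.03, 0.01, 0.8, 1.0]
        a = _stats_from_p(p1)
        b = _stats_from_p(p2, trait="sec")
        grid = pleiofdr.fit_fdr_grid(
            a, b, ld=None, min_stratum=1, secondary_cutoffs=(1.0, 0.1), seed=0
        )
        stratum = [i for i in range(10) if p2[i] < 0.1]
        for i in stratum:
            ecdf_all = sum(q <= p1[i] for q in p1) / 10
            ecdf_s = sum(p1[j] <= p1[i] for j in stratum) / len(stratum)
            expected = min(p1[i] / max(ecdf_all, ecdf_s), 1.0)
            got = pleiofdr.condfdr_lookup(grid, p1[i], p2[i])
            assert got == pytest.approx(expected, rel=0.05)

    def test_null_independent_traits_condfdr_near_one_at_large_p(self):
        cfg = simulate.SimConfig(
            n_variants=20_000, pi_null=1.0, pi_A=0, pi_B=0, pi_shared=0,
            ld_rho=0.0, seed=22,
        )
        a, b, _ = simulate.simulate_gwas_pair(cfg)
        grid = pleiofdr.fit_fdr_grid(a, b, ld=None, seed=22)
        ps = np.linspace(0.5, 1.0, 20)
        vals = pleiofdr.condfdr_lookup(grid, ps, np.ones_like(ps))
        assert np.abs(vals - 1.0).mean() < 0.05

    def test_identity_ld_pruning_keeps_everything(self):
        rng = np.random.default_rng(0)
        ld = simulate.BlockLD(np.zeros(100, dtype=int), 0.0)
        assert pleiofdr._prune_mask(100, ld, rng).all()
        ldm = simulate.simulate_ld_matrix(30, 0.0)
        assert pleiofdr._prune_mask(30, ldm, rng).all()

    def test_pruning_respects_neighborhoods(self):
        rng = np.random.default_rng(1)
        ld = simulate.BlockLD(np.zeros(200, dtype=int), 0.9)
        keep = pleiofdr._prune_mask(200, ld, rng)
        assert 0 < keep.sum() < 200


class TestCondfdrLookup:
    @pytest.fixture
    def grid(self):
        cfg = simulate.SimConfig(n_variants=20_000, seed=23, ld_rho=0.0)
        a, b, _ = simulate.simulate_gwas_pair(cfg)
        return pleiofdr.fit_fdr_grid(a, b, ld=None, seed=23)

    def test_p_one_gives_condfdr_one(self, grid):
        for p2 in (1.0, 0.05, 0.0005):
            assert pleiofdr.condfdr_lookup(grid, 1.0, p2) == pytest.approx(1.0)

    def test_out_of_range_p_errors(self, grid):
        with pytest.raises(ValueError):
            pleiofdr.condfdr_lookup(grid, 0.0, 0.5)
        with pytest.raises(ValueError):
            pleiofdr.condfdr_lookup(grid, 0.5, 1.5)

    def test_tightening_stratum_never_increases_condfdr(self, grid):
        rng = np.random.default_rng(5)
        p1 = 10 ** rng.uniform(-8, 0, size=200)
        for p2_loose, p2_tight in [(1.0, 0.05), (0.05, 0.005), (0.5, 1e-4)]:
            loose = pleiofdr.condfdr_lookup(grid, p1, np.full(200, p2_loose))
            tight = pleiofdr.condfdr_lookup(grid, p1, np.full(200, p2_tight))
            assert (tight <= loose + 1e-12).all()


class TestConjFdr:
    def test_max_rule(self):
        assert pleiofdr.conjfdr(0.2, 0.04) == pytest.approx(0.2)
        assert pleiofdr.conjfdr(0.3, 0.3) == pytest.approx(0.3)

    def test_threshold_constant(self):
        assert pleiofdr.CONJFDR_THRESHOLD == 0.05

    def test_conjfdr_bounds_both_directions_and_is_symmetric(self):
        cfg = simulate.SimConfig(n_variants=20_000, seed=24)
        a, b, truth = simulate.simulate_gwas_pair(cfg)
        ld = simulate.BlockLD(truth.block, truth.ld_rho)
        res = pleiofdr.ConjFdrModel(a, b, ld=ld).fit(seed=24)
        t = res.table
        assert (
            t["conjfdr"]
            >= np.maximum(
                t["condfdr_primary_given_secondary"],
                t["condfdr_secondary_given_primary"],
            )
            - 1e-12
        ).all()
        # swapping trait roles leaves conjFDR unchanged; without LD pruning
        # the grids are deterministic, so the symmetry is exact
        res_np = pleiofdr.ConjFdrModel(a, b, ld=None).fit(seed=24)
        res_sw = pleiofdr.ConjFdrModel(b, a, ld=None).fit(seed=24)
        m = res_np.table.merge(res_sw.table, on="variant_id", suffixes=("", "_sw"))
        assert np.allclose(m["conjfdr"], m["conjfdr_sw"], atol=1e-12)

    def test_excluded_regions_are_not_fitted_but_still_scored(self):
        cfg = simulate.SimConfig(n_variants=5000, seed=25)
        a, b, _ = simulate.simulate_gwas_pair(cfg)
        excl = [("1", 1000, 1_000_000)]
        grid = pleiofdr.fit_fdr_grid(a, b, ld=None, excluded_regions=excl, seed=0)
        assert grid.excluded_regions == excl
        # variant inside the excluded region can still be looked up
        val = pleiofdr.condfdr_lookup(grid, 0.01, 0.5)
        assert 0 < val <= 1
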