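import math

import numpy as np
import pytest
from scipy import stats as sps

from pleiomr import motif, simulate
from oracles import brute_force_pwm_hits


class TestPromoterWindow:
    def test_plus_strand_coordinates(self):
        assert motif.promoter_window(10_000, "+") == (8999, 10_299)

    def test_minus_strand_coordinates(self):
        assert motif.promoter_window(10_000, "-") == (9700, 11_000)

    def test_window_length_conserved(self):
        cfg = motif.MotifConfig()
        for tss in (5000, 12_345):
            for strand in "+-":
                s, e = motif.promoter_window(tss, strand, cfg)
                assert e - s == cfg.upstream + cfg.downstream

    def test_clipping_at_contig_start(self):
        s, e = motif.promoter_window(500, "+")
        assert s == 0

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            motif.promoter_window(10_000, "*")


class TestPwm:
    def test_row_sums_enforced(self):
        bad = np.full((5, 4), 0.3)
        with pytest.raises(ValueError):
            motif.Pwm("bad", bad)

    def test_consensus_and_score_range(self, asym_pwm):
        assert asym_pwm.consensus == "ACGTAC"
        assert asym_pwm.min_score < 0 < asym_pwm.max_score

    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0000.1 TEST\n"
            "A [ 10  0  0  5 ]\n"
            "C [  0 10  0  5 ]\n"
            "G [  0  0 10  0 ]\n"
            "T [  0  0  0  0 ]\n"
        )
        pwms = motif.read_jaspar(path)
        assert len(pwms) == 1
        assert pwms[0].length == 4
        assert pwms[0].consensus[:3] == "ACG"


class TestPwmScan:
    def test_consensus_scores_exactly_one(self, asym_pwm):
        hits = motif.pwm_scan(asym_pwm.consensus, asym_pwm, threshold=0.99)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].scaled_score == pytest.approx(1.0, abs=1e-12)

    def test_worst_sequence_scores_exactly_zero(self, asym_pwm):
        worst = "".join(
            "ACGT"[i] for i in asym_pwm.log_odds.argmin(axis=1)
        )
        hits = motif.pwm_scan(worst, asym_pwm, threshold=0.0)
        fwd = [h for h in hits if h.strand == "+" and h.offset == 0]
        assert fwd[0].scaled_score == pytest.approx(0.0, abs=1e-12)

    def test_planted_consensus_found_at_offset(self, asym_pwm):
        rng = np.random.default_rng(5)
        seq = list("T" * 30)
        seq[7: 7 + 6] = asym_pwm.consensus
        seq = "".join(seq)
        hits = motif.pwm_scan(seq, asym_pwm, threshold=0.85)
        assert [(h.offset, h.strand) for h in hits] == [(7, "+")]

    def test_matches_brute_force_oracle(self, asym_pwm):
        rng = np.random.default_rng(9)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            got = [
                (h.offset, h.strand, round(h.scaled_score, 10))
                for h in motif.pwm_scan(seq, asym_pwm, threshold=0.5)
            ]
            ref = [
                (off, strand, round(s, 10))
                for off, strand, s in brute_force_pwm_hits(
                    seq,
                    asym_pwm.log_odds,
                    asym_pwm.min_score,
                    asym_pwm.max_score,
                    0.5,
                )
            ]
            # brute force reports RC offsets at window start; map to match
            L = asym_pwm.length
            ref_mapped = sorted(
                (off, strand, s) if strand == "+" else (off, strand, s)
                for off, strand, s in ref
            )
            assert sorted(got) == ref_mapped

    def test_reverse_complement_invariance(self, asym_pwm):
        rng = np.random.default_rng(11)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            rc = "".join(comp[b] for b in reversed(seq))
            fwd_hits = motif.pwm_scan(seq, asym_pwm, threshold=0.5)
            rc_hits = motif.pwm_scan(rc, asym_pwm, threshold=0.5)
            L = asym_pwm.length
            mapped = sorted(
                (len(seq) - h.offset - L, {"+": "-", "-": "+"}[h.strand], round(h.scaled_score, 9))
                for h in rc_hits
            )
            assert mapped == sorted(
                (h.offset, h.strand, round(h.scaled_score, 9)) for h in fwd_hits
            )

    def test_n_windows_skipped_and_short_sequence_empty(self, asym_pwm):
        assert motif.pwm_scan("ACG", asym_pwm) == []
        hits = motif.pwm_scan("NNNNNNNNNN", asym_pwm, threshold=0.0)
        assert hits == []


class TestVariantMotifBreak:
    def test_consensus_disruption_detected(self, asym_pwm):
        seq = "TTTT" + asym_pwm.consensus + "TTTT"
        pos = 4 + 2  # consensus base G at motif position 2
        worst = "ACGT"[asym_pwm.log_odds[2].argmin()]
        hit = motif.variant_motif_break(seq, pos, "G", worst, asym_pwm)
        assert hit is not None
        assert hit.ref_score == pytest.approx(1.0, abs=1e-12)
        assert hit.delta < 0

    def test_below_threshold_not_retained(self, asym_pwm):
        seq = "TGTGTGTGTGTG"
        hit = motif.variant_motif_break(seq, 5, "G", "A", asym_pwm)
        assert hit is None

    def test_identical_alleles_rejected(self, asym_pwm):
        with pytest.raises(ValueError, match="identical"):
            motif.variant_motif_break("ACGTACGT", 2, "G", "G", asym_pwm)

    def test_indel_skipped(self, asym_pwm):
        assert motif.variant_motif_break("ACGTACGT", 2, "G", "GG", asym_pwm) is None

    def test_allele_swap_negates_delta(self, asym_pwm):
        seq = "TTTT" + asym_pwm.consensus + "TTTT"
        pos = 6
        worst = "ACGT"[asym_pwm.log_odds[2].argmin()]
        fwd = motif.variant_motif_break(seq, pos, "G", worst, asym_pwm)
        alt_seq = seq[:pos] + worst + seq[pos + 1:]
        rev = motif.variant_motif_break(alt_seq, pos, worst, "G", asym_pwm)
        assert fwd is not None and rev is not None
        assert fwd.delta == pytest.approx(-rev.delta)


class TestMotifSetEnrichment:
    def test_exact_hypergeometric_tail(self, asym_pwm):
        # 10 targets all contain the motif, 40 backgrounds contain nothing:
        # p = 1 / C(50, 10)
        worst = "".join("ACGT"[i] for i in asym_pwm.log_odds.argmin(axis=1))
        targets = {f"t{i}": "TT" + asym_pwm.consensus + "TT" for i in range(10)}
        background = {f"b{i}": worst * 3 for i in range(40)}
        p, counts = motif.motif_set_enrichment(targets, background, asym_pwm)
        assert counts["target_with_motif"] == 10
        assert counts["background_with_motif"] == 0
        assert p == pytest.approx(1.0 / math.comb(50, 10), rel=1e-9)

    def test_no_hits_anywhere_gives_p_one(self, asym_pwm):
        worst = "".join("ACGT"[i] for i in asym_pwm.log_odds.argmin(axis=1))
        seqs_a = {f"t{i}": worst * 2 for i in range(5)}
        seqs_b = {f"b{i}": worst * 2 for i in range(5)}
        p, _ = motif.motif_set_enrichment(seqs_a, seqs_b, asym_pwm)
        assert p == pytest.approx(1.0)

    def test_equal_plant_rates_give_uniform_p(self, asym_pwm):
        # calibration by repeated simulation at matched plant rates
        ps = []
        for s in range(200):
            targets, background, _ = simulate.simulate_promoters(
                15, 60, asym_pwm, 0.3, 0.3, seed=s
            )
            p, _ = motif.motif_set_enrichment(targets, background, asym_pwm)
            ps.append(p)
        # hypergeometric p-values are discrete; compare against their own
        # conservative null via a sign check: roughly half should be <= median
        assert sps.kstest(ps, "uniform").statistic < 0.25
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_empty_set_rejected(self, asym_pwm):
        with pytest.raises(ValueError):
            motif.motif_set_enrichment({}, {"b": "ACGT"}, asym_pwm)

    def test_report_filters_by_p(self, asym_pwm):
        targets = {f"t{i}": "TT" + asym_pwm.consensus + "TT" for i in range(10)}
        worst = "".join("ACGT"[i] for i in asym_pwm.log_odds.argmin(axis=1))
        background = {f"b{i}": worst * 3 for i in range(40)}
        table = motif.motif_enrichment_report(targets, background, [asym_pwm])
        assert len(table) == 1 and table["p"].iloc[0] < 0.05
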