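"""Allele-specific binding: assignment rules, binomial test, FDR, ROC."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import chipdesign.asb as asb
from chipdesign.genome import MaternalProbTrack


def exact_pvalue(k, n):
    """Oracle: exhaustive enumeration with exact rational arithmetic."""
    lower = Fraction(sum(comb(n, i) for i in range(0, k + 1)), 2**n)
    upper = Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)
    return float(min(1, 2 * min(lower, upper)))


class TestBinomialPvalue:
    @pytest.mark.parametrize(
        "m,p,expected",
        [(5, 5, 1.0), (9, 1, 22 / 1024), (10, 0, 2 / 1024)],
    )
    def test_known_values(self, m, p, expected):
        assert asb.binomial_pvalue(m, p) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_up_to_coverage_30(self):
        for n in range(1, 31):
            ks = np.arange(n + 1)
            got = asb.binomial_pvalues(ks, np.full(n + 1, n))
            want = np.array([exact_pvalue(int(k), n) for k in ks])
            assert np.max(np.abs(got - want)) < 1e-12

    def test_agrees_with_scipy_binomtest(self):
        from scipy.stats import binomtest

        for m, p in [(7, 3), (12, 20), (0, 8), (15, 15)]:
            assert asb.binomial_pvalue(m, p) == pytest.approx(
                binomtest(m, m + p, 0.5).pvalue, abs=1e-12
            )

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            asb.binomial_pvalue(0, 0)


class TestAssignFragmentAllele:
    def test_pe_summed_mismatches_decide(self):
        call, _ = asb.assign_fragment_allele((500, 1), (500, 2), mode="PE")
        assert call == "maternal"

    def test_pe_tie_discarded(self):
        call, reason = asb.assign_fragment_allele((500, 1), (500, 1), mode="PE")
        assert call == "discard" and reason == "mismatch_tie"

    def test_ambiguous_base_discarded(self):
        call, reason = asb.assign_fragment_allele((500, 0), (500, 1),
                                                  mode="PE", has_n=True)
        assert call == "discard" and reason == "ambiguous_base"

    def test_different_locations_discarded(self):
        call, reason = asb.assign_fragment_allele((500, 0), (730, 0), mode="PE")
        assert call == "discard" and reason == "different_locations"

    def test_single_allele_alignment_wins(self):
        assert asb.assign_fragment_allele((500, 2), None, mode="PE")[0] == "maternal"
        assert asb.assign_fragment_allele(None, (500, 2), mode="PE")[0] == "paternal"

    def test_se_tie_broken_randomly(self):
        rng = np.random.default_rng(0)
        calls = {
            asb.assign_fragment_allele((500, 1), (500, 1), mode="SE", rng=rng)[0]
            for _ in range(50)
        }
        assert calls == {"maternal", "paternal"}


def assigned_df(rows):
    return pd.DataFrame(rows, columns=["fragment_id", "allele", "start", "end"])


class TestCountAlleles:
    def test_min_reads_boundary(self):
        rows = [(f"f{i}", "maternal", 90, 140) for i in range(3)]
        rows.append(("f3", "paternal", 90, 140))
        # coverage 4 < 5: excluded
        assert len(asb.count_alleles(assigned_df(rows), [100])) == 0
        rows.append(("f4", "maternal", 90, 140))
        out = asb.count_alleles(assigned_df(rows), [100])
        assert len(out) == 1
        assert (out.iloc[0]["n_maternal"], out.iloc[0]["n_paternal"]) == (4, 1)

    def test_half_open_interval_excludes_endpoint(self):
        rows = [(f"f{i}", "maternal", 50, 100) for i in range(6)]
        # fragments end exactly at the SNP: not counted
        assert len(asb.count_alleles(assigned_df(rows), [100])) == 0

    def test_pe_fragment_counted_once_via_either_mate(self):
        rows = []
        for i in range(5):
            rows.append((f"f{i}", "maternal", 80, 116))   # mate 1 covers
            rows.append((f"f{i}", "maternal", 300, 336))  # mate 2 does not
        out = asb.count_alleles(assigned_df(rows), [100])
        assert out.iloc[0]["coverage"] == 5

    def test_winning_fraction(self):
        rows = [(f"f{i}", "maternal", 90, 140) for i in range(8)]
        rows += [(f"g{i}", "paternal", 90, 140) for i in range(2)]
        out = asb.count_alleles(assigned_df(rows), [100])
        assert out.iloc[0]["winning_allele"] == "maternal"
        assert out.iloc[0]["winning_fraction"] == pytest.approx(0.8)


class TestFdrCutoff:
    def test_null_data_calls_at_most_target_fraction(self):
        rng = np.random.default_rng(42)
        n = 2000
        cov = np.full(n, 20)
        k = rng.binomial(cov, 0.5)
        counts = asb.counts_from_numbers(np.arange(n) * 100, k, cov - k)
        cutoff = asb.fdr_cutoff(counts, target_fdr=0.1, n_sim=20, seed=1)
        called = (counts["p_value"] <= cutoff).sum()
        # under the null essentially nothing should be callable at FDR 0.1
        assert called / n <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / n)

    def test_strong_signals_yield_positive_cutoff_and_fdr_control(self):
        rng = np.random.default_rng(43)
        n_null, n_sig = 400, 100
        cov = rng.poisson(30, n_null + n_sig).clip(min=5)
        p_true = np.r_[np.full(n_null, 0.5), np.full(n_sig, 0.9)]
        k = rng.binomial(cov, p_true)
        counts = asb.counts_from_numbers(np.arange(n_null + n_sig), k, cov - k)
        cutoff = asb.fdr_cutoff(counts, target_fdr=0.1, n_sim=20, seed=2)
        assert cutoff > 0
        called = counts[counts["p_value"] <= cutoff]
        false = (called["snp_pos"] < n_null).sum()
        assert false / max(len(called), 1) <= 0.15

    def test_target_zero_calls_nothing(self):
        counts = asb.counts_from_numbers([1, 2], [20, 1], [0, 19])
        cutoff = asb.fdr_cutoff(counts, target_fdr=0.0, n_sim=10, seed=3)
        assert cutoff == 0.0
        assert len(asb.call_asb(counts, cutoff)) == 0


class TestCallAsb:
    def test_cutoff_extremes(self):
        counts = asb.counts_from_numbers([10, 20, 30], [8, 5, 1], [2, 5, 9])
        assert len(asb.call_asb(counts, 0.0)) == 0
        assert len(asb.call_asb(counts, 1.0)) == 3

    def test_peak_restriction(self):
        counts = asb.counts_from_numbers([10, 500], [9, 9], [1, 1])
        peaks = pd.DataFrame({"start": [0], "end": [100]})
        called = asb.call_asb(counts, 1.0, peaks=peaks)
        assert list(called["snp_pos"]) == [10]


class TestRocCurve:
    def make(self, k_true=4, low_coverage_true=False):
        # k true loci at prob 0.95-style counts, 6 null loci
        pos = list(range(10))
        n_mat = [19, 18, 19, 17, 10, 11, 9, 10, 11, 10]
        n_pat = [1, 2, 1, 3, 10, 9, 11, 10, 9, 10]
        truth = pd.DataFrame(
            {
                "snp_pos": pos,
                "true_maternal_prob": [0.9] * 4 + [0.5] * 6,
                "is_true_asb": [True] * 4 + [False] * 6,
            }
        )
        counts = asb.counts_from_numbers(pos, n_mat, n_pat)
        if low_coverage_true:
            counts = counts[counts["snp_pos"] != 0].reset_index(drop=True)
        return counts, truth

    def test_perfect_data_reaches_tpr_one(self):
        counts, truth = self.make()
        roc = asb.roc_curve(counts, truth)
        assert roc["tpr"].max() == 1.0
        assert (roc["tpr"].diff().dropna() >= 0).all()

    def test_coverage_excluded_locus_caps_tpr(self):
        counts, truth = self.make(low_coverage_true=True)
        roc = asb.roc_curve(counts, truth)
        assert roc["tpr"].max() == pytest.approx(3 / 4)

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(9)
        n = 40
        cov = rng.poisson(25, n).clip(min=5)
        p_true = np.where(rng.random(n) < 0.3, 0.85, 0.5)
        k = rng.binomial(cov, p_true)
        counts = asb.counts_from_numbers(np.arange(n), k, cov - k)
        truth = pd.DataFrame(
            {
                "snp_pos": np.arange(n),
                "true_maternal_prob": p_true,
                "is_true_asb": p_true > 0.6,
            }
        )
        roc = asb.roc_curve(counts, truth)
        n_pos, n_neg = truth["is_true_asb"].sum(), (~truth["is_true_asb"]).sum()
        for _, row in roc.iterrows():
            called = counts[counts["p_value"] <= row["cutoff"]]
            if row["cutoff"] == 0:
                called = counts.iloc[0:0]
            is_true = truth.set_index("snp_pos")["is_true_asb"]
            tp = called["snp_pos"].map(is_true).sum()
            assert row["tpr"] == pytest.approx(tp / n_pos)
            assert row["fpr"] == pytest.approx((len(called) - tp) / n_neg)

    def test_no_true_loci_raises(self):
        counts = asb.counts_from_numbers([1], [5], [5])
        truth = pd.DataFrame(
            {"snp_pos": [1], "true_maternal_prob": [0.5], "is_true_asb": [False]}
        )
        with pytest.raises(ValueError):
            asb.roc_curve(counts, truth)

    def test_power_increases_with_coverage_and_effect(self):
        """TPR at matched FPR grows with depth and with allelic imbalance."""
        rng = np.random.default_rng(11)

        def auc_for(cov_mean, prob):
            n = 400
            cov = rng.poisson(cov_mean, n).clip(min=5)
            p_true = np.where(np.arange(n) < n // 4, prob, 0.5)
            k = rng.binomial(cov, p_true)
            counts = asb.counts_from_numbers(np.arange(n), k, cov - k)
            truth = pd.DataFrame(
                {"snp_pos": np.arange(n), "true_maternal_prob": p_true,
                 "is_true_asb": p_true > 0.6}
            )
            return asb.roc_auc(asb.roc_curve(counts, truth))

        assert auc_for(40, 0.8) > auc_for(10, 0.8)
        assert auc_for(25, 0.9) > auc_for(25, 0.65)


class TestMakeTruth:
    def test_ratio_rule(self):
        track = MaternalProbTrack(
            components=[(0, 100, 0.61), (200, 300, 0.6), (400, 500, 0.39)]
        )
        truth = asb.make_truth([50, 250, 450, 700], track)
        assert list(truth["is_true_asb"]) == [True, False, True, False]


class TestAsocFilter:
    def test_default_stringent_thresholds(self):
        counts = asb.counts_from_numbers(
            [1, 2, 3], [30, 15, 12], [5, 10, 6]
        )
        out = asb.asoc_filter(counts)
        assert list(out["snp_pos"]) == [1]
        # (15,10): fold 1.5 passes but p ~ 0.42 fails; (12,6): coverage 18 < 20

    def test_zero_count_fold_is_infinite(self):
        counts = asb.counts_from_numbers([1], [25], [0])
        out = asb.asoc_filter(counts)
        assert len(out) == 1


class TestCobinding:
    def qual_counts(self, pos, allele):
        n_mat = 18 if allele == "maternal" else 2
        return asb.counts_from_numbers([pos], [n_mat], [20 - n_mat])

    def test_same_allele_is_ascb(self):
        a = pd.DataFrame({"chrom": "chrS", "summit": [1000], "score": [1.0]})
        b = pd.DataFrame({"chrom": "chrS", "summit": [1100], "score": [1.0]})
        out = asb.classify_cobinding(
            a, b, self.qual_counts(1000, "maternal"),
            self.qual_counts(1100, "maternal"),
        )
        assert len(out) == 1
        assert out.iloc[0]["label"] == "ASCB"
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (900, 1201)

    def test_different_alleles_is_biasb(self):
        a = pd.DataFrame({"chrom": "chrS", "summit": [1000], "score": [1.0]})
        b = pd.DataFrame({"chrom": "chrS", "summit": [1100], "score": [1.0]})
        out = asb.classify_cobinding(
            a, b, self.qual_counts(1000, "maternal"),
            self.qual_counts(1100, "paternal"),
        )
        assert out.iloc[0]["label"] == "BiASB"

    def test_conflicting_alleles_within_tf_excluded(self):
        a = pd.DataFrame({"chrom": "chrS", "summit": [1000], "score": [1.0]})
        b = pd.DataFrame({"chrom": "chrS", "summit": [1100], "score": [1.0]})
        counts_a = asb.counts_from_numbers([950, 1050], [18, 2], [2, 18])
        out = asb.classify_cobinding(
            a, b, counts_a, self.qual_counts(1100, "maternal")
        )
        assert out.iloc[0]["label"] == "excluded"

    def test_distant_summits_no_region(self):
        a = pd.DataFrame({"chrom": "chrS", "summit": [1000], "score": [1.0]})
        b = pd.DataFrame({"chrom": "chrS", "summit": [1200], "score": [1.0]})
        out = asb.classify_cobinding(
            a, b, self.qual_counts(1000, "maternal"),
            self.qual_counts(1200, "maternal"),
        )
        assert len(out) == 0  # distance 200 is not < 200
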