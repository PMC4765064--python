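"""Allele-specific binding (ASB) detection and evaluation.

Reads (SE) or fragments (PE) aligned separately to the maternal and paternal
haplotypes are assigned to the allele with fewer mismatches (PE: summed over
both mates; PE ties discarded, SE ties broken at random).  Reads containing
an ambiguous base N, or hitting the two alleles at different lifted reference
locations, are discarded.  Allelic imbalance at each phased heterozygous SNP
covered by at least five assigned reads is tested with an exact two-sided
binomial test against a null proportion of 0.5, and the p-value cutoff is
calibrated to a target FDR by simulating null counts at the observed
coverages.  ROC evaluation scores calls against the generating truth, where a
SNP is truly allele-specific when its true maternal probability exceeds 0.6
or falls below 0.4 (maternal/paternal ratio above 1.5 or below 2/3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

COUNT_COLUMNS = [
    "snp_pos",
    "n_maternal",
    "n_paternal",
    "coverage",
    "p_value",
    "winning_allele",
    "winning_fraction",
]


def binomial_pvalue(n_maternal: int, n_paternal: int) -> float:
    """Exact two-sided binomial p-value at null proportion 0.5.

    Symmetric form: twice the smaller tail, capped at 1.
    """
    n = n_maternal + n_paternal
    if n < 1:
        raise ValueError("coverage must be >= 1")
    k = n_maternal
    p = 2.0 * min(
        stats.binom.cdf(k, n, 0.5), stats.binom.sf(k - 1, n, 0.5)
    )
    return float(min(1.0, p))


def binomial_pvalues(k, n) -> np.ndarray:
    """Vectorized two-sided binomial p-values at p0 = 0.5."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if (n < 1).any():
        raise ValueError("coverage must be >= 1")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def assign_fragment_allele(mat, pat, mode: str = "PE", rng=None,
                           has_n: bool = False):
    """Assign one read/fragment to an allele from its per-allele alignments.

    ``mat``/``pat`` are None (no alignment on that haplotype) or
    ``(ref_pos, n_mismatch)`` tuples, where ref_pos is the alignment's lifted
    reference coordinate and n_mismatch the (PE: summed) mismatch count.

    Returns ``(call, reason)`` with call in {"maternal", "paternal",
    "discard"}.  Discard reasons: ambiguous base N; alignment to both alleles
    at different reference locations; equal mismatch counts in PE mode (SE
    ties are broken at random).
    """
    if has_n:
        return "discard", "ambiguous_base"
    if mat is None and pat is None:
        return "discard", "unaligned"
    if mat is None:
        return "paternal", "single_allele"
    if pat is None:
        return "maternal", "single_allele"
    if mat[0] != pat[0]:
        return "discard", "different_locations"
    if mat[1] < pat[1]:
        return "maternal", "fewer_mismatches"
    if pat[1] < mat[1]:
        return "paternal", "fewer_mismatches"
    if mode == "PE":
        return "discard", "mismatch_tie"
    if rng is None:
        rng = np.random.default_rng()
    return ("maternal" if rng.random() < 0.5 else "paternal"), "random_tie"


def count_alleles(assigned: pd.DataFrame, snp_positions, min_reads: int = 5) -> pd.DataFrame:
    """Per-SNP maternal/paternal counts of assigned reads covering the SNP.

    ``assigned`` has one row per read interval in reference coordinates with
    columns fragment_id, allele, start, end (a PE fragment contributes a row
    per mate and is counted once per SNP when either mate covers it,
    half-open).  SNPs covered by fewer than ``min_reads`` assigned reads are
    excluded.  Returns the AlleleCount table with exact two-sided binomial
    p-values.
    """
    rows = []
    if len(assigned):
        starts = assigned["start"].to_numpy()
        ends = assigned["end"].to_numpy()
        fids = assigned["fragment_id"].to_numpy()
        alleles = assigned["allele"].to_numpy()
    for pos in sorted(int(p) for p in snp_positions):
        if len(assigned) == 0:
            continue
        mask = (starts <= pos) & (pos < ends)
        if not mask.any():
            continue
        sub_f = fids[mask]
        sub_a = alleles[mask]
        _, first_idx = np.unique(sub_f, return_index=True)
        a = sub_a[first_idx]
        n_mat = int(np.count_nonzero(a == "maternal"))
        n_pat = int(np.count_nonzero(a == "paternal"))
        cov = n_mat + n_pat
        if cov < min_reads:
            continue
        p = binomial_pvalue(n_mat, n_pat)
        win = "maternal" if n_mat >= n_pat else "paternal"
        rows.append((pos, n_mat, n_pat, cov, p, win, max(n_mat, n_pat) / cov))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def counts_from_numbers(snp_pos, n_maternal, n_paternal) -> pd.DataFrame:
    """Build an AlleleCount table directly from count vectors."""
    n_maternal = np.asarray(n_maternal, dtype=np.int64)
    n_paternal = np.asarray(n_paternal, dtype=np.int64)
    cov = n_maternal + n_paternal
    p = binomial_pvalues(n_maternal, cov)
    win = np.where(n_maternal >= n_paternal, "maternal", "paternal")
    return pd.DataFrame(
        {
            "snp_pos": np.asarray(snp_pos, dtype=np.int64),
            "n_maternal": n_maternal,
            "n_paternal": n_paternal,
            "coverage": cov,
            "p_value": p,
            "winning_allele": win,
            "winning_fraction": np.maximum(n_maternal, n_paternal) / cov,
        }
    )


def fdr_cutoff(counts: pd.DataFrame, target_fdr: float = 0.1,
               n_sim: int = 20, seed: int = 0) -> float:
    """Simulation-calibrated p-value cutoff for a target FDR.

    For each simulation round, null counts Binomial(coverage, 0.5) are drawn
    at every tested SNP and their p-values computed; the estimated FDR at
    cutoff c is (mean null count of p <= c) / (observed count of p <= c),
    with a +1 added to the pooled null count so that a finite simulation
    never certifies an exactly zero FDR.  Returns the largest observed
    p-value with estimated FDR <= target (0.0 when none qualifies, i.e. no
    calls).
    """
    if len(counts) == 0:
        raise ValueError("empty counts table")
    rng = np.random.default_rng(seed)
    obs = np.sort(counts["p_value"].to_numpy())
    cov = counts["coverage"].to_numpy()
    null_p = []
    for _ in range(n_sim):
        k = rng.binomial(cov, 0.5)
        null_p.append(binomial_pvalues(k, cov))
    null_p = np.sort(np.concatenate(null_p))
    candidates = np.unique(obs)
    best = 0.0
    for c in candidates:
        n_obs = int(np.searchsorted(obs, c, side="right"))
        mean_null = (np.searchsorted(null_p, c, side="right") + 1) / n_sim
        if n_obs > 0 and mean_null / n_obs <= target_fdr:
            best = max(best, float(c))
    return best


def call_asb(counts: pd.DataFrame, cutoff: float, peaks=None) -> pd.DataFrame:
    """SNPs with p <= cutoff, optionally restricted to peak intervals.

    ``peaks`` is a DataFrame with start/end columns (reference coordinates,
    half-open).
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    called = counts[counts["p_value"] <= cutoff]
    if cutoff == 0:
        called = counts.iloc[0:0]
    if peaks is not None and len(called):
        starts = peaks["start"].to_numpy()
        ends = peaks["end"].to_numpy()
        inside = [
            bool(np.any((starts <= p) & (p < ends)))
            for p in called["snp_pos"].to_numpy()
        ]
        called = called[np.asarray(inside, dtype=bool)]
    return called.reset_index(drop=True)


def make_truth(snp_positions, track) -> pd.DataFrame:
    """AsbTruth table from SNP positions and the maternal-probability track.

    A SNP is truly allele-specific when the generating maternal probability
    implies a maternal/paternal ratio above 1.5 or below 2/3, i.e. the true
    maternal probability is > 0.6 or < 0.4.
    """
    rows = []
    for pos in sorted(int(p) for p in snp_positions):
        p = track.prob_at(pos)
        rows.append((pos, p, p > 0.6 or p < 0.4))
    return pd.DataFrame(
        rows, columns=["snp_pos", "true_maternal_prob", "is_true_asb"]
    )


def roc_curve(counts: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """(FPR, TPR) over p-value cutoffs swept from 0 to 1.

    The TPR denominator is every truly allele-specific SNP in the truth table
    including those excluded for low coverage, so the maximum TPR stays below
    1 whenever a true locus was untestable; the FPR denominator is every
    truth-negative SNP.
    """
    truth = truth.set_index("snp_pos")
    n_pos = int(truth["is_true_asb"].sum())
    n_neg = int((~truth["is_true_asb"]).sum())
    if n_pos == 0:
        raise ValueError("no true ASB loci in truth; TPR undefined")
    tested = counts.copy()
    tested["is_true"] = (
        tested["snp_pos"].map(truth["is_true_asb"]).astype(bool)
    )
    order = np.argsort(tested["p_value"].to_numpy())
    p_sorted = tested["p_value"].to_numpy()[order]
    is_true_sorted = tested["is_true"].to_numpy()[order]
    cutoffs = np.concatenate([[0.0], np.unique(p_sorted), [1.0]])
    rows = []
    for c in cutoffs:
        n_called = int(np.searchsorted(p_sorted, c, side="right")) if c > 0 else 0
        tp = int(is_true_sorted[:n_called].sum())
        fp = n_called - tp
        rows.append((c, fp / n_neg if n_neg else np.nan, tp / n_pos))
    return pd.DataFrame(rows, columns=["cutoff", "fpr", "tpr"])


def roc_auc(roc: pd.DataFrame) -> float:
    """Area under the ROC curve, extended horizontally to FPR = 1."""
    fpr = roc["fpr"].to_numpy()
    tpr = roc["tpr"].to_numpy()
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    if fpr[0] > 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    if fpr[-1] < 1:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [tpr[-1]]])
    return float(np.trapezoid(tpr, fpr))


def asoc_filter(counts: pd.DataFrame, min_reads: int = 20,
                max_p: float = 0.01, min_fold: float = 1.5) -> pd.DataFrame:
    """Stringent allele-specific locus filter (open-chromatin style).

    Keeps SNPs with coverage >= min_reads, p <= max_p and allele fold-change
    >= min_fold (fold = larger count / smaller count; a zero smaller count
    gives +inf, so the p-value filter governs).
    """
    if len(counts) == 0:
        return counts
    n_mat = counts["n_maternal"].to_numpy(dtype=float)
    n_pat = counts["n_paternal"].to_numpy(dtype=float)
    lo = np.minimum(n_mat, n_pat)
    hi = np.maximum(n_mat, n_pat)
    with np.errstate(divide="ignore"):
        fold = np.where(lo > 0, hi / np.maximum(lo, 1e-300), np.inf)
    keep = (
        (counts["coverage"].to_numpy() >= min_reads)
        & (counts["p_value"].to_numpy() <= max_p)
        & (fold >= min_fold)
    )
    return counts[keep].reset_index(drop=True)


def classify_cobinding(peaks_a, peaks_b, counts_a: pd.DataFrame,
                       counts_b: pd.DataFrame, summit_dist: int = 200,
                       halfwin: int = 100, min_reads: int = 20,
                       max_p: float = 0.1, min_win_frac: float = 0.7) -> pd.DataFrame:
    """Label co-binding regions of two TFs as ASCB / BiASB / excluded.

    Co-binding events are peak pairs with summit-to-summit distance strictly
    below ``summit_dist``; each event spans the union of the +/- ``halfwin``
    windows around the two summits, and overlapping events merge into one
    region.  Within a region, qualifying SNPs per TF have coverage >=
    min_reads, p <= max_p and winning fraction >= min_win_frac.  A region is
    ASCB when both TFs favor the same allele, BiASB when they favor different
    alleles, excluded when one TF favors different alleles at different SNPs,
    and untyped ("none") when either TF lacks a qualifying SNP.
    """
    from .peaks import as_peak_list
    from .genome import merge_intervals

    a = as_peak_list(peaks_a)
    b = as_peak_list(peaks_b)
    events = []
    for i in range(len(a)):
        sa = int(a["summit"].iat[i])
        same = b[b["chrom"] == a["chrom"].iat[i]]
        for sb in same["summit"].to_numpy():
            if abs(int(sb) - sa) < summit_dist:
                lo = min(sa, int(sb)) - halfwin
                hi = max(sa, int(sb)) + halfwin + 1  # closed window, half-open iv
                events.append((lo, hi))
    regions = merge_intervals(events)

    def qualifying(counts):
        if len(counts) == 0:
            return counts
        return counts[
            (counts["coverage"] >= min_reads)
            & (counts["p_value"] <= max_p)
            & (counts["winning_fraction"] >= min_win_frac)
        ]

    qa, qb = qualifying(counts_a), qualifying(counts_b)
    rows = []
    for lo, hi in regions:
        def alleles(q):
            if len(q) == 0:
                return set()
            in_region = q[(q["snp_pos"] >= lo) & (q["snp_pos"] < hi)]
            return set(in_region["winning_allele"])

        alle_a, alle_b = alleles(qa), alleles(qb)
        if len(alle_a) > 1 or len(alle_b) > 1:
            label = "excluded"
        elif alle_a and alle_b:
            label = "ASCB" if alle_a == alle_b else "BiASB"
        else:
            label = "none"
        rows.append((lo, hi, label))
    return pd.DataFrame(rows, columns=["start", "end", "label"])
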