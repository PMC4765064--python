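"""Peak-level evaluation: reproducibility and peak-set difference analysis.

Peak lists are DataFrames with columns ``chrom, summit, score`` ordered by
rank (row 0 = rank 1, consistent with non-increasing score).  Metrics:

* minimax summit distance L_M(j): for the rank-j peak of each replicate, the
  distance to the nearest summit among the top floor(1.5*M) peaks of every
  other replicate, maximized over ordered replicate pairs;
* reproducibility R_M: the fraction of ranks with L_M(j) <= T (default 200);
* rank-change decomposition of the differences between two ranked lists
  (unchanged / moderate / large rank change / design-specific);
* summit-coverage comparison of isolated peaks between two designs;
* motif resolution (summit-to-nearest-motif distance) and motif occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "summit", "score"]


@dataclass(frozen=True)
class RankChangeTable:
    """Counts of rank-change categories for the top M peaks of one list."""

    unchanged: int
    moderate: int
    large: int
    specific: int

    @property
    def total(self) -> int:
        return self.unchanged + self.moderate + self.large + self.specific


def as_peak_list(peaks) -> pd.DataFrame:
    """Normalize input to a ranked peak DataFrame."""
    if isinstance(peaks, pd.DataFrame):
        df = peaks.reset_index(drop=True)
        missing = set(PEAK_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"peak list missing columns {sorted(missing)}")
        return df
    # iterable of summits (single chromosome, scores by rank)
    summits = list(peaks)
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "summit": summits,
            "score": np.arange(len(summits), 0, -1, dtype=float),
        }
    )


def _per_chrom_sorted(df: pd.DataFrame):
    """chrom -> sorted summit array, for nearest-summit queries."""
    return {
        chrom: np.sort(sub["summit"].to_numpy())
        for chrom, sub in df.groupby("chrom")
    }


def _nearest_distance(chrom: str, summit: int, index) -> float:
    arr = index.get(chrom)
    if arr is None or len(arr) == 0:
        return math.inf
    i = int(np.searchsorted(arr, summit))
    best = math.inf
    if i < len(arr):
        best = min(best, abs(int(arr[i]) - summit))
    if i > 0:
        best = min(best, abs(int(arr[i - 1]) - summit))
    return float(best)


def minimax_summit_distance(peak_lists, M: int, search_factor: float = 1.5):
    """L_M(j) for j = 1..M across >= 2 ranked peak lists.

    L_M(j) = max over ordered pairs (i, k), i != k, of the distance from
    replicate i's rank-j summit to the nearest summit among the top
    floor(search_factor * M) peaks of replicate k.  Cross-chromosome
    distances are +inf.
    """
    lists = [as_peak_list(p) for p in peak_lists]
    if len(lists) < 2:
        raise ValueError("need at least two peak lists")
    search_n = int(math.floor(search_factor * M))
    for idx, df in enumerate(lists):
        if len(df) < search_n:
            raise ValueError(
                f"peak list {idx} has {len(df)} peaks, needs >= {search_n}"
            )
    indexes = [_per_chrom_sorted(df.head(search_n)) for df in lists]
    L = np.zeros(M)
    for j in range(M):
        worst = 0.0
        for i, df_i in enumerate(lists):
            chrom = df_i["chrom"].iat[j]
            summit = int(df_i["summit"].iat[j])
            for k in range(len(lists)):
                if k == i:
                    continue
                d = _nearest_distance(chrom, summit, indexes[k])
                worst = max(worst, d)
        L[j] = worst
    return L


def reproducibility(L_values, T: float = 200) -> float:
    """R_M: fraction of ranks whose minimax summit distance is <= T."""
    L = np.asarray(L_values, dtype=float)
    if len(L) == 0:
        raise ValueError("empty L_M values")
    return float(np.mean(L <= T))


def match_peaks(list_a, list_b, max_dist: int = 200):
    """Greedy one-to-one matching of A's peaks to B's, in A's rank order.

    Each A peak matches the nearest still-unmatched B summit on the same
    chromosome at distance strictly below ``max_dist``.  Returns an int array
    of B row indices per A row (-1 = unmatched).
    """
    a = as_peak_list(list_a)
    b = as_peak_list(list_b)
    matched = np.full(len(a), -1, dtype=np.int64)
    taken = np.zeros(len(b), dtype=bool)
    b_chrom = b["chrom"].to_numpy()
    b_summit = b["summit"].to_numpy()
    for i in range(len(a)):
        chrom = a["chrom"].iat[i]
        summit = int(a["summit"].iat[i])
        mask = (b_chrom == chrom) & ~taken
        if not mask.any():
            continue
        cand = np.flatnonzero(mask)
        d = np.abs(b_summit[cand] - summit)
        best = int(cand[np.argmin(d)])
        if abs(int(b_summit[best]) - summit) < max_dist:
            matched[i] = best
            taken[best] = True
    return matched


def rank_change_table(list_a, list_b, M: int, moderate_factor: float = 1.2,
                      relaxed_size=None, max_dist: int = 200) -> RankChangeTable:
    """Classify A's top M peaks by the rank of their matched B peak.

    Matched B rank <= M: unchanged; <= floor(moderate_factor*M): moderate;
    <= relaxed_size (default |B|): large; beyond that or unmatched: specific.
    """
    a = as_peak_list(list_a)
    b = as_peak_list(list_b)
    if M > len(a):
        raise ValueError(f"M={M} exceeds list size {len(a)}")
    if relaxed_size is None:
        relaxed_size = len(b)
    moderate_bound = int(math.floor(moderate_factor * M))
    matched = match_peaks(a.head(M), b, max_dist=max_dist)
    unchanged = moderate = large = specific = 0
    for bi in matched:
        if bi < 0:
            specific += 1
            continue
        b_rank = int(bi) + 1
        if b_rank <= M:
            unchanged += 1
        elif b_rank <= moderate_bound:
            moderate += 1
        elif b_rank <= relaxed_size:
            large += 1
        else:
            specific += 1
    return RankChangeTable(unchanged, moderate, large, specific)


def _window_read_count(reads: pd.DataFrame, chrom, lo: int, hi: int) -> int:
    """Reads overlapping the closed window [lo, hi] (reads half-open)."""
    sub = reads[reads["chrom"] == chrom] if "chrom" in reads.columns else reads
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    return int(np.count_nonzero((s <= hi) & (e > lo)))


def _coverage_fold(c1: int, c2: int) -> float:
    """Fold-change between two window counts.

    Plain ratio of the larger to the smaller count; a zero denominator is
    stabilized with a +1 pseudocount on both counts (so 0 vs 0 gives 1).
    """
    hi, lo = max(c1, c2), min(c1, c2)
    if lo == 0:
        return (hi + 1) / (lo + 1)
    return hi / lo


def summit_coverage_compare(peaks_a, peaks_b, reads_a: pd.DataFrame,
                            reads_b: pd.DataFrame, window: int = 100,
                            isolation: int = 500, fold: float = 1.5) -> pd.DataFrame:
    """Compare read coverage around A's summits between two designs.

    A peak is excluded when any summit of the other list lies within the
    closed +/- ``isolation`` window around its summit.  For the remaining
    peaks the coverage is the number of reads overlapping the closed
    +/- ``window`` interval in each design; the peak is flagged changed when
    the fold-change is at least ``fold``.
    """
    a = as_peak_list(peaks_a)
    b = as_peak_list(peaks_b)
    b_index = _per_chrom_sorted(b)
    rows = []
    for i in range(len(a)):
        chrom = a["chrom"].iat[i]
        summit = int(a["summit"].iat[i])
        excluded = _nearest_distance(chrom, summit, b_index) <= isolation
        if excluded:
            rows.append((chrom, summit, np.nan, np.nan, True, np.nan, False))
            continue
        ca = _window_read_count(reads_a, chrom, summit - window, summit + window)
        cb = _window_read_count(reads_b, chrom, summit - window, summit + window)
        f = _coverage_fold(ca, cb)
        rows.append((chrom, summit, ca, cb, False, f, f >= fold))
    return pd.DataFrame(
        rows,
        columns=["chrom", "summit", "cov_a", "cov_b", "excluded", "fold",
                 "changed"],
    )


def motif_resolution(peaks: pd.DataFrame, motif_positions,
                     top_fracs=(0.3, 0.5, 0.7)) -> pd.DataFrame:
    """Summit-to-nearest-motif distances and motif occurrence per top group.

    ``peaks`` needs columns chrom, summit, score and (for occurrence) start,
    end; ``motif_positions`` is a DataFrame with chrom, pos or an iterable of
    positions.  For each fraction f the top ceil(f*n) peaks contribute; the
    median nearest-motif distance is over peaks on chromosomes that carry a
    motif (others count as no-motif for occurrence and are excluded from the
    distance quantile).
    """
    pk = peaks.reset_index(drop=True)
    if isinstance(motif_positions, pd.DataFrame):
        motifs = motif_positions
    else:
        motifs = pd.DataFrame(
            {"chrom": "chrS", "pos": list(motif_positions)}
        )
    index = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in motifs.groupby("chrom")
    }
    dist = np.array(
        [
            _nearest_distance(pk["chrom"].iat[i], int(pk["summit"].iat[i]), index)
            for i in range(len(pk))
        ]
    )
    has_intervals = {"start", "end"}.issubset(pk.columns)
    rows = []
    for f in top_fracs:
        n_top = max(1, math.ceil(f * len(pk)))
        d = dist[:n_top]
        finite = d[np.isfinite(d)]
        median = float(np.median(finite)) if len(finite) else math.inf
        if has_intervals:
            occ = 0
            for i in range(n_top):
                arr = index.get(pk["chrom"].iat[i])
                if arr is None:
                    continue
                s, e = int(pk["start"].iat[i]), int(pk["end"].iat[i])
                j = int(np.searchsorted(arr, s))
                if j < len(arr) and arr[j] < e:
                    occ += 1
            occurrence = occ / n_top
        else:
            occurrence = float(np.mean(np.isfinite(d[:n_top]) & (d[:n_top] == 0)))
        rows.append((f, n_top, median, occurrence))
    return pd.DataFrame(
        rows, columns=["top_frac", "n_peaks", "median_distance", "occurrence"]
    )
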