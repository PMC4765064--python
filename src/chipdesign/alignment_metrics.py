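"""Alignment-level evaluation metrics.

Covers alignment rate, truth-based accuracy (an extended aligned read is
correct when it covers the fragment's true reference midpoint), relaxed
gold-set false-positive rates on alignment-set differences, multi-coverage
(bases covered by at least five fragments), and repeat-class coverage with
the 30% overlap inclusion rule.

Extended fragments are plain DataFrames with columns
``read_id, start, end, source`` (source: "PE-joined" or "SE-extended").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import RepeatAnnotation

FRAGMENT_COLUMNS = ["read_id", "start", "end", "source"]


def join_pe(aligned_pairs) -> pd.DataFrame:
    """Outer-span fragments from aligned mate pairs.

    ``aligned_pairs`` is an iterable of (AlignedRead, AlignedRead).
    """
    rows = [
        (m1.read_id, min(m1.start, m2.start), max(m1.end, m2.end), "PE-joined")
        for m1, m2 in aligned_pairs
    ]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def extend_se(aligned_reads, fragment_length: int, genome_length: int) -> pd.DataFrame:
    """Extend SE alignments to the average fragment length (3' direction)."""
    rows = []
    for a in aligned_reads:
        if a.strand == "+":
            s, e = a.start, min(genome_length, a.start + fragment_length)
        else:
            s, e = max(0, a.end - fragment_length), a.end
        rows.append((a.read_id, s, e, "SE-extended"))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def alignment_rate(aligned: int, total: int) -> float:
    """Fraction of reads (or pairs) aligned."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= aligned <= total:
        raise ValueError("need 0 <= aligned <= total")
    return aligned / total


def accuracy_vs_truth(fragments: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of extended fragments covering their true reference midpoint.

    Containment is half-open: a fragment [start, end) is correct when
    start <= ref_mid < end.  Every fragment read_id must be present in truth.
    """
    if len(fragments) == 0:
        raise ValueError("no fragments to score")
    mids = truth.set_index("fragment_id")["ref_mid"]
    unknown = set(fragments["read_id"]) - set(mids.index)
    if unknown:
        raise KeyError(f"read ids missing from truth: {sorted(unknown)[:5]}")
    m = fragments["read_id"].map(mids).to_numpy()
    ok = (fragments["start"].to_numpy() <= m) & (m < fragments["end"].to_numpy())
    return float(ok.mean())


def relaxed_fp_rate(set_a, set_b, relaxed_mappable):
    """False-positive rates on the set differences of two alignment sets.

    Reads absent from the relaxed (gold) mappable set are deemed unmappable;
    among reads aligned by A but not B, fp_A is the unmappable fraction
    (symmetrically for B).  An empty set difference yields NaN.
    """
    set_a, set_b = set(set_a), set(set_b)
    relaxed_mappable = set(relaxed_mappable)

    def rate(diff):
        if not diff:
            return float("nan")
        fp = len(diff - relaxed_mappable)
        return fp / len(diff)

    return rate(set_a - set_b), rate(set_b - set_a)


def multi_coverage(fragments: pd.DataFrame, genome_length: int,
                   min_depth: int = 5) -> int:
    """Number of bases covered by at least ``min_depth`` fragments."""
    if len(fragments) == 0:
        return 0
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    starts = np.clip(fragments["start"].to_numpy(dtype=np.int64), 0, genome_length)
    ends = np.clip(fragments["end"].to_numpy(dtype=np.int64), 0, genome_length)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    depth = np.cumsum(diff[:-1])
    return int(np.count_nonzero(depth >= min_depth))


def _overlap_with_merged(start: int, end: int, merged) -> int:
    """Total overlap of [start, end) with sorted merged intervals."""
    total = 0
    for s, e in merged:
        if s >= end:
            break
        if e > start:
            total += min(end, e) - max(start, s)
    return total


def repeat_coverage(fragments: pd.DataFrame, repeats: RepeatAnnotation,
                    min_overlap_frac: float = 0.30) -> dict:
    """Normalized per-class repeat coverage.

    For each repeat class: the sum of the full fragment lengths over
    fragments whose overlap with that class's elements is at least
    ``min_overlap_frac`` of the fragment length, divided by the class's total
    element length.
    """
    out = {}
    for cls in repeats.classes():
        total_len = repeats.total_length(cls)
        if total_len == 0:
            raise ValueError(f"repeat class {cls!r} has zero total length")
        merged = repeats.merged(cls)
        acc = 0
        for start, end in zip(
            fragments["start"].to_numpy(), fragments["end"].to_numpy()
        ):
            frag_len = end - start
            ov = _overlap_with_merged(int(start), int(end), merged)
            if ov >= min_overlap_frac * frag_len:
                acc += frag_len
        out[cls] = acc / total_len
    return out
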