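"""Brute-force k-mismatch aligner for small synthetic genomes.

Finds every ungapped alignment of a read with at most ``max_mismatch``
mismatches on either strand, reports the best (minimum-mismatch) stratum and
a uniqueness flag, and pairs mates under a proper forward/reverse orientation
with an insert-size constraint (default 100-700 bp).  Candidate positions are
enumerated by a pigeonhole exact-seed scan (split the read into k+1 chunks;
any alignment with <= k mismatches matches one chunk exactly), then verified
by vectorized Hamming counting, so results are identical to a full
position-by-position scan.

An ambiguous base N in a read matches nothing and always counts as a
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import revcomp


@dataclass(frozen=True)
class AlignedRead:
    """One ungapped alignment record (0-based, half-open)."""

    read_id: str
    target: str
    start: int
    end: int
    strand: str
    n_mismatch: int
    unique: bool
    mate_index: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty alignment interval")


def quality_trim(seq: str, qual: np.ndarray, threshold: int):
    """BWA-style 3' quality trimming (running-sum rule).

    Trims the suffix maximizing sum(threshold - Q) over the trimmed tail; the
    read is kept intact when no suffix has positive score.
    """
    best_score, best_len = 0, len(seq)
    score = 0
    for i in range(len(seq) - 1, -1, -1):
        score += threshold - int(qual[i])
        if score > best_score:
            best_score, best_len = score, i
    best_len = max(best_len, 1)  # never trim to nothing
    return seq[:best_len], qual[:best_len]


class ToyAligner:
    """Reusable aligner against one target sequence."""

    def __init__(self, target_seq: str, target_name: str = "reference",
                 max_mismatch: int = 2):
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.target_name = target_name
        self.max_mismatch = max_mismatch
        self._tgt_bytes = target_seq.encode()
        self._tgt_arr = np.frombuffer(self._tgt_bytes, dtype=np.uint8)
        self.n = len(target_seq)

    # -- candidate generation -------------------------------------------------

    def _chunk_candidates(self, pattern: bytes):
        """Pigeonhole candidate start positions for <=max_mismatch hits."""
        L = len(pattern)
        k = self.max_mismatch
        bounds = [round(i * L / (k + 1)) for i in range(k + 2)]
        cand = set()
        for ci in range(k + 1):
            s, e = bounds[ci], bounds[ci + 1]
            chunk = pattern[s:e]
            if not chunk or b"N" in chunk:
                continue
            pos = self._tgt_bytes.find(chunk)
            while pos != -1:
                start = pos - s
                if 0 <= start <= self.n - L:
                    cand.add(start)
                pos = self._tgt_bytes.find(chunk, pos + 1)
        return cand

    def _hits_one_strand(self, pattern: str):
        """All (start, n_mismatch) with n_mismatch <= max_mismatch."""
        pat = pattern.encode()
        L = len(pat)
        if L > self.n:
            return []
        pat_arr = np.frombuffer(pat, dtype=np.uint8)
        hits = []
        for start in self._chunk_candidates(pat):
            mm = int(
                np.count_nonzero(self._tgt_arr[start : start + L] != pat_arr)
            )
            if mm <= self.max_mismatch:
                hits.append((start, mm))
        return hits

    def all_hits(self, read_seq: str):
        """Every alignment (start, end, strand, n_mismatch) on both strands."""
        L = len(read_seq)
        out = [
            (s, s + L, "+", mm) for s, mm in self._hits_one_strand(read_seq)
        ]
        out += [
            (s, s + L, "-", mm)
            for s, mm in self._hits_one_strand(revcomp(read_seq))
        ]
        return out

    # -- single-end -----------------------------------------------------------

    def align_se(self, read_seq: str, read_id: str = "read", qual=None,
                 quality_trim_threshold=None, mate_index: int = 0):
        """Best-stratum alignments of one read; unique iff exactly one hit."""
        if quality_trim_threshold is not None:
            if qual is None:
                raise ValueError("quality trimming requires qualities")
            read_seq, qual = quality_trim(
                read_seq, np.asarray(qual), quality_trim_threshold
            )
        hits = self.all_hits(read_seq)
        if not hits:
            return []
        best = min(mm for *_, mm in hits)
        best_hits = [h for h in hits if h[3] == best]
        unique = len(best_hits) == 1
        return [
            AlignedRead(read_id, self.target_name, s, e, st, mm, unique,
                        mate_index)
            for s, e, st, mm in best_hits
        ]

    # -- paired-end -----------------------------------------------------------

    def align_pe(self, mate1_seq: str, mate2_seq: str, read_id: str = "read",
                 insert_min: int = 100, insert_max: int = 700,
                 keep_one_end_unique=None, report: str = "unique", rng=None):
        """Align a pair under the insert constraint.

        Valid pairings have the mates on opposite strands in forward/reverse
        orientation with outer span (insert) in [insert_min, insert_max]; the
        best stratum minimizes the summed mismatches, and the pairing is
        unique iff that stratum holds exactly one pairing.

        ``keep_one_end_unique``: None places no per-end requirement (pure
        unique-pairing reporting); True keeps pairs with at least one
        uniquely-mapping end (UR mode); False requires both ends unique (Uni
        mode).  ``report='random_best'`` returns one best pairing chosen at
        random instead of requiring uniqueness (multi-read keeping).

        Returns (AlignedRead mate1, AlignedRead mate2) or None if unmapped.
        """
        hits1 = self.all_hits(mate1_seq)
        hits2 = self.all_hits(mate2_seq)
        if not hits1 or not hits2:
            return None
        pairings = []
        for s1, e1, st1, mm1 in hits1:
            for s2, e2, st2, mm2 in hits2:
                if st1 == st2:
                    continue
                fwd_s = s1 if st1 == "+" else s2
                rev_s = s2 if st1 == "+" else s1
                rev_e = e2 if st1 == "+" else e1
                if rev_s < fwd_s:
                    continue  # forward mate must be upstream
                insert = rev_e - fwd_s
                if not insert_min <= insert <= insert_max:
                    continue
                pairings.append(((s1, e1, st1, mm1), (s2, e2, st2, mm2)))
        if not pairings:
            return None
        best_mm = min(h1[3] + h2[3] for h1, h2 in pairings)
        best = [p for p in pairings if p[0][3] + p[1][3] == best_mm]
        unique = len(best) == 1
        if report == "random_best":
            if rng is None:
                rng = np.random.default_rng()
            h1, h2 = best[int(rng.integers(len(best)))]
        elif report == "unique":
            if not unique:
                return None
            h1, h2 = best[0]
        else:
            raise ValueError(f"unknown report mode {report!r}")
        if keep_one_end_unique is not None:
            u1 = self._se_unique(hits1)
            u2 = self._se_unique(hits2)
            if keep_one_end_unique:
                if not (u1 or u2):  # UR: one unique end rescues the pair
                    return None
            elif not (u1 and u2):  # Uni: both ends must be unique
                return None
        return (
            AlignedRead(read_id, self.target_name, h1[0], h1[1], h1[2], h1[3],
                        unique, 1),
            AlignedRead(read_id, self.target_name, h2[0], h2[1], h2[2], h2[3],
                        unique, 2),
        )

    @staticmethod
    def _se_unique(hits) -> bool:
        best = min(mm for *_, mm in hits)
        return sum(1 for *_, mm in hits if mm == best) == 1


def align_se(read_seq: str, genome_seq: str, max_mismatch: int = 2,
             read_id: str = "read", qual=None, quality_trim_threshold=None):
    """Functional wrapper: best-stratum SE alignments against a sequence."""
    return ToyAligner(genome_seq, max_mismatch=max_mismatch).align_se(
        read_seq, read_id=read_id, qual=qual,
        quality_trim_threshold=quality_trim_threshold,
    )


def align_pe(mate1_seq: str, mate2_seq: str, genome_seq: str,
             max_mismatch: int = 2, insert_min: int = 100,
             insert_max: int = 700, keep_one_end_unique=None,
             read_id: str = "read", report: str = "unique", rng=None):
    """Functional wrapper: paired alignment against a sequence."""
    return ToyAligner(genome_seq, max_mismatch=max_mismatch).align_pe(
        mate1_seq, mate2_seq, read_id=read_id, insert_min=insert_min,
        insert_max=insert_max, keep_one_end_unique=keep_one_end_unique,
        report=report, rng=rng,
    )
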