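"""In-silico transformation of paired-end data into other sequencing designs.

From one full PE dataset these operations derive: SE data (one random mate
per pair), shorter-read designs (5' trimming to 75/50/36 bp), and half-depth
PE data ("PEhalf", half the pairs sampled without replacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ReadPair


@dataclass(frozen=True)
class SingleRead:
    read_id: str
    seq: str
    qual: str
    mate_index: int = 0  # 1 or 2 when derived from a pair, else 0

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence/quality length mismatch")


def pe_to_se(pairs, seed: int = 0):
    """Sample one end from each pair uniformly; returns SingleRead list."""
    rng = np.random.default_rng(seed)
    out = []
    for pair in pairs:
        if rng.random() < 0.5:
            out.append(SingleRead(pair.fragment_id, pair.mate1_seq, pair.mate1_qual, 1))
        else:
            out.append(SingleRead(pair.fragment_id, pair.mate2_seq, pair.mate2_qual, 2))
    return out


def trim_reads(reads, target_length: int):
    """Trim single-end reads to their first ``target_length`` bases.

    The 5' end is kept and the (low-quality) 3' end dropped; IDs and order
    are preserved.  A read shorter than the target is an error.
    """
    out = []
    for r in reads:
        if len(r.seq) < target_length:
            raise ValueError(
                f"read {r.read_id} length {len(r.seq)} < target {target_length}"
            )
        out.append(
            SingleRead(
                r.read_id,
                r.seq[:target_length],
                r.qual[:target_length],
                r.mate_index,
            )
        )
    return out


def trim_pairs(pairs, target_length: int):
    """Trim both mates of each pair to ``target_length`` (5' end kept)."""
    out = []
    for p in pairs:
        if len(p.mate1_seq) < target_length or len(p.mate2_seq) < target_length:
            raise ValueError(
                f"pair {p.fragment_id} shorter than target {target_length}"
            )
        out.append(
            ReadPair(
                p.fragment_id,
                p.mate1_seq[:target_length],
                p.mate1_qual[:target_length],
                p.mate2_seq[:target_length],
                p.mate2_qual[:target_length],
            )
        )
    return out


def subsample_half(pairs, seed: int = 0):
    """Keep exactly floor(n/2) pairs, uniformly without replacement.

    Both mates of a retained pair stay together; input order is preserved.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    keep = np.sort(rng.choice(n, size=n // 2, replace=False))
    return [pairs[i] for i in keep]
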