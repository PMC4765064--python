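"""Allele-aware paired-end ChIP-seq read simulator.

Fragments are simulated from a diploid genome in seven steps: (1) fragment
length from a shifted beta distribution round(100 + 600*Beta(2,5)); (2)
fragment midpoint on the reference from a read-density profile; (3) allele
(maternal/paternal) from the local true maternal probability; (4) liftover of
the midpoint to the assigned haplotype, perturbing iteratively when the
position is not mappable; (5) extraction of the two end reads from the
haplotype sequence; (6) per-base Phred qualities from a quality model; (7)
sequencing errors inserted at the Phred-implied rate.

Each simulated fragment carries a ground-truth record (reference midpoint,
length, allele, haplotype start, strand) sufficient to score any downstream
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BASES, DiploidGenome, DensityProfile, MaternalProbTrack, revcomp

FRAG_MIN = 100
FRAG_MAX = 700

TRUTH_COLUMNS = [
    "fragment_id",
    "ref_mid",
    "length",
    "allele",
    "allele_start",
    "strand",
]


@dataclass(frozen=True)
class ReadPair:
    """One simulated read pair (Phred+33 qualities)."""

    fragment_id: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str

    def __post_init__(self):
        if len(self.mate1_seq) != len(self.mate1_qual) or len(
            self.mate2_seq
        ) != len(self.mate2_qual):
            raise ValueError("sequence/quality length mismatch")


class QualityModel:
    """Per-base Phred quality generator.

    Parametric mode draws Q(i) ~ Normal(q_start - q_slope*i, q_noise_sd)
    clamped to [2, 41], a declining-quality profile typical of Illumina reads
    (lower quality toward the 3' end).  Empirical mode resamples quality
    strings from a user-supplied pool (e.g. read from a real FASTQ).
    """

    def __init__(self, mode, q_start=38.0, q_slope=0.06, q_noise_sd=2.0, pool=None):
        if mode not in ("parametric", "empirical", "constant"):
            raise ValueError(f"unknown quality model mode {mode!r}")
        self.mode = mode
        self.q_start = float(q_start)
        self.q_slope = float(q_slope)
        self.q_noise_sd = float(q_noise_sd)
        if mode == "empirical":
            if not pool:
                raise ValueError("empirical mode needs a pool of quality strings")
            self.pool = [qual_to_array(q) for q in pool]

    @classmethod
    def parametric(cls, q_start=38.0, q_slope=0.06, q_noise_sd=2.0):
        return cls("parametric", q_start, q_slope, q_noise_sd)

    @classmethod
    def constant(cls, q=41):
        return cls("constant", q_start=q, q_slope=0.0, q_noise_sd=0.0)

    @classmethod
    def empirical(cls, quality_strings):
        return cls("empirical", pool=quality_strings)

    def sample(self, read_length: int, rng) -> np.ndarray:
        if self.mode == "empirical":
            candidates = [q for q in self.pool if len(q) >= read_length]
            if not candidates:
                raise ValueError("no pooled quality string long enough")
            q = candidates[int(rng.integers(len(candidates)))][:read_length]
            return q.copy()
        mean = self.q_start - self.q_slope * np.arange(read_length)
        if self.mode == "constant" or self.q_noise_sd == 0:
            q = mean
        else:
            q = mean + rng.normal(0.0, self.q_noise_sd, size=read_length)
        return np.clip(np.rint(q), 2, 41).astype(np.int64)


def qual_to_array(qual: str) -> np.ndarray:
    """Phred+33 string -> integer quality array (validates the encoding)."""
    arr = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int64) - 33
    if (arr < 0).any() or (arr > 60).any():
        raise ValueError("invalid Phred+33 quality characters")
    return arr


def array_to_qual(arr: np.ndarray) -> str:
    return (np.asarray(arr, dtype=np.uint8) + 33).tobytes().decode()


def sample_fragment_length(rng, size=None):
    """Fragment length: round(100 + (700-100) * Beta(2, 5))."""
    x = rng.beta(2.0, 5.0, size=size)
    val = np.rint(FRAG_MIN + (FRAG_MAX - FRAG_MIN) * x).astype(np.int64)
    return int(val) if size is None else val


def sample_midpoint(density: DensityProfile, rng, size=None):
    """Fragment midpoint drawn proportionally to the density weights."""
    return density.sample(rng, size=size)


def assign_allele(z: int, track: MaternalProbTrack, rng) -> str:
    """Assign the fragment to an allele via the local maternal probability."""
    p = track.prob_at(z)
    return "maternal" if rng.random() < p else "paternal"


def lift_to_allele(
    z: int, genome: DiploidGenome, allele: str, max_perturb: int = 50
) -> int:
    """Map a reference position onto the assigned haplotype.

    If the map is undefined at ``z`` (inside a haplotype deletion), the
    position is perturbed iteratively (z-1, z+1, z-2, z+2, ...; lower
    coordinate first) until it maps.
    """
    m = genome.ref_to_hap(allele)
    n = len(m)
    if not 0 <= z < n:
        raise ValueError(f"position {z} outside genome")
    if m[z] >= 0:
        return int(m[z])
    for d in range(1, max_perturb + 1):
        for p in (z - d, z + d):
            if 0 <= p < n and m[p] >= 0:
                return int(m[p])
    raise ValueError(f"no mappable position within {max_perturb} of {z}")


def extract_read_pair(hap_seq: str, start: int, length: int, read_length: int,
                      strand: str):
    """Extract the two end reads of a fragment from a haplotype.

    mate1 is the read sequenced from the fragment's 5' end: on '+' the
    forward subsequence at the left end, with mate2 the reverse complement of
    the right end; on '-' the roles of the two genomic ends swap.
    """
    if read_length > length:
        raise ValueError("read_length exceeds fragment length")
    end = start + length
    if start < 0 or end > len(hap_seq):
        raise ValueError("fragment outside haplotype bounds")
    left = hap_seq[start : start + read_length]
    right = revcomp(hap_seq[end - read_length : end])
    return (left, right) if strand == "+" else (right, left)


_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _default_submatrix() -> np.ndarray:
    m = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(m, 0.0)
    return m


def insert_errors(seq: str, qual, rng, substitution_matrix=None):
    """Substitute bases at the Phred-implied error rate 10**(-Q/10).

    The substitute base is drawn from the matrix row of the true base
    (default: uniform over the other three bases).  Returns the mutated
    sequence.
    """
    q = qual_to_array(qual) if isinstance(qual, str) else np.asarray(qual)
    if len(seq) != len(q):
        raise ValueError("sequence/quality length mismatch")
    sub = _default_submatrix() if substitution_matrix is None else np.asarray(
        substitution_matrix, dtype=float
    )
    p_err = 10.0 ** (-q / 10.0)
    hit = rng.random(len(seq)) < p_err
    if not hit.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(hit):
        b = seq[i]
        if b not in _BASE_IDX:
            continue  # N stays N
        row = sub[_BASE_IDX[b]]
        out[i] = BASES[int(rng.choice(4, p=row / row.sum()))]
    return "".join(out)


def simulate_reads(
    genome: DiploidGenome,
    density: DensityProfile,
    track: MaternalProbTrack,
    quality_model: QualityModel,
    n_fragments: int,
    read_length: int,
    seed: int = 0,
    apply_errors: bool = True,
    substitution_matrix=None,
    max_perturb: int = 50,
    max_reject: int = 1000,
):
    """Run the full seven-step simulation.

    Returns ``(pairs, truth)``: a list of ReadPair and a pandas DataFrame of
    per-fragment ground truth (fragment_id, ref_mid, length, allele,
    allele_start, strand).  Fragments falling outside haplotype bounds are
    rejected and resampled, preserving the length distribution of retained
    fragments.  Deterministic given ``seed``.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    truth_rows = []
    n_rejected = 0
    for i in range(n_fragments):
        for _attempt in range(max_reject):
            L = sample_fragment_length(rng)
            if L < read_length:
                L = read_length
            z = int(sample_midpoint(density, rng))
            a = assign_allele(z, track, rng)
            za = lift_to_allele(z, genome, a, max_perturb=max_perturb)
            hap = genome.hap_seq(a)
            start = za - L // 2
            if start < 0 or start + L > len(hap):
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError("too many rejected fragments; genome too small?")
        strand = "+" if rng.random() < 0.5 else "-"
        m1, m2 = extract_read_pair(hap, start, L, read_length, strand)
        q1 = quality_model.sample(read_length, rng)
        q2 = quality_model.sample(read_length, rng)
        if apply_errors:
            m1 = insert_errors(m1, q1, rng, substitution_matrix)
            m2 = insert_errors(m2, q2, rng, substitution_matrix)
        fid = f"frag{i:07d}"
        pairs.append(
            ReadPair(fid, m1, array_to_qual(q1), m2, array_to_qual(q2))
        )
        truth_rows.append((fid, z, L, a, start, strand))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth.attrs["n_rejected"] = n_rejected
    return pairs, truth
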