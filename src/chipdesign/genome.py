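"""Synthetic diploid genomes for ChIP-seq design benchmarking.

This module builds the inputs every downstream stage consumes: a reference
chromosome with two phased haplotypes (maternal/paternal), a read-density
profile with enriched binding sites over background, a per-window maternal
probability track around heterozygous SNPs, and a planted repeat annotation.
It is a desk-scale stand-in for a real diploid human chromosome with phased
variants.

Coordinates are 0-based, half-open everywhere; BED conventions on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
REPEAT_CLASSES = ("satellite", "LINE", "SINE", "LTR", "SDR")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PhasedVariant:
    """One phased heterozygous variant, VCF-style anchored for indels.

    For SNPs all three alleles have length 1.  For indels the first base of
    every allele is the shared anchor base at ``pos``.
    """

    pos: int
    ref_allele: str
    maternal_allele: str
    paternal_allele: str

    @property
    def is_het(self) -> bool:
        return self.maternal_allele != self.paternal_allele

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.maternal_allele) == 1
            and len(self.paternal_allele) == 1
        )

    def __post_init__(self):
        if self.is_het and self.maternal_allele == self.paternal_allele:
            raise ValueError("het variant with identical alleles")


@dataclass(frozen=True)
class RepeatAnnotation:
    """Planted repeat intervals labeled by class (BED-like, half-open)."""

    intervals: tuple = ()  # tuples (start, end, repeat_class)

    def __post_init__(self):
        for start, end, _cls in self.intervals:
            if not 0 <= start < end:
                raise ValueError(f"bad repeat interval [{start}, {end})")

    def classes(self):
        return sorted({c for _, _, c in self.intervals})

    def total_length(self, repeat_class: str) -> int:
        ivs = sorted(
            (s, e) for s, e, c in self.intervals if c == repeat_class
        )
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def merged(self, repeat_class: str):
        """Merged (start, end) intervals of one class, sorted."""
        ivs = sorted((s, e) for s, e, c in self.intervals if c == repeat_class)
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out


@dataclass
class DiploidGenome:
    """Reference chromosome plus maternal/paternal haplotypes.

    ``ref_to_mat``/``ref_to_pat`` map each reference position to its haplotype
    position (-1 where the position falls inside a haplotype deletion);
    ``mat_to_ref``/``pat_to_ref`` are the inverses (-1 inside insertions).
    """

    chrom: str
    ref_seq: str
    maternal_seq: str
    paternal_seq: str
    variants: list = field(default_factory=list)
    ref_to_mat: np.ndarray = None
    ref_to_pat: np.ndarray = None
    mat_to_ref: np.ndarray = None
    pat_to_ref: np.ndarray = None
    repeats: RepeatAnnotation = field(default_factory=RepeatAnnotation)

    def __len__(self) -> int:
        return len(self.ref_seq)

    def hap_seq(self, allele: str) -> str:
        return self.maternal_seq if allele == "maternal" else self.paternal_seq

    def ref_to_hap(self, allele: str) -> np.ndarray:
        return self.ref_to_mat if allele == "maternal" else self.ref_to_pat

    def hap_to_ref(self, allele: str) -> np.ndarray:
        return self.mat_to_ref if allele == "maternal" else self.pat_to_ref

    @property
    def het_snp_positions(self) -> np.ndarray:
        return np.array(
            [v.pos for v in self.variants if v.is_snp and v.is_het], dtype=int
        )


def _apply_variants(ref: str, alleles):
    """Apply (pos, ref_allele, alt_allele) edits; return haplotype + maps.

    ``alleles`` must be sorted by position with non-overlapping ref spans.
    Returns (hap_seq, ref_to_hap, hap_to_ref) with -1 marking undefined
    positions (reference bases deleted from the haplotype, or inserted
    haplotype bases absent from the reference).
    """
    n = len(ref)
    ref_to_hap = np.full(n, -1, dtype=np.int64)
    hap_parts = []
    hap_to_ref_parts = []
    hap_pos = 0
    ref_pos = 0
    for pos, ref_allele, alt_allele in alleles:
        if pos < ref_pos:
            raise ValueError("overlapping variants")
        # identical segment before the variant
        seg = ref[ref_pos:pos]
        hap_parts.append(seg)
        ref_to_hap[ref_pos:pos] = np.arange(hap_pos, hap_pos + len(seg))
        hap_to_ref_parts.append(np.arange(ref_pos, pos))
        hap_pos += len(seg)
        ref_pos = pos
        if ref[pos : pos + len(ref_allele)] != ref_allele:
            raise ValueError(f"ref allele mismatch at {pos}")
        hap_parts.append(alt_allele)
        if len(ref_allele) == len(alt_allele) == 1:
            # SNP: position maps through
            ref_to_hap[pos] = hap_pos
            hap_to_ref_parts.append(np.array([pos]))
        else:
            # anchored indel: anchor base maps, the rest is deleted/inserted
            ref_to_hap[pos] = hap_pos
            hap_to_ref_parts.append(
                np.concatenate(
                    [[pos], np.full(len(alt_allele) - 1, -1, dtype=np.int64)]
                )
            )
            # deleted reference bases stay at -1
        hap_pos += len(alt_allele)
        ref_pos = pos + len(ref_allele)
    seg = ref[ref_pos:]
    hap_parts.append(seg)
    ref_to_hap[ref_pos:] = np.arange(hap_pos, hap_pos + len(seg))
    hap_to_ref_parts.append(np.arange(ref_pos, n))
    hap_seq = "".join(hap_parts)
    hap_to_ref = (
        np.concatenate(hap_to_ref_parts)
        if hap_to_ref_parts
        else np.empty(0, dtype=np.int64)
    )
    assert len(hap_to_ref) == len(hap_seq)
    return hap_seq, ref_to_hap, hap_to_ref


def _random_seq(length: int, rng) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _plant_duplications(seq: str, dup_frac: float, dup_unit: int, rng):
    """Copy segments around the genome until ~dup_frac of it is duplicated.

    Each event copies one ``dup_unit``-long source segment to a destination
    (satellite copies are tandem, directly after the source); both copies are
    annotated, so the annotation covers ~dup_frac of the genome.
    """
    n = len(seq)
    if dup_frac <= 0:
        return seq, []
    n_events = max(1, int(round(dup_frac * n / (2 * dup_unit))))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    intervals = []
    used = []  # (start, end) intervals already participating

    def overlaps(s, e):
        return any(s < ue and us < e for us, ue in used)

    for i in range(n_events):
        cls = REPEAT_CLASSES[i % len(REPEAT_CLASSES)]
        for _ in range(200):
            src = int(rng.integers(0, n - 2 * dup_unit))
            if cls == "satellite":
                dst = src + dup_unit
            else:
                dst = int(rng.integers(0, n - dup_unit))
            if abs(dst - src) < dup_unit:
                if cls != "satellite" or dst != src + dup_unit:
                    continue
            if overlaps(src, src + dup_unit) or overlaps(dst, dst + dup_unit):
                continue
            arr[dst : dst + dup_unit] = arr[src : src + dup_unit]
            intervals.append((src, src + dup_unit, cls))
            intervals.append((dst, dst + dup_unit, cls))
            used.append((src, src + dup_unit))
            used.append((dst, dst + dup_unit))
            break
        else:
            raise ValueError("could not place requested duplications")
    return arr.tobytes().decode(), sorted(intervals)


def generate_genome(
    length: int,
    n_snps: int,
    indel_rate: float = 0.0,
    seed: int = 0,
    dup_frac: float = 0.0,
    dup_unit: int = 300,
    chrom: str = "chrS",
    max_indel_len: int = 3,
) -> DiploidGenome:
    """Generate a random diploid genome with phased heterozygous variants.

    ``n_snps`` heterozygous SNPs are placed at distinct positions; an
    additional ``round(indel_rate * n_snps)`` short (1..max_indel_len bp)
    heterozygous indels are planted, each on one haplotype.  ``dup_frac`` of
    the genome is covered by planted duplicated segments annotated as repeat
    elements (satellite copies tandem, other classes dispersed).
    Deterministic given ``seed``.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if not 0 <= indel_rate <= 0.2:
        raise ValueError("indel_rate must be in [0, 0.2]")
    n_indels = int(round(indel_rate * n_snps))
    n_var = n_snps + n_indels
    if n_var * 10 > length - 20:
        raise ValueError(
            f"genome of length {length} too small for {n_var} variants"
        )
    rng = np.random.default_rng(seed)
    ref, rep_intervals = _plant_duplications(
        _random_seq(length, rng), dup_frac, dup_unit, rng
    )

    # distinct variant positions with >= max_indel_len+2 separation
    positions = []
    guard = max_indel_len + 2
    attempts = 0
    while len(positions) < n_var:
        p = int(rng.integers(10, length - 10))
        if all(abs(p - q) > guard for q in positions):
            positions.append(p)
        attempts += 1
        if attempts > 1000 * max(n_var, 1):
            raise ValueError("could not place requested variants")
    positions.sort()
    is_indel = np.zeros(n_var, dtype=bool)
    if n_indels:
        is_indel[rng.choice(n_var, size=n_indels, replace=False)] = True

    variants = []
    for p, indel in zip(positions, is_indel):
        if not indel:
            ref_base = ref[p]
            alt = rng.choice([b for b in BASES if b != ref_base])
            if rng.random() < 0.5:
                variants.append(PhasedVariant(p, ref_base, alt, ref_base))
            else:
                variants.append(PhasedVariant(p, ref_base, ref_base, alt))
        else:
            k = int(rng.integers(1, max_indel_len + 1))
            deletion = rng.random() < 0.5
            maternal = rng.random() < 0.5
            if deletion:
                ref_allele = ref[p : p + k + 1]
                alt_allele = ref[p]
            else:
                ref_allele = ref[p]
                alt_allele = ref[p] + _random_seq(k, rng)
            mat = alt_allele if maternal else ref_allele
            pat = ref_allele if maternal else alt_allele
            variants.append(PhasedVariant(p, ref_allele, mat, pat))

    mat_edits = [
        (v.pos, v.ref_allele, v.maternal_allele)
        for v in variants
        if v.maternal_allele != v.ref_allele
    ]
    pat_edits = [
        (v.pos, v.ref_allele, v.paternal_allele)
        for v in variants
        if v.paternal_allele != v.ref_allele
    ]
    mat_seq, ref_to_mat, mat_to_ref = _apply_variants(ref, mat_edits)
    pat_seq, ref_to_pat, pat_to_ref = _apply_variants(ref, pat_edits)
    return DiploidGenome(
        chrom=chrom,
        ref_seq=ref,
        maternal_seq=mat_seq,
        paternal_seq=pat_seq,
        variants=variants,
        ref_to_mat=ref_to_mat,
        ref_to_pat=ref_to_pat,
        mat_to_ref=mat_to_ref,
        pat_to_ref=pat_to_ref,
        repeats=RepeatAnnotation(tuple(rep_intervals)),
    )


@dataclass
class DensityProfile:
    """Per-base fragment-midpoint sampling weights (sum to one).

    ``sites`` records the planted enrichment bumps as (start, end, center)
    triples; centers double as true binding-site summits downstream.
    """

    weights: np.ndarray
    sites: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("density weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("density has zero total mass")
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total
        self._cdf = None

    def __len__(self):
        return len(self.weights)

    def mass(self, start: int, end: int) -> float:
        """Total probability mass on [start, end)."""
        return float(self.weights[start:end].sum())

    def sample(self, rng, size=None):
        """Draw midpoint positions from the discrete weight distribution."""
        if self._cdf is None:
            self._cdf = np.cumsum(self.weights)
            self._cdf[-1] = 1.0
        u = rng.random(size)
        idx = np.searchsorted(self._cdf, u, side="right")
        return int(idx) if size is None else idx.astype(np.int64)


def build_density(
    genome: DiploidGenome,
    n_sites: int,
    enrichment: float = 10.0,
    bump_width: int = 200,
    seed: int = 0,
    centers=None,
) -> DensityProfile:
    """Uniform background plus triangular enrichment bumps.

    Each bump is a symmetric triangle of total width ``bump_width`` whose
    apex weight is ``enrichment``-fold the background per-base weight; apex
    positions are recorded as true binding sites.  Explicit ``centers``
    override random placement (e.g. to center bumps on SNPs).
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    n = len(genome)
    rng = np.random.default_rng(seed)
    w = np.ones(n, dtype=float)
    half = max(1, bump_width // 2)
    if centers is None:
        centers = rng.integers(half, n - half, size=n_sites)
    else:
        centers = np.asarray(centers, dtype=int)
        if len(centers) != n_sites:
            raise ValueError("len(centers) must equal n_sites")
    sites = []
    for c in centers:
        c = int(c)
        lo, hi = max(0, c - half), min(n, c + half)
        x = np.arange(lo, hi)
        w[lo:hi] += (enrichment - 1.0) * (1.0 - np.abs(x - c) / half)
        sites.append((lo, hi, c))
    return DensityProfile(weights=w, sites=sites)


def merge_intervals(intervals):
    """Merge strictly overlapping half-open intervals (touching stay apart)."""
    out = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class MaternalProbTrack:
    """Piecewise-constant true maternal probability over the reference.

    ``components`` are disjoint (start, end, prob) with prob in [0.1, 0.9];
    the background probability outside all components is exactly 0.5.
    """

    components: list = field(default_factory=list)
    background: float = 0.5

    def __post_init__(self):
        self.components = sorted(self.components)
        starts = [s for s, _, _ in self.components]
        ends = [e for _, e, _ in self.components]
        for i in range(1, len(self.components)):
            if starts[i] < ends[i - 1]:
                raise ValueError("track components overlap")
        self._starts = np.array(starts, dtype=np.int64)
        self._ends = np.array(ends, dtype=np.int64)
        self._probs = np.array([p for _, _, p in self.components])

    def prob_at(self, pos: int) -> float:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[i]:
            return float(self._probs[i])
        return self.background

    def component_at(self, pos: int) -> int:
        """Index of the component covering pos, or -1 for background."""
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[i]:
            return i
        return -1


def assign_maternal_probs(
    genome: DiploidGenome, window: int = 1000, seed: int = 0
) -> MaternalProbTrack:
    """Draw one true maternal probability per merged SNP window.

    A window of total width ``window`` is centered on every heterozygous SNP
    ([pos - window//2, pos + window//2), clipped to the genome); transitively
    overlapping windows merge into a single component that receives a single
    probability drawn uniformly from [0.1, 0.9].  Background is 0.5.
    """
    rng = np.random.default_rng(seed)
    half = window // 2
    n = len(genome)
    raw = [
        (max(0, int(p) - half), min(n, int(p) + half))
        for p in genome.het_snp_positions
    ]
    merged = merge_intervals(raw)
    comps = [(s, e, float(rng.uniform(0.1, 0.9))) for s, e in merged]
    return MaternalProbTrack(components=comps)
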