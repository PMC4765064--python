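# Methods

`chipdesign` evaluates how paired-end (PE) versus single-end (SE) read
designs, read length, and sequencing depth affect the three core outcomes of
a ChIP-seq experiment: alignment accuracy, peak reproducibility, and
allele-specific binding (ASB) detection. Because the real comparisons of
interest require deeply sequenced human datasets, the package instead builds
a fully controlled synthetic world — a diploid genome with known variants, a
known binding-density landscape, and known per-window allelic imbalance —
and measures every metric against that ground truth.

## The synthetic diploid genome

`generate_genome(length, n_snps, indel_rate, seed, dup_frac, dup_unit)`
draws a uniform-random A/C/G/T reference and plants `n_snps` phased
heterozygous SNPs plus `round(indel_rate * n_snps)` short (1–3 bp)
heterozygous indels, each assigned to one haplotype at random. Maternal and
paternal sequences are produced by applying exactly the variants phased to
each haplotype, and bidirectional coordinate maps (reference ↔ haplotype)
are built alongside; positions inside a haplotype deletion are undefined in
the forward map, inserted haplotype bases undefined in the inverse map.
With SNP-only variants both maps are the identity.

Repetitive sequence is modeled by planted duplications: `dup_frac` of the
genome is covered by exact segment copies of length `dup_unit` (default
300 bp), cycling through the classes satellite (tandem copy), LINE, SINE,
LTR and SDR (dispersed copies). Both copies of every event are annotated,
so multi-mapping behavior and repeat-coverage metrics are testable by
construction. Coordinates are 0-based half-open throughout; BED on disk.

What this emulates and what it does not: the generator reproduces the
*structural* features the metrics are sensitive to (heterozygous sites,
ambiguous duplicated sequence, coordinate shifts from indels) but not
realistic human variation rates, recombination, GC content, or the repeat
family sequence models of a real chromosome. Passing tests therefore
demonstrate correctness of the machinery and the direction of design
effects, not quantitative agreement with any real dataset.

## Fragment and read model

Reads are simulated in seven steps per fragment:

1. **Length** `L ~ round(100 + (700 − 100)·Beta(2, 5))`, giving mean
   1900/7 ≈ 271.4 bp and SD ≈ 95.8 bp within hard bounds [100, 700] — a
   right-skewed sonication-like length distribution. The [100, 700] range
   also serves as the PE aligner's insert constraint, so simulated
   fragments are always recoverable in principle.
2. **Midpoint** `z` drawn from a discrete per-base density: uniform
   background plus triangular "binding site" bumps whose apex weight is
   `enrichment`-fold the background (apexes are recorded as true sites).
3. **Allele**: maternal with the probability of the track component
   containing `z`. The track places a 1000 bp window centered on every het
   SNP ([pos−500, pos+500)); transitively overlapping windows are merged
   into one component that receives a single probability drawn once from
   Unif[0.1, 0.9]; the background probability is exactly 0.5. One draw per
   merged component is the simplest construction giving equal probabilities
   in overlapping windows; how a chain of transitively overlapping windows
   should share a probability was genuinely open, and this choice is
   documented here deliberately.
4. **Liftover** of `z` to the assigned haplotype. If the position falls in
   a haplotype deletion it is perturbed iteratively (z−1, z+1, z−2, z+2, …,
   lower coordinate first) until it maps; the perturbation order is a fixed
   tie-break so truth tables are reproducible.
5. **Extraction**: the fragment occupies [z^a − ⌊L/2⌋, z^a − ⌊L/2⌋ + L) on
   the haplotype; mate 1 is the read at the fragment's 5′ end, mate 2 the
   reverse complement of the 3′ end. Fragment orientation is Bernoulli(0.5)
   and swaps which genomic end yields mate 1. Out-of-bounds fragments are
   rejected and fully resampled (preserving the length distribution) rather
   than clipped.
6. **Qualities** from a parametric declining-Phred model,
   Q(i) ~ N(q_start − q_slope·i, q_noise_sd²) clamped to [2, 41] (defaults
   38, 0.06/base, 2), mimicking the lower 3′-end quality of Illumina long
   reads; an empirical mode resamples quality strings pooled from any real
   FASTQ instead.
7. **Errors**: each base substituted independently with probability
   10^(−Q/10); the substitute is uniform over the other three bases by
   default, overridable by a 4×4 substitution matrix.

Per-fragment truth records (reference midpoint, length, allele, haplotype
start, strand) are sufficient to score any downstream alignment.

## Design transforms

From one full PE dataset: `pe_to_se` keeps one uniformly chosen mate per
pair; `trim_reads`/`trim_pairs` keep the 5′ prefix (75/50/36 bp designs —
the 3′ end is the low-quality end); `subsample_half` keeps exactly ⌊n/2⌋
intact pairs without replacement ("PEhalf", matching SE read counts at
equal read length). All are deterministic given their seed and preserve
read IDs and order.

## Toy aligner

A brute-force ungapped k-mismatch aligner substitutes for Bowtie/BWA at
desk scale. It reports all hits in the best (minimum-mismatch) stratum on
either strand, flags a read unique iff that stratum has exactly one hit,
and pairs mates under forward/reverse orientation with insert in
[100, 700]. Pair uniqueness means exactly one best valid pairing; optional
per-end filters implement "both ends unique" (Uni) and "one unique end
rescues" (UR) conventions, and a random-best-hit mode emulates
multi-read-keeping aligners for the accuracy analyses. N matches nothing
and always counts as a mismatch (conservative and testable). An optional
3′ quality trim implements the standard running-sum rule.

Implementation: candidate positions come from a pigeonhole exact-seed scan
(split the read into k+1 chunks; any ≤k-mismatch alignment matches one
chunk exactly — this remains complete with N bases, since every N adds a
forced mismatch), verified by vectorized Hamming counting. The test suite
proves equivalence against a literal position-by-position scan. Genomes
here are ≤ a few hundred kb, so correctness and reproducibility are worth
more than an FM-index.

## Alignment metrics

* **Alignment rate**: aligned/total reads (or pairs).
* **Accuracy vs truth**: an extended aligned read is correct iff its
  reference interval contains the fragment's true midpoint (half-open).
  PE fragments are the joined outer mate spans; SE alignments are extended
  to a supplied average fragment length — the truth-table mean by default,
  since cross-correlation fragment-size estimation is out of scope.
* **Relaxed-gold-set FP rates**: given two alignment sets A, B and a
  permissive "relaxed" mappable set, the FP rate of A is the fraction of
  A\B reads that the relaxed set deems unmappable (NaN when A\B is empty).
* **Multi-coverage**: bases with fragment pileup depth ≥ 5.
* **Repeat coverage**: per repeat class, the sum of full fragment lengths
  over fragments overlapping that class's elements by ≥ 30% *of the
  fragment length* (the denominator was unspecified in the rule's source;
  fragment length was chosen because the summed quantity is fragment
  length), normalized by the class's total element length. Overlap with
  multiple elements of one class is summed before thresholding.

## Peak metrics

Peak lists are ranked tables (chrom, summit, score). The minimax summit
distance of the rank-j peak among top-M lists is

    L_M(j) = max_{i≠k} min_{ℓ ≤ ⌊1.5M⌋} |S_ij − S_kℓ|,

with cross-chromosome distances +∞; R_M is the fraction of ranks with
L_M(j) ≤ T (default 200 bp). Floors are used for the non-integer 1.5M and
1.2M bounds (configurable). Peak matching between two lists is greedy in
the first list's rank order to the nearest unmatched summit at distance
strictly < 200 bp (the assignment rule when several peaks lie within range
was open; greedy-by-rank is deterministic and tested against exhaustive
assignment on small cases). Rank-change decomposition classifies the top M
peaks of one list by their matched rank in the other: ≤ M unchanged,
≤ ⌊1.2M⌋ moderate, ≤ relaxed-list size large, otherwise design-specific.
Summit-coverage comparison counts reads in the closed ±100 bp window
around isolated summits (no other-list summit within ±500 bp) and flags
fold-changes ≥ 1.5; the fold is the plain max/min ratio, with a +1
pseudocount on both counts only when the smaller is zero (so 0 vs 0 gives
fold 1). Motif resolution reports, per top-fraction peak group, the median
summit-to-nearest-motif distance and the fraction of peaks containing a
motif; motif positions are consumed as an input table.

## ASB detection

Reads (SE) or fragments (PE) are aligned separately to both haplotypes and
assigned to the allele with fewer mismatches — summed over both mates for
PE. PE mismatch ties are discarded; SE ties are broken at random with the
run's seed. Reads containing N, and reads hitting the two alleles at
different lifted reference positions (any nonzero difference after
liftover), are discarded. Counts are accumulated per het SNP over assigned
reads covering the SNP (half-open; a PE fragment counts once if either
mate covers), and SNPs with coverage < 5 are excluded. Imbalance is tested
with the exact two-sided binomial test at null proportion 0.5 (twice the
smaller tail, capped at 1); no reference-bias correction is needed because
the toy aligner is symmetric by construction.

The p-value cutoff for a target FDR (default 0.1) is calibrated by
simulation: null counts Binomial(coverage, 0.5) are drawn at every tested
SNP for `n_sim` rounds, and the estimated FDR at cutoff c is the mean null
call count (plus one pooled pseudo-call, so a finite simulation never
certifies FDR 0) divided by the observed call count; the largest observed
p-value meeting the target is returned. ROC curves sweep the cutoff from 0
to 1; a SNP is truly allele-specific when its generating maternal
probability exceeds 0.6 or falls below 0.4 (maternal:paternal ratio > 1.5
or < 2/3). The TPR denominator includes coverage-excluded true loci, so
the maximum TPR stays below 1 whenever a true locus was untestable; AUC
extends the curve horizontally to FPR 1. Stringent allele-specific filters
(≥ 20 reads, p ≤ 0.01, fold ≥ 1.5, with a zero minor count giving +∞ fold)
and co-binding classification (regions from merged ±100 bp windows around
summit pairs < 200 bp apart; ASCB when both factors favor the same allele,
BiASB when different, excluded when one factor is internally inconsistent)
follow the same conventions.

## Orchestration and problem sizes

`run_experiment` chains everything from a single YAML config; all
randomness derives from one master seed via SHA-256 (stage seeds < 2³¹),
and a manifest records the exact config plus a checksum of every output,
so re-running a config is bit-identical.

The shipped evaluation sizes were chosen to give each statistical check
adequate power on a single core: 10⁵ draws for sampler moments; 10⁴ null
SNPs for type-I calibration; ten 500-SNP mixture datasets (80% null, 20%
at maternal probability 0.8, ~30× coverage) for FDR control; a 100 kb
duplication-free genome with 10⁴ error-free PE fragments for the
end-to-end zero-error run; and 50 kb genomes with 20% planted duplication
for the directional design comparisons (8×10³ fragments for accuracy,
3 replicates of 1.2×10⁴ fragments and 40 SNPs for ASB ROC areas, with ROC
areas averaged over replicates as one would average over experimental
replicates).

## Known limitations

* No PCR duplicates, adapter read-through, indel sequencing errors, or GC
  bias in the simulator; no gapped alignment in the toy aligner.
* Peak calling, IDR thresholding, and motif discovery/scanning are out of
  scope: peak lists and motif positions are consumed as ranked input
  tables.
* The FDR calibration simulates the null at the *observed* coverages of
  all tested SNPs, which overestimates the null when many loci are truly
  imbalanced — the control is conservative, as the calibration tests show.
* Directional design findings (PE ≥ SE accuracy, ROC area growing with
  sequenced bases) are properties of this synthetic world; effect sizes do
  not transfer to real data. Notably, short-read PE slightly outperforms
  its nearly base-matched long-read SE counterpart here (pairing rescues
  uniqueness in duplicated sequence and PE ties are discarded rather than
  randomly assigned), so ROC areas rank SE36 ≤ SE75 ≤ PE36 ≤ PE75 rather
  than following base count alone.
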