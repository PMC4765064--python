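# chipdesign

Simulation-based evaluation of ChIP-seq sequencing designs: does paired-end
(PE) sequencing, a longer read, or more depth actually buy you better
alignments, more reproducible peaks, or more allele-specific binding (ASB)
calls?

The package is aimed at people planning ChIP-seq (or similar
enrichment-sequencing) experiments and at methods developers who need a
controlled testbed. It builds a fully synthetic diploid world — a reference
chromosome with phased heterozygous SNPs/indels, planted duplicated
("repeat") segments, a binding-density landscape, and a known per-window
maternal-allele probability — simulates allele-aware paired-end reads from
it, derives alternative designs *in silico* (single-end, trimmed to
75/50/36 bp, half depth), aligns everything with a built-in brute-force
k-mismatch aligner, and scores each design against the generating truth.

## The models in brief

* **Fragments**: length `L ~ round(100 + 600·Beta(2,5))` (mean ≈ 271 bp),
  midpoint `z` from a per-base density with enrichment bumps, allele
  `a ∈ {mat, pat}` drawn with the local true maternal probability (one
  Unif[0.1, 0.9] draw per merged 1000 bp SNP window, 0.5 background), `z`
  lifted onto haplotype coordinates, both end reads extracted, Phred
  qualities from a declining-quality model, and errors inserted at rate
  `10^(−Q/10)`.
* **Alignment accuracy**: an extended aligned read is correct iff it covers
  the fragment's true reference midpoint.
* **Peak reproducibility**: minimax summit distance
  `L_M(j) = max_{i≠k} min_{ℓ≤1.5M} |S_ij − S_kℓ|` across ranked replicate
  peak lists, and `R_M`, the fraction of top-M ranks with `L_M(j) ≤ 200` bp;
  plus rank-change decomposition and summit-coverage comparison of peak-set
  differences.
* **ASB**: reads aligned to both haplotypes, assigned to the allele with
  fewer mismatches (PE: summed over mates, ties discarded; N-containing and
  location-discordant reads dropped), exact two-sided binomial test at
  p₀ = 0.5 per SNP with ≥ 5 covering reads, and a p-value cutoff calibrated
  to a target FDR (default 0.1) by simulating null counts at the observed
  coverages. ROC curves score calls against the generating truth (true ASB:
  maternal:paternal ratio > 1.5 or < 2/3).

See `docs/methods.md` for the full model description, parameter defaults,
and design decisions.

## Worked example

Run a one-replicate experiment comparing PE36, SE36 and SE75 derived from
the same 4000 simulated fragments on a 30 kb diploid genome with 12 het
SNPs and 10% planted duplications:

```python
from chipdesign.experiment import run_experiment

summary = run_experiment(
    {
        "seed": 11,
        "replicates": 1,
        "genome": {"length": 30000, "n_snps": 12, "dup_frac": 0.1},
        "density": {"n_sites": 6, "enrichment": 8.0, "bump_width": 400},
        "simulate": {"n_fragments": 4000, "read_length": 101},
        "designs": [
            {"mode": "PE", "read_length": 36},
            {"mode": "SE", "read_length": 36},
            {"mode": "SE", "read_length": 75},
        ],
    },
    "demo_run",
)
print(summary.to_string(index=False))
```

prints

```
 replicate design mode  read_length  n_reads  alignment_rate  accuracy  multi_coverage  n_tested_snps  asb_cutoff  n_asb  roc_auc
         1   PE36   PE           36     4000         0.96650  1.000000           29944             10    0.013531      1    0.600
         1   SE36   SE           36     4000         0.87650  0.993155           29911              7    0.000000      0    0.450
         1   SE75   SE           75     4000         0.88925  0.993815           29956             11    0.015625      3    0.775
```

Reading the row for PE36: 96.7% of pairs aligned uniquely (SE36 manages
only 87.7% — short single reads are ambiguous in the duplicated segments),
every aligned fragment covered its true midpoint, 29,944 of 30,000 bases
reached ≥ 5× fragment coverage, 10 SNPs had ≥ 5 allele-assigned covering
reads, and at the FDR-0.1 calibrated cutoff one SNP was called
allele-specific. The `demo_run/` directory holds the FASTQ pairs, truth
table, per-design fragment and allele-count tables, and a manifest with the
config and a checksum of every output (re-running the same config is
bit-identical).

The same stages are scriptable from the shell via the `chipdesign` CLI
(`simulate`, `transform`, `align-toy`, `eval-align`, `eval-peaks`, `asb`,
`experiment`); try `chipdesign --help`.

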