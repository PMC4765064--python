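"""End-to-end orchestration: simulate -> transform -> align -> evaluate -> ASB.

A full paired-end dataset is simulated once per replicate; every requested
design (PE/SE x read length x optional half-depth) is derived from it in
silico, aligned with the toy aligner to the reference (alignment metrics) and
to both haplotypes (allele-specific binding), and summarized in one table.
All randomness flows from a single master seed; per-stage seeds are derived
deterministically, so re-running a config is bit-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment_metrics as am
from . import asb as asb_mod
from . import io as cio
from .align import ToyAligner
from .genome import DiploidGenome, generate_genome, build_density, assign_maternal_probs
from .simulate import QualityModel, simulate_reads
from .transform import pe_to_se, trim_pairs, trim_reads, subsample_half

CONFIG_KEYS = {
    "seed", "replicates", "genome", "density", "track", "simulate",
    "designs", "align",
}


def derive_seed(master_seed: int, *labels) -> int:
    """Deterministic stage seed below 2**31 derived from the master seed."""
    text = ":".join([str(master_seed), *map(str, labels)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def design_label(mode: str, read_length: int, half: bool = False) -> str:
    return f"{mode}{read_length}" + ("half" if half else "")


def make_design(pairs, mode: str, read_length: int, half: bool = False,
                seed: int = 0):
    """Derive one design's reads from full PE data.

    Returns (mode, data): data is a ReadPair list for PE or a SingleRead list
    for SE.  Half-depth subsampling happens before trimming/end-sampling so
    both operate on the same fragments.
    """
    if half:
        pairs = subsample_half(pairs, seed=derive_seed(seed, "half"))
    if mode == "PE":
        return "PE", trim_pairs(pairs, read_length)
    if mode == "SE":
        reads = pe_to_se(pairs, seed=derive_seed(seed, "se"))
        return "SE", trim_reads(reads, read_length)
    raise ValueError(f"unknown design mode {mode!r}")


def default_max_mismatch(read_length: int) -> int:
    """Mismatch allowance by read length: 1 for <= 50 bp, 2 for longer."""
    return 1 if read_length <= 50 else 2


def _read_has_n(*seqs) -> bool:
    return any("N" in s for s in seqs)


def align_to_reference(data, mode: str, ref_seq: str, max_mismatch: int,
                       fragment_length: int = None, report: str = "unique",
                       insert_min: int = 100, insert_max: int = 700,
                       seed: int = 0):
    """Align one design's reads to the reference and build extended fragments.

    PE fragments are the joined outer spans of uniquely paired mates; SE
    alignments are extended to ``fragment_length``.  ``report='random_best'``
    keeps multi-reads by picking one best hit at random (used for the
    accuracy analyses of multi-read-keeping alignment rules).

    Returns (fragments DataFrame, n_aligned, n_total).
    """
    aligner = ToyAligner(ref_seq, "reference", max_mismatch)
    rng = np.random.default_rng(derive_seed(seed, "align", mode, report))
    n_total = len(data)
    if mode == "PE":
        aligned_pairs = []
        for p in data:
            res = aligner.align_pe(
                p.mate1_seq, p.mate2_seq, read_id=p.fragment_id,
                insert_min=insert_min, insert_max=insert_max,
                report=report, rng=rng,
            )
            if res is not None:
                aligned_pairs.append(res)
        frags = am.join_pe(aligned_pairs)
        return frags, len(aligned_pairs), n_total
    if fragment_length is None:
        raise ValueError("SE alignment needs a fragment_length for extension")
    kept = []
    for r in data:
        hits = aligner.align_se(r.seq, read_id=r.read_id)
        if not hits:
            continue
        if report == "unique":
            if hits[0].unique:
                kept.append(hits[0])
        elif report == "random_best":
            kept.append(hits[int(rng.integers(len(hits)))])
        else:
            raise ValueError(f"unknown report mode {report!r}")
    frags = am.extend_se(kept, fragment_length, len(ref_seq))
    return frags, len(kept), n_total


def _lift_pos(genome: DiploidGenome, allele: str, hap_pos: int) -> int:
    """Haplotype -> reference coordinate, nearest defined position on gaps."""
    m = genome.hap_to_ref(allele)
    hap_pos = min(max(hap_pos, 0), len(m) - 1)
    if m[hap_pos] >= 0:
        return int(m[hap_pos])
    for d in range(1, len(m)):
        for p in (hap_pos - d, hap_pos + d):
            if 0 <= p < len(m) and m[p] >= 0:
                return int(m[p])
    raise ValueError("haplotype has no mapped positions")


def asb_assign_reads(data, mode: str, genome: DiploidGenome,
                     max_mismatch: int = 2, seed: int = 0,
                     insert_min: int = 100, insert_max: int = 700) -> pd.DataFrame:
    """Align reads to both haplotypes and assign each to an allele.

    Implements the allele-assignment rules: fewer mismatches wins (PE: summed
    over mates, ties discarded; SE: ties broken at random); reads with an
    ambiguous base N, or aligned to both alleles at different lifted
    reference locations, are discarded.  Only uniquely aligned reads/pairs on
    each haplotype are considered.

    Returns one row per read interval (reference coordinates) of every
    assigned fragment: fragment_id, allele, start, end.
    """
    mat = ToyAligner(genome.maternal_seq, "maternal", max_mismatch)
    pat = ToyAligner(genome.paternal_seq, "paternal", max_mismatch)
    rng = np.random.default_rng(derive_seed(seed, "asb", mode))
    rows = []

    def hap_result_pe(aligner, allele, p):
        res = aligner.align_pe(
            p.mate1_seq, p.mate2_seq, read_id=p.fragment_id,
            insert_min=insert_min, insert_max=insert_max,
        )
        if res is None:
            return None
        m1, m2 = res
        lifted = _lift_pos(genome, allele, min(m1.start, m2.start))
        mm = m1.n_mismatch + m2.n_mismatch
        ivs = [
            (_lift_pos(genome, allele, m.start),
             _lift_pos(genome, allele, m.end - 1) + 1)
            for m in (m1, m2)
        ]
        return lifted, mm, ivs

    def hap_result_se(aligner, allele, r):
        hits = aligner.align_se(r.seq, read_id=r.read_id)
        if not hits or not hits[0].unique:
            return None
        h = hits[0]
        lifted = _lift_pos(genome, allele, h.start)
        iv = (lifted, _lift_pos(genome, allele, h.end - 1) + 1)
        return lifted, h.n_mismatch, [iv]

    for item in data:
        if mode == "PE":
            if _read_has_n(item.mate1_seq, item.mate2_seq):
                continue
            rm = hap_result_pe(mat, "maternal", item)
            rp = hap_result_pe(pat, "paternal", item)
            fid = item.fragment_id
        else:
            if _read_has_n(item.seq):
                continue
            rm = hap_result_se(mat, "maternal", item)
            rp = hap_result_se(pat, "paternal", item)
            fid = item.read_id
        call, _reason = asb_mod.assign_fragment_allele(
            None if rm is None else rm[:2],
            None if rp is None else rp[:2],
            mode=mode,
            rng=rng,
        )
        if call == "maternal":
            for s, e in rm[2]:
                rows.append((fid, "maternal", s, e))
        elif call == "paternal":
            for s, e in rp[2]:
                rows.append((fid, "paternal", s, e))
    return pd.DataFrame(rows, columns=["fragment_id", "allele", "start", "end"])


def asb_pipeline(data, mode: str, genome: DiploidGenome, track,
                 max_mismatch: int = 2, seed: int = 0, min_reads: int = 5,
                 target_fdr: float = 0.1, n_sim: int = 20):
    """Full ASB stage for one design: assign, count, test, calibrate, score.

    Returns a dict with the assigned reads, the AlleleCount table, the FDR
    cutoff, the called loci, the truth table, and the ROC curve/AUC.
    """
    assigned = asb_assign_reads(
        data, mode, genome, max_mismatch=max_mismatch, seed=seed
    )
    snps = genome.het_snp_positions
    counts = asb_mod.count_alleles(assigned, snps, min_reads=min_reads)
    truth = asb_mod.make_truth(snps, track)
    out = {
        "assigned": assigned,
        "counts": counts,
        "truth": truth,
        "cutoff": 0.0,
        "called": counts.iloc[0:0],
        "roc": None,
        "auc": float("nan"),
    }
    if len(counts):
        cutoff = asb_mod.fdr_cutoff(
            counts, target_fdr=target_fdr, n_sim=n_sim,
            seed=derive_seed(seed, "fdr"),
        )
        out["cutoff"] = cutoff
        out["called"] = asb_mod.call_asb(counts, cutoff)
        if truth["is_true_asb"].any():
            roc = asb_mod.roc_curve(counts, truth)
            out["roc"] = roc
            out["auc"] = asb_mod.roc_auc(roc)
    return out


DEFAULT_CONFIG = {
    "seed": 1,
    "replicates": 1,
    "genome": {"length": 50_000, "n_snps": 25, "indel_rate": 0.0,
               "dup_frac": 0.0, "dup_unit": 300},
    "density": {"n_sites": 10, "enrichment": 8.0, "bump_width": 400},
    "track": {"window": 1000},
    "simulate": {"n_fragments": 5000, "read_length": 101,
                 "quality": {"q_start": 38.0, "q_slope": 0.06,
                             "q_noise_sd": 2.0}},
    "designs": [
        {"mode": "PE", "read_length": 36},
        {"mode": "SE", "read_length": 36},
    ],
    "align": {"report": "unique", "insert_min": 100, "insert_max": 700},
}


def _validate_config(config: dict) -> dict:
    cfg = {k: v for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if key not in CONFIG_KEYS:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            base = dict(cfg[key])
            for sub, sval in value.items():
                if sub not in base:
                    raise ValueError(f"unknown config key: {key}.{sub}")
                base[sub] = sval
            cfg[key] = base
        else:
            cfg[key] = value
    return cfg


def run_experiment(config: dict, outdir) -> pd.DataFrame:
    """Run replicates x designs and write FASTQ, tables and a summary TSV."""
    cfg = _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    gcfg, dcfg, tcfg, scfg = (
        cfg["genome"], cfg["density"], cfg["track"], cfg["simulate"],
    )
    genome = generate_genome(
        length=gcfg["length"], n_snps=gcfg["n_snps"],
        indel_rate=gcfg["indel_rate"], seed=derive_seed(master, "genome"),
        dup_frac=gcfg["dup_frac"], dup_unit=gcfg["dup_unit"],
    )
    density = build_density(
        genome, n_sites=dcfg["n_sites"], enrichment=dcfg["enrichment"],
        bump_width=dcfg["bump_width"], seed=derive_seed(master, "density"),
    )
    track = assign_maternal_probs(
        genome, window=tcfg["window"], seed=derive_seed(master, "track")
    )
    cio.write_genome_fasta(genome, outdir / "genome")
    cio.write_variants(outdir / "variants.tsv", genome.variants)
    if genome.repeats.intervals:
        cio.write_repeats_bed(outdir / "repeats.bed", genome.repeats,
                              chrom=genome.chrom)

    quality = QualityModel.parametric(**scfg["quality"])
    base_rl = scfg["read_length"]
    acfg = cfg["align"]
    summary_rows = []
    outputs = []
    for rep in range(1, int(cfg["replicates"]) + 1):
        pairs, truth = simulate_reads(
            genome, density, track, quality,
            n_fragments=scfg["n_fragments"], read_length=base_rl,
            seed=derive_seed(master, "simulate", rep),
        )
        r1 = outdir / f"rep{rep}_R1.fastq"
        r2 = outdir / f"rep{rep}_R2.fastq"
        cio.write_fastq_pair(pairs, r1, r2)
        cio.write_truth(outdir / f"rep{rep}_truth.tsv", truth)
        outputs += [r1, r2, outdir / f"rep{rep}_truth.tsv"]
        mean_fraglen = int(round(truth["length"].mean()))
        for dsg in cfg["designs"]:
            mode, rl = dsg["mode"], dsg["read_length"]
            half = bool(dsg.get("half", False))
            label = design_label(mode, rl, half)
            dseed = derive_seed(master, "design", rep, label)
            mode, data = make_design(pairs, mode, rl, half=half, seed=dseed)
            max_mm = dsg.get("max_mismatch", default_max_mismatch(rl))
            frags, n_aligned, n_total = align_to_reference(
                data, mode, genome.ref_seq, max_mm,
                fragment_length=mean_fraglen, report=acfg["report"],
                insert_min=acfg["insert_min"], insert_max=acfg["insert_max"],
                seed=dseed,
            )
            rate = am.alignment_rate(n_aligned, n_total)
            acc = (
                am.accuracy_vs_truth(frags, truth) if len(frags) else float("nan")
            )
            mcov = am.multi_coverage(frags, len(genome))
            asb_res = asb_pipeline(
                data, mode, genome, track, max_mismatch=max_mm, seed=dseed
            )
            frag_path = outdir / f"rep{rep}_{label}_fragments.tsv"
            cio.write_tsv(frag_path, frags)
            counts_path = outdir / f"rep{rep}_{label}_allele_counts.tsv"
            cio.write_tsv(counts_path, asb_res["counts"])
            outputs += [frag_path, counts_path]
            summary_rows.append(
                {
                    "replicate": rep,
                    "design": label,
                    "mode": mode,
                    "read_length": rl,
                    "n_reads": n_total,
                    "alignment_rate": rate,
                    "accuracy": acc,
                    "multi_coverage": mcov,
                    "n_tested_snps": len(asb_res["counts"]),
                    "asb_cutoff": asb_res["cutoff"],
                    "n_asb": len(asb_res["called"]),
                    "roc_auc": asb_res["auc"],
                }
            )
    summary = pd.DataFrame(summary_rows)
    cio.write_tsv(outdir / "summary.tsv", summary)
    outputs.append(outdir / "summary.tsv")
    cio.write_manifest(outdir / "manifest.json", cfg, outputs)
    return summary
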