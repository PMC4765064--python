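"""Plain-text readers/writers for the formats the pipeline exchanges.

FASTA/FASTQ via Biopython, BED-like interval tables and TSV tables via
pandas.  Everything is uncompressed text; alignment tables produced by
external aligners can be imported as long as they follow the same TSV schema.
Writers emit a canonical form that round-trips byte-exactly through the
matching reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignedRead
from .simulate import ReadPair, TRUTH_COLUMNS
from .transform import SingleRead
from .genome import PhasedVariant, RepeatAnnotation

ALIGN_COLUMNS = [
    "read_id", "target", "start", "end", "strand", "n_mismatch", "unique",
    "mate",
]


# -- FASTA ---------------------------------------------------------------


def write_fasta(path, records):
    """Write (name, seq) pairs as 60-column wrapped FASTA."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path):
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_genome_fasta(genome, prefix):
    """ref/maternal/paternal FASTA files under a common prefix."""
    prefix = Path(prefix)
    write_fasta(prefix.with_suffix(".ref.fa"), [(genome.chrom, genome.ref_seq)])
    write_fasta(
        prefix.with_suffix(".maternal.fa"),
        [(genome.chrom, genome.maternal_seq)],
    )
    write_fasta(
        prefix.with_suffix(".paternal.fa"),
        [(genome.chrom, genome.paternal_seq)],
    )


# -- FASTQ ---------------------------------------------------------------


def write_fastq(path, reads):
    """Write SingleRead records (Phred+33)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path):
    reads = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(SingleRead(rec.id, str(rec.seq), qual))
    return reads


def write_fastq_pair(pairs, path_r1, path_r2):
    """Write mate files with matching IDs encoding the fragment id."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.fragment_id}\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            f2.write(f"@{p.fragment_id}\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")


def read_fastq_pair(path_r1, path_r2):
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise ValueError("mate files have different read counts")
    offenders = [
        (a.read_id, b.read_id) for a, b in zip(r1, r2) if a.read_id != b.read_id
    ]
    if offenders:
        raise ValueError(f"unpaired read IDs: {offenders[:5]}")
    return [
        ReadPair(a.read_id, a.seq, a.qual, b.seq, b.qual)
        for a, b in zip(r1, r2)
    ]


# -- BED / TSV tables ----------------------------------------------------


def write_bed(path, intervals, chrom="chrS"):
    """Write (start, end[, name]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end = iv[0], iv[1]
            if end <= start:
                raise ValueError(f"zero/negative-length interval [{start}, {end})")
            name = iv[2] if len(iv) > 2 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: zero/negative-length interval"
                )
            name = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_repeats_bed(path, repeats: RepeatAnnotation, chrom="chrS"):
    write_bed(path, [(s, e, c) for s, e, c in repeats.intervals], chrom=chrom)


def read_repeats_bed(path) -> RepeatAnnotation:
    df = read_bed(path)
    return RepeatAnnotation(
        tuple((int(r.start), int(r.end), r.name) for r in df.itertuples())
    )


def write_tsv(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(path, truth: pd.DataFrame):
    write_tsv(path, truth[TRUTH_COLUMNS])


def read_truth(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns {sorted(missing)}")
    return df


def write_variants(path, variants):
    rows = [
        (v.pos, v.ref_allele, v.maternal_allele, v.paternal_allele)
        for v in variants
    ]
    write_tsv(path, pd.DataFrame(rows, columns=["pos", "ref", "mat", "pat"]))


def read_variants(path):
    df = read_tsv(path)
    return [
        PhasedVariant(int(r.pos), str(r.ref), str(r.mat), str(r.pat))
        for r in df.itertuples()
    ]


def write_alignments(path, alignments):
    """AlignedRead records as BED-like TSV (importable from external tools)."""
    rows = [
        (a.read_id, a.target, a.start, a.end, a.strand, a.n_mismatch,
         int(a.unique), a.mate_index)
        for a in alignments
    ]
    write_tsv(path, pd.DataFrame(rows, columns=ALIGN_COLUMNS))


def read_alignments(path):
    df = read_tsv(path)
    missing = set(ALIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns {sorted(missing)}")
    return [
        AlignedRead(str(r.read_id), str(r.target), int(r.start), int(r.end),
                    str(r.strand), int(r.n_mismatch), bool(r.unique),
                    int(r.mate))
        for r in df.itertuples()
    ]


# -- config / manifest ----------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(path, config: dict, files):
    """Record the exact config plus a checksum for every output file."""
    manifest = {
        "config": config,
        "files": {str(f): sha256_file(f) for f in files},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
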