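"""File I/O: FASTA, BED, Newick, VCF, and MSMC-style rate tables."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord
import dendropy

from ._trees import Node, from_dendropy
from .genome_windows import ConsensusGenome, MaskTrack
from .msc_sim import BASES, DiploidGenotypes
from .diversity_demog import RateCurve


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(records)


def read_genome(path, sample: Optional[str] = None) -> ConsensusGenome:
    seqs = read_fasta(path)
    name = sample if sample is not None else str(path)
    return ConsensusGenome(name, seqs)


def write_genome(g: ConsensusGenome, path, wrap: int = 80) -> None:
    write_fasta(g.chromosomes, path, wrap=wrap)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> MaskTrack:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start), int(end)))
    return MaskTrack(intervals)


def write_bed(track: MaskTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for s, e in track.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Newick


def read_trees(path) -> list[Node]:
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    return [from_dendropy(t) for t in trees]


def write_trees(trees: Sequence, path) -> None:
    from ._trees import as_node

    with open(path, "w") as fh:
        for t in trees:
            fh.write(as_node(t).newick() + "\n")


# ---------------------------------------------------------------------------
# VCF (single-sample diploid genotypes; plain text, GT field only)


def write_vcf(g: DiploidGenotypes, path) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={g.chrom},length={g.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{g.sample}\n")
        for pos in range(g.length):
            call = int(g.genotypes[pos]) if g.callable_mask[pos] else -1
            if call == 0:
                continue  # emit variant and missing sites only
            fh.write(f"{g.chrom}\t{pos + 1}\t.\t{BASES[g.ref[pos]]}\t"
                     f"{BASES[g.alt[pos]]}\t.\tPASS\t.\tGT\t{gt_str[call]}\n")


def read_vcf(path, length: int, sample: Optional[str] = None,
             chrom: str = "chr1") -> DiploidGenotypes:
    """Read a single-sample VCF written by :func:`write_vcf`.

    Sites absent from the file are hom-ref; ``length`` fixes the
    coordinate axis.
    """
    genotypes = np.zeros(length, dtype=np.int8)
    callable_mask = np.ones(length, dtype=bool)
    ref = np.zeros(length, dtype=np.uint8)
    alt = np.ones(length, dtype=np.uint8)
    name = sample or "sample1"
    code = {b: i for i, b in enumerate(BASES)}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                name = line.rstrip("\n").split("\t")[9]
                continue
            parts = line.rstrip("\n").split("\t")
            pos = int(parts[1]) - 1
            ref[pos] = code.get(parts[3], 0)
            alt[pos] = code.get(parts[4], 1)
            gt = parts[9].split(":")[0].replace("|", "/")
            if gt in ("./.", "."):
                genotypes[pos] = -1
                callable_mask[pos] = False
            elif gt == "0/1" or gt == "1/0":
                genotypes[pos] = 1
            elif gt == "1/1":
                genotypes[pos] = 2
    return DiploidGenotypes(name, genotypes, callable_mask, ref, alt, chrom)


# ---------------------------------------------------------------------------
# MSMC-style rate tables


def read_rate_curve(path, rate_column: str = "lambda",
                    label: str = "") -> RateCurve:
    """Read an MSMC-style TSV (left_time_boundary, right_time_boundary, lambda)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    left = df[cols["left_time_boundary"]].to_numpy(float)
    right = df[cols["right_time_boundary"]].to_numpy(float)
    lam = df[cols.get(rate_column, rate_column)].to_numpy(float)
    return RateCurve(left, right, lam, label=label or str(path))


def write_rate_curve(r: RateCurve, path) -> None:
    pd.DataFrame({"left_time_boundary": r.left,
                  "right_time_boundary": r.right,
                  "lambda": r.rate}).to_csv(path, sep="\t", index=False)
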