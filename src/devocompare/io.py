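"""File I/O: FASTA/FASTQ (via Biopython), GFF3, BED, bedGraph and TSV tables."""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import Exon, Gene, Genome

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq_sequences",
    "write_gff3",
    "read_gff3",
    "read_bed_mask",
    "write_bedgraph",
    "write_tsv",
    "read_tsv",
]


def write_fasta(chroms: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (read_id, sequence) pairs with dummy qualities."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq_sequences(path: str | os.PathLike) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_gff3(genome: Genome, path: str | os.PathLike) -> None:
    """GFF3 with gene + exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\tdevocompare\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tdevocompare\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Parse the gene/exon GFF3 layout written by :func:`write_gff3`."""
    exons_by_gene: dict[str, list[tuple[int, Exon]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                meta[attr["ID"]] = (chrom, strand)
            elif ftype == "exon":
                parent = attr["Parent"]
                order = len(exons_by_gene.setdefault(parent, []))
                exons_by_gene[parent].append(
                    (order, Exon(int(start) - 1, int(end)))
                )
    genes = []
    for gene_id, (chrom, strand) in meta.items():
        exons = [e for _, e in sorted(exons_by_gene.get(gene_id, []))]
        genes.append(Gene(gene_id, chrom, exons, strand))
    return genes


def read_bed_mask(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """BED intervals (0-based half-open) to exclude from mapping/mapability."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            mask.setdefault(chrom, []).append((int(start), int(end)))
    return mask


def write_bedgraph(
    tracks: dict[str, np.ndarray], path: str | os.PathLike, name: str = "mapability"
) -> None:
    """Run-length-encoded bedGraph of per-nucleotide 0/1 values."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, values in tracks.items():
            v = np.asarray(values).astype(int)
            if v.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [v.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]}\n")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
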