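"""K-mer mapability, effective gene lengths, splice-junction library, toy mapper.

A nucleotide is *mapable* when the k-mer (default k=35, one read length)
starting at it occurs at exactly one location in the genome; the effective
length of a gene is the count of mapable nucleotides in its exonic span and is
the per-gene denominator of the abundance scaling. The toy mapper reproduces
the multi-step expanded-genome strategy at desk scale: exact unique matching
against chromosomes, then against a splice-junction library, then iterative
3'-trimming of unmatched reads down to a minimum length.

All matching here is exact; the trimming loop supplies error tolerance.
Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Gene, Genome
from .errors import MissingDataError

logger = logging.getLogger(__name__)

__all__ = [
    "MapabilityTrack",
    "EffectiveLengths",
    "JunctionEntry",
    "compute_mapability",
    "effective_lengths",
    "build_junction_library",
    "map_reads_multistep",
    "MapResult",
]

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class MapabilityTrack:
    """Per-chromosome boolean vectors: True where the k-mer at that position is unique."""

    k: int
    strand_mode: str
    tracks: dict[str, np.ndarray]


@dataclass
class EffectiveLengths:
    per_gene: pd.Series  # l_i, indexed by gene_id
    median: float        # L, dataset constant

    def mapable_fraction(self, exonic_lengths: pd.Series) -> pd.Series:
        return self.per_gene / exonic_lengths


@dataclass(frozen=True)
class JunctionEntry:
    gene_id: str
    junction_index: int  # 0-based index of the (exon_i, exon_{i+1}) pair
    sequence: str
    flank_up: int        # bases of the entry that come from the upstream exon


def _valid_windows(
    seq: str, k: int, mask: list[tuple[int, int]] | None
) -> np.ndarray:
    """Boolean per position: window [p, p+k) is all-ACGT, unmasked, in bounds."""
    n = len(seq)
    ok = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    acgt = (ok == 65) | (ok == 67) | (ok == 71) | (ok == 84)
    if not acgt.all():
        logger.warning("non-ACGT characters present; affected windows are unmapable")
    if mask:
        for s, e in mask:
            acgt[max(s, 0) : min(e, n)] = False
    if n < k:
        return np.zeros(n, dtype=bool)
    # window valid iff all k positions valid
    c = np.concatenate([[0], np.cumsum(acgt.astype(np.int64))])
    valid = np.zeros(n, dtype=bool)
    valid[: n - k + 1] = (c[k:] - c[: n - k + 1]) == k
    return valid


def compute_mapability(
    genome: Genome | dict[str, str],
    k: int = 35,
    strand_mode: str = "both_strands",
    mask: dict[str, list[tuple[int, int]]] | None = None,
) -> MapabilityTrack:
    """Exact-uniqueness mapability of every genomic position.

    In ``both_strands`` mode a k-mer is ambiguous if it or its reverse
    complement occurs anywhere else in the genome; ``forward_only`` considers
    forward occurrences only. Positions within k-1 of a chromosome's 3' end
    are unmapable by convention, as are windows containing non-ACGT characters
    or masked intervals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strand_mode not in ("forward_only", "both_strands"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    chroms = genome.chroms if isinstance(genome, Genome) else genome
    if not chroms or all(len(s) == 0 for s in chroms.values()):
        raise ValueError("genome is empty")
    mask = mask or {}

    validity = {name: _valid_windows(seq, k, mask.get(name)) for name, seq in chroms.items()}
    counts: Counter[str] = Counter()
    for name, seq in chroms.items():
        valid = validity[name]
        counts.update(seq[p : p + k] for p in np.flatnonzero(valid))

    tracks = {}
    for name, seq in chroms.items():
        valid = validity[name]
        track = np.zeros(len(seq), dtype=bool)
        for p in np.flatnonzero(valid):
            w = seq[p : p + k]
            occ = counts[w]
            if strand_mode == "both_strands":
                rc = revcomp(w)
                if rc != w:
                    occ += counts[rc]
            track[p] = occ == 1
        tracks[name] = track
    return MapabilityTrack(k=k, strand_mode=strand_mode, tracks=tracks)


def effective_lengths(track: MapabilityTrack, genes: list[Gene]) -> EffectiveLengths:
    """Per-gene count of mapable exonic nucleotides and their median L."""
    values = {}
    for g in genes:
        if g.chrom not in track.tracks:
            raise MissingDataError(
                f"gene {g.gene_id!r} lies on chromosome {g.chrom!r} absent from the track"
            )
        t = track.tracks[g.chrom]
        if g.end > t.size:
            raise MissingDataError(f"gene {g.gene_id!r} extends past chromosome {g.chrom!r}")
        values[g.gene_id] = int(sum(t[e.start : e.end].sum() for e in g.exons))
    per_gene = pd.Series(values, name="effective_length")
    median = float(np.median(per_gene.to_numpy())) if len(per_gene) else 0.0
    return EffectiveLengths(per_gene=per_gene, median=median)


def build_junction_library(
    genome: Genome,
    read_length: int = 35,
    include_skipping: bool = False,
) -> list[JunctionEntry]:
    """Splice-junction sequences: read_length-1 bases of flank on each side.

    One entry per annotated adjacent exon pair; ``include_skipping`` adds
    non-adjacent (exon-skipping) pairs as well. Flanks are truncated at exon
    boundaries, so an entry is at most 2*(read_length-1) bases.
    """
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    flank = read_length - 1
    entries = []
    for g in genome.genes:
        seq = genome.chroms[g.chrom]
        pairs = (
            [(i, j) for i in range(len(g.exons)) for j in range(i + 1, len(g.exons))]
            if include_skipping
            else [(i, i + 1) for i in range(len(g.exons) - 1)]
        )
        for idx, (i, j) in enumerate(pairs):
            e1, e2 = g.exons[i], g.exons[j]
            up = seq[max(e1.end - flank, e1.start) : e1.end]
            down = seq[e2.start : min(e2.start + flank, e2.end)]
            entries.append(
                JunctionEntry(
                    gene_id=g.gene_id,
                    junction_index=idx,
                    sequence=up + down,
                    flank_up=len(up),
                )
            )
    return entries


@dataclass
class MapResult:
    gene_counts: pd.Series  # unique reads per gene
    intergenic: int         # unique genomic matches outside any exonic span
    unmapped: int

    @property
    def total(self) -> int:
        return int(self.gene_counts.sum()) + self.intergenic + self.unmapped


_AMBIGUOUS = ("__ambiguous__", -1)


class _ExpandedGenomeIndex:
    """Lazily built exact-match dictionaries per query length."""

    def __init__(self, genome: Genome, junctions: list[JunctionEntry]):
        self.genome = genome
        self.junctions = junctions
        self._genomic: dict[int, dict[str, tuple[str, int]]] = {}
        self._junction: dict[int, dict[str, str]] = {}
        # exonic ownership: gene index per position, -1 elsewhere
        self.owner = {
            name: np.full(len(seq), -1, dtype=np.int32)
            for name, seq in genome.chroms.items()
        }
        self.gene_ids = [g.gene_id for g in genome.genes]
        for gi, g in enumerate(genome.genes):
            for e in g.exons:
                self.owner[g.chrom][e.start : e.end] = gi

    def genomic(self, length: int) -> dict[str, tuple[str, int]]:
        if length not in self._genomic:
            index: dict[str, tuple[str, int]] = {}
            for name, seq in self.genome.chroms.items():
                for p in range(len(seq) - length + 1):
                    w = seq[p : p + length]
                    index[w] = _AMBIGUOUS if w in index else (name, p)
            self._genomic[length] = index
        return self._genomic[length]

    def junction(self, length: int) -> dict[str, str]:
        """Boundary-spanning substrings of junction entries -> gene id."""
        if length not in self._junction:
            index: dict[str, str] = {}
            for ent in self.junctions:
                seq = ent.sequence
                lo = max(0, ent.flank_up - length + 1)
                hi = min(ent.flank_up, len(seq) - length)
                for p in range(lo, hi + 1):
                    w = seq[p : p + length]
                    if w in index and index[w] != ent.gene_id:
                        index[w] = _AMBIGUOUS[0]
                    elif w not in index:
                        index[w] = ent.gene_id
            self._junction[length] = index
        return self._junction[length]


def map_reads_multistep(
    reads: list[str],
    genome: Genome,
    junctions: list[JunctionEntry],
    min_length: int = 25,
    trim_step: int = 2,
) -> MapResult:
    """Map reads by exact unique matching with iterative 3'-trimming.

    Stage order per length: (1) unique match to the chromosomes — counted for
    gene i when the whole alignment lies within gene i's exonic span, otherwise
    intergenic; (2) unique gene via boundary-spanning junction-library match;
    then the read is trimmed by ``trim_step`` from the 3' end and both stages
    retried while its length stays >= ``min_length``. Reads with zero or
    multiple best matches at every stage are reported unmapped.
    """
    index = _ExpandedGenomeIndex(genome, junctions)
    counts = pd.Series(0, index=pd.Index(index.gene_ids, name="gene_id"), dtype=np.int64)
    intergenic = 0
    unmapped = 0
    for read in reads:
        read = read.upper()
        assigned = False
        seq = read
        while len(seq) >= min_length:
            hit = index.genomic(len(seq)).get(seq)
            if hit is not None and hit != _AMBIGUOUS:
                chrom, p = hit
                own = index.owner[chrom][p : p + len(seq)]
                gi = own[0]
                if gi >= 0 and (own == gi).all():
                    counts.iloc[gi] += 1
                else:
                    intergenic += 1
                assigned = True
                break
            jhit = index.junction(len(seq)).get(seq)
            if jhit is not None and jhit != _AMBIGUOUS[0]:
                counts.loc[jhit] += 1
                assigned = True
                break
            seq = seq[: len(seq) - trim_step]
        if not assigned:
            unmapped += 1
    return MapResult(gene_counts=counts, intergenic=intergenic, unmapped=unmapped)
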