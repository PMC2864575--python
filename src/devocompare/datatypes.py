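"""Shared containers: genomes, gene models, sample naming.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based inclusive convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingDataError

__all__ = [
    "Exon",
    "Gene",
    "Genome",
    "sample_name",
    "parse_sample_name",
]


@dataclass(frozen=True)
class Exon:
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty exon [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    """A gene model: ordered exons on one chromosome, forward strand."""

    gene_id: str
    chrom: str
    exons: list[Exon]
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exonic_positions(self) -> np.ndarray:
        """All genomic positions covered by exons, ascending."""
        return np.concatenate([np.arange(e.start, e.end) for e in self.exons])

    def transcript_sequence(self, chrom_seq: str) -> str:
        """Mature (spliced) transcript sequence."""
        return "".join(chrom_seq[e.start:e.end] for e in self.exons)


@dataclass
class Genome:
    """A named set of chromosome sequences plus gene models."""

    name: str
    chroms: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise MissingDataError(f"gene {gene_id!r} not found in genome {self.name!r}")

    def check_gene_bounds(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chroms:
                raise MissingDataError(
                    f"gene {g.gene_id!r} lies on missing chromosome {g.chrom!r}"
                )
            if g.end > len(self.chroms[g.chrom]):
                raise MissingDataError(
                    f"gene {g.gene_id!r} extends past the end of {g.chrom!r}"
                )


def sample_name(species: str, hours: int, replicate: int) -> str:
    """Canonical count-matrix column name, e.g. ``DD_T08_R2``."""
    return f"{species}_T{hours:02d}_R{replicate}"


def parse_sample_name(name: str) -> tuple[str, int, int]:
    """Invert :func:`sample_name`; returns (species, hours, replicate)."""
    species, t, r = name.rsplit("_", 2)
    if not (t.startswith("T") and r.startswith("R")):
        raise ValueError(f"malformed sample name {name!r}")
    return species, int(t[1:]), int(r[1:])
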