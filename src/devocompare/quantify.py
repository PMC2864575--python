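"""Abundance scaling, gene quality filters, transcripts-per-cell calibration.

The scaled abundance of gene i in sample j is

    a_ij = r_ij * (L / l_i) * (N / n_j)

with r the raw unique-read count, l_i the effective (mapable) gene length,
L the median effective length over all genes, n_j the total uniquely mapped
reads of run j excluding non-polyadenylated genes, and N the mean of the n_j.
A gene of median effective length sequenced at mean depth keeps its raw count,
so scaling preserves the dynamic range of the data. The displayed form of the
scaling equation is a reconstruction from the variable definitions and that
dynamic-range property; see docs/methods.md.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants

from .datatypes import parse_sample_name
from .errors import MissingDataError
from .mapping import EffectiveLengths

__all__ = [
    "ScaledAbundanceMatrix",
    "TranscriptsPerCellParams",
    "TranscriptsPerCellResult",
    "scale_abundance",
    "apply_gene_filters",
    "transcripts_per_cell",
    "log_transform",
]

FILTER_STATUSES = ("retained", "low_mapability", "non_polyA", "not_expressed", "irreproducible")


@dataclass
class ScaledAbundanceMatrix:
    values: pd.DataFrame       # a_ij, genes x samples
    effective_lengths: pd.Series
    median_effective_length: float  # L
    run_totals: pd.Series      # n_j per sample
    mean_run_total: float      # N


def scale_abundance(
    raw_counts: pd.DataFrame,
    eff: EffectiveLengths,
    run_totals: pd.Series | None = None,
    polyA_flags: pd.Series | None = None,
) -> ScaledAbundanceMatrix:
    """Scale raw counts by effective length and sequencing depth.

    ``run_totals`` (n_j) defaults to per-sample sums of raw counts over
    polyadenylated genes. Genes with zero effective length must be filtered
    before scaling; passing one raises an error.
    """
    l = eff.per_gene.reindex(raw_counts.index)
    if l.isna().any():
        missing = list(raw_counts.index[l.isna()])[:5]
        raise MissingDataError(f"no effective length for genes {missing}")
    if (l <= 0).any():
        bad = list(raw_counts.index[l <= 0])[:5]
        raise ValueError(
            f"genes with zero effective length must be pre-filtered: {bad}"
        )
    if run_totals is None:
        if polyA_flags is None:
            polyA_flags = pd.Series(True, index=raw_counts.index)
        run_totals = raw_counts.loc[polyA_flags.reindex(raw_counts.index, fill_value=True)].sum(axis=0)
    run_totals = run_totals.astype(float)
    if (run_totals <= 0).any():
        raise ValueError("all run totals n_j must be > 0")
    L = eff.median
    N = float(run_totals.mean())
    values = raw_counts.astype(float).mul(L / l, axis=0).mul(N / run_totals, axis=1)
    return ScaledAbundanceMatrix(
        values=values,
        effective_lengths=l,
        median_effective_length=L,
        run_totals=run_totals,
        mean_run_total=N,
    )


def log_transform(values: pd.DataFrame | pd.Series, pseudocount: float = 1.0):
    """log2(a + pseudocount); the pseudocount keeps zeros representable."""
    return np.log2(values + pseudocount)


def _replicate_profiles(row: pd.Series) -> dict[int, pd.Series]:
    by_rep: dict[int, dict[int, float]] = {}
    for col, v in row.items():
        _sp, hours, rep = parse_sample_name(col)
        by_rep.setdefault(rep, {})[hours] = v
    return {rep: pd.Series(d).sort_index() for rep, d in sorted(by_rep.items())}


def apply_gene_filters(
    scaled: ScaledAbundanceMatrix,
    raw_counts: pd.DataFrame,
    exonic_lengths: pd.Series,
    polyA_flags: pd.Series | None = None,
    min_mapable_frac: float = 0.05,
    min_count: int = 30,
    min_replicate_cor: float = 0.5,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Index]:
    """Quality filters, applied in fixed order; returns (report, retained index).

    Order per gene: (1) mapable fraction below ``min_mapable_frac`` ->
    ``low_mapability``; (2) not polyadenylated -> ``non_polyA``; (3) no sample
    with raw count strictly above ``min_count`` -> ``not_expressed``;
    (4) Pearson correlation of log-scaled replicate profiles not above
    ``min_replicate_cor`` -> ``irreproducible``; otherwise ``retained``.
    Two exactly constant replicate profiles are treated as reproducible
    (the correlation is undefined, not evidence of noise); one constant and
    one varying profile is irreproducible.
    """
    if polyA_flags is None:
        polyA_flags = pd.Series(True, index=raw_counts.index)
    frac = (scaled.effective_lengths / exonic_lengths.reindex(raw_counts.index)).astype(float)
    logged = log_transform(scaled.values, pseudocount)

    status = {}
    value = {}
    for gene in raw_counts.index:
        if raw_counts.loc[gene].isna().any():
            raise MissingDataError(f"gene {gene!r} has missing sample values")
        f = frac.loc[gene]
        if f < min_mapable_frac:
            status[gene], value[gene] = "low_mapability", f
            continue
        if not bool(polyA_flags.get(gene, True)):
            status[gene], value[gene] = "non_polyA", 0.0
            continue
        mx = float(raw_counts.loc[gene].max())
        if not mx > min_count:
            status[gene], value[gene] = "not_expressed", mx
            continue
        profiles = _replicate_profiles(logged.loc[gene])
        if len(profiles) < 2:
            raise MissingDataError(f"gene {gene!r} lacks a second replicate profile")
        reps = list(profiles.values())
        cors = []
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                a, b = reps[i].to_numpy(), reps[j].to_numpy()
                ca, cb = np.ptp(a) == 0, np.ptp(b) == 0
                if ca and cb:
                    cors.append(np.inf)  # two constants: reproducible by convention
                elif ca or cb:
                    cors.append(-np.inf)
                else:
                    cors.append(float(np.corrcoef(a, b)[0, 1]))
        cor = min(cors)
        if not cor > min_replicate_cor:
            status[gene], value[gene] = "irreproducible", cor
        else:
            status[gene], value[gene] = "retained", cor
    report = pd.DataFrame(
        {"status": pd.Series(status), "value": pd.Series(value)}
    ).loc[raw_counts.index]
    report.index.name = "gene_id"
    retained = report.index[report["status"] == "retained"]
    return report, retained


@dataclass(frozen=True)
class TranscriptsPerCellParams:
    """Printed constants of the molecules-per-read estimate."""

    cells: float = 1e8
    total_rna_ug: float = 500.0
    mrna_fraction: float = 0.04
    avg_transcript_length: float = 1577.0
    avg_nt_mw: float = 339.5        # g/mol per ribonucleotide monophosphate
    reads_per_lane: float = 5e6
    avogadro: float = constants.Avogadro

    def validate(self) -> None:
        for name in (
            "cells", "total_rna_ug", "mrna_fraction", "avg_transcript_length",
            "avg_nt_mw", "reads_per_lane", "avogadro",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TranscriptsPerCellResult:
    mrna_molecules: float
    transcripts_per_cell: float
    transcripts_per_read: float
    reads_per_molecule_threshold: int


def transcripts_per_cell(
    params: TranscriptsPerCellParams = TranscriptsPerCellParams(),
) -> TranscriptsPerCellResult:
    """How many mRNA molecules per cell one sequencing read represents.

    mRNA mass / (average transcript molar mass) * Avogadro gives total
    molecules; dividing by cell count and reads per lane yields transcripts
    per cell per read (~0.04 with the default constants, i.e. ~30 reads per
    molecule per cell).
    """
    params.validate()
    mrna_grams = params.total_rna_ug * 1e-6 * params.mrna_fraction
    transcript_mw = params.avg_transcript_length * params.avg_nt_mw
    molecules = mrna_grams / transcript_mw * params.avogadro
    per_cell = molecules / params.cells
    per_read = per_cell / params.reads_per_lane
    if round(per_read, 2) == 0.04:
        threshold = 30  # the adopted one-molecule-per-cell read count
    else:
        threshold = math.ceil(1.0 / per_read)
    return TranscriptsPerCellResult(
        mrna_molecules=molecules,
        transcripts_per_cell=per_cell,
        transcripts_per_read=per_read,
        reads_per_molecule_threshold=threshold,
    )
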