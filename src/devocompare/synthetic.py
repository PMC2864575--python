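"""Synthetic two-species developmental RNA-seq generator with planted ground truth.

Emulates the study design this package analyses: two amoeba species sampled at
seven developmental time points (4-hour intervals, 0-24 h) in two biological
replicates, a one-to-one ortholog map covering more than half of each genome,
and slug-stage prespore/prestalk cell-type samples with a known-marker subset.

Planted structure
-----------------
* Regulation classes: monotone *up*, monotone *down*, single-peak *transient*
  and exactly flat *invariant* mean trajectories (log2 scale).
* A subset of ortholog pairs carries a +4 h developmental delay in species B,
  planted on transient (peaked) genes because a one-step shift of a monotone
  trajectory is statistically indistinguishable from no shift at T=7.
* Cell-type enrichment: 4-fold (|log2 FC| = 2) prespore or prestalk bias,
  shared between ortholog partners; markers are a subset of enriched ortholog
  genes in species A, transferred to B through the ortholog map.
* Non-ortholog genes are planted 2-fold less abundant than orthologs.
* Counts are negative binomial with variance mu + alpha*mu^2 (alpha = 0 is the
  Poisson limit); per-nucleotide cell-type coverage adds a shared positional
  sequence-bias factor and a monotone 3'-bias ramp.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import Exon, Gene, Genome, sample_name
from .errors import ConfigurationError, ConsistencyError

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "CellTypeCounts",
    "generate_toy_genomes",
    "simulate_timecourse_counts",
    "simulate_celltype_coverage",
    "simulate_nucleotide_coverage",
    "simulate_reads",
    "annotation_table",
]

#: Functional categories ordered from least to most abundant planted expression,
#: mirroring the rank ordering reported for broad GO-slim groups.
FUNCTIONAL_CATEGORIES = (
    "transcription",
    "catalytic_activity",
    "enzyme_regulator",
    "translation",
    "structural_molecule",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions emulated here."""

    n_genes_per_species: int = 2000
    ortholog_fraction: float = 0.60
    n_timepoints: int = 7
    timestep_hours: float = 4.0
    n_replicates: int = 2
    read_length: int = 35
    up_fraction: float = 0.40
    down_fraction: float = 0.22
    transient_fraction: float = 0.28
    invariant_fraction: float = 0.10
    shift_fraction: float = 0.08
    celltype_enriched_fraction: float = 0.20
    marker_fraction: float = 0.075
    nb_dispersion: float = 0.05
    library_size_per_sample: int = 1_000_000
    threeprime_bias_strength: float = 0.3
    positional_noise_sd: float = 1.0
    species_names: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes_per_species < 1:
            raise ConfigurationError("n_genes_per_species must be >= 1")
        for name in (
            "ortholog_fraction",
            "up_fraction",
            "down_fraction",
            "transient_fraction",
            "invariant_fraction",
            "shift_fraction",
            "celltype_enriched_fraction",
            "marker_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        class_sum = (
            self.up_fraction
            + self.down_fraction
            + self.transient_fraction
            + self.invariant_fraction
        )
        if abs(class_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"regulation class fractions must sum to 1 (up_fraction + down_fraction"
                f" + transient_fraction + invariant_fraction = {class_sum})"
            )
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.read_length < 25:
            raise ConfigurationError("read_length must be >= 25")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.library_size_per_sample < 1:
            raise ConfigurationError("library_size_per_sample must be >= 1")
        if self.threeprime_bias_strength < 0:
            raise ConfigurationError("threeprime_bias_strength must be >= 0")
        if self.positional_noise_sd < 0:
            raise ConfigurationError("positional_noise_sd must be >= 0")
        if self.timestep_hours <= 0:
            raise ConfigurationError("timestep_hours must be > 0")

    @property
    def timepoint_hours(self) -> list[int]:
        return [int(round(i * self.timestep_hours)) for i in range(self.n_timepoints)]


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per simulated gene, plus the ortholog view."""

    config: SimConfig
    genes: pd.DataFrame
    orthologs: pd.DataFrame
    expression: dict[str, pd.DataFrame]  # species -> genes x time, linear scale

    def genes_of(self, species: str) -> pd.DataFrame:
        return self.genes[self.genes["species"] == species]

    def check_against(self, config: SimConfig) -> None:
        if config != self.config:
            raise ConsistencyError(
                "SimConfig does not match the configuration this truth was generated with"
            )


@dataclass
class CellTypeCounts:
    """Slug-stage cell-type data: gene counts and optional per-nucleotide coverage."""

    counts: pd.DataFrame  # genes x (cell type, replicate) columns
    coverage: dict[str, np.ndarray] = field(default_factory=dict)  # gene -> (L, 4)
    markers: pd.Series | None = None  # marker cell type, indexed by marker gene id
    sample_columns: tuple[str, ...] = (
        "prespore_R1",
        "prespore_R2",
        "prestalk_R1",
        "prestalk_R2",
    )


def largest_remainder_counts(fractions: list[float], n: int) -> list[int]:
    """Integer class counts summing to n; remainders ranked, ties by list index."""
    raw = [f * n for f in fractions]
    counts = [math.floor(x) for x in raw]
    leftover = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _build_species_genome(
    rng: np.random.Generator, species: str, cfg: SimConfig
) -> Genome:
    genes: list[Gene] = []
    pos = int(rng.integers(100, 301))
    for i in range(cfg.n_genes_per_species):
        n_exons = int(rng.integers(1, 4))
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(40, 121, size=max(n_exons - 1, 0))
        exons = []
        p = pos
        for j, el in enumerate(exon_lens):
            exons.append(Exon(p, p + int(el)))
            p += int(el)
            if j < n_exons - 1:
                p += int(intron_lens[j])
        genes.append(Gene(f"{species}g{i:05d}", "chr1", exons))
        pos = p + int(rng.integers(100, 301))
    chrom = _random_sequence(rng, pos + 100)
    return Genome(name=species, chroms={"chr1": chrom}, genes=genes)


def _assign_classes(
    rng: np.random.Generator, cfg: SimConfig, n_orth: int
) -> tuple[list[str], list[str]]:
    """Per-species class labels; ortholog partners (the first n_orth) share labels."""
    fractions = [
        cfg.up_fraction,
        cfg.down_fraction,
        cfg.transient_fraction,
        cfg.invariant_fraction,
    ]
    names = ["up", "down", "transient", "invariant"]
    totals = largest_remainder_counts(fractions, cfg.n_genes_per_species)
    labels_a = np.repeat(names, totals)
    rng.shuffle(labels_a)
    labels_a = list(labels_a)
    # Species B: ortholog genes copy the partner's class, the rest top up the
    # per-class totals so both species match the configured fractions exactly.
    orth_counts = {c: labels_a[:n_orth].count(c) for c in names}
    rest = np.repeat(names, [totals[i] - orth_counts[names[i]] for i in range(4)])
    rng.shuffle(rest)
    labels_b = labels_a[:n_orth] + list(rest)
    return labels_a, labels_b


def _mean_trajectory(
    reg_class: str, base: float, fold: float, peak: int, n_t: int
) -> np.ndarray:
    t = np.arange(n_t, dtype=float)
    if reg_class == "up":
        traj = base + fold * t / (n_t - 1)
    elif reg_class == "down":
        traj = base + fold * (1.0 - t / (n_t - 1))
    elif reg_class == "transient":
        traj = np.full(n_t, base)
        traj[peak] += fold
    else:  # invariant: exactly flat
        traj = np.full(n_t, base)
    return traj


def generate_toy_genomes(
    config: SimConfig,
) -> tuple[dict[str, Genome], pd.DataFrame, SyntheticTruth]:
    """Generate both species' genomes, the ortholog table and the planted truth.

    Deterministic given ``config.seed``: the same configuration always yields
    byte-identical genomes, tables and trajectories.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species_names
    n = config.n_genes_per_species
    n_t = config.n_timepoints
    n_orth = int(round(config.ortholog_fraction * n))

    genomes = {
        sp_a: _build_species_genome(rng, sp_a, config),
        sp_b: _build_species_genome(rng, sp_b, config),
    }
    ids = {sp: [g.gene_id for g in genomes[sp].genes] for sp in (sp_a, sp_b)}

    labels_a, labels_b = _assign_classes(rng, config, n_orth)

    # Shared trajectory parameters; ortholog partners inherit species A's draw.
    base_a = rng.uniform(7.0, 11.0, size=n)
    fold_a = rng.uniform(2.0, 4.0, size=n)
    tfold_a = rng.uniform(2.5, 4.0, size=n)  # transient peak height (log2)
    peak_a = rng.integers(1, n_t - 2, size=n)  # interior, leaving room for +1 shift
    base_b = base_a.copy()
    fold_b = fold_a.copy()
    tfold_b = tfold_a.copy()
    peak_b = peak_a.copy()
    fresh = slice(n_orth, n)
    base_b[fresh] = rng.uniform(7.0, 11.0, size=n - n_orth)
    fold_b[fresh] = rng.uniform(2.0, 4.0, size=n - n_orth)
    tfold_b[fresh] = rng.uniform(2.5, 4.0, size=n - n_orth)
    peak_b[fresh] = rng.integers(1, n_t - 2, size=n - n_orth)
    # Non-orthologs are planted 2-fold less abundant in both species.
    base_a[fresh] -= 1.0
    base_b[fresh] -= 1.0

    # Planted +4 h delay in species B, drawn from transient ortholog pairs.
    n_shift = int(round(config.shift_fraction * n_orth))
    transient_orth = [i for i in range(n_orth) if labels_a[i] == "transient"]
    if n_shift > len(transient_orth):
        raise ConfigurationError(
            f"shift_fraction: {n_shift} planted shifts requested but only "
            f"{len(transient_orth)} transient ortholog pairs are available"
        )
    shift_idx = set(
        rng.choice(np.array(transient_orth, dtype=int), size=n_shift, replace=False).tolist()
        if n_shift
        else []
    )
    shift_hours = np.zeros(n)
    for i in shift_idx:
        peak_b[i] = peak_a[i] + 1
        shift_hours[i] = config.timestep_hours

    # Cell-type enrichment: ortholog pairs share status; markers live in A.
    n_ct = int(round(config.celltype_enriched_fraction * n))
    n_ct_pairs = min(int(round(config.celltype_enriched_fraction * n_orth)), n_orth)
    n_ct_single = n_ct - n_ct_pairs
    ct_pairs = rng.choice(n_orth, size=n_ct_pairs, replace=False) if n_ct_pairs else np.array([], int)
    singles_a = (
        rng.choice(np.arange(n_orth, n), size=n_ct_single, replace=False)
        if n_ct_single
        else np.array([], int)
    )
    singles_b = (
        rng.choice(np.arange(n_orth, n), size=n_ct_single, replace=False)
        if n_ct_single
        else np.array([], int)
    )
    celltype_a = np.array(["none"] * n, dtype=object)
    celltype_b = np.array(["none"] * n, dtype=object)
    pair_types = np.where(np.arange(n_ct_pairs) % 2 == 0, "prespore", "prestalk")
    celltype_a[ct_pairs] = pair_types
    celltype_b[ct_pairs] = pair_types
    single_types_a = np.where(np.arange(n_ct_single) % 2 == 0, "prespore", "prestalk")
    celltype_a[singles_a] = single_types_a
    celltype_b[singles_b] = np.where(
        np.arange(n_ct_single) % 2 == 0, "prestalk", "prespore"
    )
    # Planted cell-type enrichment is 4-fold (|log2 FC| = 2), comfortably
    # above the two-fold call rule.
    ct_fold_a = np.where(celltype_a != "none", 2.0, 0.0)
    ct_fold_b = np.where(celltype_b != "none", 2.0, 0.0)

    n_markers = int(round(config.marker_fraction * n_ct))
    if n_markers > n_ct_pairs:
        n_markers = n_ct_pairs
    marker_pairs = (
        rng.choice(ct_pairs, size=n_markers, replace=False) if n_markers else np.array([], int)
    )
    marker_a = np.zeros(n, dtype=bool)
    marker_b = np.zeros(n, dtype=bool)
    marker_a[marker_pairs] = True
    marker_b[marker_pairs] = True  # transferred through the ortholog map

    # Abundance-linked functional categories (rank-percentile demonstration).
    def _funcats(base: np.ndarray) -> np.ndarray:
        quint = np.searchsorted(np.quantile(base, [0.2, 0.4, 0.6, 0.8]), base)
        cats = np.array([FUNCTIONAL_CATEGORIES[q] for q in quint], dtype=object)
        randomize = rng.random(len(base)) > 0.7
        cats[randomize] = rng.choice(FUNCTIONAL_CATEGORIES, size=int(randomize.sum()))
        return cats

    funcat_a = _funcats(base_a)
    funcat_b = _funcats(base_b)

    def _species_frame(
        sp: str,
        labels: list[str],
        base: np.ndarray,
        fold: np.ndarray,
        tfold: np.ndarray,
        peak: np.ndarray,
        celltype: np.ndarray,
        ct_fold: np.ndarray,
        marker: np.ndarray,
        funcat: np.ndarray,
        partner_ids: list[str],
    ) -> pd.DataFrame:
        is_orth = np.arange(n) < n_orth
        return pd.DataFrame(
            {
                "species": sp,
                "reg_class": labels,
                "base_log2": base,
                "fold_log2": np.where(np.array(labels) == "transient", tfold, fold),
                "peak": np.where(np.array(labels) == "transient", peak, -1),
                "shift_hours": shift_hours * is_orth,
                "celltype": celltype,
                "celltype_fold_log2": ct_fold,
                "marker": marker,
                "polyA": True,
                "is_ortholog": is_orth,
                "partner": [partner_ids[i] if i < n_orth else "" for i in range(n)],
                "funcat": funcat,
            },
            index=pd.Index(ids[sp], name="gene_id"),
        )

    genes_df = pd.concat(
        [
            _species_frame(
                sp_a, labels_a, base_a, fold_a, tfold_a, peak_a, celltype_a,
                ct_fold_a, marker_a, funcat_a, ids[sp_b],
            ),
            _species_frame(
                sp_b, labels_b, base_b, fold_b, tfold_b, peak_b, celltype_b,
                ct_fold_b, marker_b, funcat_b, ids[sp_a],
            ),
        ]
    )

    corr_class = []
    for i in range(n_orth):
        if i in shift_idx:
            corr_class.append("shifted")
        elif labels_a[i] == "invariant":
            corr_class.append("flat")
        else:
            corr_class.append("high")
    orthologs = pd.DataFrame(
        {
            "gene_a": ids[sp_a][:n_orth],
            "gene_b": ids[sp_b][:n_orth],
            "shift_hours": [config.timestep_hours if i in shift_idx else 0.0 for i in range(n_orth)],
            "corr_class": corr_class,
        }
    )

    expression = {}
    for sp, labels, base, fold, tfold, peak in (
        (sp_a, labels_a, base_a, fold_a, tfold_a, peak_a),
        (sp_b, labels_b, base_b, fold_b, tfold_b, peak_b),
    ):
        rows = np.empty((n, n_t))
        for i in range(n):
            f = tfold[i] if labels[i] == "transient" else fold[i]
            rows[i] = _mean_trajectory(labels[i], base[i], f, int(peak[i]), n_t)
        linear = np.exp2(rows)
        # Trajectories are planted in relative-abundance (library-share) space:
        # sequencing measures shares, so the total length-weighted transcript
        # output is held constant over time by tilting the regulated classes;
        # invariant genes then stay exactly flat after depth normalization.
        lengths = np.array([g.exonic_length for g in genomes[sp].genes], dtype=float)
        regulated = np.array([c != "invariant" for c in labels])
        w = linear * lengths[:, None]
        s_inv = w[~regulated].sum(axis=0)
        s_reg = w[regulated].sum(axis=0)
        if regulated.any() and (s_reg > 0).all():
            target = np.exp(np.log(s_reg).mean())
            linear[regulated] *= target / s_reg
        del s_inv
        expression[sp] = pd.DataFrame(
            linear,
            index=pd.Index(ids[sp], name="gene_id"),
            columns=config.timepoint_hours,
        )

    truth = SyntheticTruth(
        config=replace(config), genes=genes_df, orthologs=orthologs, expression=expression
    )
    return genomes, orthologs, truth


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean=mu, var=mu+alpha*mu^2); alpha = 0 falls back to Poisson."""
    mu = np.clip(mu, 1e-12, None)
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_timecourse_counts(
    genomes: dict[str, Genome], truth: SyntheticTruth, config: SimConfig
) -> dict[str, pd.DataFrame]:
    """Per-species raw count matrices (gene x time x replicate).

    Expected counts follow the planted mean trajectory scaled by the gene's
    exonic length and the per-sample library size; noise is negative binomial
    at ``config.nb_dispersion``.
    """
    truth.check_against(config)
    out = {}
    for sp in config.species_names:
        rng = np.random.default_rng(_derive_seed(config.seed, f"timecourse:{sp}"))
        genome = genomes[sp]
        expr = truth.expression[sp]
        if list(expr.index) != [g.gene_id for g in genome.genes]:
            raise ConsistencyError(f"gene models and truth disagree for species {sp!r}")
        lengths = np.array([g.exonic_length for g in genome.genes], dtype=float)
        weights = expr.to_numpy() * lengths[:, None]
        mu = config.library_size_per_sample * weights / weights.sum(axis=0, keepdims=True)
        cols = {}
        for rep in range(1, config.n_replicates + 1):
            for j, hours in enumerate(config.timepoint_hours):
                cols[sample_name(sp, hours, rep)] = _draw_counts(
                    rng, mu[:, j], config.nb_dispersion
                )
        df = pd.DataFrame(cols, index=expr.index)
        out[sp] = df[sorted(df.columns)]
    return out


def simulate_celltype_coverage(
    genomes: dict[str, Genome],
    truth: SyntheticTruth,
    config: SimConfig,
    include_coverage: bool = True,
    sample_noise: bool = True,
) -> dict[str, CellTypeCounts]:
    """Slug-stage prespore/prestalk counts and per-nucleotide coverage.

    Coverage combines a per-gene positional sequence-bias factor (log2 sd
    ``config.positional_noise_sd``, shared across samples), a monotone 3'-bias
    ramp of total log2 span ``config.threeprime_bias_strength``, and Poisson
    sampling of integer per-nucleotide read counts. With ``sample_noise=False``
    the expected (float) coverage is returned instead, which is exactly flat
    when both bias parameters are zero.
    """
    truth.check_against(config)
    out = {}
    for sp in config.species_names:
        rng = np.random.default_rng(_derive_seed(config.seed, f"celltype:{sp}"))
        genome = genomes[sp]
        info = truth.genes_of(sp)
        mus = _celltype_expected_counts(genome, info, config)
        cols = {}
        for ct in ("prespore", "prestalk"):
            for rep in (1, 2):
                cols[f"{ct}_R{rep}"] = (
                    _draw_counts(rng, mus[ct], config.nb_dispersion)
                    if sample_noise
                    else mus[ct]
                )
        counts = pd.DataFrame(cols, index=info.index)
        counts = counts[["prespore_R1", "prespore_R2", "prestalk_R1", "prestalk_R2"]]

        coverage: dict[str, np.ndarray] = {}
        if include_coverage:
            coverage = simulate_nucleotide_coverage(
                genomes, truth, config, sp, sample_noise=sample_noise
            )

        markers = info.loc[info["marker"], "celltype"]
        out[sp] = CellTypeCounts(counts=counts, coverage=coverage, markers=markers)
    return out


def _celltype_expected_counts(
    genome: Genome, info: pd.DataFrame, config: SimConfig
) -> dict[str, np.ndarray]:
    """Expected per-gene counts in each slug cell type (library-normalized)."""
    lengths = np.array([g.exonic_length for g in genome.genes], dtype=float)
    base = info["base_log2"].to_numpy()
    delta = np.where(
        info["celltype"].to_numpy() == "prespore", 1.0,
        np.where(info["celltype"].to_numpy() == "prestalk", -1.0, 0.0),
    ) * (info["celltype_fold_log2"].to_numpy() / 2.0)
    expr = {"prespore": np.exp2(base + delta), "prestalk": np.exp2(base - delta)}
    mus = {}
    for ct in ("prespore", "prestalk"):
        w = expr[ct] * lengths
        mus[ct] = config.library_size_per_sample * w / w.sum()
    return mus


def simulate_nucleotide_coverage(
    genomes: dict[str, Genome],
    truth: SyntheticTruth,
    config: SimConfig,
    species: str,
    gene_ids: list[str] | None = None,
    sample_noise: bool = True,
) -> dict[str, np.ndarray]:
    """Per-nucleotide coverage for (a subset of) one species' genes.

    The random stream is derived per gene, so any subset reproduces exactly
    the values the full run would produce for those genes.
    """
    truth.check_against(config)
    genome = genomes[species]
    info = truth.genes_of(species)
    mus = _celltype_expected_counts(genome, info, config)
    wanted = set(gene_ids) if gene_ids is not None else None
    coverage: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(genome.genes):
        if wanted is not None and gene.gene_id not in wanted:
            continue
        rng = np.random.default_rng(
            _derive_seed(config.seed, f"coverage:{species}:{gene.gene_id}")
        )
        L = gene.exonic_length
        pos_bias = (
            rng.normal(0.0, config.positional_noise_sd, size=L)
            if config.positional_noise_sd > 0
            else np.zeros(L)
        )
        ramp = config.threeprime_bias_strength * (np.arange(L) / max(L - 1, 1) - 0.5)
        factor = np.exp2(pos_bias + ramp)
        factor /= factor.mean()
        lam = np.empty((L, 4))
        for s, ct in enumerate(("prespore", "prespore", "prestalk", "prestalk")):
            lam[:, s] = mus[ct][gi] / L * factor
        coverage[gene.gene_id] = rng.poisson(lam).astype(np.int32) if sample_noise else lam
    return coverage


def simulate_reads(
    genome: Genome,
    truth: SyntheticTruth,
    config: SimConfig,
    n_reads: int,
    timepoint_index: int = 0,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Toy FASTQ reads drawn uniformly along spliced transcripts.

    Per-gene read numbers are multinomial with weights proportional to the
    planted expression at ``timepoint_index``; junction-spanning reads arise
    naturally for multi-exon genes. Returns (records, per-gene origin counts).
    Genes whose mature transcript is shorter than the read length are skipped
    with a logged warning.
    """
    truth.check_against(config)
    sp = genome.name
    rng = np.random.default_rng(
        _derive_seed(config.seed if seed is None else seed, f"reads:{sp}:{timepoint_index}")
    )
    expr = truth.expression[sp].iloc[:, timepoint_index].to_numpy().astype(float).copy()
    transcripts = []
    for gi, gene in enumerate(genome.genes):
        seq = gene.transcript_sequence(genome.chroms[gene.chrom])
        if len(seq) < config.read_length and expr[gi] > 0:
            logger.warning(
                "gene %s transcript (%d nt) shorter than read length %d; skipped",
                gene.gene_id, len(seq), config.read_length,
            )
            expr[gi] = 0.0
        transcripts.append(seq)
    if expr.sum() <= 0:
        empty = pd.Series(0, index=truth.expression[sp].index, name="reads")
        return [], empty
    per_gene = rng.multinomial(n_reads, expr / expr.sum())
    records: list[tuple[str, str]] = []
    read_no = 0
    for gi, gene in enumerate(genome.genes):
        k = int(per_gene[gi])
        if k == 0:
            continue
        seq = transcripts[gi]
        starts = rng.integers(0, len(seq) - config.read_length + 1, size=k)
        for s in starts:
            records.append((f"read{read_no:07d}", seq[s : s + config.read_length]))
            read_no += 1
    origin = pd.Series(per_gene, index=truth.expression[sp].index, name="reads")
    return records, origin


def annotation_table(truth: SyntheticTruth, species: str) -> pd.DataFrame:
    """Toy GO-style two-column (gene_id, term) annotation for one species.

    Terms encode the planted structure: regulation class (``dev:*``),
    cell-type status (``ct:*``) and the abundance-linked functional category
    (``fc:*``), which makes enrichment results interpretable against truth.
    """
    info = truth.genes_of(species)
    rows = []
    for gene_id, row in info.iterrows():
        rows.append((gene_id, f"dev:{row['reg_class']}"))
        if row["celltype"] != "none":
            rows.append((gene_id, f"ct:{row['celltype']}"))
        rows.append((gene_id, f"fc:{row['funcat']}"))
    return pd.DataFrame(rows, columns=["gene_id", "term"])


def _derive_seed(seed: int, stage: str) -> int:
    import zlib

    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)
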