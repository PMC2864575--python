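"""End-to-end orchestration: simulate -> mapability -> quantify -> profiles ->
compare -> celltype -> enrich, with a machine-readable, seed-reproducible
run report.

Every stage writes its tabular outputs under the run directory; the report
aggregates per-stage summaries and is checked for internal consistency
(section counts sum to pair counts, filter statuses partition the gene set,
and so on) before being written. The two expensive stages (simulation and
mapability) can resume from their on-disk outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import Genome
from . import celltype as ct
from . import compare, enrich, io, mapping, profiles, quantify
from . import synthetic as syn
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Thresholds", "run_pipeline", "assert_report_consistent", "load_config"]


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """All analysis thresholds in one block; defaults are the study's values."""

    cor_threshold: float = 0.5          # up/down regulation and conservation sections
    fold_threshold: float = 2.0         # invariance and cell-type fold rule
    shift_threshold: float = 0.75       # temporal-shift gate and target correlation
    min_mapable_frac: float = 0.05
    min_count: int = 30                 # ~1 mRNA molecule per cell
    min_replicate_cor: float = 0.5
    pseudocount: float = 1.0
    min_length: int = 25                # mapper trimming floor
    trim_step: int = 2
    min_nucleotides: int = 50           # nucleotide DE method


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    sim: syn.SimConfig = dataclasses.field(default_factory=syn.SimConfig)
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)

    def to_dict(self) -> dict:
        d = {
            "sim": dataclasses.asdict(self.sim),
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        d["sim"]["species_names"] = list(self.sim.species_names)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | os.PathLike, seed: int | None = None) -> PipelineConfig:
    """Read a YAML config with optional ``sim:`` and ``thresholds:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = dict(raw.get("sim", {}))
    if "species_names" in sim_kwargs:
        sim_kwargs["species_names"] = tuple(sim_kwargs["species_names"])
    if seed is not None:
        sim_kwargs["seed"] = seed
    try:
        cfg = PipelineConfig(
            sim=syn.SimConfig(**sim_kwargs),
            thresholds=Thresholds(**raw.get("thresholds", {})),
        )
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg.sim.validate()
    return cfg


def _class_counts(series: pd.Series) -> dict[str, int]:
    return {str(k): int(v) for k, v in series.value_counts().sort_index().items()}


def run_pipeline(
    config: PipelineConfig, outdir: str | os.PathLike, resume: bool = False
) -> dict:
    """Execute every stage and return (and write) the run report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    th = config.thresholds
    sp_a, sp_b = cfg.species_names
    report: dict = {
        "provenance": {
            "package": "devocompare",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": config.hash(),
            "config": config.to_dict(),
        },
        "stages": {},
    }

    # ---- simulate -------------------------------------------------------
    sim_files = [out / f"counts_{sp}.tsv" for sp in cfg.species_names]
    genomes, orthologs, truth = syn.generate_toy_genomes(cfg)
    if resume and all(f.exists() for f in sim_files):
        logger.info("resuming: loading simulated counts from %s", out)
        counts = {sp: io.read_tsv(out / f"counts_{sp}.tsv") for sp in cfg.species_names}
        ct_data = syn.simulate_celltype_coverage(genomes, truth, cfg, include_coverage=False)
    else:
        counts = syn.simulate_timecourse_counts(genomes, truth, cfg)
        ct_data = syn.simulate_celltype_coverage(genomes, truth, cfg, include_coverage=False)
        for sp in cfg.species_names:
            io.write_fasta(genomes[sp].chroms, out / f"genome_{sp}.fasta")
            io.write_gff3(genomes[sp], out / f"genes_{sp}.gff3")
            io.write_tsv(counts[sp], out / f"counts_{sp}.tsv")
            io.write_tsv(ct_data[sp].counts, out / f"celltype_counts_{sp}.tsv")
        orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
        io.write_tsv(truth.genes, out / "truth_genes.tsv")
    report["stages"]["simulate"] = {
        "n_genes_per_species": cfg.n_genes_per_species,
        "n_ortholog_pairs": int(len(orthologs)),
        "planted_class_counts": _class_counts(truth.genes_of(sp_a)["reg_class"]),
        "planted_shifted_pairs": int((orthologs["shift_hours"] != 0).sum()),
        "n_markers": int(truth.genes_of(sp_a)["marker"].sum()),
    }

    # ---- mapability -----------------------------------------------------
    eff: dict[str, mapping.EffectiveLengths] = {}
    stage_map: dict = {}
    for sp in cfg.species_names:
        eff_path = out / f"effective_lengths_{sp}.tsv"
        genes = genomes[sp].genes
        if resume and eff_path.exists():
            df = io.read_tsv(eff_path)
            per_gene = df["effective_length"]
            eff[sp] = mapping.EffectiveLengths(
                per_gene=per_gene, median=float(np.median(per_gene))
            )
            frac_mapable = float(df["mapable"].mean()) if "mapable" in df else np.nan
        else:
            track = mapping.compute_mapability(
                genomes[sp], k=cfg.read_length, strand_mode="both_strands"
            )
            eff[sp] = mapping.effective_lengths(track, genes)
            frac_mapable = float(
                np.mean([t.mean() for t in track.tracks.values()])
            )
            df = eff[sp].per_gene.to_frame()
            df["mapable"] = frac_mapable
            io.write_tsv(df, eff_path)
        stage_map[sp] = {
            "genome_mapable_fraction": round(frac_mapable, 6),
            "median_effective_length": eff[sp].median,
        }
    report["stages"]["mapability"] = stage_map

    # ---- quantify -------------------------------------------------------
    scaled: dict[str, quantify.ScaledAbundanceMatrix] = {}
    retained: dict[str, pd.Index] = {}
    stage_q: dict = {}
    for sp in cfg.species_names:
        exonic = pd.Series(
            {g.gene_id: g.exonic_length for g in genomes[sp].genes}, name="exonic_length"
        )
        polyA = truth.genes_of(sp)["polyA"]
        scaled[sp] = quantify.scale_abundance(counts[sp], eff[sp], polyA_flags=polyA)
        fr, kept = quantify.apply_gene_filters(
            scaled[sp],
            counts[sp],
            exonic,
            polyA_flags=polyA,
            min_mapable_frac=th.min_mapable_frac,
            min_count=th.min_count,
            min_replicate_cor=th.min_replicate_cor,
            pseudocount=th.pseudocount,
        )
        retained[sp] = kept
        io.write_tsv(scaled[sp].values, out / f"scaled_{sp}.tsv")
        io.write_tsv(fr, out / f"filter_report_{sp}.tsv")
        stage_q[sp] = {
            "filter_counts": _class_counts(fr["status"]),
            "n_retained": int(len(kept)),
            "n_total": int(len(fr)),
        }
    report["stages"]["quantify"] = stage_q

    # ---- profiles -------------------------------------------------------
    logp: dict[str, pd.DataFrame] = {}
    calls: dict[str, pd.DataFrame] = {}
    stage_p: dict = {}
    for sp in cfg.species_names:
        logged = quantify.log_transform(scaled[sp].values.loc[retained[sp]], th.pseudocount)
        logp[sp] = profiles.replicate_mean_profiles(logged)
        calls[sp] = profiles.classify_regulation(
            logp[sp], fold_threshold=th.fold_threshold, cor_threshold=th.cor_threshold
        )
        z = profiles.standardize_profiles(logp[sp])
        layout = profiles.heatmap_order(calls[sp], z)
        linkmat, labels = profiles.cluster_timepoints(logp[sp])
        io.write_tsv(calls[sp], out / f"regulation_calls_{sp}.tsv")
        io.write_tsv(z, out / f"zscores_{sp}.tsv")
        stage_p[sp] = {
            "class_counts": _class_counts(calls[sp]["reg_class"]),
            "heatmap_boundaries": layout.boundaries,
            "dendrogram": [
                [int(a), int(b), round(float(h), 10), int(n)] for a, b, h, n in linkmat
            ],
            "timepoint_labels": [int(x) for x in labels],
        }
    report["stages"]["profiles"] = stage_p

    # ---- compare --------------------------------------------------------
    both = orthologs[
        orthologs["gene_a"].isin(retained[sp_a]) & orthologs["gene_b"].isin(retained[sp_b])
    ].reset_index(drop=True)
    pairs, sections, density = compare.ortholog_similarity(logp[sp_a], logp[sp_b], both)
    corr_map = compare.timepoint_correspondence(
        logp[sp_a].loc[both["gene_a"]],
        logp[sp_b].loc[both["gene_b"]].set_axis(both["gene_a"], axis=0),
    )
    shifts = compare.shift_classification(
        logp[sp_a],
        logp[sp_b],
        both,
        threshold=th.shift_threshold,
        step_hours=cfg.timestep_hours,
    )
    cons = compare.abundance_conservation(
        scaled[sp_a].values.loc[retained[sp_a]],
        scaled[sp_b].values.loc[retained[sp_b]],
        both,
    )
    rank_summaries = {}
    for sp in cfg.species_names:
        sums = compare.developmental_sums(scaled[sp].values.loc[retained[sp]])
        fc = truth.genes_of(sp)["funcat"].loc[retained[sp]]
        cat_map = {str(k): list(v) for k, v in fc.groupby(fc).groups.items()}
        rk = compare.category_rank_percentile(sums, cat_map)
        rank_summaries[sp] = {
            term: round(float(row["median_percentile"]), 4) for term, row in rk.iterrows()
        }
        io.write_tsv(rk, out / f"rank_percentiles_{sp}.tsv", index_label="category")
    nonorth = {}
    for sp in cfg.species_names:
        sums = compare.developmental_sums(scaled[sp].values.loc[retained[sp]])
        flags = truth.genes_of(sp)["is_ortholog"].loc[retained[sp]]
        res = compare.nonortholog_abundance_test(sums, flags)
        nonorth[sp] = {
            "t": round(res.statistic, 6),
            "pvalue": res.pvalue,
            "direction": res.direction,
        }
    pairs.to_csv(out / "ortholog_similarity.tsv", sep="\t", index=False)
    shifts.to_csv(out / "shift_classes.tsv", sep="\t", index=False)
    with open(out / "density_grid.json", "w") as fh:
        json.dump(density, fh)
    report["stages"]["compare"] = {
        "n_pairs_analyzed": int(len(both)),
        "similarity_sections": sections,
        "fraction_conserved": round(
            sections["r>0.5"] / len(both), 6
        )
        if len(both)
        else None,
        "timepoint_correspondence": {
            str(b): int(row["best_a"]) for b, row in corr_map.iterrows()
        },
        "shift_class_counts": _class_counts(shifts["shift_class"]),
        "abundance_sum_correlation": round(float(cons.correlation), 6),
        "abundance_tiers_a": _class_counts(cons.tiers_a),
        "rank_percentiles": rank_summaries,
        "nonortholog_abundance": nonorth,
    }

    # ---- celltype -------------------------------------------------------
    stage_ct: dict = {}
    ct_calls: dict[str, pd.Series] = {}
    for sp in cfg.species_names:
        ct_counts = ct_data[sp].counts.loc[ct_data[sp].counts.index.intersection(retained[sp])]
        ct_scaled = quantify.scale_abundance(ct_counts, eff[sp])
        de = ct.whole_transcript_de(ct_scaled.values, pseudocount=th.pseudocount)
        markers = ct_data[sp].markers
        threshold, absent = ct.derive_thresholds(de, markers)
        called = ct.call_enriched(de, threshold, fold_threshold=th.fold_threshold)
        ct_calls[sp] = called["call"]
        # nucleotide method on the genes the whole-transcript method called,
        # plus the markers (cost control; coverage streams are per-gene seeded)
        nuc_genes = sorted(
            set(called.index[called["call"] != "none"])
            | (set(markers.index) & set(called.index))
        )
        cov = syn.simulate_nucleotide_coverage(genomes, truth, cfg, sp, gene_ids=nuc_genes)
        nuc = ct.nucleotide_de(cov, min_nucleotides=th.min_nucleotides)
        nuc_threshold, _ = ct.derive_thresholds(
            nuc[nuc["status"] == "ok"], markers
        )
        nuc_called = ct.call_enriched(
            nuc[nuc["status"] == "ok"], nuc_threshold, fold_threshold=th.fold_threshold
        )
        io.write_tsv(called, out / f"celltype_calls_{sp}.tsv")
        stage_ct[sp] = {
            "p_threshold": threshold,
            "markers_used": int(len(markers) - len(absent)),
            "markers_absent": len(absent),
            "whole_transcript_calls": _class_counts(called["call"]),
            "nucleotide_calls": _class_counts(nuc_called["call"]),
        }
    venn = ct.conserved_overlap(
        ct_calls[sp_a],
        ct_calls[sp_b],
        both,
        other_set=set(pairs.loc[pairs["section"] == "r>0.5", "gene_a"]),
    )
    stage_ct["conservation"] = {
        "n_enriched_a": venn.n_enriched_a,
        "n_enriched_b": venn.n_enriched_b,
        "n_conserved": venn.n_conserved,
        "per_celltype": venn.per_celltype,
        "overlap_with_conserved_profiles": venn.enrichment,
    }
    report["stages"]["celltype"] = stage_ct

    # ---- enrich ---------------------------------------------------------
    stage_e: dict = {}
    for sp in cfg.species_names:
        ann = enrich.AnnotationTable.from_pairs(
            syn.annotation_table(truth, sp), set(truth.genes_of(sp).index)
        )
        query = set(calls[sp].index[calls[sp]["reg_class"] == "up"])
        res = enrich.hypergeometric_enrichment(query, ann)
        io.write_tsv(res, out / f"enrichment_up_{sp}.tsv", index_label="term")
        stage_e[sp] = {
            "query": "up-regulated genes",
            "n_query": len(query),
            "top_terms": [
                {"term": t, "k": int(r["k"]), "K": int(r["K"]), "p_adjusted": float(r["p_adjusted"])}
                for t, r in res.head(3).iterrows()
            ],
        }
    report["stages"]["enrich"] = stage_e

    assert_report_consistent(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report


def assert_report_consistent(report: dict) -> None:
    """Programmatic internal-consistency checks on a run report."""
    stages = report["stages"]
    expected = ["simulate", "mapability", "quantify", "profiles", "compare", "celltype", "enrich"]
    if sorted(stages) != sorted(expected):
        raise AssertionError(f"stages {sorted(stages)} != expected {sorted(expected)}")
    for sp, q in stages["quantify"].items():
        if sum(q["filter_counts"].values()) != q["n_total"]:
            raise AssertionError(f"filter statuses do not partition genes for {sp}")
        if q["filter_counts"].get("retained", 0) != q["n_retained"]:
            raise AssertionError(f"retained count mismatch for {sp}")
    for sp, p in stages["profiles"].items():
        n_classified = sum(p["class_counts"].values())
        if n_classified != stages["quantify"][sp]["n_retained"]:
            raise AssertionError(f"classification does not cover retained genes for {sp}")
        if p["heatmap_boundaries"][-1] != n_classified:
            raise AssertionError(f"heat-map sections do not cover all genes for {sp}")
    comp = stages["compare"]
    if sum(comp["similarity_sections"].values()) != comp["n_pairs_analyzed"]:
        raise AssertionError("similarity sections + undefined must sum to pair count")
    if sum(comp["shift_class_counts"].values()) != comp["n_pairs_analyzed"]:
        raise AssertionError("shift classes must sum to pair count")
    cons = stages["celltype"]["conservation"]
    for ctype, d in cons["per_celltype"].items():
        if d["conserved"] > min(d["a"], d["b"]):
            raise AssertionError(f"conserved {ctype} exceeds per-species call count")
    if cons["n_conserved"] > min(cons["n_enriched_a"], cons["n_enriched_b"]):
        raise AssertionError("conserved calls exceed per-species enriched counts")


def write_yaml_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
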