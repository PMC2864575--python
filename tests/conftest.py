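import numpy as np
import pandas as pd
import pytest

from devocompare import mapping, quantify
from devocompare.synthetic import SimConfig, generate_toy_genomes, simulate_timecourse_counts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes_per_species=120, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genomes, ortholog table and truth for a 120-gene toy dataset."""
    genomes, orthologs, truth = generate_toy_genomes(small_config)
    return genomes, orthologs, truth


@pytest.fixture(scope="session")
def small_counts(small_config, small_dataset):
    genomes, _orthologs, truth = small_dataset
    return simulate_timecourse_counts(genomes, truth, small_config)


def exonic_effective_lengths(genome) -> mapping.EffectiveLengths:
    """Effective lengths equal to exonic lengths (fully mapable toy genome)."""
    per_gene = pd.Series({g.gene_id: g.exonic_length for g in genome.genes})
    return mapping.EffectiveLengths(per_gene=per_gene, median=float(np.median(per_gene)))


def scaled_log_profiles(genome, counts, pseudocount: float = 1.0):
    """Replicate-mean log2 trajectories from raw counts (helper for tests)."""
    from devocompare import profiles

    eff = exonic_effective_lengths(genome)
    scaled = quantify.scale_abundance(counts, eff)
    return profiles.replicate_mean_profiles(
        quantify.log_transform(scaled.values, pseudocount)
    )
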