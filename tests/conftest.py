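from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lincscout.synthetic_genome import (  # noqa: E402
    SimulationConfig,
    build_genome,
    generate_coding_training_set,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down scenario that keeps every structural feature."""
    return SimulationConfig(
        seed=9,
        n_scaffolds=8,
        scaffold_length=200_000,
        n_coding_genes=60,
        n_noncoding_loci=40,
        n_decoy_coding_transcripts=20,
        n_gene_overlap_candidates=10,
        n_mirna_embeds=4,
        n_training_per_class=60,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    genomes, genes, candidates, truth = build_genome(small_config)
    counts = simulate_counts(small_config, truth)
    coding, noncoding = generate_coding_training_set(small_config)
    return {
        "config": small_config,
        "genomes": genomes,
        "genes": genes,
        "candidates": candidates,
        "truth": truth,
        "counts": counts,
        "train_coding": [s for _, s in coding],
        "train_noncoding": [s for _, s in noncoding],
    }


@pytest.fixture(scope="session")
def small_identification(small_sim):
    from lincscout.lincrna_identify import run_identification

    return run_identification(
        small_sim["candidates"],
        small_sim["genes"],
        small_sim["counts"],
        small_sim["train_coding"],
        small_sim["train_noncoding"],
    )
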