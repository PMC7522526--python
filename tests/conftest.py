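"""Shared fixtures: one desk-scale synthetic study reused across the suite."""

from __future__ import annotations

import pytest

from methylink.genome_io import scan_motif
from methylink.synthetic_data import (
    SyntheticScenario,
    generate_genome,
    generate_kinetics,
    generate_methylation_truth,
)


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=11)


@pytest.fixture(scope="session")
def study(scenario):
    """Genome + annotation + motif hits + per-condition methylation truth and kinetics."""
    genome, genes, planted = generate_genome(scenario)
    hits = scan_motif(genome, scenario.motif, strand="both")
    truth = generate_methylation_truth(scenario, genome, genes, hits)
    kinetics = generate_kinetics(scenario, genome, truth)
    return {
        "scenario": scenario,
        "genome": genome,
        "genes": genes,
        "planted_motifs": planted,
        "motif_hits": hits,
        "truth": truth,
        "kinetics": kinetics,
    }
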