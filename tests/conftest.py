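import numpy as np
import pytest

from mitocurate import (AnnotationTable, GeneAnnotation, Genome,
                        SimulationConfig, simulate_genome, simulate_panel)


@pytest.fixture(scope="session")
def small_truth():
    """One synthetic genome with default architecture (seed 11)."""
    return simulate_genome(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def panel_truth():
    """A 4-species panel at 20% divergence with one relocated tRNA."""
    return simulate_panel(SimulationConfig(seed=7, n_species=4,
                                           substitution_rate=0.2,
                                           trna_relocations=1))


@pytest.fixture()
def toy_genome():
    """A 60 bp circular genome of repeating ACGT (no stop codons needed)."""
    return Genome(id="toy", sequence="ACGT" * 15)


def make_table(genome, rows):
    """Helper: build a validated AnnotationTable from (gene, type, s, e)."""
    feats = [GeneAnnotation(gene=g, type=t, start=s, end=e)
             for g, t, s, e in rows]
    table = AnnotationTable(genome_id=genome.id, features=feats)
    table.validate_against(genome)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
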