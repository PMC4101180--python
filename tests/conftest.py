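import pytest

from whiterot.simulate import (
    SimulationConfig,
    generate_class2_set,
    generate_genome,
    generate_proteome_set,
    toy_ontology,
)


@pytest.fixture(scope="session")
def small_proteome_set():
    """3 species x 4 families, no duplications, moderate divergence."""
    cfg = SimulationConfig(
        seed=101, n_species=3, n_families=4,
        duplication_rate=0.0, substitution_rate=0.1, protein_length=150,
    )
    return generate_proteome_set(cfg)


@pytest.fixture(scope="session")
def feature_genome():
    """Genome with planted TE copies, SSRs, tandem arrays and gene models."""
    cfg = SimulationConfig(
        seed=202, genome_length=50_000,
        planted_te_specs=[(500, 12, 0.03)],
        planted_ssr_specs=[("AG", 8), ("ACG", 6), ("A", 12)],
        planted_tandem_specs=[(20, 10, 0.05), (120, 3, 0.0)],
        planted_gene_specs=[(3, [60, 75]), (4, [50, 50, 50])],
    )
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def class2_set():
    cfg = SimulationConfig(
        seed=303, substitution_rate=0.05,
        class2_counts={"LiP": 2, "shortMnP": 1, "longMnP": 1,
                       "VP": 1, "atypicalVP": 1, "GP": 1},
    )
    return generate_class2_set(cfg)


@pytest.fixture(scope="session")
def ontology():
    return toy_ontology()
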