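import pytest

import capspop as cp


@pytest.fixture(scope="session")
def table2_defs():
    return cp.load_table2_markers()


@pytest.fixture(scope="session")
def table3_df():
    return cp.load_table3_stats()


@pytest.fixture(scope="session")
def enzymes():
    return cp.load_enzyme_table()


@pytest.fixture(scope="session")
def default_cfg():
    return cp.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_freqs(default_cfg):
    return cp.simulate_allele_frequencies(default_cfg)


@pytest.fixture(scope="session")
def synthetic_gm(default_cfg, default_freqs):
    """41 accessions x 70 loci, two populations + admixed tail."""
    return cp.simulate_genotypes(default_cfg, default_freqs)


def make_gm(cells, accession_ids=None, marker_ids=None, pops=None):
    """Build a GenotypeMatrix from a list of lists of 'X/Y' strings."""
    n, l = len(cells), len(cells[0])
    return cp.GenotypeMatrix(
        accession_ids=accession_ids or [f"A{i+1}" for i in range(n)],
        marker_ids=marker_ids or [f"M{j+1}" for j in range(l)],
        calls=[[cp.AlleleCall.parse(c) for c in row] for row in cells],
        population_labels=pops,
    )
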