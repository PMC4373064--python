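import pytest

from wildtx.synthdata import SynthConfig, generate


@pytest.fixture(scope="session")
def default_data():
    """One default synthetic dataset shared across the suite (seed 1)."""
    ref, acc = generate(SynthConfig(seed=1))
    return ref, acc


@pytest.fixture(scope="session")
def reference(default_data):
    return default_data[0]


@pytest.fixture(scope="session")
def accession(default_data):
    return default_data[1]


@pytest.fixture(scope="session")
def genome_dict(reference):
    return {r.id: r.seq for r in reference.genome}


@pytest.fixture(scope="session")
def genes_by_id(reference):
    return {g.gene_id: g for g in reference.genes}
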