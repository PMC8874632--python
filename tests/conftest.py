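import pytest

from cdftpep.datasets import (load_admet_table, load_benchmark_table,
                              load_bioactivity_scores,
                              load_global_descriptor_reference,
                              load_kid_reference,
                              load_veraguamide_energetics)


@pytest.fixture(scope="session")
def veraguamides():
    """The seven Veraguamide species triads (MN12SX, SMD water)."""
    return load_veraguamide_energetics()


@pytest.fixture(scope="session")
def veraguamides_by_id(veraguamides):
    return {t.molecule_id: t for t in veraguamides}


@pytest.fixture(scope="session")
def descriptor_reference():
    return load_global_descriptor_reference()


@pytest.fixture(scope="session")
def kid_reference():
    return load_kid_reference()


@pytest.fixture(scope="session")
def benchmark_cells():
    return load_benchmark_table()


@pytest.fixture(scope="session")
def bioactivity_scores():
    return load_bioactivity_scores()


@pytest.fixture(scope="session")
def admet_flags():
    return load_admet_table()
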