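import pytest

from gliamp import epitope as ep
from gliamp import synthetic_data as sd


@pytest.fixture(scope="session")
def epitopes():
    return ep.load_epitope_table()


@pytest.fixture(scope="session")
def family():
    """The default BW208-like ground-truth family (seed 42)."""
    return sd.build_family(sd.bw208_like(seed=42))


@pytest.fixture(scope="session")
def annotated_family(family, epitopes):
    return ep.annotate_database(family.records, epitopes, family.reference_cds, family.exemplars)
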