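import pytest

from regvar.pipeline import run_bundle
from regvar.synthetic_data import LocusSpec, gen_locus_fixture


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic long-range-enhancer locus (seed 42)."""
    return gen_locus_fixture(LocusSpec(seed=42))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_bundle(default_bundle, traits=["Psoriasis"])
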