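import pytest

from evsyn import load_fixture
from evsyn.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def mdd_catalog():
    return load_fixture("mdd_variants")


@pytest.fixture(scope="session")
def response_catalog():
    return load_fixture("response_variants")


@pytest.fixture(scope="session")
def mdd_bundle(mdd_catalog):
    return run_pipeline(
        mdd_catalog,
        PipelineConfig(domain="mdd"),
        gene_catalog=load_fixture("mdd_genes"),
        annotations=load_fixture("annotations_mdd"),
    )


@pytest.fixture(scope="session")
def response_bundle(response_catalog):
    return run_pipeline(
        response_catalog,
        PipelineConfig(domain="response"),
        gene_catalog=load_fixture("response_genes"),
        annotations=load_fixture("annotations_response"),
    )
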