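import pytest

from remreg import fixtures, pipeline


@pytest.fixture(scope="session")
def locus():
    """The worked-example SMCHD1 locus bundle."""
    return fixtures.paper_locus()


@pytest.fixture(scope="session")
def prediction(locus):
    """Steps 1-5 run on the worked-example bundle."""
    return pipeline.predict(locus.gene, locus.contacts_coarse, locus.tracks,
                            locus.contacts_fine)
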