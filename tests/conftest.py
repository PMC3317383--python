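import pytest

from ptmcrosstalk import fixtures as fx
from ptmcrosstalk.conservation import conservation_profile
from ptmcrosstalk.crosstalk import annotate_sites


@pytest.fixture(scope="session")
def foxo3():
    return fx.foxo3_record()


@pytest.fixture(scope="session")
def foxo1():
    return fx.foxo1_record()


@pytest.fixture(scope="session")
def ortholog_msa():
    return fx.ortholog_msa()


@pytest.fixture(scope="session")
def foxo3_profile(ortholog_msa):
    return conservation_profile(ortholog_msa, min_fraction=1.0)


@pytest.fixture(scope="session")
def foxo3_sites():
    return fx.site_scores()


@pytest.fixture(scope="session")
def foxo3_annotations(foxo3_sites, foxo3_profile):
    conserved = {p: foxo3_profile.is_conserved(p) for p in range(1, len(foxo3_profile) + 1)}
    return annotate_sites(
        foxo3_sites, conserved, fx.ev_sites(), kinase_map=fx.kinase_map()
    )
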