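import pytest

from rivercast import fixtures
from rivercast.datamodel import DEFAULT_CATALOG, FishSample


def make_fish(i=0, year=2020, week=15, vsi="upriver", clip="AI",
              genstock="12_HELLSC", brood=None, obs=None,
              fork_length=700.0):
    """Shorthand fish factory for composition/concordance tests."""
    return FishSample(
        sample_id=f"F{i:04d}", year=year, stat_week=week,
        origin_site="SCTF", fork_length_mm=fork_length, vsi_stock=vsi,
        fin_clip=clip, genstock_obs=obs if obs is not None else genstock,
        pbt_broodstock=brood, genstock_exp=genstock if brood else None,
    )


@pytest.fixture(scope="session")
def catalog():
    return DEFAULT_CATALOG


@pytest.fixture(scope="session")
def table1_records():
    return fixtures.fixture("table1")


@pytest.fixture(scope="session")
def table4_reference():
    return fixtures.fixture("table4")


@pytest.fixture(scope="session")
def table5_sample_list():
    return fixtures.table5_samples()


@pytest.fixture(scope="session")
def table7_frame():
    return fixtures.fixture("table7")
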