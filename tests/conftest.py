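import pytest

from guanofe import (
    GuanoParameters,
    UncertainQuantity,
    ZoneCensus,
    run_pipeline,
    vapour_col_config,
)


@pytest.fixture
def params():
    """Default guano parameters (Fe 3.0 ± 1.4 mg/g, w 0.4, t 2 cm, ...)."""
    return GuanoParameters()


@pytest.fixture
def printed_zones():
    """The four colony zones with their reported counts (all surveyed)."""
    mk = lambda zid, cls, area, n, sd: ZoneCensus(
        zid, cls, UncertainQuantity(area, 0.0, "m2"),
        UncertainQuantity(n, sd, "ind"))
    return [
        mk("NT_GRZ", "GRZ", 4356, 2265, 159),
        mk("NT_OZ", "OZ", 66179, 1853, 130),
        mk("RVC_GRZ", "GRZ", 14637, 7611, 439),
        mk("RVC_OZ", "OZ", 178429, 4996, 179),
    ]


@pytest.fixture(scope="session")
def replication():
    """One full run of the packaged Vapour Col configuration."""
    return run_pipeline(vapour_col_config())
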