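import numpy as np
import pandas as pd
import pytest

from cotswatch.surveillance_io import Registry, ThresholdConfig


@pytest.fixture
def registry() -> Registry:
    rows = []
    for s, sector in enumerate(["North", "Central", "South"], start=1):
        for r in range(1, 4):
            rows.append(
                {
                    "reef_id": f"R{s}{r}",
                    "sector_id": sector,
                    "sector_order": s,
                    "uses_established_inception": sector == "Central",
                }
            )
    return Registry(table=pd.DataFrame(rows))


@pytest.fixture
def thresholds() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def tow_fixture(registry) -> pd.DataFrame:
    """3 reefs x 2 years x 2 tows of valid records."""
    rng = np.random.default_rng(11)
    rows = []
    for reef in ["R11", "R12", "R13"]:
        for year in (2015, 2016):
            for tow in (1, 2):
                rows.append(
                    {
                        "reef_id": reef,
                        "year": year,
                        "program": "LTMP",
                        "tow_index": tow,
                        "cover_category": int(rng.integers(0, 6)),
                        "cots_count": int(rng.poisson(0.4)),
                    }
                )
    return pd.DataFrame(rows)
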