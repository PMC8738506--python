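import numpy as np
import pandas as pd
import pytest

from palynores.harmonization import HarmonizationEntry, HarmonizationTable, IndicativeCapacity
from palynores.records import EcologicalGroup, PollenRecord
from palynores.synthetic import SyntheticConfig, generate_harmonization_table, generate_record

C = IndicativeCapacity
G = EcologicalGroup


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def synthetic_record(default_config) -> PollenRecord:
    return generate_record(default_config)


@pytest.fixture(scope="session")
def synthetic_table(default_config) -> HarmonizationTable:
    return generate_harmonization_table(default_config)


@pytest.fixture
def plantago_table() -> HarmonizationTable:
    """The worked Plantago merge: two adventives + two wild types -> Plantago."""
    return HarmonizationTable(
        [
            HarmonizationEntry("Plantago lanceolata-type", "Plantago lanceolata-type",
                               "Plantago", C.ADVENTIVE, G.UPLAND_HERB),
            HarmonizationEntry("Plantago major-type", "Plantago major-type",
                               "Plantago", C.ADVENTIVE, G.UPLAND_HERB),
            HarmonizationEntry("Plantago maritima-type", "Plantago maritima-type",
                               "Plantago", C.NONE, G.UPLAND_HERB),
            HarmonizationEntry("Plantago atrata-type", "Plantago atrata-type",
                               "Plantago", C.NONE, G.UPLAND_HERB),
            HarmonizationEntry("Quercus", "Quercus", "Quercus", C.NONE, G.TREE),
        ]
    )


def make_record(counts: dict, ages, groups=None, site="test") -> PollenRecord:
    df = pd.DataFrame(counts, index=pd.Index(np.asarray(ages, float), name="age_calBP"))
    return PollenRecord(site_name=site, counts=df, groups=groups)
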