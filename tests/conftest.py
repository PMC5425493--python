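import numpy as np
import pytest

from aquacens import (
    AnalysisConfig,
    Analyte,
    CensoredMeasurement,
    HarmonizedValue,
    SourceRecord,
    generate,
    default_preset,
)
from aquacens.synthetic_survey import write_dataset


def hv(value, censored=False, analyte=Analyte.ARSENIC, source_id="s"):
    """Shorthand HarmonizedValue constructor for tests."""
    return HarmonizedValue(source_id=source_id, analyte=analyte,
                           value_ug_L=value, censored=censored)


def hvs(values, censored, analyte=Analyte.ARSENIC):
    return [hv(v, bool(c), analyte, f"s{i}")
            for i, (v, c) in enumerate(zip(values, censored))]


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def multiply_censored():
    """The worked five-point example {<1, 1.5, <2, 2.5, 5}."""
    values = np.array([1.0, 1.5, 2.0, 2.5, 5.0])
    censored = np.array([True, False, True, False, False])
    return values, censored


@pytest.fixture(scope="session")
def preset_dataset():
    """One generated study-shaped dataset, shared across tests."""
    return generate(default_preset(seed=1))


@pytest.fixture(scope="session")
def preset_paths(preset_dataset, tmp_path_factory):
    sources, mines, truth = preset_dataset
    out = tmp_path_factory.mktemp("preset")
    return write_dataset(sources, mines, truth, out)


@pytest.fixture
def small_sources():
    """Three sources with mixed-unit, mixed-censoring histories."""
    return [
        SourceRecord("w1", 36.0, -109.0, region="east", measurements=[
            CensoredMeasurement(Analyte.ARSENIC, False, value=12.0, survey_id="a"),
            CensoredMeasurement(Analyte.URANIUM, False, value=20.1,
                                units="pCi_per_L", survey_id="a"),
        ]),
        SourceRecord("w2", 36.5, -110.0, region="west", measurements=[
            CensoredMeasurement(Analyte.ARSENIC, True, reporting_limit=5.0,
                                survey_id="b"),
            CensoredMeasurement(Analyte.ARSENIC, False, value=3.0, survey_id="c"),
            CensoredMeasurement(Analyte.URANIUM, False, value=31.0, survey_id="b"),
        ]),
        SourceRecord("w3", 35.5, -108.5, region="east", measurements=[
            CensoredMeasurement(Analyte.ARSENIC, False, value=0.4, survey_id="c",
                                method_documented=False),
        ]),
    ]
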