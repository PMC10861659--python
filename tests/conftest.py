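import dataclasses

import pytest

import hairscreen as hs


@pytest.fixture(scope="session")
def panel():
    return hs.load_model_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {r.name: r for r in panel}


@pytest.fixture(scope="session")
def design():
    return hs.StudyDesign()


@pytest.fixture(scope="session")
def pk_map():
    return hs.default_pk_map()


@pytest.fixture(scope="session")
def meas():
    return hs.MeasurementModel()


@pytest.fixture(scope="session")
def short_params(pk_map):
    """Noise-free short-elimination preset."""
    return dataclasses.replace(pk_map["furosemide"], bsv_sigma=0.0)


@pytest.fixture(scope="session")
def small_design(design):
    """Two animals per group, plasma + hair only - fast end-to-end runs."""
    return dataclasses.replace(
        design,
        group_sizes={"vehicle": 2, "half": 2, "one": 2, "two": 2},
        collection_days={"plasma": (0, 7, 10), "hair": (0, 28)},
    )
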