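import numpy as np
import pytest

from baselinetox import load_assay_systems, load_packaged, load_partition_regressions


@pytest.fixture(scope="session")
def systems():
    return load_assay_systems()


@pytest.fixture(scope="session")
def generic_system(systems):
    return systems["generic"]


@pytest.fixture(scope="session")
def table1():
    return load_packaged("table1").table


@pytest.fixture(scope="session")
def regressions():
    return load_partition_regressions()


@pytest.fixture(scope="session")
def anionic_pairs(table1):
    """The nine experimental anionic (log D_lip/w, log D_BSA/w, log D_SP/w)
    triples used to calibrate the anionic protein regressions (chemicals
    whose log D_lip/w is itself predicted are excluded)."""
    rows = table1[(table1["charge_class"] == "anionic") & (~table1["dlip_predicted"])]
    assert len(rows) == 9
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
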