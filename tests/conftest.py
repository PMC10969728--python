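import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def emulsion_table():
    from encapkin import studydata

    return studydata.emulsion_table()


@pytest.fixture(scope="session")
def kinetic_fits_table():
    from encapkin import studydata

    return studydata.kinetic_fits_table()


@pytest.fixture(scope="session")
def powder_table():
    from encapkin import studydata

    return studydata.powder_table()


@pytest.fixture(scope="session")
def release_fits_table():
    from encapkin import studydata

    return studydata.release_fits_table()


@pytest.fixture()
def fixture_dir(tmp_path):
    """Study dataset written out as pipeline input CSVs."""
    from encapkin import studydata

    studydata.stability_long().to_csv(tmp_path / "stability.csv", index=False)
    studydata.powder_table().to_csv(tmp_path / "powder.csv", index=False)
    studydata.release_fits_table()[["sample_id", "k_per_min", "d_eff_1e10"]].to_csv(
        tmp_path / "release_fits.csv", index=False
    )
    return tmp_path
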