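import numpy as np
import pandas as pd
import pytest

from pmexposure import (
    ExposureData,
    SimScenario,
    StudyConfig,
    TWAExposureModel,
    simulate_study,
)


@pytest.fixture(scope="session")
def cfg():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_study():
    """One small-preset synthetic study shared across tests."""
    return simulate_study(SimScenario(rng_seed=7))


@pytest.fixture(scope="session")
def tiny_study():
    """A very small study for fast pipeline tests."""
    return simulate_study(
        SimScenario(n_participants=2, n_days=3, n_sensors=30, rng_seed=11)
    )


@pytest.fixture(scope="session")
def fitted_results(small_study):
    data = ExposureData.from_simulation(small_study)
    return TWAExposureModel(data, StudyConfig(rng_seed=7)).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_csv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.fixture()
def csv_writer(tmp_path):
    def _write(name, text):
        return write_csv(tmp_path, name, text)

    return _write


@pytest.fixture()
def one_day_occupancy():
    """A hand-built single participant-day occupancy frame: 46 house slots
    and 2 outdoor slots, constant concentrations."""
    slots = pd.date_range("2023-01-02", periods=48, freq="30min")
    micro = np.array(["house"] * 48, dtype=object)
    micro[[24, 25]] = "outdoor"
    return pd.DataFrame(
        {
            "participant_id": "P000",
            "slot_start": slots,
            "microenv": micro,
            "is_gap": False,
            "c_outdoor_gps": 10.0,
            "c_outdoor_home": 8.0,
            "c_house": 30.0,
        }
    )
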