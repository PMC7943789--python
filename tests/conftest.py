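import numpy as np
import pandas as pd
import pytest

from phenoscreen.simulate import RegressionSpec, SimulationConfig, SubpopulationSpec


@pytest.fixture
def small_screen_config() -> SimulationConfig:
    """10-compound single-line screen with two planted strong hits."""
    return SimulationConfig(
        seed=11,
        noise_cv=0.1,
        compounds=tuple(f"C{i}" for i in range(10)),
        doses=(0.2, 1.0),
        replicates=2,
        control_replicates=20,
        cell_lines=("L1",),
        baseline_mu={"L1": 0.6},
        mapk_conditions=("DMSO",),
        mapk_mu_delta={"DMSO": 0.0},
        planted_effects={"C0": -1.0, "C1": -1.0},
    )


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        seed=0,
        noise_cv=0.0,
        n0=1000,
        timepoints=(0.0, 1.0, 2.0),
        cell_lines=("L1",),
        baseline_mu={"L1": 0.5},
    )


@pytest.fixture
def bimodal_config() -> SimulationConfig:
    """Well-separated 70/30 two-state marker mixture."""
    return SimulationConfig(
        seed=42,
        subpopulations=(
            SubpopulationSpec(0.7, {"Mitf": 7.0, "Axl": 4.0}, 0.3, "low"),
            SubpopulationSpec(0.3, {"Mitf": 5.0, "Axl": 7.0}, 0.3, "high"),
        ),
    )


@pytest.fixture
def regression_config() -> SimulationConfig:
    return SimulationConfig(
        seed=5,
        regression=RegressionSpec(
            n_samples=8, n_features=8, rank=2, noise_sd=0.1
        ),
    )


def exponential_timecourse(
    mu: float, n0: float = 1000.0, timepoints=(0.0, 1.0, 2.0)
) -> pd.DataFrame:
    """Noiseless exponential count series as a one-replicate table."""
    t = np.asarray(timepoints, dtype=float)
    return pd.DataFrame(
        {
            "condition_id": "c",
            "cell_line": "L",
            "treatment": "c",
            "replicate": 1,
            "time_days": t,
            "live_count": n0 * np.exp(mu * t),
        }
    )
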