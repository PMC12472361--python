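import numpy as np
import pandas as pd
import pytest

from gmindex import CountMatrix, SyntheticScenario, simulate_lab_experiment


def make_matrix(values: dict[str, list[float]], transcripts: list[str], conditions: dict[str, str]) -> CountMatrix:
    """Small helper: build a CountMatrix from literal columns."""
    frame = pd.DataFrame(values, index=pd.Index(transcripts, name="transcript_id"), dtype=float)
    samples = pd.DataFrame(
        {
            "condition": [conditions[s] for s in frame.columns],
            "site": "lab",
            "replicate": range(1, frame.shape[1] + 1),
        },
        index=frame.columns,
    )
    return CountMatrix(frame, samples)


@pytest.fixture(scope="session")
def low_noise_lab():
    """Low-dispersion lab simulation with strong fold changes (5 replicates)."""
    scenario = SyntheticScenario(
        seed=7,
        n_transcripts=800,
        n_up_cold=25,
        n_down_cold=25,
        n_up_des=25,
        n_down_des=25,
        n_constant=40,
        dispersion=0.01,
        n_replicates_per_condition=5,
    )
    lab, truth = simulate_lab_experiment(scenario)
    return scenario, lab, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20251)
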