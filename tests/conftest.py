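import numpy as np
import pandas as pd
import pytest

from serialdep import DoGParams, SimConfig, derive_trials, simulate_experiment


def build_trials(targets, reports, experiment="exp", subject="s0", session="1"):
    """Small trial table straight from target/report angle arrays (radians)."""
    targets = np.asarray(targets, dtype=float)
    reports = np.asarray(reports, dtype=float)
    return pd.DataFrame(
        {
            "experiment": experiment,
            "subject": subject,
            "session": session,
            "trial_index": np.arange(targets.size),
            "target": targets,
            "report": reports,
        }
    )


@pytest.fixture
def trials_factory():
    return build_trials


@pytest.fixture(scope="session")
def null_sim():
    """Simulation without attraction but with both systematic biases."""
    cfg = SimConfig(n_subjects=20, n_trials=300, seed=11)
    return simulate_experiment(cfg, DoGParams(a=0.0))


@pytest.fixture(scope="session")
def attract_sim():
    """Simulation with default attraction and both systematic biases."""
    cfg = SimConfig(n_subjects=20, n_trials=300, seed=11)
    return simulate_experiment(cfg, DoGParams())


@pytest.fixture(scope="session")
def attract_derived(attract_sim):
    return derive_trials(attract_sim)
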