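import numpy as np
import pytest

from alpinekin.pipeline import analyze_run
from alpinekin.synthetic import default_profiles, simulate_run


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def gs_run(profiles):
    """A medium-length GS run with noise on, plus its ground truth."""
    return simulate_run(profiles["GS"], 24, seed=7)


@pytest.fixture(scope="session")
def gs_analysis(gs_run):
    run, _ = gs_run
    return analyze_run(run)


@pytest.fixture(scope="session")
def all_runs(profiles):
    """One noisy 20-turn run per discipline, seed 3."""
    return {name: simulate_run(p, 20, seed=3) for name, p in profiles.items()}
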