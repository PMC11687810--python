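import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from mirpanel.pipeline import RunConfig
from mirpanel.synthetic import generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """One full-size synthetic cohort (fixed seed) shared across tests."""
    cfg = RunConfig(seed=7)
    cfg.cohort.seed = 7
    plates, samples, truth = generate_cohort(cfg.cohort)
    return cfg, plates, samples, truth


@pytest.fixture(scope="session")
def analyzed(study_cohort):
    """The shared cohort pushed through QC, hemolysis, normalization and DE."""
    from mirpanel.analysis import analyze

    cfg, plates, samples, truth = study_cohort
    return analyze(plates, samples, cfg), truth
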