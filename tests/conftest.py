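import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gaucher_ert.population_model import reference_joint_model
from gaucher_ert.registry_io import apply_analysis_window
from gaucher_ert.synthetic_registry import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def joint_truth_no_cov():
    return reference_joint_model(with_covariates=False)


@pytest.fixture(scope="session")
def joint_truth_cov():
    return reference_joint_model(with_covariates=True)


@pytest.fixture(scope="session")
def default_cohort(joint_truth_cov):
    """One default-configuration synthetic registry cohort (windowed)."""
    cohort, truth = generate_cohort(GeneratorConfig(), seed=77)
    return apply_analysis_window(cohort), truth
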