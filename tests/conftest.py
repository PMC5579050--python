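import warnings

import pytest

from pointrisk import GeneratorConfig, fit_cox, simulate_cohort

# lifelines emits convergence chatter on tiny/degenerate fixtures
warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture(scope="session")
def midsize_cohort():
    """One 12,000-subject cohort at the default generating parameters."""
    return simulate_cohort(GeneratorConfig(n_subjects=12000, seed=42))


@pytest.fixture(scope="session")
def midsize_fit(midsize_cohort):
    return fit_cox(midsize_cohort)
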