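import warnings

import pytest

from ehrms.simulate import GeneratorConfig, generate_center_subset, generate_datamart
from ehrms.text import default_term_dictionary

# constant-column and degenerate-replicate warnings are part of tested
# contracts; keep the output readable
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(n_patients=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_datamart(small_cfg)


@pytest.fixture(scope="session")
def small_center(small_cfg, small_cohort):
    return generate_center_subset(small_cohort, small_cfg)


@pytest.fixture(scope="session")
def term_dictionary():
    return default_term_dictionary()
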