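import warnings

import numpy as np
import pandas as pd
import pytest

import costdisc.cohort as ch
from costdisc import task_design as td

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def effort_design():
    return td.build_effort_design(td.effort_spec(), seed=42)


@pytest.fixture(scope="session")
def delay_design():
    return td.build_delay_design(td.delay_spec(), session_index=1, seed=42)


@pytest.fixture(scope="session")
def small_effort_cohort():
    """8-subject effort cohort from the default generative population."""
    return ch.simulate_task_cohort(ch.default_effort_truth(8), seed=5)


@pytest.fixture(scope="session")
def small_delay_cohort():
    return ch.simulate_task_cohort(ch.default_delay_truth(8), seed=6)
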