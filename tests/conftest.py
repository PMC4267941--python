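import numpy as np
import pandas as pd
import pytest

from dielcycle.layout import SamplingLayout
from dielcycle.simulate import ExpressionConfig, generate_expression


@pytest.fixture(scope="session")
def layout():
    """The study design: 3-h sampling, two appended 24-h days."""
    return SamplingLayout()


@pytest.fixture(scope="session")
def small_cohort(layout):
    """200 cycling + 200 flat genes at default noise, with truth."""
    cfg = ExpressionConfig(n_cycling=200, n_flat=200)
    return generate_expression(cfg, layout, seed=7)


@pytest.fixture(scope="session")
def pure_cosine(layout):
    """Noiseless diel cosine peaking at ZT 6, amplitude half the mean."""
    t = layout.sample_times()
    return 10.0 * (1 + 0.5 * np.cos(2 * np.pi * (t - 6.0) / 24.0))
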