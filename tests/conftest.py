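import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ipass import ExpressionMatrix, fixture_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The packaged synthetic fixture cohort (70 samples, 1000 genes)."""
    return fixture_cohort()


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with hand-pickable values."""
    df = pd.DataFrame(
        np.array(
            [
                [0.0, 1.0, 3.0, 7.0],
                [1.0, 1.0, 1.0, 1.0],
                [2.0, 4.0, 8.0, 16.0],
            ]
        ),
        index=["CXCL9", "CD27", "LIF"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df)
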