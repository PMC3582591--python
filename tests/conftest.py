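import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_table():
    """Two-sample, two-chromosome probe table with one missing cell."""
    from pcfseg import CopyNumberTable

    return CopyNumberTable(
        chrom=np.array(["1", "1", "1", "2", "2"], dtype=object),
        pos=np.array([100, 200, 300, 50, 150]),
        sample_ids=["s1", "s2"],
        values=np.array(
            [[0.1, 0.2, np.nan, 1.0, 1.1], [-0.1, -0.2, -0.3, 0.0, 0.1]]
        ),
    )
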