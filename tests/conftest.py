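import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_table():
    """Tiny feature table exercising every column type the criteria use."""
    return pd.DataFrame(
        {
            "logFC": [2.5, -0.1, -1.8, 0.9, np.nan],
            "AveExpr": [9.0, 5.0, 7.5, 6.1, 8.0],
            "p_value": [1e-5, 0.5, 3e-4, 0.02, 0.01],
            "SD": [1.2, 0.1, 0.9, 0.6, 0.8],
            "annotated": [1, 0, 1, 0, 1],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="feature_id"),
    )
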