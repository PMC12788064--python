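import numpy as np
import pandas as pd
import pytest

import soilhealth as sh
from soilhealth.indicators import IndicatorTable


@pytest.fixture
def default_table():
    """Default four-treatment synthetic experiment, fixed seed."""
    table, truth = sh.generate_indicator_table(sh.default_config(42))
    return table, truth


@pytest.fixture
def small_table():
    """Hand-built 6-sample, 4-indicator table with a perfectly correlated pair."""
    rng = np.random.default_rng(7)
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    frame = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "treatment": ["CK", "CK", "CK", "T", "T", "T"],
            "replicate": [1, 2, 3, 1, 2, 3],
            "A": a,
            "B": 2.0 * a + 1.0,  # rho(A, B) = 1
            "C": rng.permutation(a),
            "D": rng.permutation(a),
        }
    )
    return IndicatorTable(frame)
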