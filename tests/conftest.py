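import numpy as np
import pandas as pd
import pytest

from attnet.preprocessing import RunTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_run():
    """Small deterministic 3-ROI run for exact-value tests."""
    data = np.array(
        [
            [1.0, 2.0, 0.5],
            [2.0, 1.5, 1.0],
            [3.0, 3.5, -0.5],
            [4.0, 2.0, 2.0],
            [5.0, 4.5, 0.0],
            [6.0, 3.0, 1.5],
        ]
    )
    return RunTimeSeries(data, tr=2.0, roi_names=["a", "b", "c"])


@pytest.fixture
def balanced_mixed_table(rng):
    """3 groups x 10 subjects x 4 within levels with subject random effects."""
    rows = []
    for gi, g in enumerate(["A", "B", "C"]):
        for s in range(10):
            base = rng.normal()
            for w in range(4):
                rows.append(
                    {
                        "subject": f"{g}{s}",
                        "group": g,
                        "within": f"d{w}",
                        "value": base + 0.3 * gi * w + rng.normal(),
                    }
                )
    return pd.DataFrame(rows)
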