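import numpy as np
import pandas as pd
import pytest

from itemprecision import ScaleSpec, ScoreTable


@pytest.fixture
def toy_long() -> pd.DataFrame:
    """Two items x three participants, one missing score."""
    return pd.DataFrame(
        {
            "participant": ["p1", "p2", "p3", "p1", "p2", "p3"],
            "item": ["a", "a", "a", "b", "b", "b"],
            "score": [1.0, 2.0, 3.0, 4.0, np.nan, 6.0],
        }
    )


@pytest.fixture
def toy_wide() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": ["p1", "p2", "p3"],
            "a": [1.0, 2.0, 3.0],
            "b": [4.0, np.nan, 6.0],
        }
    )


@pytest.fixture
def likert_pilot() -> ScoreTable:
    """Deterministic 12-item pilot on a 1-7 scale, 30 scores per item."""
    rng = np.random.default_rng(20240917)
    frames = []
    for i in range(12):
        scores = np.clip(np.round(rng.normal(4, 1 + 0.1 * i, 30)), 1, 7)
        frames.append(
            pd.DataFrame(
                {"participant": np.arange(30), "item": f"it{i}", "score": scores}
            )
        )
    return ScoreTable(
        pd.concat(frames, ignore_index=True), scale=ScaleSpec(1, 7, discrete=True)
    )
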