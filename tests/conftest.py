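import numpy as np
import pandas as pd
import pytest

from gazebench import DEFAULT_SCREEN, GazeStream


@pytest.fixture
def geom():
    return DEFAULT_SCREEN


def make_stream(t_ms, x_px, y_px, confidence=None, validity=None,
                source="test", rate_hz=None):
    """Build a GazeStream from plain arrays (helper for tests)."""
    t = np.asarray(t_ms, float)
    n = t.size
    df = pd.DataFrame({
        "t_ms": t,
        "x_px": np.asarray(x_px, float),
        "y_px": np.asarray(y_px, float),
        "confidence": (np.full(n, np.nan) if confidence is None
                       else np.asarray(confidence, float)),
        "validity": (np.ones(n, bool) if validity is None
                     else np.asarray(validity, bool)),
    })
    if rate_hz is None:
        rate_hz = 1000.0 * (n - 1) / (t[-1] - t[0]) if n > 1 else 1.0
    return GazeStream(source=source, nominal_rate_hz=rate_hz, data=df)
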