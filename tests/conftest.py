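import numpy as np
import pytest

from mfwarn.features import CumulantSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_series(
    n_channels=3,
    n_windows=40,
    step=15.0,
    c1=None,
    c2=None,
    valid=None,
    labels=None,
):
    """A fabricated CumulantSeries for tests that do not need real signals."""
    starts = np.arange(n_windows) * step
    if c1 is None:
        c1 = np.zeros((n_channels, n_windows))
    if c2 is None:
        c2 = np.zeros((n_channels, n_windows))
    if valid is None:
        valid = np.ones((n_channels, n_windows), bool)
    if labels is None:
        labels = [f"CH{i}" for i in range(n_channels)]
    return CumulantSeries(
        window_starts=starts,
        c1=np.asarray(c1, float),
        c2=np.asarray(c2, float),
        valid=np.asarray(valid, bool),
        channel_labels=list(labels),
    )
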