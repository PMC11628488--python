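import numpy as np
import pandas as pd
import pytest

from asmebci.erp import EpochSet
from asmebci.synthetic import simulate_session


@pytest.fixture(scope="session")
def small_session():
    """Scaled-down two-stream session at 250 Hz with the default SNR preset."""
    return simulate_session(
        "asme2stream",
        n_runs=2,
        trials_per_run=2,
        snr="default",
        fs=250.0,
        seed=11,
        n_stimuli_per_trial=120,
    )


def build_epochset(
    epochs: np.ndarray,
    fs: float = 250.0,
    t0: float = -0.1,
    channels=None,
    labels=None,
) -> EpochSet:
    """Assemble an EpochSet directly from an (epochs, channels, times) array."""
    n, n_ch, n_t = epochs.shape
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n_ch))
    times = t0 + np.arange(n_t) / fs
    if labels is None:
        labels = pd.DataFrame({"label": ["target"] * n, "role": ["deviant"] * n})
    if "stimulus_id" not in labels:
        labels = labels.assign(stimulus_id="D1", stream=1)
    return EpochSet(
        epochs=np.asarray(epochs, dtype=float),
        times=times,
        sampling_rate=fs,
        channels=tuple(channels),
        labels=labels.reset_index(drop=True),
        band=(1.0, 40.0),
    )
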