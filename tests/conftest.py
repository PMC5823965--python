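import numpy as np
import pandas as pd
import pytest

import stoperp as sp
from stoperp.eeg import CHANNELS, CLUSTERS, cluster_topography, gaussian_bump
from stoperp.erp import STOP_LOCK, EpochSet


@pytest.fixture(scope="session")
def default_session():
    """One full default session (8 x 50 trials), fixed seed."""
    return sp.simulate_session(sp.SessionConfig(), sp.RaceModelParams(), seed=1234)


@pytest.fixture
def small_config():
    """A short session used where full length is not needed."""
    return sp.SessionConfig(n_blocks=2, trials_per_block=40)


def build_overlap_epochs(ssd_counts, rng, noise_sd=1.0, go_amp=8.0):
    """Stop-locked epochs with identical planted stop components but an
    SSD-dependent go-evoked overlap, for the overlap-equating check.

    ``ssd_counts`` maps SSD (ms) -> epoch count.  The go-evoked wave is a
    slow positivity peaking 300 ms after go onset (i.e. 300 - SSD relative
    to the stop signal), so its intrusion into the P3 scoring window is a
    pure function of the SSD.
    """
    fs = 256.0
    start, n_t = -26, 205
    times = (start + np.arange(n_t)) / fs * 1000.0
    p3_topo = cluster_topography(CLUSTERS["P3"])
    n1_topo = cluster_topography(CLUSTERS["N1"])
    go_topo = cluster_topography(CLUSTERS["GoEvoked"])
    stop_part = (
        20.0 * p3_topo[:, None] * gaussian_bump(times, 340.0, 120.0)[None, :]
        - 4.0 * n1_topo[:, None] * gaussian_bump(times, 155.0, 60.0)[None, :]
    )
    data, labels = [], []
    for ssd, count in ssd_counts.items():
        go_part = (
            go_amp * go_topo[:, None]
            * gaussian_bump(times, 300.0 - ssd, 250.0)[None, :]
        )
        for _ in range(count):
            x = stop_part + go_part + noise_sd * rng.standard_normal((32, n_t))
            x = x - x[:, :27].mean(axis=1, keepdims=True)  # -100..0 ms baseline
            data.append(x)
            labels.append({"trial_index": 0, "trial_type": "UNSUCC",
                           "condition": None, "ssd": float(ssd)})
    return EpochSet(
        data=np.stack(data), channel_names=CHANNELS, sfreq=fs,
        start_sample=start, labels=pd.DataFrame(labels), lock=STOP_LOCK,
        baseline_window=(-100.0, 0.0),
    )
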