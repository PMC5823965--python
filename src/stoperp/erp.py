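"""Epoching, artifact rejection, equal-weight SSD subaveraging, and
component scoring.

Epoch windows: stimulus-locked -100..700 ms around stop-signal onset and
response-locked -150..600 ms around the key press.  The time-to-sample
mapping is: epoch start sample = round(t0 * fs / 1000) relative to the
lock event (which is sample 0 of the epoch time axis), epoch length =
round((t1 - t0) * fs / 1000) samples, so the -100..700 ms stop-locked
window at 256 Hz spans exactly 205 samples.  Analysis windows inside an
epoch map both endpoints with round() and are inclusive on both.

Trials with any value outside +/-65 uV are rejected.  Because the
go-evoked overlap inside a stop-locked epoch is a pure function of the
SSD, condition averages are formed by first averaging within each SSD
bin and then averaging the bin means with equal weight, which equates
the expected overlap across conditions with different SSD histograms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, ContractError
from .task import EMO, NEU, SUCC_STOP, UNSUCC_STOP, HIT, GO_ERROR
from . import eeg as _eeg

logger = logging.getLogger(__name__)

STOP_LOCK = "stop_onset"
RESPONSE_LOCK = "response"
GO_LOCK = "go_onset"

#: default epoch and baseline windows (ms) per lock
DEFAULT_WINDOWS = {
    STOP_LOCK: ((-100.0, 700.0), (-100.0, 0.0)),
    RESPONSE_LOCK: ((-150.0, 600.0), (-150.0, -50.0)),
    GO_LOCK: ((-100.0, 700.0), (-100.0, 0.0)),
}

_LOCK_CODES = {
    STOP_LOCK: (_eeg.STOP_EMO, _eeg.STOP_NEU),
    RESPONSE_LOCK: (_eeg.RESPONSE,),
    GO_LOCK: (_eeg.GO,),
}

_TRIAL_TYPE = {SUCC_STOP: "SUCC", UNSUCC_STOP: "UNSUCC", HIT: "HIT",
               GO_ERROR: "GO_ERROR", "GO_OMISSION": "GO_OMISSION"}


def ms_to_sample(ms: float, sfreq: float) -> int:
    """Nearest-sample mapping of a latency in ms (round to nearest)."""
    return int(np.rint(ms * sfreq / 1000.0))


@dataclass
class EpochSet:
    """Baseline-corrected epochs with per-epoch labels.

    ``data`` is (n_epochs, n_channels, n_times); ``start_sample`` is the
    index of the first sample relative to the lock event (lock = 0), so
    ``times_ms[i] = (start_sample + i) / sfreq * 1000``.
    """

    data: np.ndarray
    channel_names: tuple
    sfreq: float
    start_sample: int
    labels: pd.DataFrame  # trial_index, trial_type, condition, ssd
    lock: str
    baseline_window: tuple

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return (self.start_sample + np.arange(self.n_times)) / self.sfreq * 1000.0

    def subset(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels.loc[mask].reset_index(drop=True),
        )

    def save_npz(self, path) -> None:
        """Columnar persistence: array in npz, labels as a JSON sidecar."""
        np.savez_compressed(
            path, data=self.data.astype(np.float32), sfreq=self.sfreq,
            start_sample=self.start_sample,
            channel_names=np.array(self.channel_names),
            baseline_window=np.array(self.baseline_window), lock=self.lock,
        )
        self.labels.to_json(str(path) + ".labels.json", orient="records")

    @classmethod
    def load_npz(cls, path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as z:
            labels = pd.read_json(str(path) + ".labels.json", orient="records")
            return cls(
                data=z["data"].astype(float),
                channel_names=tuple(str(c) for c in z["channel_names"]),
                sfreq=float(z["sfreq"]),
                start_sample=int(z["start_sample"]),
                labels=labels,
                lock=str(z["lock"]),
                baseline_window=tuple(float(x) for x in z["baseline_window"]),
            )


def extract_epochs(
    recording: "_eeg.EEGRecording",
    lock: str,
    window_ms: Optional[tuple] = None,
    baseline_window_ms: Optional[tuple] = None,
) -> EpochSet:
    """Cut and baseline-correct epochs around all events of a lock type.

    Each epoch is corrected by subtracting, per channel, its mean over
    the baseline window.  Events too close to a recording edge are
    skipped with a logged warning; zero extractable epochs is an error.
    """
    if lock not in _LOCK_CODES:
        raise ContractError(f"unknown lock {lock!r}")
    default_win, default_base = DEFAULT_WINDOWS[lock]
    w0, w1 = window_ms if window_ms is not None else default_win
    b0, b1 = baseline_window_ms if baseline_window_ms is not None else default_base
    if not (w0 <= b0 <= b1 <= w1):
        raise ContractError("baseline window must lie inside the epoch window")

    fs = recording.sfreq
    start = ms_to_sample(w0, fs)
    n_times = ms_to_sample(w1 - w0, fs)
    if n_times < 1:
        raise ContractError("epoch window is empty at this sampling rate")

    codes = _LOCK_CODES[lock]
    sel = recording.events[recording.events["code"].isin(codes)]
    if sel.empty:
        raise AnalysisError(f"recording has no {lock!r} events")

    trial_info = None
    if recording.trial_table is not None:
        trial_info = recording.trial_table.set_index("trial_index")

    epochs, rows = [], []
    n_skipped = 0
    for ev in sel.itertuples(index=False):
        s0 = int(ev.sample) + start
        s1 = s0 + n_times
        if s0 < 0 or s1 > recording.n_samples:
            n_skipped += 1
            continue
        epochs.append(recording.data[:, s0:s1].copy())
        row = {"trial_index": int(ev.trial_index), "event_code": ev.code}
        if trial_info is not None and ev.trial_index in trial_info.index:
            t = trial_info.loc[ev.trial_index]
            row["trial_type"] = _TRIAL_TYPE.get(t["outcome"], t["outcome"])
            row["condition"] = t["condition"] if pd.notna(t["condition"]) else None
            row["ssd"] = float(t["ssd"]) if pd.notna(t["ssd"]) else np.nan
        rows.append(row)
    if n_skipped:
        msg = f"skipped {n_skipped} epoch(s) too close to a recording edge"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not epochs:
        raise AnalysisError("no extractable epochs")

    data = np.stack(epochs)
    # baseline correction: inclusive sample window per the mapping rule
    i0 = ms_to_sample(b0, fs) - start
    i1 = ms_to_sample(b1, fs) - start
    i1 = min(i1, n_times - 1)
    base = data[:, :, i0 : i1 + 1].mean(axis=2, keepdims=True)
    data = data - base
    return EpochSet(
        data=data,
        channel_names=recording.channel_names,
        sfreq=fs,
        start_sample=start,
        labels=pd.DataFrame(rows),
        lock=lock,
        baseline_window=(b0, b1),
    )


def reject_artifacts(epochs: EpochSet, threshold_uV: float = 65.0) -> tuple:
    """Drop epochs with any sample exceeding +threshold or below -threshold.

    Returns (kept EpochSet, log DataFrame with per-epoch verdicts).
    """
    if threshold_uV <= 0:
        raise ContractError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2)) if len(epochs) else np.empty(0)
    keep = peak <= threshold_uV
    log = epochs.labels.copy()
    log["max_abs_uV"] = peak
    log["kept"] = keep
    return epochs.subset(keep), log


@dataclass(frozen=True)
class ERPWaveform:
    """Averaged waveform (channels x time) with provenance."""

    data: np.ndarray
    channel_names: tuple
    sfreq: float
    start_sample: int
    n_epochs: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_epochs < 1:
            raise AnalysisError("an ERP average needs at least one epoch")
        if not np.all(np.isfinite(self.data)):
            raise AnalysisError("ERP waveform contains non-finite values")

    @property
    def times_ms(self) -> np.ndarray:
        return (self.start_sample + np.arange(self.data.shape[1])) / self.sfreq * 1000.0


def average_epochs(epochs: EpochSet, provenance: Optional[dict] = None) -> ERPWaveform:
    """Plain arithmetic mean over epochs (naive pooling)."""
    if len(epochs) == 0:
        raise AnalysisError("cannot average an empty EpochSet")
    return ERPWaveform(
        data=epochs.data.mean(axis=0),
        channel_names=epochs.channel_names,
        sfreq=epochs.sfreq,
        start_sample=epochs.start_sample,
        n_epochs=len(epochs),
        provenance=provenance or {"method": "pooled"},
    )


def average_by_ssd_equal_weight(epochs: EpochSet, min_per_bin: int = 1) -> ERPWaveform:
    """Equal-weight collapse of per-SSD subaverages.

    The mean waveform is computed within each SSD bin holding at least
    ``min_per_bin`` epochs; the bin means are then averaged without
    weighting by bin size, so unequal SSD histograms across conditions do
    not translate into unequal go-evoked overlap.
    """
    if "ssd" not in epochs.labels.columns:
        raise ContractError("epochs carry no SSD labels")
    ssds = epochs.labels["ssd"].to_numpy(dtype=float)
    if np.isnan(ssds).all():
        raise AnalysisError("no epochs with a defined SSD")
    bin_means, bins, counts = [], [], []
    for value in np.unique(ssds[~np.isnan(ssds)]):
        mask = ssds == value
        if mask.sum() >= min_per_bin:
            bin_means.append(epochs.data[mask].mean(axis=0))
            bins.append(float(value))
            counts.append(int(mask.sum()))
    if not bin_means:
        raise AnalysisError(f"no SSD bin holds >= {min_per_bin} epochs")
    return ERPWaveform(
        data=np.mean(bin_means, axis=0),
        channel_names=epochs.channel_names,
        sfreq=epochs.sfreq,
        start_sample=epochs.start_sample,
        n_epochs=int(sum(counts)),
        provenance={"method": "ssd_equal_weight", "bins": bins, "counts": counts},
    )


@dataclass(frozen=True)
class ComponentDefinition:
    """Scoring window, electrode cluster and polarity of one component."""

    name: str
    lock: str
    window_ms: tuple
    cluster: tuple
    polarity: int

    def __post_init__(self):
        if self.window_ms[0] > self.window_ms[1]:
            raise ConfigurationError("component window endpoints out of order")
        if self.polarity not in (-1, 1):
            raise ConfigurationError("polarity must be +1 or -1")


#: the study's component definitions
DEFAULT_COMPONENTS = {
    "N1": ComponentDefinition("N1", STOP_LOCK, (120.0, 190.0), _eeg.CLUSTERS["N1"], -1),
    "P3": ComponentDefinition("P3", STOP_LOCK, (270.0, 400.0), _eeg.CLUSTERS["P3"], +1),
    "ERN": ComponentDefinition("ERN", RESPONSE_LOCK, (0.0, 80.0), _eeg.CLUSTERS["ERN"], -1),
    "Pe": ComponentDefinition("Pe", RESPONSE_LOCK, (120.0, 270.0), _eeg.CLUSTERS["Pe"], +1),
}


def _window_slice(erp: ERPWaveform, comp: ComponentDefinition) -> slice:
    lo = ms_to_sample(comp.window_ms[0], erp.sfreq) - erp.start_sample
    hi = ms_to_sample(comp.window_ms[1], erp.sfreq) - erp.start_sample
    if lo < 0 or hi >= erp.data.shape[1]:
        raise ContractError(
            f"{comp.name} window {comp.window_ms} lies outside the epoch span"
        )
    return slice(lo, hi + 1)  # inclusive endpoints


def _cluster_indices(erp: ERPWaveform, comp: ComponentDefinition) -> list:
    idx = []
    for name in comp.cluster:
        if name not in erp.channel_names:
            raise ContractError(f"cluster channel {name!r} missing from waveform")
        idx.append(erp.channel_names.index(name))
    return idx


def mean_amplitude(erp: ERPWaveform, comp: ComponentDefinition) -> float:
    """Mean voltage over the component's cluster channels and window."""
    sl = _window_slice(erp, comp)
    idx = _cluster_indices(erp, comp)
    return float(erp.data[idx, sl].mean())


def peak_latency(erp: ERPWaveform, comp: ComponentDefinition) -> float:
    """Latency (ms from lock) of the polarity-appropriate extremum of the
    cluster-mean waveform inside the window; plateau ties break to the
    earliest sample."""
    sl = _window_slice(erp, comp)
    idx = _cluster_indices(erp, comp)
    wave = erp.data[idx].mean(axis=0)[sl]
    j = int(np.argmax(comp.polarity * wave))  # argmax returns the first max
    sample = erp.start_sample + sl.start + j
    return sample / erp.sfreq * 1000.0


@dataclass(frozen=True)
class ComponentScore:
    subject: int
    component: str
    condition: Optional[str]
    trial_type: str
    mean_amplitude_uV: float
    peak_latency_ms: float
    n_epochs: int
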