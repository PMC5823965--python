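"""Synthetic 32-channel EEG with planted ERP components.

Every trial of a simulated session contributes a go-locked evoked
response (whose overlap into stop-locked epochs is a pure function of
the SSD), stop trials add stop-locked N1 and P3 templates with
condition- and trial-type-specific amplitudes, and unsuccessfully
inhibited responses add response-locked ERN and Pe templates.  Templates
are Gaussian bumps in time (peak latency + FWHM) scaled by a fixed
topographic weight map that is maximal over the component's analysis
electrode cluster.  Background activity is a 1/f + white noise mixture;
occasional large square artifacts exercise the +/-65 uV rejection rule.

The cross-subject structure mirrors the study's regression finding: a
subject's Pe amplitude is a linear function of the subject's P3 and N1
amplitudes (standardized coefficients .82 and -.22, predictor
correlation .16) plus residual noise scaled so that the population
R^2 is ~.66.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .task import (
    EMO,
    GO_ERROR,
    HIT,
    NEU,
    SUCC_STOP,
    UNSUCC_STOP,
    RaceModelParams,
    SessionData,
    _as_rng,
)

SFREQ = 256.0

#: the 32 recording sites (extended 10-20 montage)
CHANNELS = (
    "Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6", "T7", "T8", "C3", "C4",
    "CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8",
    "PO3", "PO4", "O1", "O2", "Fz", "Cz", "Pz", "Oz",
)

#: analysis electrode clusters per component
CLUSTERS = {
    "N1": ("FC1", "FC2", "C3", "C4", "Cz", "CP1", "CP2"),
    "P3": ("Cz", "CP1", "CP2", "P3", "P4", "Pz"),
    "ERN": ("F3", "F4", "Fz", "FC1", "FC2", "C3", "C4", "Cz"),
    "Pe": ("Cz", "CP1", "CP2", "P3", "P4", "Pz"),
    "GoEvoked": ("Cz", "CP1", "CP2", "Pz"),
}

# event codes
GO = "GO"
STOP_EMO = "STOP_EMO"
STOP_NEU = "STOP_NEU"
RESPONSE = "RESPONSE"

SUCC = "SUCC"
UNSUCC = "UNSUCC"


def cluster_topography(cluster, off_weight: float = 0.3) -> np.ndarray:
    """Weight map: 1.0 over the cluster, ``off_weight`` elsewhere."""
    w = np.full(len(CHANNELS), off_weight)
    for name in cluster:
        w[CHANNELS.index(name)] = 1.0
    return w


def gaussian_bump(times_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    """Unit-amplitude temporal kernel; ``width_ms`` is the FWHM."""
    sigma = width_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((times_ms - peak_ms) / sigma) ** 2)


@dataclass(frozen=True)
class ComponentTemplate:
    """Shape and scaling of one planted component.

    ``amplitude_uV`` maps a cell key -- (condition, trial_type) for
    stop-locked components, condition for response-locked ones, or
    ``None`` for the go-evoked response -- to a signed amplitude.
    ``peak_latency_ms`` maps condition (or None) to the peak time
    relative to the lock event.
    """

    name: str
    lock: str  # go_onset | stop_onset | response
    peak_latency_ms: dict
    width_ms: float
    amplitude_uV: dict
    polarity: int
    topography: np.ndarray

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ConfigurationError("component width must be positive")


@dataclass(frozen=True)
class ERPPopulation:
    """Population-level ERP structure the generator emulates.

    Cell means follow the study's ordinal amplitude pattern (uV):
    emotional > neutral for N1 (more negative), P3 and Pe; ERN roughly
    equal across conditions.  ``beta_p3``/``beta_n1`` are the
    standardized coefficients linking a subject's Pe amplitude to the
    subject's P3 and N1 amplitudes; ``pe_resid_sd`` = sqrt(1 - R^2_pop)
    keeps the standardized Pe variance at 1 so fitted standardized betas
    estimate the generating ones directly.
    """

    n1_cell_means: dict = field(default_factory=lambda: {
        (NEU, UNSUCC): -1.3, (EMO, UNSUCC): -4.3,
        (NEU, SUCC): -5.1, (EMO, SUCC): -6.1,
    })
    p3_cell_means: dict = field(default_factory=lambda: {
        (NEU, UNSUCC): 13.6, (EMO, UNSUCC): 20.0,
        (NEU, SUCC): 18.8, (EMO, SUCC): 21.9,
    })
    ern_cond_means: dict = field(default_factory=lambda: {EMO: -4.1, NEU: -4.6})
    pe_cond_means: dict = field(default_factory=lambda: {EMO: 11.0, NEU: 6.4})
    go_evoked_amp: float = 8.0
    n1_between_sd: float = 6.0
    p3_between_sd: float = 7.0
    ern_between_sd: float = 4.0
    pe_between_sd: float = 5.5
    beta_p3: float = 0.82
    beta_n1: float = -0.22
    predictor_corr: float = 0.16
    pe_resid_sd: float = 0.5806  # sqrt(1 - population R^2 of ~.663)
    # emotional-enhancement structure: per-subject EMO-minus-NEU amplitude
    # differences, with the Pe difference linked to the P3/N1 differences
    dp3_between_sd: float = 3.0
    dn1_between_sd: float = 2.5
    dpe_between_sd: float = 3.5
    diff_beta_p3: float = 0.60
    diff_beta_n1: float = -0.22
    diff_predictor_corr: float = 0.33
    dpe_resid_sd: float = 0.8239  # sqrt(1 - population R^2 of ~.321)
    dern_between_sd: float = 2.0  # unlinked: the ERN condition effect is null
    n1_latency_ms: float = 155.0
    p3_latency_ms: dict = field(default_factory=lambda: {EMO: 337.4, NEU: 368.7})
    ern_latency_ms: float = 40.0
    pe_latency_ms: dict = field(default_factory=lambda: {EMO: 190.5, NEU: 217.9})
    go_evoked_latency_ms: float = 300.0
    p3_latency_resid_sd: float = 12.5
    p3_latency_stop_coupling: float = 0.5  # ms of latency per ms of subject stop shift
    pe_latency_sd: float = 27.0
    n1_width_ms: float = 60.0
    p3_width_ms: float = 120.0
    ern_width_ms: float = 50.0
    pe_width_ms: float = 140.0
    go_evoked_width_ms: float = 250.0

    def __post_init__(self):
        if self.pe_resid_sd < 0:
            raise ConfigurationError("residual scale must be >= 0")
        if not (-1.0 < self.predictor_corr < 1.0):
            raise ConfigurationError("predictor correlation must lie in (-1, 1)")
        for sd in (self.n1_between_sd, self.p3_between_sd,
                   self.ern_between_sd, self.pe_between_sd,
                   self.dn1_between_sd, self.dp3_between_sd,
                   self.dpe_between_sd, self.dpe_resid_sd,
                   self.dern_between_sd):
            if sd < 0:
                raise ConfigurationError("between-subject SDs must be >= 0")


@dataclass(frozen=True)
class SubjectERPParams:
    """Per-subject component amplitudes/latencies plus the latent
    standardized scores that generated them."""

    z_n1: float
    z_p3: float
    z_pe: float
    z_ern: float
    z_dn1: float
    z_dp3: float
    z_dpe: float
    z_dern: float
    n1_amps: dict  # (condition, trial_type) -> uV
    p3_amps: dict
    ern_amps: dict  # condition -> uV
    pe_amps: dict
    p3_latencies: dict  # condition -> ms
    pe_latencies: dict
    n1_latency: float
    ern_latency: float


def draw_subject_params(
    population: ERPPopulation,
    seed,
    stop_shift_ms: float = 0.0,
) -> SubjectERPParams:
    """Draw one subject's ERP parameters.

    ``stop_shift_ms`` is the subject's shared stop-latency deviation from
    the population mean; it shifts the P3 peak latency by
    ``p3_latency_stop_coupling`` ms/ms, so that slower stopping goes with
    a later failed-stop P3 (the latency-SSRT association the pipeline's
    correlation analyses probe).
    """
    rng = _as_rng(seed)
    rho = population.predictor_corr
    z_p3 = rng.standard_normal()
    z_n1 = rho * z_p3 + math.sqrt(1.0 - rho**2) * rng.standard_normal()
    z_pe = (
        population.beta_p3 * z_p3
        + population.beta_n1 * z_n1
        + population.pe_resid_sd * rng.standard_normal()
    )
    z_ern = rng.standard_normal()
    rho_d = population.diff_predictor_corr
    z_dp3 = rng.standard_normal()
    z_dn1 = rho_d * z_dp3 + math.sqrt(1.0 - rho_d**2) * rng.standard_normal()
    z_dpe = (
        population.diff_beta_p3 * z_dp3
        + population.diff_beta_n1 * z_dn1
        + population.dpe_resid_sd * rng.standard_normal()
    )
    z_dern = rng.standard_normal()
    lat_shift = (
        population.p3_latency_stop_coupling * stop_shift_ms
        + population.p3_latency_resid_sd * rng.standard_normal()
    )
    pe_lat_shift = population.pe_latency_sd * rng.standard_normal()
    def _cond_sign(key):  # +1 for EMO cells, -1 for NEU (symmetric split)
        cond = key[0] if isinstance(key, tuple) else key
        return 1.0 if cond == EMO else -1.0

    return SubjectERPParams(
        z_n1=float(z_n1),
        z_p3=float(z_p3),
        z_pe=float(z_pe),
        z_ern=float(z_ern),
        z_dn1=float(z_dn1),
        z_dp3=float(z_dp3),
        z_dpe=float(z_dpe),
        z_dern=float(z_dern),
        n1_amps={k: v + population.n1_between_sd * z_n1
                 + 0.5 * _cond_sign(k) * population.dn1_between_sd * z_dn1
                 for k, v in population.n1_cell_means.items()},
        p3_amps={k: v + population.p3_between_sd * z_p3
                 + 0.5 * _cond_sign(k) * population.dp3_between_sd * z_dp3
                 for k, v in population.p3_cell_means.items()},
        ern_amps={k: v + population.ern_between_sd * z_ern
                  + 0.5 * _cond_sign(k) * population.dern_between_sd * z_dern
                  for k, v in population.ern_cond_means.items()},
        pe_amps={k: v + population.pe_between_sd * z_pe
                 + 0.5 * _cond_sign(k) * population.dpe_between_sd * z_dpe
                 for k, v in population.pe_cond_means.items()},
        p3_latencies={k: v + lat_shift for k, v in population.p3_latency_ms.items()},
        pe_latencies={k: v + pe_lat_shift for k, v in population.pe_latency_ms.items()},
        n1_latency=population.n1_latency_ms,
        ern_latency=population.ern_latency_ms,
    )


def subject_templates(
    population: ERPPopulation, subject: SubjectERPParams
) -> list:
    """Materialize the five planted ComponentTemplates for one subject."""
    return [
        ComponentTemplate(
            "GoEvoked", "go_onset", {None: population.go_evoked_latency_ms},
            population.go_evoked_width_ms, {None: population.go_evoked_amp},
            +1, cluster_topography(CLUSTERS["GoEvoked"]),
        ),
        ComponentTemplate(
            "N1", "stop_onset",
            {EMO: subject.n1_latency, NEU: subject.n1_latency},
            population.n1_width_ms, dict(subject.n1_amps),
            -1, cluster_topography(CLUSTERS["N1"]),
        ),
        ComponentTemplate(
            "P3", "stop_onset", dict(subject.p3_latencies),
            population.p3_width_ms, dict(subject.p3_amps),
            +1, cluster_topography(CLUSTERS["P3"]),
        ),
        ComponentTemplate(
            "ERN", "response",
            {EMO: subject.ern_latency, NEU: subject.ern_latency},
            population.ern_width_ms, dict(subject.ern_amps),
            -1, cluster_topography(CLUSTERS["ERN"]),
        ),
        ComponentTemplate(
            "Pe", "response", dict(subject.pe_latencies),
            population.pe_width_ms, dict(subject.pe_amps),
            +1, cluster_topography(CLUSTERS["Pe"]),
        ),
    ]


@dataclass(frozen=True)
class NoiseConfig:
    """Additive background activity and artifact injection."""

    white_sd_uV: float = 3.0
    pink_sd_uV: float = 6.0
    artifact_probability: float = 0.06
    artifact_amplitude_uV: float = 150.0

    def __post_init__(self):
        if self.white_sd_uV < 0 or self.pink_sd_uV < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not (0.0 <= self.artifact_probability <= 1.0):
            raise ConfigurationError("artifact probability must lie in [0, 1]")
        if self.artifact_amplitude_uV <= 65.0:
            raise ConfigurationError(
                "artifact amplitude must exceed the 65 uV rejection threshold"
            )


@dataclass
class EEGRecording:
    """Continuous multichannel recording with event markers.

    ``events`` has columns (sample, code, trial_index); ``trial_table``
    is the session's trial table, carried along so epochs can be labeled
    with condition, trial type, and SSD.
    """

    channel_names: tuple
    sfreq: float
    data: np.ndarray  # channels x samples, microvolts
    events: pd.DataFrame
    trial_table: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.sfreq <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError("channel count mismatch")
        if len(self.events) and (
            self.events["sample"].min() < 0
            or self.events["sample"].max() >= self.data.shape[1]
        ):
            raise ConfigurationError("event sample index outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            data=self.data.astype(np.float32),
            sfreq=self.sfreq,
            channel_names=np.array(self.channel_names),
            event_sample=self.events["sample"].to_numpy(),
            event_code=self.events["code"].to_numpy().astype(str),
            event_trial=self.events["trial_index"].to_numpy(),
        )

    @classmethod
    def load_npz(cls, path, trial_table=None) -> "EEGRecording":
        with np.load(path, allow_pickle=False) as z:
            events = pd.DataFrame(
                {
                    "sample": z["event_sample"].astype(int),
                    "code": z["event_code"].astype(str),
                    "trial_index": z["event_trial"].astype(int),
                }
            )
            return cls(
                channel_names=tuple(str(c) for c in z["channel_names"]),
                sfreq=float(z["sfreq"]),
                data=z["data"].astype(float),
                events=events,
                trial_table=trial_table,
            )

    def events_to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


def pink_noise(n_channels: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise per channel (spectral shaping of white noise)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / SFREQ)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec /= np.sqrt(freqs)
    shaped = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _ms_to_samples(ms: float, sfreq: float = SFREQ) -> int:
    return int(np.rint(ms * sfreq / 1000.0))


def _add_bump(
    data: np.ndarray,
    center_sample: int,
    amplitude: float,
    width_ms: float,
    topography: np.ndarray,
    sfreq: float = SFREQ,
) -> None:
    """Add amplitude * kernel * topography in place, clipped to the record."""
    half = _ms_to_samples(3.0 * width_ms, sfreq)  # +/-3 sigma-ish support
    lo = max(center_sample - half, 0)
    hi = min(center_sample + half + 1, data.shape[1])
    if hi <= lo:
        return
    t_ms = (np.arange(lo, hi) - center_sample) * 1000.0 / sfreq
    kernel = gaussian_bump(t_ms, 0.0, width_ms)
    data[:, lo:hi] += amplitude * topography[:, None] * kernel[None, :]


def synthesize_session_eeg(
    session: SessionData,
    subject: SubjectERPParams,
    noise: NoiseConfig = NoiseConfig(),
    seed=0,
    population: ERPPopulation = ERPPopulation(),
    pad_ms: float = 1000.0,
) -> EEGRecording:
    """Render one session's EEG.

    Per trial: the go-evoked template at go onset; for stop trials the
    stop-locked N1 + P3 with condition/trial-type cell amplitudes; for
    unsuccessfully inhibited responses the response-locked ERN + Pe.
    Event markers are written at go onset, stop onset (condition coded)
    and the response sample.  With probability
    ``noise.artifact_probability`` a trial receives a square artifact of
    ``artifact_amplitude_uV`` on one random channel spanning the trial.
    """
    rng = _as_rng(seed)
    cfg = session.config
    trial_samples = _ms_to_samples(cfg.trial_duration_ms)
    pad = _ms_to_samples(pad_ms)
    n_samples = pad + trial_samples * cfg.n_trials + pad

    n_ch = len(CHANNELS)
    data = np.zeros((n_ch, n_samples))
    if noise.pink_sd_uV > 0:
        data += noise.pink_sd_uV * pink_noise(n_ch, n_samples, rng)
    if noise.white_sd_uV > 0:
        data += noise.white_sd_uV * rng.standard_normal((n_ch, n_samples))

    templates = {t.name: t for t in subject_templates(population, subject)}
    go_t = templates["GoEvoked"]
    events = []

    for trial in session.trials:
        t0 = pad + trial.trial_index * trial_samples
        go_sample = t0 + _ms_to_samples(cfg.fixation_ms)
        events.append((go_sample, GO, trial.trial_index))
        _add_bump(
            data, go_sample + _ms_to_samples(go_t.peak_latency_ms[None]),
            go_t.amplitude_uV[None], go_t.width_ms, go_t.topography,
        )
        if trial.is_stop:
            cond = trial.condition
            stop_sample = go_sample + _ms_to_samples(trial.ssd)
            events.append((stop_sample, STOP_EMO if cond == EMO else STOP_NEU,
                           trial.trial_index))
            ttype = SUCC if trial.outcome == SUCC_STOP else UNSUCC
            for name in ("N1", "P3"):
                tmpl = templates[name]
                _add_bump(
                    data, stop_sample + _ms_to_samples(tmpl.peak_latency_ms[cond]),
                    tmpl.amplitude_uV[(cond, ttype)], tmpl.width_ms, tmpl.topography,
                )
        if trial.go_rt is not None:
            resp_sample = (t0 + _ms_to_samples(cfg.fixation_ms)
                           + _ms_to_samples(trial.go_rt))
            events.append((resp_sample, RESPONSE, trial.trial_index))
            if trial.outcome == UNSUCC_STOP:
                cond = trial.condition
                for name in ("ERN", "Pe"):
                    tmpl = templates[name]
                    _add_bump(
                        data,
                        resp_sample + _ms_to_samples(tmpl.peak_latency_ms[cond]),
                        tmpl.amplitude_uV[cond], tmpl.width_ms, tmpl.topography,
                    )
        if noise.artifact_probability > 0 and rng.random() < noise.artifact_probability:
            # broadband movement-like burst spanning the trial on one channel;
            # a burst (unlike a DC offset) survives baseline correction, so
            # every epoch cut from this trial exceeds the rejection threshold
            ch = int(rng.integers(n_ch))
            data[ch, t0 : t0 + trial_samples] += (
                noise.artifact_amplitude_uV * rng.standard_normal(trial_samples)
            )

    events_df = pd.DataFrame(events, columns=["sample", "code", "trial_index"])
    events_df = events_df.sort_values("sample", kind="stable").reset_index(drop=True)
    return EEGRecording(
        channel_names=CHANNELS,
        sfreq=SFREQ,
        data=data,
        events=events_df,
        trial_table=session.to_frame(),
    )
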