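"""Trial-level simulator for the emotional auditory stop-signal task.

The task is a binary-choice (left/right arrow) go task in which a random
25% of trials additionally present an aversive or neutral sound -- the
stop signal -- after a variable stop-signal delay (SSD).  The SSD follows
a single 1-up/1-down staircase shared by both sound conditions: +50 ms
after a successful inhibition, -50 ms after a failed one, clamped to
[100, 400] ms, starting at 150 ms.  Trial outcomes are produced by an
independent horse-race model: a response occurs on a stop trial iff the
go process finishes before SSD + stop latency.

A session is 8 blocks of 50 trials; the 100 stop trials are split evenly
between the emotional and neutral condition, each condition uses five
sounds, and each sound occurs equally often with the left and the right
arrow.  Consecutive stop-trial condition pairs (EE, EN, NE, NN) are kept
as close to equal counts as the odd number of transitions permits.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import AnalysisError, ConfigurationError, ContractError

# condition / outcome vocabulary
EMO = "EMO"
NEU = "NEU"
LEFT = "left"
RIGHT = "right"
ARROWS = (LEFT, RIGHT)

HIT = "HIT"
GO_ERROR = "GO_ERROR"
GO_OMISSION = "GO_OMISSION"
SUCC_STOP = "SUCC_STOP"
UNSUCC_STOP = "UNSUCC_STOP"

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


@dataclass(frozen=True)
class SessionConfig:
    """Static design parameters of one task session.

    All durations are milliseconds.  ``response_deadline_ms=None`` means
    the deadline is the end of the trial (onset of the next fixation).
    """

    n_blocks: int = 8
    trials_per_block: int = 50
    stop_fraction: float = 0.25
    ssd_min: float = 100.0
    ssd_max: float = 400.0
    ssd_step: float = 50.0
    ssd_init: float = 150.0
    n_sounds_per_condition: int = 5
    fixation_ms: float = 800.0
    go_duration_ms: float = 100.0
    stop_duration_ms: float = 100.0
    trial_duration_ms: float = 2000.0
    response_deadline_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("need at least one block and one trial per block")
        if not (0.0 < self.stop_fraction < 1.0):
            raise ConfigurationError("stop_fraction must lie strictly between 0 and 1")
        if not (self.ssd_min <= self.ssd_init <= self.ssd_max):
            raise ConfigurationError("require ssd_min <= ssd_init <= ssd_max")
        if self.ssd_step <= 0:
            raise ConfigurationError("ssd_step must be positive")
        span = self.ssd_max - self.ssd_min
        if abs(span / self.ssd_step - round(span / self.ssd_step)) > 1e-9:
            raise ConfigurationError("(ssd_max - ssd_min) must be divisible by ssd_step")
        init_off = (self.ssd_init - self.ssd_min) / self.ssd_step
        if abs(init_off - round(init_off)) > 1e-9:
            raise ConfigurationError("ssd_init must lie on the staircase lattice")
        n_stop = self.stop_fraction * self.n_trials
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ConfigurationError(
                "stop_fraction * total trial count must be an integer"
            )
        if round(n_stop) % 2 != 0:
            raise ConfigurationError("stop-trial count must split evenly in two conditions")
        if self.fixation_ms < 0 or self.trial_duration_ms <= self.fixation_ms:
            raise ConfigurationError("trial must be longer than the fixation period")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_stop_trials(self) -> int:
        return int(round(self.stop_fraction * self.n_trials))

    @property
    def ssd_values(self) -> np.ndarray:
        """All reachable staircase SSDs (inclusive lattice)."""
        n = int(round((self.ssd_max - self.ssd_min) / self.ssd_step))
        return self.ssd_min + self.ssd_step * np.arange(n + 1)

    @property
    def deadline_ms(self) -> float:
        if self.response_deadline_ms is not None:
            return self.response_deadline_ms
        return self.trial_duration_ms - self.fixation_ms

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class RaceModelParams:
    """Latency model for one subject.

    Go RTs are ex-Gaussian (mu, sigma, tau); the stop process latency is
    normal per condition, truncated at 1 ms to stay positive.
    """

    go_mu: float = 330.0
    go_sigma: float = 40.0
    go_tau: float = 45.0
    stop_mean_emo: float = 203.0
    stop_mean_neu: float = 217.0
    stop_sd: float = 30.0
    p_go_omission: float = 0.0
    p_go_error: float = 0.016

    def __post_init__(self) -> None:
        if min(self.go_mu, self.go_sigma, self.go_tau) < 0:
            raise ConfigurationError("ex-Gaussian parameters must be non-negative")
        if self.stop_mean_emo <= 0 or self.stop_mean_neu <= 0 or self.stop_sd < 0:
            raise ConfigurationError("stop latencies must be positive")
        for p in (self.p_go_omission, self.p_go_error):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("probabilities must lie in [0, 1]")

    def stop_mean(self, condition: str) -> float:
        return self.stop_mean_emo if condition == EMO else self.stop_mean_neu


@dataclass(frozen=True)
class StopTrialPlan:
    trial_index: int
    condition: str  # EMO | NEU
    sound_id: int  # 1..5 emotional, 6..10 neutral (defaults)
    arrow: str


@dataclass(frozen=True)
class StopSchedule:
    entries: tuple

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def conditions(self) -> list:
        return [e.condition for e in self.entries]

    @property
    def trial_indices(self) -> list:
        return [e.trial_index for e in self.entries]

    def pair_counts(self) -> dict:
        """Counts of ordered condition pairs of consecutive stop trials."""
        counts = {(a, b): 0 for a in (EMO, NEU) for b in (EMO, NEU)}
        cond = self.conditions
        for a, b in zip(cond, cond[1:]):
            counts[(a, b)] += 1
        return counts


def _balanced_condition_sequence(n_stop: int, rng: np.random.Generator) -> list:
    """Sequence of EMO/NEU over stop trials with near-equal ordered-pair counts.

    Built as a directed Eulerian trail on the two-node transition
    multigraph.  With ``n_stop`` even and S = n_stop, the pair counts are
    a permutation of {S/4, S/4, S/4, S/4 - 1} rounded to integers (for
    S = 100: {25, 25, 25, 24}), while each condition occurs exactly S/2
    times.  Which condition starts the trail is decided by the seed.
    """
    if n_stop == 0:
        return []
    if n_stop % 2:
        raise ConfigurationError("stop-trial count must be even")
    half = n_stop // 2
    first, second = (EMO, NEU) if rng.random() < 0.5 else (NEU, EMO)
    # pair counts: first->first = a, first->second = b, second->first = c,
    # second->second = d; Eulerian-trail balance requires b = c + 1 with the
    # trail starting at `first` and ending at `second`.
    b = max(1, int(round(n_stop / 4)))
    b = min(b, half)
    a = half - b
    c = b - 1
    d = half - b
    out = {
        first: [first] * a + [second] * b,
        second: [first] * c + [second] * d,
    }
    for node in out:
        edges = out[node]
        perm = rng.permutation(len(edges))
        out[node] = [edges[i] for i in perm]
    # Hierholzer's algorithm for the Eulerian trail
    stack = [first]
    trail: list = []
    while stack:
        v = stack[-1]
        if out[v]:
            stack.append(out[v].pop())
        else:
            trail.append(stack.pop())
    trail.reverse()
    assert len(trail) == n_stop
    return trail


def _sound_arrow_pool(count: int, n_sounds: int, rng: np.random.Generator) -> list:
    """(sound, arrow) assignments, each combination as equal as possible."""
    pairs = [(s, a) for s in range(1, n_sounds + 1) for a in ARROWS]
    base, rem = divmod(count, len(pairs))
    pool = pairs * base + [pairs[i] for i in rng.permutation(len(pairs))[:rem]]
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def build_stop_schedule(config: SessionConfig, seed: RngLike) -> StopSchedule:
    """Plan which trials carry a stop signal and with which sound/arrow.

    Deterministic for a given seed.  Satisfies: exact stop-trial count,
    even condition split, equal sound occurrences split equally between
    arrows (exactly when counts divide; otherwise as balanced as integer
    arithmetic permits), and near-equal ordered condition-pair counts.
    """
    rng = _as_rng(seed)
    n_stop = config.n_stop_trials
    indices = np.sort(rng.choice(config.n_trials, size=n_stop, replace=False))
    conditions = _balanced_condition_sequence(n_stop, rng)
    half = n_stop // 2
    pools = {
        EMO: _sound_arrow_pool(half, config.n_sounds_per_condition, rng),
        NEU: _sound_arrow_pool(half, config.n_sounds_per_condition, rng),
    }
    entries = []
    for idx, cond in zip(indices, conditions):
        sound, arrow = pools[cond].pop()
        if cond == NEU:
            sound += config.n_sounds_per_condition
        entries.append(StopTrialPlan(int(idx), cond, sound, arrow))
    return StopSchedule(tuple(entries))


def staircase_update(ssd: float, outcome: str, config: SessionConfig) -> float:
    """1-up/1-down SSD tracking: +step after SUCC_STOP, -step after UNSUCC_STOP,
    clamped to [ssd_min, ssd_max]."""
    lattice = config.ssd_values
    if not np.any(np.isclose(lattice, ssd)):
        raise ContractError(f"SSD {ssd} is not a legal staircase value")
    if outcome == SUCC_STOP:
        new = ssd + config.ssd_step
    elif outcome == UNSUCC_STOP:
        new = ssd - config.ssd_step
    else:
        raise ContractError(f"staircase outcome must be a stop outcome, got {outcome!r}")
    return float(min(max(new, config.ssd_min), config.ssd_max))


def race_trial(ssd: float, go_rt: float, stop_latency: float) -> str:
    """Independent horse race: a response escapes iff go_rt < ssd + stop_latency.

    Ties go to the stop process (they have measure zero under continuous
    latencies).
    """
    if min(ssd, go_rt, stop_latency) <= 0:
        raise ContractError("ssd, go_rt and stop_latency must be positive")
    return UNSUCC_STOP if go_rt < ssd + stop_latency else SUCC_STOP


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    block: int
    arrow: str
    is_stop: bool
    condition: Optional[str]  # EMO | NEU | None
    sound_id: Optional[int]
    ssd: Optional[float]
    go_rt: Optional[float]
    response: Optional[str]
    outcome: str


@dataclass(frozen=True)
class SessionData:
    """One simulated session: config/parameter snapshot plus ordered trials."""

    config: SessionConfig
    params: RaceModelParams
    trials: tuple
    seed: Optional[int] = None

    @property
    def stop_trials(self) -> list:
        return [t for t in self.trials if t.is_stop]

    @property
    def go_trials(self) -> list:
        return [t for t in self.trials if not t.is_stop]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        config: Optional[SessionConfig] = None,
        params: Optional[RaceModelParams] = None,
        seed: Optional[int] = None,
    ) -> "SessionData":
        trials = []
        for row in frame.itertuples(index=False):
            trials.append(
                TrialRecord(
                    trial_index=int(row.trial_index),
                    block=int(row.block),
                    arrow=str(row.arrow),
                    is_stop=bool(row.is_stop),
                    condition=None if pd.isna(row.condition) else str(row.condition),
                    sound_id=None if pd.isna(row.sound_id) else int(row.sound_id),
                    ssd=None if pd.isna(row.ssd) else float(row.ssd),
                    go_rt=None if pd.isna(row.go_rt) else float(row.go_rt),
                    response=None if pd.isna(row.response) else str(row.response),
                    outcome=str(row.outcome),
                )
            )
        return cls(
            config=config or SessionConfig(),
            params=params or RaceModelParams(),
            trials=tuple(trials),
            seed=seed,
        )

    @classmethod
    def from_csv(cls, path, config=None, params=None) -> "SessionData":
        return cls.from_frame(pd.read_csv(path), config=config, params=params)


def _draw_ex_gaussian(params: RaceModelParams, rng: np.random.Generator) -> float:
    rt = params.go_mu + params.go_sigma * rng.standard_normal()
    if params.go_tau > 0:
        rt += rng.exponential(params.go_tau)
    return max(rt, 1.0)


def _draw_stop_latency(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal stop latency truncated at 1 ms (rejection sampling)."""
    if sd == 0:
        return max(mean, 1.0)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= 1.0:
            return x
    return 1.0


def simulate_session(
    config: SessionConfig, params: RaceModelParams, seed: RngLike
) -> SessionData:
    """Run one session of the task under the race model.

    A single staircase threads through all stop trials in presentation
    order, starting at ``ssd_init``, regardless of condition.  Go trials
    draw an ex-Gaussian RT and apply omission/commission probabilities;
    responses slower than the deadline count as omissions.  A go omission
    on a stop trial counts as a successful stop (no response occurred).
    """
    rng = _as_rng(seed)
    seed_val = seed if isinstance(seed, int) else None
    schedule = build_stop_schedule(config, rng)
    plan_by_index = {e.trial_index: e for e in schedule.entries}
    deadline = config.deadline_ms

    ssd = config.ssd_init
    trials = []
    for t in range(config.n_trials):
        block = t // config.trials_per_block
        plan = plan_by_index.get(t)
        if plan is None:
            arrow = ARROWS[int(rng.random() < 0.5)]
            if rng.random() < params.p_go_omission:
                trials.append(
                    TrialRecord(t, block, arrow, False, None, None, None, None, None, GO_OMISSION)
                )
                continue
            rt = _draw_ex_gaussian(params, rng)
            if rt > deadline:
                trials.append(
                    TrialRecord(t, block, arrow, False, None, None, None, None, None, GO_OMISSION)
                )
                continue
            if rng.random() < params.p_go_error:
                response = ARROWS[1 - ARROWS.index(arrow)]
                outcome = GO_ERROR
            else:
                response = arrow
                outcome = HIT
            trials.append(
                TrialRecord(t, block, arrow, False, None, None, None, rt, response, outcome)
            )
        else:
            cond = plan.condition
            if rng.random() < params.p_go_omission:
                outcome = SUCC_STOP
                rt = None
                response = None
            else:
                go_rt = _draw_ex_gaussian(params, rng)
                stop_lat = _draw_stop_latency(params.stop_mean(cond), params.stop_sd, rng)
                outcome = race_trial(ssd, go_rt, stop_lat)
                if outcome == UNSUCC_STOP and go_rt > deadline:
                    outcome = SUCC_STOP  # escaped response landed after the deadline
                if outcome == UNSUCC_STOP:
                    rt = go_rt
                    if rng.random() < params.p_go_error:
                        response = ARROWS[1 - ARROWS.index(plan.arrow)]
                    else:
                        response = plan.arrow
                else:
                    rt = None
                    response = None
            trials.append(
                TrialRecord(
                    t, block, plan.arrow, True, cond, plan.sound_id, ssd, rt, response, outcome
                )
            )
            ssd = staircase_update(ssd, outcome, config)
    return SessionData(config=config, params=params, trials=tuple(trials), seed=seed_val)


@dataclass(frozen=True)
class PopulationParams:
    """Between-subject distribution of race-model parameters.

    Subject-level means are normal around the population means; the
    emotional/neutral stop-latency difference is a fixed within-subject
    offset, with a shared subject shift of SD ``stop_between_sd``.
    """

    go_mu_mean: float = 330.0
    go_mu_sd: float = 35.0
    go_sigma_mean: float = 40.0
    go_sigma_sd: float = 8.0
    go_tau_mean: float = 45.0
    go_tau_sd: float = 10.0
    stop_mean_emo: float = 203.0
    stop_mean_neu: float = 217.0
    stop_between_sd: float = 20.0
    stop_sd: float = 30.0
    p_go_omission: float = 0.0
    p_go_error: float = 0.016


def draw_subject_race_params(
    population: PopulationParams, rng: np.random.Generator
) -> tuple:
    """Draw one subject's RaceModelParams; returns (params, stop_shift_ms)."""
    shift = population.stop_between_sd * rng.standard_normal()
    params = RaceModelParams(
        go_mu=max(50.0, rng.normal(population.go_mu_mean, population.go_mu_sd)),
        go_sigma=max(0.0, rng.normal(population.go_sigma_mean, population.go_sigma_sd)),
        go_tau=max(0.0, rng.normal(population.go_tau_mean, population.go_tau_sd)),
        stop_mean_emo=max(20.0, population.stop_mean_emo + shift),
        stop_mean_neu=max(20.0, population.stop_mean_neu + shift),
        stop_sd=population.stop_sd,
        p_go_omission=population.p_go_omission,
        p_go_error=population.p_go_error,
    )
    return params, float(shift)


def simulate_cohort(
    n_subjects: int,
    population: PopulationParams = PopulationParams(),
    seed: RngLike = 0,
    config: SessionConfig = SessionConfig(),
) -> list:
    """Simulate ``n_subjects`` independent sessions with subject-level
    race parameters drawn from ``population``.  Reproducible by seed."""
    if n_subjects < 1:
        raise ContractError("n_subjects must be >= 1")
    rng = _as_rng(seed)
    sessions = []
    for _ in range(n_subjects):
        params, _shift = draw_subject_race_params(population, rng)
        session_seed = int(rng.integers(2**31))
        sessions.append(simulate_session(config, params, session_seed))
    return sessions
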