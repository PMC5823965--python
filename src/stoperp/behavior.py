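"""Behavioral indices of stop-signal performance: inhibition rates,
condition-wise SSD means, and SSRT by the integration method.

SSRT follows the classical horse-race integration estimate: go RTs from
no-stop-signal trials are pooled and rank ordered, the n-th RT is taken
at n = ceil(p_respond * N), and the mean SSD is subtracted.  Condition
SSRTs use the condition-wise probability of responding and a
condition-wise SSD mean, where the emotional/neutral SSD is the mean of
the SSDs realized on the stop trial that directly follows each
emotional/neutral stop trial in the staircase (the initial SSD belongs
only to the global mean; the session's final stop trial has no
follower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ContractError
from .task import EMO, GO_ERROR, HIT, NEU, SUCC_STOP, SessionData

GLOBAL = "global"
_SCOPES = (GLOBAL, EMO, NEU)


def _stop_trials(session: SessionData, scope: str) -> list:
    if scope not in _SCOPES:
        raise ContractError(f"scope must be one of {_SCOPES}, got {scope!r}")
    stops = session.stop_trials
    if scope != GLOBAL:
        stops = [t for t in stops if t.condition == scope]
    return stops


def inhibition_rate(session: SessionData, scope: str = GLOBAL) -> float:
    """Percentage of successfully inhibited stop trials within scope."""
    stops = _stop_trials(session, scope)
    if not stops:
        raise AnalysisError(f"no stop trials in scope {scope!r}")
    n_succ = sum(t.outcome == SUCC_STOP for t in stops)
    return 100.0 * n_succ / len(stops)


def mean_ssd(session: SessionData, scope: str = GLOBAL) -> float:
    """Mean SSD.

    global: mean over all realized SSDs, including the initial one.
    EMO/NEU: mean of the SSDs realized on the stop trial immediately
    following each scope-category stop trial, regardless of the category
    of that following trial (the last stop trial contributes no
    follower).
    """
    stops = _stop_trials(session, GLOBAL)
    if not stops:
        raise AnalysisError("session has no stop trials")
    if scope == GLOBAL:
        return float(np.mean([t.ssd for t in stops]))
    followers = [
        nxt.ssd
        for cur, nxt in zip(stops, stops[1:])
        if cur.condition == scope
    ]
    if not followers:
        raise AnalysisError(f"no follower SSDs for scope {scope!r}")
    return float(np.mean(followers))


def estimate_ssrt(
    go_rts: Sequence[float], p_respond: float, mean_ssd: float
) -> tuple:
    """Integration-method SSRT.

    n = ceil(p_respond * N) clamped to [1, N]; returns (nth_rt, ssrt)
    with ssrt = nth_rt - mean_ssd.
    """
    rts = np.sort(np.asarray(go_rts, dtype=float))
    if rts.size == 0:
        raise AnalysisError("go RT distribution is empty")
    if not (0.0 <= p_respond <= 1.0):
        raise ContractError("p_respond must lie in [0, 1]")
    n = math.ceil(p_respond * rts.size)
    n = min(max(n, 1), rts.size)
    nth_rt = float(rts[n - 1])
    return nth_rt, nth_rt - float(mean_ssd)


@dataclass(frozen=True)
class BehavioralSummary:
    mean_go_rt: float
    go_error_rate: float  # percent of responded no-stop trials
    inhibition_rate_global: float
    inhibition_rate_emo: float
    inhibition_rate_neu: float
    p_respond_global: float
    p_respond_emo: float
    p_respond_neu: float
    mean_ssd_global: float
    mean_ssd_emo: float
    mean_ssd_neu: float
    nth_rt_global: float
    nth_rt_emo: float
    nth_rt_neu: float
    ssrt_global: float
    ssrt_emo: float
    ssrt_neu: float

    def as_dict(self) -> dict:
        return asdict(self)


def go_rt_distribution(session: SessionData, include_go_errors: bool = True) -> np.ndarray:
    """Go RTs entering the SSRT integration: responses on no-stop trials.

    By default all responded no-stop trials count (hits and choice
    errors); ``include_go_errors=False`` restricts to correct responses.
    """
    wanted = {HIT, GO_ERROR} if include_go_errors else {HIT}
    rts = [t.go_rt for t in session.go_trials if t.outcome in wanted]
    return np.asarray(rts, dtype=float)


def behavioral_summary(
    session: SessionData, include_go_errors: bool = True
) -> BehavioralSummary:
    """All behavioral quantities for one session."""
    rts = go_rt_distribution(session, include_go_errors=include_go_errors)
    if rts.size == 0:
        raise AnalysisError("no responded go trials")
    responded = [t for t in session.go_trials if t.go_rt is not None]
    n_err = sum(t.outcome == GO_ERROR for t in responded)
    go_error_rate = 100.0 * n_err / len(responded)

    out = {"mean_go_rt": float(np.mean(rts)), "go_error_rate": go_error_rate}
    for scope, tag in ((GLOBAL, "global"), (EMO, "emo"), (NEU, "neu")):
        inh = inhibition_rate(session, scope)
        p_resp = 1.0 - inh / 100.0
        ssd = mean_ssd(session, scope)
        nth, ssrt = estimate_ssrt(rts, p_resp, ssd)
        out[f"inhibition_rate_{tag}"] = inh
        out[f"p_respond_{tag}"] = p_resp
        out[f"mean_ssd_{tag}"] = ssd
        out[f"nth_rt_{tag}"] = nth
        out[f"ssrt_{tag}"] = ssrt
    return BehavioralSummary(**out)


def summarize_cohort(
    sessions: Iterable[SessionData], include_go_errors: bool = True
) -> pd.DataFrame:
    """One-row-per-subject behavioral summary table."""
    rows = []
    for i, session in enumerate(sessions):
        row = {"subject": i}
        row.update(behavioral_summary(session, include_go_errors).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
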