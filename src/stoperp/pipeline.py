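"""End-to-end orchestration: simulate a cohort, synthesize EEG, score
behavior and ERP components, and run the study's statistical analyses.

The master seed deterministically derives every module seed, so a full
run is byte-identical given (config, seed).  Outputs mirror the study's
reporting: a one-row-per-subject behavioral table, a component amplitude
table over the four stop-signal cells (SUCC/UNSUCC x EMO/NEU) and three
response cells (HIT, EMO error, NEU error), an ANOVA effects table
(F, p, partial eta^2), the two cross-subject regressions (raw
amplitudes; emotional-minus-neutral differences), and the SSRT-latency
correlation comparison via Steiger's Z.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import AnalysisError, ConfigurationError, ContractError
from .task import (
    EMO,
    NEU,
    PopulationParams,
    RaceModelParams,
    SessionConfig,
    SessionData,
    draw_subject_race_params,
    simulate_session,
)
from .behavior import behavioral_summary, summarize_cohort
from .eeg import (
    ERPPopulation,
    EEGRecording,
    NoiseConfig,
    SubjectERPParams,
    draw_subject_params,
    synthesize_session_eeg,
)
from .erp import (
    DEFAULT_COMPONENTS,
    RESPONSE_LOCK,
    STOP_LOCK,
    average_by_ssd_equal_weight,
    average_epochs,
    extract_epochs,
    mean_amplitude,
    peak_latency,
    reject_artifacts,
)
from . import stats as st

logger = logging.getLogger(__name__)

_CELLS_STOP = [(c, t) for t in ("SUCC", "UNSUCC") for c in (EMO, NEU)]


def _encode_keyed(d: dict) -> dict:
    return {k if isinstance(k, str) else "_".join(map(str, k)): v for k, v in d.items()}


def _decode_keyed(d: dict, tuple_keys: bool) -> dict:
    if not tuple_keys:
        return dict(d)
    return {tuple(k.split("_")): v for k, v in d.items()}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of a full run."""

    n_subjects: int = 32
    master_seed: int = 0
    session: SessionConfig = field(default_factory=SessionConfig)
    population: PopulationParams = field(default_factory=PopulationParams)
    erp_population: ERPPopulation = field(default_factory=ERPPopulation)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    min_per_bin: int = 1
    include_go_errors: bool = True
    steiger_variant: str = "updated"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.min_per_bin < 1:
            raise ConfigurationError("min_per_bin must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("n1_cell_means", "p3_cell_means", "ern_cond_means", "pe_cond_means",
                    "p3_latency_ms", "pe_latency_ms"):
            d["erp_population"][key] = _encode_keyed(d["erp_population"][key])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "session" in d and isinstance(d["session"], dict):
            d["session"] = SessionConfig(**d["session"])
        if "population" in d and isinstance(d["population"], dict):
            d["population"] = PopulationParams(**d["population"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseConfig(**d["noise"])
        if "erp_population" in d and isinstance(d["erp_population"], dict):
            ep = dict(d["erp_population"])
            for key, tuple_keys in (
                ("n1_cell_means", True), ("p3_cell_means", True),
                ("ern_cond_means", False), ("pe_cond_means", False),
                ("p3_latency_ms", False), ("pe_latency_ms", False),
            ):
                if key in ep:
                    ep[key] = _decode_keyed(ep[key], tuple_keys)
            d["erp_population"] = ERPPopulation(**ep)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SubjectRecord:
    subject: int
    race_params: RaceModelParams
    stop_shift: float
    session_seed: int
    erp_seed: int
    eeg_seed: int
    session: Optional[SessionData] = None
    erp_params: Optional[SubjectERPParams] = None


def build_cohort(config: PipelineConfig, simulate: bool = True) -> list:
    """Draw per-subject parameters and (optionally) run the sessions.

    All randomness descends from the master seed in a fixed order, so
    any stage can be reproduced independently.
    """
    rng = np.random.default_rng(config.master_seed)
    cohort = []
    for i in range(config.n_subjects):
        race_params, shift = draw_subject_race_params(config.population, rng)
        session_seed = int(rng.integers(2**31))
        erp_seed = int(rng.integers(2**31))
        eeg_seed = int(rng.integers(2**31))
        rec = SubjectRecord(i, race_params, shift, session_seed, erp_seed, eeg_seed)
        rec.erp_params = draw_subject_params(
            config.erp_population, erp_seed, stop_shift_ms=shift
        )
        if simulate:
            rec.session = simulate_session(config.session, race_params, session_seed)
        cohort.append(rec)
    return cohort


def score_subject_erp(
    session: SessionData,
    erp_params: SubjectERPParams,
    config: PipelineConfig,
    eeg_seed: int,
    recording: Optional[EEGRecording] = None,
) -> dict:
    """Synthesize (or take) one subject's EEG and score every component cell.

    Stop-locked cells use artifact rejection followed by equal-weight
    per-SSD collapsing; response-locked cells use plain averaging.
    """
    if recording is None:
        recording = synthesize_session_eeg(
            session, erp_params, config.noise, seed=eeg_seed,
            population=config.erp_population,
        )
    out: dict = {}

    stop_epochs = extract_epochs(recording, STOP_LOCK)
    stop_kept, stop_log = reject_artifacts(stop_epochs)
    resp_epochs = extract_epochs(recording, RESPONSE_LOCK)
    resp_kept, resp_log = reject_artifacts(resp_epochs)
    n_total = len(stop_log) + len(resp_log)
    out["rejected_fraction"] = (
        ((~stop_log["kept"]).sum() + (~resp_log["kept"]).sum()) / n_total
        if n_total else np.nan
    )

    n1_def, p3_def = DEFAULT_COMPONENTS["N1"], DEFAULT_COMPONENTS["P3"]
    ern_def, pe_def = DEFAULT_COMPONENTS["ERN"], DEFAULT_COMPONENTS["Pe"]

    labels = stop_kept.labels
    for cond, ttype in _CELLS_STOP:
        mask = (labels["condition"] == cond) & (labels["trial_type"] == ttype)
        cell = stop_kept.subset(mask.to_numpy())
        if len(cell) == 0:
            raise AnalysisError(f"empty stop cell {cond}/{ttype} after rejection")
        wave = average_by_ssd_equal_weight(cell, config.min_per_bin)
        out[f"n1_{cond}_{ttype}"] = mean_amplitude(wave, n1_def)
        out[f"p3_{cond}_{ttype}"] = mean_amplitude(wave, p3_def)
        if ttype == "UNSUCC":
            out[f"p3_lat_{cond}"] = peak_latency(wave, p3_def)

    unsucc = stop_kept.subset((labels["trial_type"] == "UNSUCC").to_numpy())
    wave_unsucc = average_by_ssd_equal_weight(unsucc, config.min_per_bin)
    out["n1_UNSUCC"] = mean_amplitude(wave_unsucc, n1_def)
    out["p3_UNSUCC"] = mean_amplitude(wave_unsucc, p3_def)

    rl = resp_kept.labels
    hit = resp_kept.subset((rl["trial_type"] == "HIT").to_numpy())
    if len(hit) == 0:
        raise AnalysisError("no HIT response epochs after rejection")
    wave_hit = average_epochs(hit)
    out["ern_HIT"] = mean_amplitude(wave_hit, ern_def)
    out["pe_HIT"] = mean_amplitude(wave_hit, pe_def)

    err_mask = (rl["trial_type"] == "UNSUCC").to_numpy()
    err = resp_kept.subset(err_mask)
    if len(err) == 0:
        raise AnalysisError("no error response epochs after rejection")
    wave_err = average_epochs(err)
    out["ern_ERROR"] = mean_amplitude(wave_err, ern_def)
    out["pe_ERROR"] = mean_amplitude(wave_err, pe_def)
    for cond in (EMO, NEU):
        cell = resp_kept.subset(((rl["trial_type"] == "UNSUCC")
                                 & (rl["condition"] == cond)).to_numpy())
        if len(cell) == 0:
            raise AnalysisError(f"no {cond} error epochs after rejection")
        wave = average_epochs(cell)
        out[f"ern_ERROR_{cond}"] = mean_amplitude(wave, ern_def)
        out[f"pe_ERROR_{cond}"] = mean_amplitude(wave, pe_def)
        out[f"pe_lat_{cond}"] = peak_latency(wave, pe_def)
    return out


def _anova_table_rows(scores: pd.DataFrame) -> list:
    """Table-1 shaped effects: F, p, partial eta^2 per component/effect."""
    n = len(scores)
    rows = []

    def cube(prefix):  # subjects x trial type (SUCC, UNSUCC) x condition (EMO, NEU)
        return np.stack(
            [
                np.column_stack(
                    [scores[f"{prefix}_{EMO}_{t}"], scores[f"{prefix}_{NEU}_{t}"]]
                )
                for t in ("SUCC", "UNSUCC")
            ],
            axis=1,
        )

    anovas = {name: st.rm_anova_2x2(cube(name.lower())) for name in ("N1", "P3")}
    for comp in ("N1", "P3"):
        e = anovas[comp].interaction
        rows.append(("Trial Type x Stop-Signal Condition", comp,
                     e.F, e.df_effect, e.df_error, e.p, e.partial_eta_sq))
    for comp in ("N1", "P3"):
        e = anovas[comp].factor_a
        rows.append(("Trial Type (SUCC vs. UNSUCC)", comp,
                     e.F, e.df_effect, e.df_error, e.p, e.partial_eta_sq))

    def one_way(x, y):  # two-level repeated factor: F = t^2 with df (1, n-1)
        t = st.paired_t(x, y)
        F = t.t**2
        return F, 1, t.df, t.p, st.partial_eta_sq(F, 1, t.df)

    for comp in ("ERN", "Pe"):
        key = comp.lower()
        rows.append(("Response Type (HIT vs. ERROR)", comp,
                     *one_way(scores[f"{key}_HIT"], scores[f"{key}_ERROR"])))
    for comp in ("N1", "P3"):
        e = anovas[comp].factor_b
        rows.append(("Stop-Signal Condition (EMO vs. NEU)", comp,
                     e.F, e.df_effect, e.df_error, e.p, e.partial_eta_sq))
    for comp in ("ERN", "Pe"):
        key = comp.lower()
        rows.append(("Error Response Condition (EMO vs. NEU)", comp,
                     *one_way(scores[f"{key}_ERROR_{EMO}"],
                              scores[f"{key}_ERROR_{NEU}"])))
    return rows


def _amplitude_table(scores: pd.DataFrame) -> pd.DataFrame:
    cells = []
    for comp in ("n1", "p3"):
        for cond, ttype in _CELLS_STOP:
            cells.append((comp.upper(), f"{cond} {ttype}",
                          scores[f"{comp}_{cond}_{ttype}"]))
    for comp in ("ern", "pe"):
        cells.append((comp.upper(), "HIT", scores[f"{comp}_HIT"]))
        cells.append((comp.upper(), "ERROR", scores[f"{comp}_ERROR"]))
        for cond in (EMO, NEU):
            cells.append((comp.upper(), f"{cond} ERROR",
                          scores[f"{comp}_ERROR_{cond}"]))
    return pd.DataFrame(
        [
            {"component": c, "cell": cell,
             "mean_uV": float(np.mean(v)), "sd_uV": float(np.std(v, ddof=1))}
            for c, cell, v in cells
        ]
    )


def _regression_row(res: st.RegressionResult, model: str) -> list:
    rows = [{"model": model, "term": "model", "beta": np.nan,
             "t": np.nan, "p": res.p_model, "R2": res.r_squared,
             "adj_R2": res.adj_r_squared, "F": res.F,
             "df1": res.df_model, "df2": res.df_resid}]
    for name, b, t, p in zip(res.predictor_names, res.betas, res.t_values,
                             res.p_values):
        rows.append({"model": model, "term": name, "beta": float(b),
                     "t": float(t), "p": float(p), "R2": np.nan,
                     "adj_R2": np.nan, "F": np.nan, "df1": np.nan, "df2": np.nan})
    return rows


@dataclass
class ReportTables:
    behavioral: pd.DataFrame
    behavioral_tests: pd.DataFrame
    amplitudes: pd.DataFrame
    effects: pd.DataFrame
    posthoc: pd.DataFrame
    regressions: pd.DataFrame
    correlations: pd.DataFrame
    normality: pd.DataFrame
    scores: pd.DataFrame
    run_log: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("behavioral", "behavioral_tests", "amplitudes", "effects",
                     "posthoc", "regressions", "correlations", "normality",
                     "scores"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)


def stats_tables(config: PipelineConfig, behav: pd.DataFrame,
                 scores: pd.DataFrame) -> dict:
    """The study's statistics layer on cohort-level tables."""
    n = len(behav)

    def t_row(var, x, y):
        r = st.paired_t(x, y)
        return {"variable": var, "mean_emo": float(np.mean(x)),
                "sd_emo": float(np.std(x, ddof=1)), "mean_neu": float(np.mean(y)),
                "sd_neu": float(np.std(y, ddof=1)), "t": r.t, "df": r.df,
                "p": r.p, "d_av": r.d_av, "d_z": r.d_z}

    behavioral_tests = pd.DataFrame([
        t_row("inhibition_rate", behav["inhibition_rate_emo"],
              behav["inhibition_rate_neu"]),
        t_row("mean_ssd", behav["mean_ssd_emo"], behav["mean_ssd_neu"]),
        t_row("ssrt", behav["ssrt_emo"], behav["ssrt_neu"]),
    ])

    effects = pd.DataFrame(
        _anova_table_rows(scores),
        columns=["effect", "component", "F", "df1", "df2", "p", "partial_eta_sq"],
    )

    # post-hoc EMO vs NEU within trial type, Bonferroni over the two tests
    posthoc_rows = []
    for comp in ("n1", "p3"):
        ps = []
        for ttype in ("SUCC", "UNSUCC"):
            r = st.paired_t(scores[f"{comp}_{EMO}_{ttype}"],
                            scores[f"{comp}_{NEU}_{ttype}"])
            posthoc_rows.append({"component": comp.upper(), "trial_type": ttype,
                                 "t": r.t, "df": r.df, "p": r.p,
                                 "d_av": r.d_av, "d_z": r.d_z})
            ps.append(r.p)
        adj = st.bonferroni(ps, m=2)
        for row, p_adj in zip(posthoc_rows[-2:], adj):
            row["p_bonferroni"] = float(p_adj)
    posthoc = pd.DataFrame(posthoc_rows)

    # regression model 1: raw amplitudes in failed-stop / error trials;
    # model 2: emotional-minus-neutral difference measures.  Degenerate
    # configurations (zero-variance inputs) skip the affected model.
    reg_rows = []
    pred_corr = np.nan
    model1 = st.ols_regression_standardized(
        scores["pe_ERROR"],
        {"P3_UNSUCC": scores["p3_UNSUCC"], "N1_UNSUCC": scores["n1_UNSUCC"]},
    )
    reg_rows += _regression_row(model1, "model1_raw")
    try:
        pred_corr = st.pearson_r(scores["p3_UNSUCC"], scores["n1_UNSUCC"]).r
    except AnalysisError:
        pass
    try:
        model2 = st.ols_regression_standardized(
            scores[f"pe_ERROR_{EMO}"] - scores[f"pe_ERROR_{NEU}"],
            {
                "dP3_UNSUCC": scores[f"p3_{EMO}_UNSUCC"] - scores[f"p3_{NEU}_UNSUCC"],
                "dN1_UNSUCC": scores[f"n1_{EMO}_UNSUCC"] - scores[f"n1_{NEU}_UNSUCC"],
            },
        )
        reg_rows += _regression_row(model2, "model2_diff")
    except AnalysisError as exc:
        logger.warning("difference-measure regression skipped: %s", exc)
    regressions = pd.DataFrame(reg_rows)
    regressions.attrs["predictor_corr_model1"] = pred_corr

    # SSRT vs component peak latency, compared across components per condition
    corr_rows = []
    for cond in (EMO, NEU):
        try:
            ssrt = behav[f"ssrt_{cond.lower()}"]
            p3_lat = scores[f"p3_lat_{cond}"]
            pe_lat = scores[f"pe_lat_{cond}"]
            r_p3 = st.pearson_r(ssrt, p3_lat)
            r_pe = st.pearson_r(ssrt, pe_lat)
            r_ll = st.pearson_r(p3_lat, pe_lat)
            zres = st.steiger_z(r_p3.r, r_pe.r, r_ll.r, n, config.steiger_variant)
        except (AnalysisError, ContractError):
            logger.warning("latency correlations undefined for %s", cond)
            continue
        corr_rows.append({"condition": cond, "pair": "SSRT~P3_latency",
                          "r": r_p3.r, "n": r_p3.n, "p": r_p3.p,
                          "steiger_Z": np.nan, "steiger_p": np.nan})
        corr_rows.append({"condition": cond, "pair": "SSRT~Pe_latency",
                          "r": r_pe.r, "n": r_pe.n, "p": r_pe.p,
                          "steiger_Z": np.nan, "steiger_p": np.nan})
        corr_rows.append({"condition": cond, "pair": "P3_vs_Pe_latency_corr_diff",
                          "r": r_ll.r, "n": n, "p": np.nan,
                          "steiger_Z": zres.Z, "steiger_p": zres.p})
    correlations = pd.DataFrame(
        corr_rows,
        columns=["condition", "pair", "r", "n", "p", "steiger_Z", "steiger_p"],
    )

    # normality screen of the variables entering t tests / regressions
    norm_rows = []
    for name, vals in (
        ("ssrt_emo", behav["ssrt_emo"]), ("ssrt_neu", behav["ssrt_neu"]),
        ("pe_ERROR", scores["pe_ERROR"]), ("p3_UNSUCC", scores["p3_UNSUCC"]),
        ("n1_UNSUCC", scores["n1_UNSUCC"]),
    ):
        try:
            D, p = st.ks_normality(vals)
        except (AnalysisError, ContractError):  # tiny cohort / zero variance
            D, p = np.nan, np.nan
        norm_rows.append({"variable": name, "D": D, "p": p})
    normality = pd.DataFrame(norm_rows)

    return {
        "behavioral_tests": behavioral_tests,
        "amplitudes": _amplitude_table(scores),
        "effects": effects,
        "posthoc": posthoc,
        "regressions": regressions,
        "correlations": correlations,
        "normality": normality,
    }


def run_pipeline(config: PipelineConfig, outdir=None) -> ReportTables:
    """Simulate, synthesize, score and analyze a full cohort."""
    t_start = time.time()
    cohort = build_cohort(config)
    behav = summarize_cohort(
        [rec.session for rec in cohort], include_go_errors=config.include_go_errors
    )
    score_rows = []
    for rec in cohort:
        logger.info("scoring subject %d", rec.subject)
        row = {"subject": rec.subject}
        row.update(
            score_subject_erp(rec.session, rec.erp_params, config, rec.eeg_seed)
        )
        score_rows.append(row)
    scores = pd.DataFrame(score_rows)

    tables = stats_tables(config, behav, scores)
    from . import __version__

    run_log = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "subject_seeds": [
            {"subject": r.subject, "session_seed": r.session_seed,
             "erp_seed": r.erp_seed, "eeg_seed": r.eeg_seed}
            for r in cohort
        ],
        "elapsed_s": round(time.time() - t_start, 2),
    }
    report = ReportTables(
        behavioral=behav, scores=scores, run_log=run_log, **tables
    )
    if outdir is not None:
        report.write(outdir)
    return report
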