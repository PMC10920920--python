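"""End-to-end analysis pipeline: session files to machine-readable report.

Stages: read session data -> gait extraction and trial QC -> stride-phase
projection of behavioural events -> Fourier sweep with permutation nulls
(group and participant level) -> band counts and Bayesian prevalence ->
phase clustering (Rayleigh).  Every stage's event counts are recorded so
conservation can be audited, and all randomness derives from one master
seed, making reports byte-identical across reruns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular, gait, oscillation, prevalence, projection

MEASURES = ("accuracy", "rt", "response_likelihood")
BANDS = ("two_cps", "four_cps", "any")


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str = "analysis"
    n_bins: int = 40
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    measures: tuple = MEASURES
    participant_rule: str = "maxstat"        # or "perfreq"
    response_target_locked: bool = False     # alternative response measure
    pooled_group: bool = False               # pool events instead of averaging
    freq_step: float = 0.2
    freq_max: float = 10.0

    def grid(self) -> np.ndarray:
        n = int(round(self.freq_max / self.freq_step))
        return np.round((np.arange(n) + 1) * self.freq_step, 10)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every config violation (not just the first)."""
    problems = []
    if not Path(config.data_dir).exists():
        problems.append(f"data_dir does not exist: {config.data_dir}")
    if config.n_perm < 1:
        problems.append("n_perm must be >= 1")
    if config.n_bins not in (20, 40, 100, 200):
        problems.append("n_bins must be one of 20, 40, 100, 200")
    if not (0 < config.alpha < 1):
        problems.append("alpha must be in (0, 1)")
    if config.freq_step <= 0 or config.freq_max <= config.freq_step:
        problems.append("invalid frequency grid")
    if config.participant_rule not in ("maxstat", "perfreq"):
        problems.append("participant_rule must be 'maxstat' or 'perfreq'")
    for m in config.measures:
        if m not in MEASURES:
            problems.append(f"unknown measure: {m}")
    return problems


REQUIRED_COLUMNS = {
    "frames.csv": ["participant_id", "trial_id", "condition", "t", "head_z"],
    "targets.csv": ["participant_id", "trial_id", "onset_s", "outcome"],
    "responses.csv": ["participant_id", "trial_id", "press_onset_s"],
}


@dataclass
class SessionData:
    frames: pd.DataFrame
    targets: pd.DataFrame
    responses: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def read_session(data_dir: str | Path) -> SessionData:
    """Load and schema-check the session CSVs.

    Missing files or columns raise with the file and column named; unknown
    columns are ignored with a warning.  Rows with non-finite head height
    are dropped here, which surfaces as a sampling gap caught by gait QC.
    """
    d = Path(data_dir)
    frames_needed = True
    dfs = {}
    for fname, cols in REQUIRED_COLUMNS.items():
        path = d / fname
        if not path.exists():
            if fname == "responses.csv":
                dfs[fname] = pd.DataFrame(columns=cols)
                continue
            raise FileNotFoundError(f"missing session file: {path}")
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{fname}: missing column(s) {missing}")
        extra = [c for c in df.columns if c not in cols
                 and not c.startswith(("head_", "gaze_"))
                 and c not in ("intensity", "quantile_level", "rt_s")]
        if extra:
            warnings.warn(f"{fname}: ignoring unknown column(s) {extra}",
                          stacklevel=2)
        dfs[fname] = df
    frames = dfs["frames.csv"]
    bad = ~np.isfinite(frames["head_z"].to_numpy(dtype=float))
    if bad.any():
        warnings.warn(f"frames.csv: dropping {int(bad.sum())} row(s) with "
                      "non-finite head_z (flagged for QC)", stacklevel=2)
        frames = frames.loc[~bad]
    manifest = {}
    mpath = d / "manifest.json"
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    return SessionData(frames=frames, targets=dfs["targets.csv"],
                       responses=dfs["responses.csv"], manifest=manifest)


@dataclass
class ParticipantData:
    """Per-participant event-level results of gait + projection stages."""

    participant_id: str
    n_trials: int = 0
    n_trials_accepted: int = 0
    stride_durations: list = field(default_factory=list)
    target_phase: list = field(default_factory=list)
    target_hit: list = field(default_factory=list)
    target_rt: list = field(default_factory=list)
    response_phase: list = field(default_factory=list)
    n_targets: int = 0
    n_targets_dropped: int = 0
    n_responses: int = 0
    n_responses_dropped: int = 0
    qc_reasons: dict = field(default_factory=dict)
    stride_rows: list = field(default_factory=list)
    curve_sum: np.ndarray | None = None
    curve_n: int = 0


def _extract_participant(
    pid: str,
    frames: pd.DataFrame,
    targets: pd.DataFrame,
    responses: pd.DataFrame,
    config: PipelineConfig,
) -> ParticipantData:
    """Gait extraction, QC and event phase assignment for one participant."""
    pdata = ParticipantData(participant_id=pid)
    walk = frames[frames["condition"] == "walk"]
    for trial_id, tf in walk.groupby("trial_id"):
        pdata.n_trials += 1
        trace = gait.HeadTrace(pid, int(trial_id),
                               tf["t"].to_numpy(dtype=float),
                               tf["head_z"].to_numpy(dtype=float))
        trace = gait.detrend_height(trace)
        troughs = gait.detect_troughs(trace)
        qc = gait.qc_trials(trace, troughs)
        if not qc.accepted:
            for r in qc.reasons:
                pdata.qc_reasons[r] = pdata.qc_reasons.get(r, 0) + 1
            continue
        pdata.n_trials_accepted += 1
        trough_times = trace.t[troughs]
        n_strides = (trough_times.size - 1) // 2
        strides = trough_times[:2 * n_strides + 1:2]
        pdata.stride_durations.extend(np.diff(strides).tolist())
        for k in range(n_strides):
            pdata.stride_rows.append({
                "participant_id": pid, "trial_id": int(trial_id),
                "start_s": float(trough_times[2 * k]),
                "mid_s": float(trough_times[2 * k + 1]),
                "end_s": float(trough_times[2 * k + 2]),
                "duration_s": float(trough_times[2 * k + 2]
                                    - trough_times[2 * k]),
            })
        for ep in gait.epoch_strides(troughs, trace, mode="overlap"):
            try:
                curve = gait.resample_stride(ep, trace)
            except ValueError:
                continue
            if pdata.curve_sum is None:
                pdata.curve_sum = np.zeros_like(curve)
            pdata.curve_sum += curve
            pdata.curve_n += 1

        tt = targets[targets["trial_id"] == trial_id]
        if len(tt):
            asg = projection.assign_stride_phase(
                tt["onset_s"].to_numpy(dtype=float), trough_times)
            hit = (tt["outcome"].to_numpy() == "hit").astype(float)
            rt = (tt["rt_s"].to_numpy(dtype=float)
                  if "rt_s" in tt.columns else np.full(len(tt), np.nan))
            keep = asg.kept
            pdata.n_targets += len(tt)
            pdata.n_targets_dropped += asg.n_dropped
            pdata.target_phase.extend(asg.phase_pct[keep].tolist())
            pdata.target_hit.extend(hit[keep].tolist())
            pdata.target_rt.extend(rt[keep].tolist())
        rr = responses[responses["trial_id"] == trial_id]
        if len(rr):
            asg = projection.assign_stride_phase(
                rr["press_onset_s"].to_numpy(dtype=float), trough_times)
            pdata.n_responses += len(rr)
            pdata.n_responses_dropped += asg.n_dropped
            pdata.response_phase.extend(
                asg.phase_pct[asg.kept].tolist())
    return pdata


def _participant_events(
    pdata: ParticipantData, measure: str, config: PipelineConfig,
) -> oscillation.ParticipantEvents | None:
    phase = np.asarray(pdata.target_phase)
    hit = np.asarray(pdata.target_hit)
    if measure == "accuracy":
        if phase.size == 0:
            return None
        return oscillation.ParticipantEvents(phase, hit)
    if measure == "rt":
        rt = np.asarray(pdata.target_rt)
        ok = (hit == 1) & ~np.isnan(rt)
        if ok.sum() == 0:
            return None
        return oscillation.ParticipantEvents(phase[ok], rt[ok])
    if measure == "response_likelihood":
        if config.response_target_locked:
            return oscillation.ParticipantEvents(phase, hit)
        rp = np.asarray(pdata.response_phase)
        if rp.size == 0:
            return None
        return oscillation.ParticipantEvents(rp, None)
    raise ValueError(f"unknown measure {measure}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the JSON report plus CSV sidecars.

    Returns the report dict.  Identical config and seed produce a
    byte-identical report file.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    session = read_session(config.data_dir)
    pids = sorted(session.frames["participant_id"].unique())

    seed_root = np.random.SeedSequence(config.seed)
    group_seeds = seed_root.spawn(len(config.measures))
    part_seeds = seed_root.spawn(len(pids))

    participants: dict[str, ParticipantData] = {}
    for pid in pids:
        participants[pid] = _extract_participant(
            pid,
            session.frames[session.frames["participant_id"] == pid],
            session.targets[session.targets["participant_id"] == pid],
            session.responses[session.responses["participant_id"] == pid],
            config,
        )

    report: dict = {
        "config": asdict(config),
        "participants": {},
        "group": {},
        "prevalence": {},
        "phase_clustering": {},
        "conservation": {},
    }
    sweep_rows, part_rows, phase_rows, series_rows = [], [], [], []

    for pid, pdata in participants.items():
        report["participants"][pid] = {
            "n_trials": pdata.n_trials,
            "n_trials_accepted": pdata.n_trials_accepted,
            "qc_reasons": pdata.qc_reasons,
            "n_targets": pdata.n_targets,
            "n_targets_dropped": pdata.n_targets_dropped,
            "n_responses": pdata.n_responses,
            "n_responses_dropped": pdata.n_responses_dropped,
            "mean_stride_s": (round(float(np.mean(pdata.stride_durations)), 6)
                              if pdata.stride_durations else None),
            "measures": {},
        }

    results_by_measure: dict[str, list[oscillation.ParticipantResult]] = {}
    sweeps_by_measure: dict[str, dict[str, oscillation.SweepResult]] = {}
    for mi, measure in enumerate(config.measures):
        statistic = ("density" if (measure == "response_likelihood"
                                   and not config.response_target_locked)
                     else "mean")
        events = {pid: _participant_events(participants[pid], measure, config)
                  for pid in pids}
        have = [pid for pid in pids if events[pid] is not None]
        if not have:
            continue

        gs = oscillation.group_series(
            [events[p] for p in have], config.n_bins, statistic,
            measure=measure, pooled=config.pooled_group)
        g_sweep = oscillation.sweep(gs, grid)
        g_null = oscillation.permutation_null(
            [events[p] for p in have], config.n_bins, statistic,
            config.n_perm, np.random.default_rng(group_seeds[mi]),
            level="group", grid=grid)
        ranges = oscillation.significant_ranges(g_sweep, g_null)
        report["group"][measure] = {
            "best_freq_cps": g_sweep.best_freq,
            "best_r2": round(float(np.nanmax(g_sweep.r2_by_freq)), 6),
            "crit95": round(g_null.crit95, 6),
            "significant_ranges_cps": [[lo, hi] for lo, hi in ranges],
            "amplitude": round(g_sweep.best_fit.amplitude, 6),
            "phase_rad": round(g_sweep.best_fit.phi, 6),
            "n_participants": len(have),
        }
        for w, r2 in zip(grid, g_sweep.r2_by_freq):
            sweep_rows.append({"level": "group", "participant_id": "GROUP",
                               "measure": measure, "freq_cps": float(w),
                               "r2": float(r2)})
        for c, v, n in zip(gs.bin_centers, gs.values, gs.counts):
            series_rows.append({"participant_id": "GROUP", "measure": measure,
                                "n_bins": config.n_bins,
                                "bin_center_pct": float(c),
                                "value": float(v) if np.isfinite(v) else "",
                                "count": float(n)})

        # participant level
        m_results = []
        m_sweeps = {}
        for pi, pid in enumerate(pids):
            ev = events[pid]
            if ev is None:
                continue
            ps = oscillation.sweep(
                projection.bin_series(ev.phase_pct, ev.values, config.n_bins,
                                      statistic, measure=measure), grid)
            rng_p = np.random.default_rng(
                part_seeds[pi].spawn(len(config.measures))[mi])
            pnull = oscillation.permutation_null(
                [ev], config.n_bins, statistic, config.n_perm, rng_p,
                level="participant", grid=grid)
            res = oscillation.participant_test(
                pid, measure, ps, pnull, config.alpha,
                config.participant_rule)
            m_results.append(res)
            m_sweeps[pid] = ps
            report["participants"][pid]["measures"][measure] = {
                "best_freq_cps": res.best_freq,
                "best_r2": round(res.best_r2, 6),
                "significant": res.significant,
                "band": res.band,
            }
            part_rows.append({"participant_id": pid, "measure": measure,
                              "best_freq_cps": res.best_freq,
                              "best_r2": res.best_r2,
                              "significant": res.significant,
                              "band": res.band})
            for w, r2 in zip(grid, ps.r2_by_freq):
                sweep_rows.append({"level": "participant",
                                   "participant_id": pid, "measure": measure,
                                   "freq_cps": float(w), "r2": float(r2)})
        results_by_measure[measure] = m_results
        sweeps_by_measure[measure] = m_sweeps

        # prevalence per band
        n = len(m_results)
        prev = {}
        for band in BANDS:
            if band == "any":
                k = sum(r.significant for r in m_results)
            else:
                k = sum(r.band == band for r in m_results)
            post = prevalence.prevalence_posterior(k, n, config.alpha)
            prev[band] = {"k": k, "n": n, "map": round(post.map, 4),
                          "hpdi": [round(post.hpdi_low, 4),
                                   round(post.hpdi_high, 4)]}
        report["prevalence"][measure] = prev

        # phase clustering at 2 cps among two_cps-significant participants
        two = [r.participant_id for r in m_results if r.band == "two_cps"]
        angles = []
        for pid in two:
            ev = events[pid]
            fit = oscillation.fit_fixed_frequency(
                projection.bin_series(ev.phase_pct, ev.values, config.n_bins,
                                      statistic), 2.0)
            angles.append(fit.phi)
            phase_rows.append({"participant_id": pid, "measure": measure,
                               "freq_cps": 2.0, "phase_rad": fit.phi})
        if len(angles) >= 4:
            ray = circular.rayleigh_test(np.array(angles))
            report["phase_clustering"][measure] = {
                "n": ray.n, "mean_angle_rad": round(ray.mean_angle, 4),
                "rbar": round(ray.rbar, 4), "z": round(ray.z, 4),
                "p": round(ray.p, 6),
                "circ_variance": round(ray.circ_variance, 4),
            }
        else:
            report["phase_clustering"][measure] = {
                "n": len(angles),
                "note": "too few phase-clustered participants for Rayleigh",
            }

    report["summary"] = oscillation.cohort_summary(results_by_measure)

    durations = {pid: float(np.mean(p.stride_durations))
                 for pid, p in participants.items() if p.stride_durations}
    if len(durations) >= 5 and "accuracy" in sweeps_by_measure:
        try:
            report["stride_duration_correlations"] = (
                oscillation.stride_duration_correlation(
                    durations, sweeps_by_measure["accuracy"]))
        except ValueError:
            pass

    total_targets = int(sum(p.n_targets for p in participants.values()))
    kept_targets = int(sum(p.n_targets - p.n_targets_dropped
                           for p in participants.values()))
    report["conservation"] = {
        "targets_total": total_targets,
        "targets_kept": kept_targets,
        "targets_dropped": total_targets - kept_targets,
        "responses_total": int(sum(p.n_responses
                                   for p in participants.values())),
        "responses_dropped": int(sum(p.n_responses_dropped
                                     for p in participants.values())),
        "seed": config.seed,
    }

    stride_rows = [r for p in participants.values() for r in p.stride_rows]
    pd.DataFrame(stride_rows, columns=[
        "participant_id", "trial_id", "start_s", "mid_s", "end_s",
        "duration_s",
    ]).to_csv(out / "strides.csv", index=False, float_format="%.6f")
    curve_rows = []
    for pid, p in participants.items():
        if p.curve_n:
            for c, v in zip(gait.PHASE_GRID, p.curve_sum / p.curve_n):
                curve_rows.append({"participant_id": pid,
                                   "phase_pct": float(c),
                                   "mean_height_m": float(v)})
    pd.DataFrame(curve_rows, columns=[
        "participant_id", "phase_pct", "mean_height_m",
    ]).to_csv(out / "stride_curves.csv", index=False, float_format="%.6f")
    pd.DataFrame(sweep_rows).to_csv(out / "sweep.csv", index=False,
                                    float_format="%.8f")
    pd.DataFrame(part_rows).to_csv(out / "participants.csv", index=False,
                                   float_format="%.8f")
    pd.DataFrame(phase_rows).to_csv(out / "phases.csv", index=False,
                                    float_format="%.8f")
    pd.DataFrame(series_rows).to_csv(out / "binned_series.csv", index=False,
                                     float_format="%.8f")
    write_report(report, out / "report.json")
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Write the analysis report as JSON with a stable key order."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
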