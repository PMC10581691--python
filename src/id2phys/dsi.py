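"""Depolarization-induced suppression of inhibition (DSI) quantification.

IPSC peak amplitude and 80→20% decay measurements on voltage-clamp traces,
and the per-cell / population summary of percent suppression across the
pre → depolarization → post → recovery trial protocol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError, Sweep, TruncationError, VOLTAGE_CLAMP, ModeError

PHASES = ("pre", "post", "recovery")
CONDITIONS = ("control", "AM251", "dp_plus", "dp_minus")


@dataclass
class PeakMeasurement:
    amplitude_pA: float            # outward positive, baseline-subtracted
    peak_time_ms: float
    no_response: bool


@dataclass
class DsiResult:
    """Per-cell DSI summary. percent_suppression = 100·(1 − post/pre)."""

    cell_id: str
    condition: str
    pre_mean: float
    post_mean: float
    recovery_mean: float
    percent_suppression: float
    n_reps: int
    recovered: bool


def ipsc_peak(
    sweep: Sweep,
    stim_time_ms: float,
    baseline_window_ms: float = 50.0,
    search_window_ms: float = 100.0,
) -> PeakMeasurement:
    """Peak outward IPSC amplitude after a light stimulus.

    Amplitude = max(trace − pre-stimulus baseline mean) in the search
    window (outward currents positive at the −50 mV holding potential).
    A non-positive result is clipped to 0 and flagged as no-response.
    """
    if sweep.mode != VOLTAGE_CLAMP:
        raise ModeError("IPSC measurement requires a voltage-clamp sweep")
    if not (0 <= stim_time_ms <= sweep.duration_ms):
        raise DomainError("stim_time outside the trace")
    i_stim = sweep.index(stim_time_ms)
    i_b0 = sweep.index(max(0.0, stim_time_ms - baseline_window_ms))
    baseline = float(np.mean(sweep.samples[i_b0:i_stim])) if i_stim > i_b0 else float(
        sweep.samples[0]
    )
    i_end = sweep.index(min(stim_time_ms + search_window_ms, sweep.duration_ms))
    seg = sweep.samples[i_stim : i_end + 1] - baseline
    k = int(np.argmax(seg))
    amp = float(seg[k])
    if amp <= 0:
        return PeakMeasurement(0.0, (i_stim + k) * sweep.dt, True)
    return PeakMeasurement(amp, (i_stim + k) * sweep.dt, False)


def decay_80_20(
    trace: np.ndarray,
    dt_ms: float,
    peak_index: int,
) -> float:
    """Decay time (ms) from 80% to 20% of the (baseline-subtracted) peak.

    Measured from the last downward crossing of the 80% level to the first
    subsequent crossing of the 20% level, with linear interpolation
    between samples. For an exponential decay with time constant τ this
    equals τ·ln 4.
    """
    v = np.asarray(trace, dtype=float)
    peak = v[peak_index]
    if peak <= 0:
        raise DomainError("peak amplitude must be positive (baseline-subtracted)")
    l80, l20 = 0.8 * peak, 0.2 * peak
    post = v[peak_index:]
    below20 = np.flatnonzero(post[1:] < l20)
    if below20.size == 0:
        raise TruncationError("trace never decays to 20% of peak")
    i20 = int(below20[0]) + 1  # first sample below the 20% level
    seg = post[: i20 + 1]
    down80 = np.flatnonzero((seg[:-1] >= l80) & (seg[1:] < l80))
    if down80.size == 0:
        raise DomainError("no downward crossing of the 80% level before 20%")
    i80 = int(down80[-1])
    t80 = i80 + (l80 - seg[i80]) / (seg[i80 + 1] - seg[i80])
    t20 = (i20 - 1) + (l20 - seg[i20 - 1]) / (seg[i20] - seg[i20 - 1])
    return (t20 - t80) * dt_ms


def dsi_summary(
    trials: pd.DataFrame,
    min_reps: int = 3,
) -> Tuple[pd.DataFrame, Dict]:
    """Per-cell and population DSI from a trial amplitude table.

    ``trials`` columns: cell_id, repetition, phase (pre/post/recovery),
    condition, amplitude. Suppression is computed per repetition as
    100·(1 − post/pre), then averaged within cell, then across cells.
    Cells with fewer than ``min_reps`` complete repetitions are excluded
    (with the reason logged in the summary). Population statistics per
    condition include mean ± SEM and paired pre-vs-post / recovery-vs-post
    t-tests; control-vs-AM251 is an unpaired contrast and dp+ vs dp− a
    paired one where cell ids match.
    """
    required = {"cell_id", "repetition", "phase", "condition", "amplitude"}
    missing = required - set(trials.columns)
    if missing:
        raise DomainError(f"trial table missing columns: {sorted(missing)}")
    rows, excluded = [], {}
    for (cell, cond), g in trials.groupby(["cell_id", "condition"], sort=True):
        wide = g.pivot_table(
            index="repetition", columns="phase", values="amplitude", aggfunc="mean"
        )
        ok = wide.dropna(subset=[p for p in ("pre", "post") if p in wide.columns])
        if "pre" not in wide.columns or "post" not in wide.columns or len(ok) < min_reps:
            excluded[str(cell)] = f"fewer than {min_reps} complete repetitions"
            continue
        supp = 100.0 * (1.0 - ok["post"] / ok["pre"])
        rec = float(ok["recovery"].mean()) if "recovery" in ok.columns else math.nan
        rows.append(
            DsiResult(
                cell_id=str(cell),
                condition=str(cond),
                pre_mean=float(ok["pre"].mean()),
                post_mean=float(ok["post"].mean()),
                recovery_mean=rec,
                percent_suppression=float(supp.mean()),
                n_reps=int(len(ok)),
                recovered=bool(rec > float(ok["post"].mean()))
                if not math.isnan(rec)
                else False,
            )
        )
    per_cell = pd.DataFrame([r.__dict__ for r in rows])
    summary: Dict = {"excluded": excluded, "conditions": {}}
    if per_cell.empty:
        return per_cell, summary

    for cond, g in per_cell.groupby("condition"):
        s = g["percent_suppression"].to_numpy()
        entry = {
            "n_cells": int(len(g)),
            "mean_suppression_pct": float(np.mean(s)),
            "sem_suppression_pct": float(np.std(s, ddof=1) / math.sqrt(len(s)))
            if len(s) > 1
            else math.nan,
        }
        if len(g) > 1:
            t_pp = stats.ttest_rel(g["pre_mean"], g["post_mean"])
            entry["p_pre_vs_post"] = float(t_pp.pvalue)
            if g["recovery_mean"].notna().all():
                t_rp = stats.ttest_rel(g["recovery_mean"], g["post_mean"])
                entry["p_recovery_vs_post"] = float(t_rp.pvalue)
        summary["conditions"][str(cond)] = entry

    by_cond = {c: g for c, g in per_cell.groupby("condition")}
    if "control" in by_cond and "AM251" in by_cond:
        t = stats.ttest_ind(
            by_cond["control"]["percent_suppression"],
            by_cond["AM251"]["percent_suppression"],
        )
        summary["p_control_vs_am251"] = float(t.pvalue)
    if "dp_plus" in by_cond and "dp_minus" in by_cond:
        a = by_cond["dp_plus"].set_index("cell_id")["percent_suppression"]
        b = by_cond["dp_minus"].set_index("cell_id")["percent_suppression"]
        common = a.index.intersection(b.index)
        if len(common) > 1:
            t = stats.ttest_rel(a.loc[common], b.loc[common])
            summary["p_dp_plus_vs_dp_minus"] = float(t.pvalue)
        elif len(a) > 1 and len(b) > 1:
            t = stats.ttest_ind(a, b)
            summary["p_dp_plus_vs_dp_minus"] = float(t.pvalue)
    return per_cell, summary
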