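"""Intrinsic/active-property extraction from current-clamp sweep sets.

Implements the slice-physiology measurements used to characterize
neurogliaform-type interneurons: spike detection from the voltage
derivative, AP waveform properties, input resistance, membrane time
constant, rheobase, first-spike latency, adaptation index, ISI regularity,
firing-rate interpolation, and the late-spiking (LS) / irregular-spiking
(IS) / burst-spiking (BS) rule-based classification.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    CURRENT_CLAMP,
    ContaminationError,
    DomainError,
    ExtrapolationError,
    FitError,
    InsufficientSpikesError,
    ModeError,
    SubthresholdError,
    Sweep,
    TruncationError,
)

LS, IS, BS, UNCLASSIFIED = "LS", "IS", "BS", "UNCLASSIFIED"

#: dV/dt threshold defining the AP threshold crossing (mV/ms).
DVDT_THRESHOLD = 20.0
#: An AP must exceed its threshold crossing by this much within 2 ms (mV).
MIN_AP_AMPLITUDE = 20.0
#: Minimum separation between detected threshold crossings (ms).
REFRACTORY_MS = 1.0
#: First-ISI cut for a >100 Hz burst at rheobase (ms).
BURST_ISI_MS = 10.0
#: Latency bounds for the LS / IS split at rheobase (ms).
LS_LATENCY_MS = 500.0
IS_LATENCY_MS = 100.0


@dataclass
class APFeatures:
    """Waveform properties of one action potential (or a cell mean).

    ``fall_slope_mV_per_ms`` is the (negative) minimum dV/dt; use
    :attr:`fall_slope_magnitude` where a positive number is tabulated.
    """

    threshold_mV: float
    peak_mV: float
    halfwidth_ms: float
    ahp_mV: float
    rise_slope_mV_per_ms: float
    fall_slope_mV_per_ms: float
    threshold_time_ms: float
    peak_time_ms: float

    @property
    def fall_slope_magnitude(self) -> float:
        return abs(self.fall_slope_mV_per_ms)


@dataclass
class CellProfile:
    """Per-cell intrinsic/active parameters plus the firing-pattern class.

    Missing fields are NaN (or None for ``ap``) with the reason recorded in
    ``missing``.
    """

    rheobase_pA: float = math.nan
    input_resistance_MOhm: float = math.nan
    tau_ms: float = math.nan
    first_ap_latency_ms: float = math.nan
    latency_over_tau: float = math.nan
    ai_near: float = math.nan
    ai_2x: float = math.nan
    cv_isi_2x: float = math.nan
    firing_rate_2x_Hz: float = math.nan
    ap: Optional[APFeatures] = None
    firing_class: str = UNCLASSIFIED
    missing: Dict[str, str] = field(default_factory=dict)


def _dvdt(sweep: Sweep, smooth: bool = False) -> np.ndarray:
    """Central-difference dV/dt in mV/ms (endpoints one-sided)."""
    v = sweep.samples
    if smooth:
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (2.0 * sweep.dt)
    d[0] = (v[1] - v[0]) / sweep.dt
    d[-1] = (v[-1] - v[-2]) / sweep.dt
    return d


def detect_action_potentials(
    sweep: Sweep,
    dvdt_threshold: float = DVDT_THRESHOLD,
    min_ap_amplitude: float = MIN_AP_AMPLITUDE,
    refractory_ms: float = REFRACTORY_MS,
    smooth: bool = False,
) -> List[Tuple[float, float]]:
    """Detect APs as upward dV/dt crossings of ``dvdt_threshold``.

    A crossing counts as an AP only if the voltage within the following
    2 ms exceeds the crossing voltage by at least ``min_ap_amplitude`` mV.
    Returns ``(threshold_time_ms, peak_time_ms)`` per AP, with the peak at
    the voltage maximum in the 2 ms after the crossing.
    """
    if sweep.mode != CURRENT_CLAMP:
        raise ModeError("spike detection requires a current-clamp sweep")
    v = sweep.samples
    d = _dvdt(sweep, smooth=smooth)
    crossings = np.flatnonzero((d[:-1] < dvdt_threshold) & (d[1:] >= dvdt_threshold)) + 1
    win = max(1, int(round(2.0 / sweep.dt)))
    events: List[Tuple[float, float]] = []
    last_thr = -math.inf
    for i in crossings:
        t_thr = i * sweep.dt
        if t_thr - last_thr < refractory_ms:
            continue
        seg = v[i + 1 : i + 1 + win]
        if seg.size == 0:
            continue
        k = int(np.argmax(seg))
        if seg[k] - v[i] < min_ap_amplitude:
            continue
        t_peak = (i + 1 + k) * sweep.dt
        if events and t_peak <= events[-1][1]:
            continue  # overlapping windows resolved to the same peak
        events.append((t_thr, t_peak))
        last_thr = t_thr
    return events


def _interp_crossing(t0, t1, v0, v1, level):
    """Time where a line through (t0,v0)-(t1,v1) crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def ap_waveform_features(sweep: Sweep, event: Tuple[float, float]) -> APFeatures:
    """Measure one AP's waveform properties.

    Threshold = voltage at the dV/dt crossing; peak = max voltage within
    2 ms after it; half-width = total time above the threshold/peak
    midpoint around the peak (sub-sample via linear interpolation); AHP =
    threshold minus the minimum voltage within 10 ms after the peak;
    rise/fall slopes = max/min dV/dt within 10 ms after the crossing.
    """
    t_thr, t_peak = event
    v = sweep.samples
    dt = sweep.dt
    i_thr = sweep.index(t_thr)
    i_peak = sweep.index(t_peak)
    if t_peak + 10.0 > sweep.duration_ms - dt:
        raise TruncationError("AP within 10 ms of sweep end")

    threshold = float(v[i_thr])
    peak = float(v[i_peak])
    mid = 0.5 * (threshold + peak)

    # walk outwards from the peak to the first samples below the midpoint
    j = i_peak
    while j > 0 and v[j - 1] > mid:
        j -= 1
    k = i_peak
    while k < v.size - 1 and v[k + 1] > mid:
        k += 1
    t_up = _interp_crossing((j - 1) * dt, j * dt, v[j - 1], v[j], mid) if j > 0 else j * dt
    t_down = (
        _interp_crossing(k * dt, (k + 1) * dt, v[k], v[k + 1], mid)
        if k < v.size - 1
        else k * dt
    )
    halfwidth = t_down - t_up

    n10 = int(round(10.0 / dt))
    ahp_win = v[i_peak + 1 : i_peak + 1 + n10]
    ahp = threshold - float(np.min(ahp_win))

    d = _dvdt(sweep)
    slope_win = d[i_thr : i_thr + n10 + 1]
    rise = float(np.max(slope_win))
    fall = float(np.min(slope_win))

    return APFeatures(
        threshold_mV=threshold,
        peak_mV=peak,
        halfwidth_ms=halfwidth,
        ahp_mV=ahp,
        rise_slope_mV_per_ms=rise,
        fall_slope_mV_per_ms=fall,
        threshold_time_ms=t_thr,
        peak_time_ms=t_peak,
    )


def ap_summary(sweeps: Sequence[Sweep], max_ap_count: int = 50) -> APFeatures:
    """Cell-mean AP features over first APs of qualifying sweeps.

    Only the first AP of each sweep contributes, and only from sweeps whose
    total AP count is below ``max_ap_count`` (later APs in bursty cells
    widen; very dense trains are excluded entirely).
    """
    feats: List[APFeatures] = []
    for sw in sweeps:
        try:
            events = detect_action_potentials(sw)
        except ModeError:
            continue
        if not events or len(events) >= max_ap_count:
            continue
        try:
            feats.append(ap_waveform_features(sw, events[0]))
        except TruncationError:
            continue
    if not feats:
        raise InsufficientSpikesError("no qualifying first APs")
    mean = lambda attr: float(np.mean([getattr(f, attr) for f in feats]))
    return APFeatures(
        threshold_mV=mean("threshold_mV"),
        peak_mV=mean("peak_mV"),
        halfwidth_ms=mean("halfwidth_ms"),
        ahp_mV=mean("ahp_mV"),
        rise_slope_mV_per_ms=mean("rise_slope_mV_per_ms"),
        fall_slope_mV_per_ms=mean("fall_slope_mV_per_ms"),
        threshold_time_ms=mean("threshold_time_ms"),
        peak_time_ms=mean("peak_time_ms"),
    )


def input_resistance(
    sweep: Sweep, baseline_ms: float = 50.0, steady_ms: float = 50.0
) -> float:
    """Input resistance (MΩ) by Ohm's law from a hyperpolarizing step.

    ΔV is measured from the pre-step baseline mean to the mean over the
    last ``steady_ms`` of the step; R[MΩ] = 1000 · ΔV[mV] / ΔI[pA].
    """
    if sweep.mode != CURRENT_CLAMP:
        raise ModeError("input resistance requires a current-clamp sweep")
    if sweep.step_amplitude >= 0:
        raise DomainError("input resistance requires a negative current step")
    if sweep.step_duration_ms < 150.0:
        raise DomainError("input-resistance step must be >= 150 ms long")
    if detect_action_potentials(sweep):
        raise ContaminationError("spikes detected during the resistance step")
    i_on, i_off = sweep.index(sweep.step_onset), sweep.index(sweep.step_offset)
    i_b0 = sweep.index(max(0.0, sweep.step_onset - baseline_ms))
    baseline = float(np.mean(sweep.samples[i_b0:i_on])) if i_on > i_b0 else float(
        sweep.samples[0]
    )
    i_s0 = sweep.index(sweep.step_offset - steady_ms)
    steady = float(np.mean(sweep.samples[i_s0:i_off]))
    return 1000.0 * (steady - baseline) / sweep.step_amplitude


def membrane_time_constant(
    sweep: Sweep, fit_window_ms: float = 300.0
) -> float:
    """Membrane τ (ms) from an exponential fit to a subthreshold step.

    Fits V(t) = V∞ + A·exp(−t/τ) over ``[step_onset, step_onset +
    fit_window_ms]`` by least squares.
    """
    if sweep.mode != CURRENT_CLAMP:
        raise ModeError("membrane τ requires a current-clamp sweep")
    if sweep.step_duration_ms < 1000.0 - 1e-6:
        raise DomainError("membrane-τ step must be >= 1 s long")
    if detect_action_potentials(sweep):
        raise ContaminationError("suprathreshold sweep passed to membrane τ fit")
    i_on = sweep.index(sweep.step_onset)
    i_end = sweep.index(min(sweep.step_onset + fit_window_ms, sweep.step_offset))
    t = (np.arange(i_on, i_end) - i_on) * sweep.dt
    v = sweep.samples[i_on:i_end]
    v_inf0 = float(np.mean(v[-max(5, v.size // 10):]))
    a0 = float(v[0] - v_inf0)
    if abs(a0) < 0.25:
        raise FitError("no measurable step transient", data=(t, v))
    try:
        popt, _ = curve_fit(
            lambda tt, vinf, a, tau: vinf + a * np.exp(-tt / tau),
            t,
            v,
            p0=(v_inf0, a0, 15.0),
            bounds=([-200.0, -200.0, 0.1], [100.0, 200.0, 500.0]),
            maxfev=5000,
        )
    except Exception as exc:  # scipy raises RuntimeError on non-convergence
        raise FitError(f"membrane τ fit failed: {exc}", data=(t, v)) from exc
    return float(popt[2])


def _spike_count(sweep: Sweep) -> int:
    ev = detect_action_potentials(sweep)
    on, off = sweep.step_onset, sweep.step_offset
    return sum(1 for t_thr, t_pk in ev if on <= t_pk <= off)


def find_rheobase(sweeps: Sequence[Sweep]) -> Tuple[float, List[Sweep]]:
    """Smallest positive step amplitude whose sweep(s) contain >= 1 AP."""
    supra = sorted(
        (sw for sw in sweeps if sw.mode == CURRENT_CLAMP and sw.step_amplitude > 0),
        key=lambda sw: sw.step_amplitude,
    )
    spiking = [sw for sw in supra if _spike_count(sw) >= 1]
    if not spiking:
        raise SubthresholdError("no sweep elicited an action potential")
    rheo = spiking[0].step_amplitude
    at_rheo = [sw for sw in spiking if abs(sw.step_amplitude - rheo) < 1e-9]
    return float(rheo), at_rheo


def first_spike_latency(rheobase_sweeps: Sequence[Sweep]) -> float:
    """Mean (first AP peak time − step onset) over the rheobase sweeps, ms."""
    lats = []
    for sw in rheobase_sweeps:
        ev = detect_action_potentials(sw)
        if ev:
            lats.append(ev[0][1] - sw.step_onset)
    if not lats:
        raise InsufficientSpikesError("no APs in the rheobase sweeps")
    return float(np.mean(lats))


def classify_firing_pattern(
    sweeps: Sequence[Sweep],
    burst_isi_ms: float = BURST_ISI_MS,
    ls_latency_ms: float = LS_LATENCY_MS,
    is_latency_ms: float = IS_LATENCY_MS,
) -> str:
    """Classify a cell as LS / IS / BS from its rheobase sweeps.

    BS: any rheobase sweep holds >= 2 APs whose first ISI is < 10 ms
    (>100 Hz burst). Otherwise LS if the first-spike latency exceeds
    500 ms, IS if below 100 ms, and UNCLASSIFIED in between.
    """
    _, rheo_sweeps = find_rheobase(sweeps)
    for sw in rheo_sweeps:
        ev = detect_action_potentials(sw)
        if len(ev) >= 2 and (ev[1][1] - ev[0][1]) < burst_isi_ms:
            return BS
    latency = first_spike_latency(rheo_sweeps)
    if latency > ls_latency_ms:
        return LS
    if latency < is_latency_ms:
        return IS
    return UNCLASSIFIED


def _instantaneous_rates(sweep: Sweep) -> Tuple[np.ndarray, np.ndarray]:
    """(t, rate) points: 1/ISI (Hz) at ISI midpoints, t from step onset (ms)."""
    ev = detect_action_potentials(sweep)
    peaks = np.array([pk for _, pk in ev if sweep.step_onset <= pk <= sweep.step_offset])
    isis = np.diff(peaks)
    mids = 0.5 * (peaks[1:] + peaks[:-1]) - sweep.step_onset
    return mids, 1000.0 / isis


def adaptation_index(sweep: Sweep, min_spikes: int = 6) -> float:
    """Adaptation index AI = f(1000 ms)/f(100 ms) of a fitted rate decay.

    An exponential f(t) = A·exp(−t/τ_a) + C is fitted by bounded least
    squares to the instantaneous-rate points (1/ISI at ISI midpoints, t
    from step onset). Requires at least ``min_spikes`` APs in the step. If
    the fit does not converge, falls back to the ratio of the mean of the
    last two instantaneous rates to the mean of the first two after
    100 ms.
    """
    mids, rates = _instantaneous_rates(sweep)
    if rates.size + 1 < min_spikes:
        raise InsufficientSpikesError(
            f"adaptation index requires >= {min_spikes} APs in the step"
        )
    if np.ptp(rates) < 1e-9:
        return 1.0
    r0 = float(np.mean(rates))
    try:
        popt, _ = curve_fit(
            lambda t, a, tau, c: a * np.exp(-t / tau) + c,
            mids,
            rates,
            p0=(rates[0] - rates[-1], 400.0, max(rates[-1], 0.1)),
            bounds=([-10 * r0 - 1, 20.0, 0.0], [10 * r0 + 1, 5000.0, 10 * r0 + 1]),
            maxfev=5000,
        )
        a, tau, c = popt
        f = lambda t: a * math.exp(-t / tau) + c
        if f(1000.0) <= 0 or f(100.0) <= 0:
            raise FitError("fitted rate non-positive on [100, 1000] ms")
        return f(1000.0) / f(100.0)
    except (FitError, RuntimeError, ValueError):
        late = float(np.mean(rates[-2:]))
        post100 = rates[mids >= 100.0]
        early = float(np.mean(post100[:2])) if post100.size >= 1 else float(
            np.mean(rates[:2])
        )
        return late / early if early > 0 else math.nan


def isi_cv(sweep: Sweep, window_ms: float = 500.0, min_isis: int = 3) -> float:
    """CV (sample sd / mean) of ISIs inside the last ``window_ms`` of the step."""
    ev = detect_action_potentials(sweep)
    peaks = np.array([pk for _, pk in ev])
    lo = sweep.step_offset - window_ms
    inside = peaks[(peaks >= lo) & (peaks <= sweep.step_offset)]
    isis = np.diff(inside)
    if isis.size < min_isis:
        raise InsufficientSpikesError(
            f"ISI CV requires >= {min_isis} ISIs in the last {window_ms:g} ms"
        )
    return float(np.std(isis, ddof=1) / np.mean(isis))


def firing_rate_at(sweeps: Sequence[Sweep], multiple: float = 2.0) -> float:
    """Firing rate (Hz) at ``multiple × rheobase``, interpolating if needed.

    The per-sweep rate is the spike count in the (1 s) step. If a sweep
    exists at the target amplitude its rate is taken directly; otherwise
    the rate is linearly interpolated between the two bracketing
    amplitudes. Extrapolation is refused.
    """
    rheo, _ = find_rheobase(sweeps)
    target = multiple * rheo
    amps, rates = [], []
    for sw in sweeps:
        if sw.mode != CURRENT_CLAMP or sw.step_amplitude <= 0:
            continue
        amps.append(sw.step_amplitude)
        rates.append(_spike_count(sw) / (sw.step_duration_ms / 1000.0))
    amps = np.array(amps)
    rates = np.array(rates)
    exact = np.flatnonzero(np.abs(amps - target) < 1e-6)
    if exact.size:
        return float(np.mean(rates[exact]))
    below = amps[amps < target]
    above = amps[amps > target]
    if below.size == 0 or above.size == 0:
        raise ExtrapolationError(
            f"target {target:g} pA outside tested range [{amps.min():g}, {amps.max():g}]"
        )
    a0, a1 = below.max(), above.min()
    r0 = float(np.mean(rates[amps == a0]))
    r1 = float(np.mean(rates[amps == a1]))
    return r0 + (r1 - r0) * (target - a0) / (a1 - a0)


def _ai_at(sweeps: Sequence[Sweep], rheo: float, multiple: float) -> float:
    """AI taken at, or interpolated to, ``multiple × rheobase``."""
    target = multiple * rheo
    pts = []
    for sw in sweeps:
        if sw.mode != CURRENT_CLAMP or sw.step_amplitude <= 0:
            continue
        try:
            pts.append((sw.step_amplitude, adaptation_index(sw)))
        except InsufficientSpikesError:
            continue
    if not pts:
        raise InsufficientSpikesError("no sweep qualifies for the adaptation index")
    amps = np.array([a for a, _ in pts])
    ais = np.array([x for _, x in pts])
    exact = np.flatnonzero(np.abs(amps - target) < 1e-6)
    if exact.size:
        return float(np.mean(ais[exact]))
    below, above = amps[amps < target], amps[amps > target]
    if below.size == 0 or above.size == 0:
        # take the nearest tested amplitude rather than extrapolate
        return float(ais[np.argmin(np.abs(amps - target))])
    a0, a1 = below.max(), above.min()
    r0 = float(np.mean(ais[amps == a0]))
    r1 = float(np.mean(ais[amps == a1]))
    return float(r0 + (r1 - r0) * (target - a0) / (a1 - a0))


def profile_cell(sweeps: Sequence[Sweep]) -> CellProfile:
    """Assemble the full per-cell profile from a sweep set.

    Component failures are recorded per-field in ``profile.missing`` and
    leave the field NaN rather than aborting the profile. The
    near-rheobase adaptation index (1.3× rheobase) is computed for LS
    cells only; the 2× index for all classes.
    """
    prof = CellProfile()

    def attempt(name, fn):
        try:
            setattr(prof, name, fn())
        except Exception as exc:
            prof.missing[name] = f"{type(exc).__name__}: {exc}"

    hyper = [
        sw
        for sw in sweeps
        if sw.mode == CURRENT_CLAMP
        and sw.step_amplitude < 0
        and sw.step_duration_ms >= 150.0
    ]
    if hyper:
        attempt("input_resistance_MOhm", lambda: input_resistance(hyper[0]))
    else:
        prof.missing["input_resistance_MOhm"] = "no hyperpolarizing step"

    try:
        rheo, rheo_sweeps = find_rheobase(sweeps)
        prof.rheobase_pA = rheo
    except SubthresholdError as exc:
        for name in (
            "rheobase_pA",
            "first_ap_latency_ms",
            "latency_over_tau",
            "ai_near",
            "ai_2x",
            "cv_isi_2x",
            "firing_rate_2x_Hz",
        ):
            prof.missing[name] = str(exc)
        rheo, rheo_sweeps = None, []

    sub = [
        sw
        for sw in sweeps
        if sw.mode == CURRENT_CLAMP
        and sw.step_amplitude > 0
        and sw.step_duration_ms >= 1000.0 - 1e-6
        and (rheo is None or sw.step_amplitude < rheo)
    ]
    if sub:
        # the largest subthreshold step has the cleanest transient
        attempt(
            "tau_ms",
            lambda: membrane_time_constant(max(sub, key=lambda s: s.step_amplitude)),
        )
    else:
        prof.missing["tau_ms"] = "no subthreshold >= 1 s step"

    if rheo_sweeps:
        attempt("first_ap_latency_ms", lambda: first_spike_latency(rheo_sweeps))
        attempt("firing_class", lambda: classify_firing_pattern(sweeps))
        attempt("firing_rate_2x_Hz", lambda: firing_rate_at(sweeps, 2.0))
        attempt("ai_2x", lambda: _ai_at(sweeps, rheo, 2.0))
        if prof.firing_class == LS:
            attempt("ai_near", lambda: _ai_at(sweeps, rheo, 1.3))

        def cv2x():
            target = 2.0 * rheo
            cand = [
                sw
                for sw in sweeps
                if sw.mode == CURRENT_CLAMP and abs(sw.step_amplitude - target) < 1e-6
            ]
            if not cand:
                cand = sorted(
                    (sw for sw in sweeps if sw.step_amplitude > rheo),
                    key=lambda s: abs(s.step_amplitude - target),
                )[:1]
            if not cand:
                raise InsufficientSpikesError("no sweep near 2x rheobase")
            return isi_cv(cand[0])

        attempt("cv_isi_2x", cv2x)

    attempt("ap", lambda: ap_summary(sweeps))
    if not math.isnan(prof.first_ap_latency_ms) and not math.isnan(prof.tau_ms):
        prof.latency_over_tau = prof.first_ap_latency_ms / prof.tau_ms
    return prof
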