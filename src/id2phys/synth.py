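"""Synthetic-data generators with ground truth.

Three families:

* phenotype-labeled current-clamp sweep sets (late-spiking, irregular,
  bursting) built from a passive RC response plus stereotyped AP templates,
* full in vivo sessions (behavioral-state schedule, NREM up/down
  alternation, opto pulse trains, class-labeled Poisson units, LFP + EMG +
  motion channels),
* IPSC trial cohorts with a configurable suppression effect.

All generators are deterministic given (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    EventSeries,
    IntervalSet,
    SessionBundle,
    SpecError,
    Sweep,
    Trace,
    UnitRecord,
)
from .intracell import BS, IS, LS

# ------------------------------------------------------------------
# intracellular phenotypes
# ------------------------------------------------------------------


@dataclass
class PhenotypeSpec:
    """Targets for one firing phenotype.

    Defaults per class are set by :func:`default_phenotype`; the numbers
    are population means for neurogliaform-type (LS), irregular-spiking
    (IS) and burst-spiking (BS) interneurons.
    """

    firing_class: str
    rin_MOhm: float
    tau_ms: float
    rheobase_pA: float
    latency_mean_ms: float
    latency_sd_ms: float
    ai_2x: float
    ai_near: Optional[float]
    cv_2x: float
    rate_2x_hz: float
    rate_near_hz: float
    halfwidth_ms: float
    ahp_mV: float
    threshold_mV: float = -35.0
    peak_mV: float = 25.0
    rise_slope_mV_per_ms: float = 283.0
    tau_adapt_ms: float = 400.0
    burst_n: int = 0          # spikes in the rheobase burst (BS only)
    burst_isi_ms: float = 6.0
    noise_sd_mV: float = 0.15
    v_rest_mV: float = -70.0

    def __post_init__(self):
        for name in ("rin_MOhm", "tau_ms", "rheobase_pA", "latency_mean_ms",
                     "halfwidth_ms", "rate_2x_hz"):
            if not getattr(self, name) > 0:
                raise SpecError(f"PhenotypeSpec.{name} must be positive")


_PHENOTYPES = {
    LS: dict(rin_MOhm=188.0, tau_ms=12.0, rheobase_pA=139.0,
             latency_mean_ms=805.0, latency_sd_ms=22.0,
             ai_2x=0.76, ai_near=1.14, cv_2x=0.053,
             rate_2x_hz=38.0, rate_near_hz=20.0,
             halfwidth_ms=0.70, ahp_mV=14.4, tau_adapt_ms=400.0),
    IS: dict(rin_MOhm=199.0, tau_ms=13.0, rheobase_pA=155.0,
             latency_mean_ms=53.0, latency_sd_ms=4.0,
             ai_2x=0.26, ai_near=None, cv_2x=0.112,
             rate_2x_hz=40.0, rate_near_hz=26.0,
             halfwidth_ms=0.48, ahp_mV=9.9, rise_slope_mV_per_ms=404.0,
             tau_adapt_ms=150.0),
    BS: dict(rin_MOhm=301.0, tau_ms=17.0, rheobase_pA=51.0,
             latency_mean_ms=143.0, latency_sd_ms=37.0,
             ai_2x=0.24, ai_near=None, cv_2x=0.262,
             rate_2x_hz=31.0, rate_near_hz=20.0,
             halfwidth_ms=0.57, ahp_mV=6.6, rise_slope_mV_per_ms=322.0,
             tau_adapt_ms=150.0, burst_n=3),
}


def default_phenotype(firing_class: str, **overrides) -> PhenotypeSpec:
    """Default :class:`PhenotypeSpec` for ``"LS"``, ``"IS"`` or ``"BS"``."""
    if firing_class not in _PHENOTYPES:
        raise SpecError(f"unknown firing class {firing_class!r}")
    kwargs = dict(_PHENOTYPES[firing_class])
    kwargs.update(overrides)
    return PhenotypeSpec(firing_class=firing_class, **kwargs)


def rate_profile_for(
    ai: float, count: float, tau_adapt_ms: float
) -> Tuple[float, float]:
    """Solve (A, C) of f(t) = A·exp(−t/τ_a) + C [Hz] for a 1 s step.

    Constrains f(1000 ms)/f(100 ms) = ``ai`` and the integral of f over the
    step to ``count`` spikes.
    """
    u = math.exp(-1000.0 / tau_adapt_ms)
    v = math.exp(-100.0 / tau_adapt_ms)
    denom = u - ai * v
    if abs(denom) < 1e-12:
        raise SpecError("adaptation profile degenerate for this (AI, tau)")
    k = (ai - 1.0) / denom  # A = k * C
    tau_s = tau_adapt_ms / 1000.0
    integral_per_c = 1.0 + k * tau_s * (1.0 - u)
    if integral_per_c <= 0:
        raise SpecError("infeasible (AI, count, tau) combination")
    c = count / integral_per_c
    if c <= 0 or (k * c + c) <= 0:
        raise SpecError("adaptation profile implies non-positive rate")
    return k * c, c


def plant_spike_times(
    A: float,
    C: float,
    tau_adapt_ms: float,
    duration_ms: float,
    target_cv: float,
    rng: np.random.Generator,
    cv_window_ms: float = 500.0,
    min_isi_ms: float = 2.0,
) -> np.ndarray:
    """Spike times (ms from step onset) realizing a planted rate profile.

    Deterministic placement at equal-mass quantiles of the cumulative rate
    realizes the adaptation profile; Gaussian time jitter is then added,
    sized so that the ISI CV over the last ``cv_window_ms`` equals
    ``target_cv``. The profile's own ISI drift contributes a deterministic
    CV component which is subtracted in quadrature (jitter is zero when the
    drift alone exceeds the target).
    """
    tau_s = tau_adapt_ms / 1000.0
    t_grid = np.linspace(0.0, duration_ms / 1000.0, 4001)
    cum = C * t_grid + A * tau_s * (1.0 - np.exp(-t_grid / tau_s))
    total = cum[-1]
    n = int(round(total))
    if n < 1:
        return np.empty(0)
    targets = (np.arange(n) + 0.5) * total / n
    times = np.interp(targets, cum, t_grid) * 1000.0  # ms

    if times.size >= 3:
        lo = duration_ms - cv_window_ms
        inside = times[(times >= lo) & (times <= duration_ms)]
        isis = np.diff(inside)
        if isis.size >= 2:
            cv_det = float(np.std(isis, ddof=1) / np.mean(isis))
            mean_isi = float(np.mean(isis))
        else:
            cv_det, mean_isi = 0.0, float(np.mean(np.diff(times)))
        resid = math.sqrt(max(target_cv**2 - cv_det**2, 0.0))
        sigma_t = resid * mean_isi / math.sqrt(2.0)
        if sigma_t > 0:
            times = np.sort(times + rng.normal(0.0, sigma_t, size=times.size))
    # enforce a minimal ISI by dropping violators
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= min_isi_ms:
            keep.append(i)
    return times[keep]


def ap_template_params(spec: PhenotypeSpec) -> Dict[str, float]:
    rise_ms = max((spec.peak_mV - spec.threshold_mV) / spec.rise_slope_mV_per_ms,
                  0.1)
    fall_ms = max(2.0 * spec.halfwidth_ms - rise_ms, 0.1)
    return dict(rise_ms=rise_ms, fall_ms=fall_ms, ahp_fall_ms=1.5,
                recovery_tau_ms=8.0, recovery_ms=25.0, lead_ms=2.0)


def _insert_spike(
    v: np.ndarray,
    dt: float,
    peak_time_ms: float,
    baseline: np.ndarray,
    spec: PhenotypeSpec,
) -> None:
    """Overwrite ``v`` in place with one stereotyped AP peaking at peak_time.

    The pre-spike lead ramps from the current trace value to threshold (its
    slope stays below the dV/dt detection criterion), so the dV/dt crossing
    lands exactly on the first sample of the fast rise.
    """
    p = ap_template_params(spec)
    thr, peak = spec.threshold_mV, spec.peak_mV
    i_peak = int(round(peak_time_ms / dt))
    n_rise = max(int(round(p["rise_ms"] / dt)), 2)
    n_fall = max(int(round(p["fall_ms"] / dt)), 2)
    n_lead = max(int(round(p["lead_ms"] / dt)), 2)
    n_ahpf = max(int(round(p["ahp_fall_ms"] / dt)), 2)
    n_rec = int(round(p["recovery_ms"] / dt))

    i_rise = i_peak - n_rise
    i_lead = i_rise - n_lead
    if i_lead < 0 or i_peak + n_fall + n_ahpf >= v.size:
        return  # spike does not fit; generator specs avoid this
    v_start = v[i_lead]
    v[i_lead : i_rise + 1] = np.linspace(v_start, thr, n_rise + 1 - n_rise + n_lead)
    v[i_rise : i_peak + 1] = np.linspace(thr, peak, n_rise + 1)
    v[i_peak : i_peak + n_fall + 1] = np.linspace(peak, thr, n_fall + 1)
    i_ft = i_peak + n_fall
    ahp_min = thr - spec.ahp_mV
    v[i_ft : i_ft + n_ahpf + 1] = np.linspace(thr, ahp_min, n_ahpf + 1)
    i_am = i_ft + n_ahpf
    i_re = min(i_am + n_rec, v.size)
    t_rec = (np.arange(i_re - i_am)) * dt
    target = baseline[i_am:i_re]
    v[i_am:i_re] = target + (ahp_min - target) * np.exp(-t_rec / p["recovery_tau_ms"])


def sweep_from_spike_times(
    spike_times_ms: Sequence[float],
    spec: PhenotypeSpec,
    step_amplitude: float,
    rng: np.random.Generator,
    dt: float = 0.05,
    duration_ms: float = 1200.0,
    step_onset: float = 100.0,
    step_offset: float = 1100.0,
    ramp_to_threshold: bool = False,
) -> Tuple[Sweep, np.ndarray]:
    """Build a current-clamp sweep with APs planted at given times.

    Times are in ms from step onset; returns the sweep and the realized
    (sample-grid-aligned) peak times in ms from sweep start.
    """
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    v_rest = spec.v_rest_mV
    dv_passive = spec.rin_MOhm * step_amplitude / 1000.0
    if step_amplitude > 0:
        # cap the inter-spike depolarization below threshold
        dv = min(dv_passive, spec.threshold_mV - 8.0 - v_rest)
    else:
        dv = dv_passive
    baseline = np.full(n, v_rest)
    on = (t >= step_onset) & (t < step_offset)
    baseline[on] = v_rest + dv * (1.0 - np.exp(-(t[on] - step_onset) / spec.tau_ms))
    off = t >= step_offset
    v_end = v_rest + dv * (1.0 - math.exp(-(step_offset - step_onset) / spec.tau_ms))
    baseline[off] = v_rest + (v_end - v_rest) * np.exp(
        -(t[off] - step_offset) / spec.tau_ms
    )

    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    if ramp_to_threshold and spike_times_ms.size:
        # slow depolarizing ramp toward threshold before the first spike
        t_sp = step_onset + spike_times_ms[0]
        ramp_len = min(300.0, spike_times_ms[0] - 20.0)
        if ramp_len > 10.0:
            m = (t >= t_sp - ramp_len) & (t < t_sp)
            frac = (t[m] - (t_sp - ramp_len)) / ramp_len
            top = spec.threshold_mV - 0.5
            baseline[m] = baseline[m] + frac * np.maximum(top - baseline[m], 0.0)

    v = baseline.copy()
    realized = []
    for ts in spike_times_ms:
        i_peak = int(round((step_onset + ts) / dt))
        _insert_spike(v, dt, i_peak * dt, baseline, spec)
        realized.append(i_peak * dt)
    if spec.noise_sd_mV > 0:
        v = v + rng.normal(0.0, spec.noise_sd_mV, size=n)
    sweep = Sweep(samples=v, dt=dt, step_amplitude=step_amplitude,
                  step_onset=step_onset, step_offset=step_offset)
    return sweep, np.array(realized)


def gen_intracellular_cell(
    spec: PhenotypeSpec,
    step_grid_pA: float = 10.0,
    seed: int = 0,
    n_rheo_sweeps: int = 2,
) -> Tuple[List[Sweep], Dict]:
    """One synthetic cell: hyperpolarizing, subthreshold and spiking sweeps.

    The realized rheobase is the planted rheobase rounded up to the step
    grid; train sweeps are delivered at exactly 1.3× and 2× that value so
    the downstream interpolation takes them directly.
    """
    rng = np.random.default_rng(seed)
    step_len = 1000.0
    rheo_grid = math.ceil(spec.rheobase_pA / step_grid_pA) * step_grid_pA
    if spec.latency_mean_ms + 4 * spec.latency_sd_ms > step_len:
        raise SpecError("planted latency does not fit in the 1 s step")

    sweeps: List[Sweep] = []
    truth: Dict = {
        "firing_class": spec.firing_class,
        "rheobase_planted_pA": spec.rheobase_pA,
        "rheobase_grid_pA": rheo_grid,
        "rin_MOhm": spec.rin_MOhm,
        "tau_ms": spec.tau_ms,
        "ai_2x": spec.ai_2x,
        "cv_2x": spec.cv_2x,
        "rate_2x_hz": spec.rate_2x_hz,
        "halfwidth_ms": spec.halfwidth_ms,
        "ahp_mV": spec.ahp_mV,
    }

    # hyperpolarizing step (input resistance)
    sw, _ = sweep_from_spike_times([], spec, -20.0, rng)
    sweeps.append(sw)
    # subthreshold step (membrane tau)
    sw, _ = sweep_from_spike_times([], spec, rheo_grid - step_grid_pA, rng)
    sweeps.append(sw)

    # rheobase sweeps: single spike (LS/IS) or a fast burst (BS)
    latencies = []
    for _ in range(n_rheo_sweeps):
        lat = float(rng.normal(spec.latency_mean_ms, spec.latency_sd_ms))
        if spec.firing_class == LS:
            while lat <= 500.0:
                lat = float(rng.normal(spec.latency_mean_ms, spec.latency_sd_ms))
        lat = float(np.clip(lat, 10.0, step_len - 40.0))
        if spec.burst_n >= 2:
            times = lat + spec.burst_isi_ms * np.arange(spec.burst_n)
        else:
            times = np.array([lat])
        sw, realized = sweep_from_spike_times(
            times, spec, rheo_grid, rng,
            ramp_to_threshold=(spec.firing_class == LS),
        )
        sweeps.append(sw)
        latencies.append(realized[0] - sw.step_onset)
    truth["latencies_ms"] = latencies

    # train sweeps at 1.3x and 2x rheobase
    for mult, count, ai in (
        (1.3, spec.rate_near_hz, spec.ai_near if spec.ai_near else spec.ai_2x),
        (2.0, spec.rate_2x_hz, spec.ai_2x),
    ):
        A, C = rate_profile_for(ai, count, spec.tau_adapt_ms)
        times = plant_spike_times(A, C, spec.tau_adapt_ms, step_len,
                                  spec.cv_2x, rng)
        sw, realized = sweep_from_spike_times(times, spec, mult * rheo_grid, rng)
        sweeps.append(sw)
        if mult == 2.0:
            truth["spike_times_2x_ms"] = realized
    return sweeps, truth


def gen_cell_population(
    n_per_class: int, seed: int = 0, jitter_frac: float = 0.10
) -> List[Tuple[List[Sweep], Dict]]:
    """Cells of all three classes with parameters drawn around class means."""
    rng = np.random.default_rng(seed)
    out = []
    for cls in (LS, IS, BS):
        base = default_phenotype(cls)
        for _ in range(n_per_class):
            spec = replace(
                base,
                rin_MOhm=base.rin_MOhm * (1 + jitter_frac * rng.standard_normal()),
                tau_ms=base.tau_ms * (1 + jitter_frac * rng.standard_normal()),
                rheobase_pA=base.rheobase_pA
                * (1 + jitter_frac * rng.standard_normal()),
            )
            out.append(gen_intracellular_cell(spec, seed=int(rng.integers(2**31))))
    return out


# ------------------------------------------------------------------
# spike-train helpers
# ------------------------------------------------------------------


def gen_poisson_train(
    rate_hz: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def gen_refractory_train(
    rate_hz: float,
    tau_recovery_ms: float,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Renewal train with hazard λ(s) = rate·(1 − exp(−s/τ)) after each spike.

    The autocorrelogram of this process rises with time constant ≈ τ when
    the mean ISI is long relative to τ.
    """
    tau_s = tau_recovery_ms / 1000.0
    times = []
    t = 0.0
    # sample by thinning a homogeneous process at rate_hz
    last = -10.0 * tau_s
    while t < duration_s:
        t += rng.exponential(1.0 / rate_hz)
        if rng.uniform() < 1.0 - math.exp(-(t - last) / tau_s):
            times.append(t)
            last = t
    return np.asarray(times)


# ------------------------------------------------------------------
# in vivo sessions
# ------------------------------------------------------------------


@dataclass
class SessionSpec:
    """Parameters of a synthetic multi-unit recording session.

    The opto pulse train mirrors the acquisition protocol: 100 ms pulses at
    400 ± 200 ms uniform random intervals, several hundred pulses.
    ``rebound_gain_sd`` is the planted post-down rebound size in baseline
    standard deviations of the peri-down PSTH.
    """

    seed: int
    duration_s: float = 1800.0
    n_pc: int = 15
    n_nw: int = 6
    n_ww: int = 4
    n_id2: int = 11
    base_rates_hz: Dict[str, float] = field(
        default_factory=lambda: {"PC": 1.8, "NW": 10.0, "WW": 6.0, "ID2": 4.0}
    )
    state_mult: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "PC": {"RUN": 1.3, "QUIET": 1.0, "NREM": 0.65, "REM": 0.55},
            "NW": {"RUN": 1.3, "QUIET": 1.0, "NREM": 0.7, "REM": 0.6},
            "WW": {"RUN": 1.1, "QUIET": 1.0, "NREM": 0.9, "REM": 0.9},
            "ID2": {"RUN": 1.0, "QUIET": 1.0, "NREM": 1.0, "REM": 1.3},
        }
    )
    down_rate_hz: float = 0.5
    down_mean_s: float = 0.15
    down_shape: float = 4.0
    down_suppression: float = 0.02
    n_rebound: int = 7
    rebound_gain_sd: float = 4.0
    rebound_window_s: Tuple[float, float] = (0.09, 0.20)
    n_pulses: int = 600
    pulse_width_s: float = 0.1
    pulse_interval_s: float = 0.4
    pulse_interval_jitter_s: float = 0.2
    tag_reliability: float = 0.9
    tag_latency_ms: float = 5.0
    tag_jitter_ms: float = 2.0
    frac_neg_mod: float = 0.5
    frac_pos_mod: float = 0.15
    neg_mod_gain: float = 0.25
    neg_mod_window_s: Tuple[float, float] = (0.0, 0.08)
    pos_mod_gain: float = 2.2
    pos_mod_window_s: Tuple[float, float] = (0.06, 0.16)
    lfp_fs: float = 1250.0
    aux_fs: float = 100.0
    with_lfp: bool = True

    def __post_init__(self):
        if self.n_rebound > self.n_id2:
            raise SpecError("n_rebound cannot exceed n_id2")
        for name in ("duration_s", "down_rate_hz", "down_mean_s"):
            if not getattr(self, name) > 0:
                raise SpecError(f"SessionSpec.{name} must be positive")
        if not 0 <= self.tag_reliability <= 1:
            raise SpecError("tag_reliability must be in [0, 1]")


_T2P_MS = {"PC": 0.90, "NW": 0.30, "WW": 0.65, "ID2": 0.70}
_ACG_TAU_MS = {"PC": 30.0, "NW": 3.0, "WW": 6.0, "ID2": 8.0}


def _class_waveform(cls: str, rng: np.random.Generator, fs: float = 20000.0):
    """Biphasic extracellular template with a class-specific trough-to-peak."""
    n = int(round(0.0025 * fs))  # 2.5 ms
    t = np.arange(n) / fs * 1000.0  # ms
    t_trough = 0.8
    t2p = _T2P_MS[cls] * (1 + 0.05 * rng.standard_normal())
    trough = -100.0 * np.exp(-0.5 * ((t - t_trough) / 0.12) ** 2)
    peak = 35.0 * np.exp(-0.5 * ((t - (t_trough + t2p)) / (0.22 + 0.25 * t2p)) ** 2)
    return trough + peak, fs


def gen_schedule(
    duration_s: float, rng: np.random.Generator
) -> IntervalSet:
    """Alternating wake/sleep schedule containing all four states."""
    mean = {"QUIET": 90.0, "RUN": 70.0, "NREM": 260.0, "REM": 90.0}
    pattern = ["QUIET", "RUN", "QUIET", "NREM", "REM", "NREM"]
    records = []
    t, k = 0.0, 0
    while t < duration_s:
        state = pattern[k % len(pattern)]
        dur = mean[state] * rng.uniform(0.7, 1.3)
        stop = min(t + dur, duration_s)
        if stop - t >= 15.0:
            records.append((t, stop, state))
        else:
            # extend the previous epoch to the session end
            if records:
                last = records.pop()
                records.append((last[0], duration_s, last[2]))
            t = duration_s
            break
        t, k = stop, k + 1
    return IntervalSet.from_records(records)


def _mask_from_intervals(edges: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask over grid cells (defined by left edges) inside intervals."""
    mask = np.zeros(edges.size, dtype=bool)
    for a, b in intervals:
        i0, i1 = np.searchsorted(edges, [a, b])
        mask[max(i0 - 1, 0) : i1] = True
    return mask


def gen_state_channels(
    schedule: IntervalSet,
    duration_s: float,
    rng: np.random.Generator,
    down_intervals: Optional[np.ndarray] = None,
    lfp_fs: float = 1250.0,
    aux_fs: float = 100.0,
) -> Tuple[Trace, Trace, Trace]:
    """LFP, EMG and motion channels for a state schedule.

    NREM carries ~1.5 Hz delta (amplified during down-states), REM a 7 Hz
    theta rhythm, wake broadband noise. EMG is high awake / low asleep;
    motion is high only during RUN.
    """
    n = int(round(duration_s * lfp_fs))
    t = np.arange(n) / lfp_fs
    lfp = rng.normal(0.0, 0.3, size=n)
    phase = rng.uniform(0, 2 * np.pi)
    delta = np.sin(2 * np.pi * 1.5 * t + phase)
    theta = np.sin(2 * np.pi * 7.0 * t + phase)
    nrem_mask = _mask_from_intervals(t, schedule.for_label("NREM"))
    rem_mask = _mask_from_intervals(t, schedule.for_label("REM"))
    wake_mask = ~(nrem_mask | rem_mask)
    delta_amp = np.where(nrem_mask, 2.2, 0.0)
    if down_intervals is not None and len(down_intervals):
        down_mask = _mask_from_intervals(t, down_intervals)
        delta_amp = delta_amp * (1.0 + 0.8 * down_mask)
    lfp += delta_amp * delta
    lfp += np.where(rem_mask, 1.2, 0.0) * theta
    lfp += np.where(wake_mask, 1.0, 0.0) * rng.normal(0.0, 0.6, size=n)

    m = int(round(duration_s * aux_fs))
    ta = np.arange(m) / aux_fs
    run_a = _mask_from_intervals(ta, schedule.for_label("RUN"))
    sleep_a = _mask_from_intervals(
        ta, np.vstack([schedule.for_label("NREM"), schedule.for_label("REM")])
        if len(schedule.for_label("NREM")) or len(schedule.for_label("REM"))
        else np.empty((0, 2))
    )
    emg = np.where(sleep_a, 0.12, 0.90) + rng.normal(0.0, 0.04, size=m)
    motion = np.where(run_a, 1.0, 0.1) + rng.normal(0.0, 0.04, size=m)
    return (
        Trace(lfp, lfp_fs),
        Trace(emg, aux_fs),
        Trace(motion, aux_fs),
    )


def gen_session(spec: SessionSpec) -> SessionBundle:
    """Full synthetic session with ground truth.

    Units are inhomogeneous Poisson processes modulated by behavioral
    state, silenced during NREM down-states, and (per class assignment)
    given post-down rebound kernels, pulse-locked opto-tag responses, or
    positive/negative stimulation modulation. Ground truth (state schedule,
    down/up epochs, per-unit class and planted effects, pulse times) rides
    along in ``bundle.ground_truth``.
    """
    rng = np.random.default_rng(spec.seed)
    dur = spec.duration_s
    schedule = gen_schedule(dur, rng)

    # --- down states: renewal process inside NREM
    down_records = []
    for a, b in schedule.for_label("NREM"):
        t = a + rng.uniform(0.5, 1.5)
        while True:
            # durations bounded so a down never extends into the +90 ms
            # post-down analysis window of its own peak
            d = float(
                np.clip(
                    rng.gamma(spec.down_shape, spec.down_mean_s / spec.down_shape),
                    0.08,
                    0.18,
                )
            )
            if t + d > b - 0.3:
                break
            down_records.append((t, t + d))
            # renewal gap with a slow-oscillation floor: successive downs
            # are separated by a full up state
            gap = rng.gamma(4.0, (1.0 / spec.down_rate_hz - spec.down_mean_s) / 4.0)
            t = t + d + max(gap, 0.65)
    down_intervals = np.array(down_records) if down_records else np.empty((0, 2))
    down_peaks = down_intervals.mean(axis=1) if len(down_intervals) else np.empty(0)

    # --- up epochs: gaps between consecutive downs within one NREM bout
    up_records = []
    for a, b in schedule.for_label("NREM"):
        inside = down_intervals[
            (down_intervals[:, 0] >= a) & (down_intervals[:, 1] <= b)
        ]
        for (s0, e0), (s1, e1) in zip(inside[:-1], inside[1:]):
            if 0.2 <= s1 - e0 <= 4.0:
                up_records.append((e0, s1, "UP"))
    up_epochs = IntervalSet.from_records(up_records)

    # --- opto pulses: delivered in blocks during waking epochs so the
    # tagging stimulation does not contaminate the sleep analyses
    wake = np.vstack([schedule.for_label("RUN"), schedule.for_label("QUIET")])
    wake = wake[np.argsort(wake[:, 0])]
    pulse_list: List[float] = []
    for a, b in wake:
        t = a + 0.5
        while t < b - spec.pulse_width_s and len(pulse_list) < spec.n_pulses:
            pulse_list.append(t)
            t += spec.pulse_interval_s + rng.uniform(
                -spec.pulse_interval_jitter_s, spec.pulse_interval_jitter_s
            )
        if len(pulse_list) >= spec.n_pulses:
            break
    pulse_times = np.array(pulse_list)
    pulses = EventSeries(pulse_times, label="pulse")

    # --- unit roster
    roster: List[Dict] = []
    for cls, count in (("PC", spec.n_pc), ("NW", spec.n_nw),
                       ("WW", spec.n_ww), ("ID2", spec.n_id2)):
        for j in range(count):
            roster.append({"unit_id": f"{cls.lower()}{j:02d}", "cls": cls})
    for info in roster:
        if info["cls"] == "ID2":
            info["mod"] = "tagged"
        else:
            u = rng.uniform()
            info["mod"] = (
                "neg" if u < spec.frac_neg_mod
                else "pos" if u < spec.frac_neg_mod + spec.frac_pos_mod
                else "none"
            )
    id2_units = [i for i, info in enumerate(roster) if info["cls"] == "ID2"]
    rebound_set = set(id2_units[: spec.n_rebound])
    for i, info in enumerate(roster):
        info["rebound"] = i in rebound_set

    # --- rate grids and spikes
    dt_r = 0.002
    edges = np.arange(0.0, dur, dt_r)
    n_grid = edges.size
    state_idx = np.full(n_grid, -1)
    state_order = ("RUN", "QUIET", "NREM", "REM")
    for si, state in enumerate(state_order):
        state_idx[_mask_from_intervals(edges, schedule.for_label(state))] = si
    down_mask = _mask_from_intervals(edges, down_intervals)
    reb_mask = np.zeros(n_grid, dtype=bool)
    for pk in down_peaks:
        i0, i1 = np.searchsorted(
            edges, [pk + spec.rebound_window_s[0], pk + spec.rebound_window_s[1]]
        )
        reb_mask[i0:i1] = True
    mod_masks = {}
    for kind, (w0, w1) in (("neg", spec.neg_mod_window_s),
                           ("pos", spec.pos_mod_window_s)):
        m = np.zeros(n_grid, dtype=bool)
        for pt in pulse_times:
            i0, i1 = np.searchsorted(edges, [pt + w0, pt + w1])
            m[i0:i1] = True
        mod_masks[kind] = m

    nrem_total = schedule.total_duration("NREM")
    n_downs = max(len(down_peaks), 1)

    units: List[UnitRecord] = []
    for info in roster:
        cls = info["cls"]
        base = spec.base_rates_hz[cls] * rng.uniform(0.75, 1.35)
        mult = np.array([spec.state_mult[cls][s] for s in state_order] + [1.0])
        rate = base * mult[state_idx]
        rate = np.where(down_mask, rate * spec.down_suppression, rate)
        if info["rebound"] and spec.rebound_gain_sd > 0:
            # additive kernel: plants exactly gain_sd baseline standard
            # deviations of the 10 ms peri-down PSTH above the NREM rate
            r_nrem = base * spec.state_mult[cls]["NREM"]
            delta = spec.rebound_gain_sd * math.sqrt(r_nrem / (0.01 * n_downs))
            rate = np.where(reb_mask & ~down_mask, rate + delta, rate)
        if info["mod"] == "neg":
            rate = np.where(mod_masks["neg"], rate * spec.neg_mod_gain, rate)
        elif info["mod"] == "pos":
            rate = np.where(mod_masks["pos"], rate * spec.pos_mod_gain, rate)
        counts = rng.poisson(rate * dt_r)
        hot = np.flatnonzero(counts)
        spikes = np.repeat(edges[hot], counts[hot]) + rng.uniform(
            0.0, dt_r, size=int(counts.sum())
        )
        if info["mod"] == "tagged":
            fire = rng.uniform(size=pulse_times.size) < spec.tag_reliability
            tag_spikes = (
                pulse_times[fire]
                + spec.tag_latency_ms / 1000.0
                + rng.normal(0.0, spec.tag_jitter_ms / 1000.0, size=int(fire.sum()))
            )
            spikes = np.concatenate([spikes, tag_spikes])
        spikes = np.sort(spikes)
        wf, fs = _class_waveform(cls, rng)
        units.append(
            UnitRecord(
                unit_id=info["unit_id"],
                spike_times=spikes,
                waveform=wf,
                waveform_fs=fs,
                ground_truth=cls,
            )
        )

    lfp = emg = motion = None
    aux = {}
    if spec.with_lfp:
        lfp, emg, motion = gen_state_channels(
            schedule, dur, rng, down_intervals, spec.lfp_fs, spec.aux_fs
        )
        aux = {"emg": emg, "motion": motion}

    truth = {
        "schedule": schedule.records(),
        "down_peaks": down_peaks.tolist(),
        "down_intervals": down_intervals.tolist(),
        "up_epochs": up_epochs.records(),
        "units": [
            {
                "unit_id": info["unit_id"],
                "cls": info["cls"],
                "rebound": bool(info["rebound"]),
                "mod": info["mod"],
            }
            for info in roster
        ],
        "n_pulses": int(pulse_times.size),
    }
    return SessionBundle(
        units=units,
        events={"pulse": pulses},
        intervals=schedule,
        lfp=lfp,
        aux=aux,
        duration_s=dur,
        ground_truth=truth,
    )


def gen_rank_session(
    n_units: int = 10,
    n_epochs: int = 40,
    early_unit: int = 0,
    lead_ms: float = 30.0,
    spikes_per_epoch: float = 6.0,
    spread_ms: float = 60.0,
    seed: int = 0,
) -> Tuple[List[UnitRecord], IntervalSet]:
    """Up-state firing sequences with one planted early-firing unit.

    Every unit fires a Gaussian packet around the epoch center; the early
    unit's packet is shifted ``lead_ms`` earlier.
    """
    rng = np.random.default_rng(seed)
    epoch_len, spacing = 0.5, 1.5
    records, unit_spikes = [], [[] for _ in range(n_units)]
    for e in range(n_epochs):
        a = 1.0 + e * spacing
        records.append((a, a + epoch_len, "UP"))
        center = a + epoch_len / 2.0
        for u in range(n_units):
            mu = center - (lead_ms / 1000.0 if u == early_unit else 0.0)
            n_sp = max(1, rng.poisson(spikes_per_epoch))
            sp = rng.normal(mu, spread_ms / 1000.0, size=n_sp)
            unit_spikes[u].extend(np.clip(sp, a + 1e-4, a + epoch_len - 1e-4))
    units = [
        UnitRecord(unit_id=f"u{u:02d}", spike_times=np.sort(unit_spikes[u]))
        for u in range(n_units)
    ]
    return units, IntervalSet.from_records(records)


# ------------------------------------------------------------------
# DSI cohorts
# ------------------------------------------------------------------


def gen_dsi_cohort(
    n_cells: int = 18,
    mean_suppression: float = 16.0,
    cell_sd: float = 8.0,
    trial_sd: float = 5.0,
    n_reps: int = 4,
    condition: str = "control",
    seed: int = 0,
):
    """IPSC amplitude trial table with a planted per-cell suppression.

    Per-cell true suppression ~ N(mean, cell_sd²) %; per-trial amplitudes
    carry multiplicative noise of ``trial_sd`` %; recovery amplitudes
    return to the pre level. Returns a DataFrame with columns
    (cell_id, repetition, phase, condition, amplitude).
    """
    import pandas as pd

    if not (-100.0 < mean_suppression < 100.0):
        raise SpecError("mean_suppression must be in (-100, 100)")
    if n_cells < 1 or n_reps < 1:
        raise SpecError("n_cells and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cells):
        s = float(np.clip(rng.normal(mean_suppression, cell_sd), -60.0, 95.0))
        amp0 = rng.uniform(80.0, 220.0)
        for r in range(n_reps):
            noise = lambda: 1.0 + rng.normal(0.0, trial_sd / 100.0)
            rows += [
                dict(cell_id=f"c{c:02d}", repetition=r, phase="pre",
                     condition=condition, amplitude=amp0 * noise()),
                dict(cell_id=f"c{c:02d}", repetition=r, phase="post",
                     condition=condition, amplitude=amp0 * (1 - s / 100.0) * noise()),
                dict(cell_id=f"c{c:02d}", repetition=r, phase="recovery",
                     condition=condition, amplitude=amp0 * noise()),
            ]
    return pd.DataFrame(rows)
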