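"""Brain-state scoring from a single LFP channel plus EMG/motion.

A simplified automatic re-implementation of spectrogram-based sleep
scoring: 1 s-step / 10 s-window FFT at log-spaced frequencies (1–100 Hz),
broadband PC1 of the z-transformed spectrogram, a theta ratio, and an EMG
channel, divided hierarchically at the troughs of bimodal metric
distributions into RUN / QUIET / NREM / REM. Scoring is fully automatic
(no manual review stage).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import gaussian_kde

from .core import DomainError, IntervalSet, SessionBundle, Trace

DEFAULT_FS = 1250.0


class ResampleRequiredError(DomainError):
    """LFP sampling rate differs from the rate the pipeline expects."""


@dataclass
class SpectrogramFeatures:
    """Per-1 s spectrogram features used for state scoring."""

    times: np.ndarray              # s, centers of the 10 s windows
    freqs: np.ndarray              # Hz, log-spaced in [1, 100]
    power: np.ndarray              # (n_freqs, n_times)
    pc1: Optional[np.ndarray] = None
    theta_ratio: Optional[np.ndarray] = None
    emg: Optional[np.ndarray] = None
    motion: Optional[np.ndarray] = None


@dataclass
class ThresholdResult:
    value: float
    bimodal: bool                  # False -> flagged median fallback


def spectrogram_logf(
    lfp: np.ndarray,
    fs: float = DEFAULT_FS,
    expected_fs: float = DEFAULT_FS,
    window_s: float = 10.0,
    step_s: float = 1.0,
    n_freqs: int = 100,
    fmin: float = 1.0,
    fmax: float = 100.0,
) -> SpectrogramFeatures:
    """Sliding-window Hann FFT power at log-spaced frequencies.

    Windows are 10 s long and advance by 1 s; power is linearly
    interpolated from the FFT grid onto ``n_freqs`` log-spaced frequencies
    between 1 and 100 Hz.
    """
    if abs(fs - expected_fs) > 1e-6:
        raise ResampleRequiredError(
            f"LFP sampled at {fs:g} Hz; resample to {expected_fs:g} Hz first"
        )
    x = np.asarray(lfp, dtype=float)
    n_win = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    if x.size < 3 * n_win:
        raise DomainError("LFP must be at least 30 s long")
    n_frames = (x.size - n_win) // n_step + 1
    win = np.hanning(n_win)
    fft_freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    log_freqs = np.logspace(math.log10(fmin), math.log10(fmax), n_freqs)
    # interpolation weights from the FFT grid onto the log grid
    hi = np.searchsorted(fft_freqs, log_freqs)
    lo = hi - 1
    wq = (log_freqs - fft_freqs[lo]) / (fft_freqs[hi] - fft_freqs[lo])

    power = np.empty((n_freqs, n_frames))
    for k in range(n_frames):
        seg = x[k * n_step : k * n_step + n_win] * win
        psd = np.abs(np.fft.rfft(seg)) ** 2
        power[:, k] = psd[lo] * (1 - wq) + psd[hi] * wq
    times = window_s / 2.0 + np.arange(n_frames) * step_s
    return SpectrogramFeatures(times=times, freqs=log_freqs, power=power)


def theta_ratio(
    features: SpectrogramFeatures,
    theta_band: Tuple[float, float] = (6.0, 9.0),
    broad_band: Tuple[float, float] = (1.0, 20.0),
) -> np.ndarray:
    """Power(6–9 Hz) / power(1–20 Hz) per time bin."""
    f = features.freqs
    num = features.power[(f >= theta_band[0]) & (f <= theta_band[1])].sum(axis=0)
    den = features.power[(f >= broad_band[0]) & (f <= broad_band[1])].sum(axis=0)
    return num / np.maximum(den, 1e-30)


def broadband_pc1(features: SpectrogramFeatures, min_bins: int = 100) -> np.ndarray:
    """First PC score of the z-transformed log-frequency spectrogram.

    Each frequency row is z-scored over time before the PCA; the sign is
    fixed so that the mean loading over frequencies below 20 Hz is
    positive (slow-wave activity scores high).
    """
    P = features.power
    if P.shape[1] < min_bins:
        raise DomainError(f"PC1 requires >= {min_bins} time bins")
    sd = P.std(axis=1, keepdims=True)
    if np.all(sd <= 1e-12 * (np.abs(P).mean() + 1e-300)):
        raise DomainError("degenerate (constant) spectrogram: PCA rank error")
    z = (P - P.mean(axis=1, keepdims=True)) / np.maximum(sd, 1e-30)
    # first right singular vector over frequencies
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    loading = u[:, 0]
    if np.mean(loading[features.freqs < 20.0]) < 0:
        loading = -loading
    return loading @ z


def bin_aux(trace: Trace, times: np.ndarray, half_width_s: float = 0.5) -> np.ndarray:
    """Mean |signal| of an auxiliary channel around each feature time."""
    idx0 = np.clip(((times - half_width_s) * trace.fs).astype(int), 0, trace.samples.size)
    idx1 = np.clip(((times + half_width_s) * trace.fs).astype(int), 1, trace.samples.size)
    a = np.abs(trace.samples)
    cs = np.concatenate([[0.0], np.cumsum(a)])
    return (cs[idx1] - cs[idx0]) / np.maximum(idx1 - idx0, 1)


def bimodal_trough_threshold(
    values: np.ndarray, n_grid: int = 512, min_values: int = 200
) -> ThresholdResult:
    """Threshold at the KDE trough between the two highest density peaks.

    If the kernel density estimate is unimodal, the division is
    undetectable; the result falls back to the median with
    ``bimodal=False``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_values:
        raise DomainError(f"trough threshold requires >= {min_values} values")
    if np.ptp(v) < 1e-12:
        return ThresholdResult(float(np.median(v)), False)
    kde = gaussian_kde(v)
    lo, hi = v.min(), v.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if interior.size < 2:
        return ThresholdResult(float(np.median(v)), False)
    top2 = interior[np.argsort(dens[interior])][-2:]
    i0, i1 = sorted(top2)
    trough = i0 + int(np.argmin(dens[i0 : i1 + 1]))
    return ThresholdResult(float(grid[trough]), True)


def score_states(
    features: SpectrogramFeatures,
    min_duration_s: float = 10.0,
) -> IntervalSet:
    """Hierarchical state division into RUN / QUIET / NREM / REM.

    Division 1 splits awake from sleep at the EMG trough; division 2
    splits sleep into NREM vs. candidate REM at the broadband-PC1 trough;
    division 3 confirms REM by the theta ratio; awake bins split RUN vs.
    QUIET on the motion channel (EMG if no motion channel exists). When a
    metric's distribution is unimodal the corresponding division is
    undetectable and all affected bins go to a single branch (all awake,
    all NREM, no REM, all QUIET respectively). Epochs shorter than
    ``min_duration_s`` are merged into their neighbors.
    """
    for name in ("pc1", "theta_ratio", "emg"):
        if getattr(features, name) is None:
            raise DomainError(f"score_states requires features.{name}")
    t = features.times
    n = t.size
    emg, pc1, theta = features.emg, features.pc1, features.theta_ratio
    labels = np.empty(n, dtype=object)

    thr_emg = bimodal_trough_threshold(emg)
    awake = emg > thr_emg.value if thr_emg.bimodal else np.ones(n, dtype=bool)

    sleep = ~awake
    if sleep.any():
        thr_pc1 = bimodal_trough_threshold(pc1[sleep], min_values=2)
        nrem = sleep & (
            (pc1 > thr_pc1.value) if thr_pc1.bimodal else np.ones(n, dtype=bool)
        )
        cand_rem = sleep & ~nrem
        thr_th = bimodal_trough_threshold(theta[sleep], min_values=2)
        if thr_th.bimodal:
            rem = cand_rem & (theta > thr_th.value)
        else:
            rem = np.zeros(n, dtype=bool)
        labels[nrem | (cand_rem & ~rem)] = "NREM"
        labels[rem] = "REM"

    if awake.any():
        mov = features.motion if features.motion is not None else emg
        thr_mov = bimodal_trough_threshold(mov[awake], min_values=2)
        if thr_mov.bimodal:
            run = awake & (mov > thr_mov.value)
        else:
            run = np.zeros(n, dtype=bool)
        labels[awake & ~run] = "QUIET"
        labels[run] = "RUN"

    labels = _enforce_min_duration(labels, int(round(min_duration_s)))

    # assemble intervals tiling [t0 - 0.5, tN + 0.5]
    records = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            records.append(
                (float(t[start] - 0.5), float(t[i - 1] + 0.5), str(labels[start]))
            )
            start = i
    return IntervalSet.from_records(records)


def _enforce_min_duration(labels: np.ndarray, min_bins: int) -> np.ndarray:
    """Merge runs shorter than ``min_bins`` into the preceding epoch."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, labels.size + 1):
            if i == labels.size or labels[i] != labels[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            break
        for k, (a, b) in enumerate(runs):
            if b - a < min_bins:
                neighbor = labels[runs[k - 1][0]] if k > 0 else labels[runs[k + 1][0]]
                labels[a:b] = neighbor
                changed = True
                break
    return labels


def labels_at(intervals: IntervalSet, times: np.ndarray) -> np.ndarray:
    """State label at each query time (None where no interval covers it)."""
    out = np.full(times.size, None, dtype=object)
    for a, b, lab in intervals.records():
        out[(times >= a) & (times < b)] = lab
    return out


def features_from_session(bundle: SessionBundle) -> SpectrogramFeatures:
    """All scoring features (spectrogram, PC1, theta, EMG, motion) of a session."""
    if bundle.lfp is None:
        raise DomainError("session bundle has no LFP channel")
    feats = spectrogram_logf(bundle.lfp.samples, fs=bundle.lfp.fs)
    feats.pc1 = broadband_pc1(feats)
    feats.theta_ratio = theta_ratio(feats)
    if "emg" in bundle.aux:
        feats.emg = bin_aux(bundle.aux["emg"], feats.times)
    if "motion" in bundle.aux:
        feats.motion = bin_aux(bundle.aux["motion"], feats.times)
    return feats


def score_session(bundle: SessionBundle) -> IntervalSet:
    """Convenience wrapper: features + hierarchical division in one call."""
    return score_states(features_from_session(bundle))
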