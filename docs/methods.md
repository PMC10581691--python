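# Methods

`id2phys` re-implements, as a tested library, the quantitative procedures
used to characterize neurogliaform-type (Id2) cortical interneurons:
intracellular feature extraction with late-spiking / irregular-spiking /
burst-spiking classification, opto-tagging and peri-down-state analysis of
extracellular units, up-state rank order, state-dependent rate indices,
LFP-based sleep scoring, and quantification of depolarization-induced
suppression of inhibition (DSI). Every analysis is exercised end to end on
synthetic data with known ground truth; this note records the models, the
parameter choices, and what the synthetic data do and do not emulate.

## Intracellular feature extraction (`intracell`)

Cells are probed with 1 s square current steps. The measurements follow
the standard slice-physiology conventions:

* **AP detection.** An AP threshold crossing is an upward crossing of
  dV/dt through 20 mV/ms; the AP peak is the voltage maximum within the
  following 2 ms. dV/dt is a central difference on the raw trace
  (optional 3-point smoothing, off by default). Two guards reject noise:
  the peak must exceed the crossing voltage by ≥ 20 mV, and crossings
  closer than 1 ms (or resolving to the same peak) are merged. All three
  values are keyword arguments.
* **Waveform properties.** Threshold voltage at the crossing; peak within
  2 ms; half-width as the total time above the threshold/peak midpoint
  (sub-sample, linearly interpolated); AHP as threshold minus the minimum
  within 10 ms after the peak; rise/fall slopes as the max/min dV/dt
  within 10 ms after the crossing (the fall slope is stored negative;
  `fall_slope_magnitude` gives the tabulated positive convention).
  Cell means average the first AP of every sweep with fewer than 50 APs —
  later APs of bursting cells widen, and very dense trains are excluded.
* **Input resistance.** Ohm's law on a ≥ 150 ms hyperpolarizing step
  (typically −20 pA): ΔV from the pre-step baseline mean (50 ms) to the
  mean of the last 50 ms of the step. Sweeps containing spikes raise a
  contamination error.
* **Membrane τ.** Least-squares fit of V(t) = V∞ + A·e^(−t/τ) over the
  first 300 ms of a subthreshold 1 s step. The baseline/steady-state
  windows and the fit span are not dictated by the protocol itself; the
  values here are declared defaults, all configurable.
* **Rheobase.** Smallest positive step amplitude eliciting ≥ 1 AP, with
  all sweeps at that amplitude returned for latency averaging.
* **Classification.** BS if any rheobase sweep holds ≥ 2 APs with first
  ISI < 10 ms (a > 100 Hz burst); otherwise LS if the first-spike latency
  exceeds 500 ms and IS if below 100 ms. Single-spike latencies in
  [100, 500] ms return UNCLASSIFIED rather than a guess — the three
  groups are empirically well separated, so the band is normally empty.
* **Adaptation index.** Instantaneous rate points (1/ISI at ISI
  midpoints, a symmetric convention) are fit with
  f(t) = A·e^(−t/τ_a) + C by bounded least squares (τ_a ∈ [20 ms, 5 s],
  C ≥ 0); AI = f(1000 ms)/f(100 ms). Requires ≥ 6 APs. A non-convergent
  fit falls back to the ratio of the last-two to the first-two
  instantaneous rates after 100 ms. AI is evaluated at 2× rheobase for
  all classes and additionally at 1.3× rheobase for LS cells (near
  rheobase, IS/BS firing is too irregular for the fit to be meaningful).
* **Regularity.** CV (sample sd / mean, n−1) of the ISIs lying entirely
  inside the last 500 ms of the step, at 2× rheobase; ≥ 3 ISIs required.
* **Firing rate at 2× rheobase.** Spike count per 1 s step, taken
  directly when a sweep exists at the target amplitude, otherwise
  linearly interpolated in current between the bracketing amplitudes;
  extrapolation is refused.

## In vivo unit analyses (`invivo`)

* **PSTH.** Event-aligned rate in 10 ms bins, z-scored against the bins
  of a pre-event baseline window. Baselines are [−0.3, 0] s for pulses
  and [−0.5, −0.25] s for down-state alignment (pre-event windows avoid
  contamination by the event itself; both configurable). A zero baseline
  sd flags z as undefined rather than producing infinities.
* **Opto-tagging.** Three criteria: (1) the mean response rate in the
  0–100 ms post-pulse window exceeds the shuffle-null mean by > 2 of its
  standard deviations; (2) significant modulation at the 10⁻³ cutoff,
  tested as a Poisson excess of the response-window spike count over the
  null-mean expectation — an analytic test is needed here because an
  empirical p from 500 replicates floors at 1/501 ≈ 0.002 and can never
  resolve 10⁻³; (3) the observed statistic differs from the distribution
  of 500 count-preserving pulse-time shuffles (empirical p with the +1
  correction, reported as `p_shuffle`). The default null redraws pulse
  times uniformly over the session; when stimulation is confined to
  particular behavioral epochs (as in the synthetic sessions, where
  pulse blocks run during waking), a session-wide null conflates state
  preference with light response, so a state-matched variant redraws each
  pulse within ± a few seconds of its true time (`null_jitter_s`).
* **Unit classes.** Trough-to-peak duration of the mean waveform (global
  minimum to subsequent maximum) and the rising time constant of the
  autocorrelogram, fit with c·(1 − e^(−t/τ)) + b on 1 ms bins over
  0–50 ms (≥ 500 spikes). Narrow-waveform interneurons: trough-to-peak
  < 0.425 ms; the remainder split into pyramidal (ACG τ > 15 ms) and
  wide-waveform interneurons. The published figures show the separation
  but print no cut values; both thresholds are configurable arguments.
* **Down-state detection.** The summed population rate (≥ 20 units,
  10 ms bins, Gaussian-smoothed with 15 ms sd) is thresholded at 0.2× the
  NREM median; contiguous sub-threshold epochs inside NREM lasting
  50–400 ms are down-states. The peak is the midpoint of the linearly
  interpolated threshold crossings — for the symmetric smoothed valley of
  a population silence this is the minimum's location, and unlike a
  literal argmin it is not dominated by single stray spikes inside the
  silence. Up states are inter-down gaps of 0.2–4 s within one NREM bout.
  The detector is a reconstruction (the original works delegate it to
  prior methods); every parameter is exposed.
* **Peri-down rebound.** `down_z` is the mean z within ±50 ms of the down
  peak and `postdown_z` the mean z in the +90…+200 ms window; a unit is a
  rebound unit when `postdown_z` exceeds 2 s.d.
* **Rank order.** Per up state, each participating unit's rate centroid
  (mean spike time in the epoch) is ranked and normalized to
  (rank−1)/(n−1); epochs with fewer than 5 participants are skipped, and
  a unit's score is its mean normalized rank. The outputs are invariant
  to time translation and dilation of the session.
* **State rates.** Per-state rate = spikes/duration over RUN, QUIET,
  NREM, REM (each requiring ≥ 10 s);
  sleep–awake index = (r_awake − r_sleep)/(r_awake + r_sleep) with
  r_awake = mean(RUN, QUIET), r_sleep = mean(REM, NREM); `rate_cv` is the
  population-sd/mean over the four state rates.
* **Stimulation modulation.** `resp_0_100` is the 0–100 ms response in
  null standard deviations (same shuffle machinery, two-sided p). Units
  are `neg`/`pos` when the response passes ∓2 s.d. with p < 0.05, else
  `none` (the class cuts are declared choices; the source figures print
  none). Peak latency is the location, within 0–200 ms, of the largest
  absolute deviation of the 1 ms PSTH (Gaussian-smoothed, 5 ms sd) from
  its baseline mean. A population helper assigns five equal-count
  response quantiles.

## State scoring (`statescore`)

Spectrograms use a 10 s Hann window sliding by 1 s over 1250 Hz LFP,
sampled at 100 log-spaced frequencies in 1–100 Hz. The broadband metric is
the first principal component of the row-z-scored spectrogram, its sign
fixed so the mean loading below 20 Hz is positive (slow-wave activity
scores high). The theta ratio is power(6–9 Hz)/power(1–20 Hz) — the band
is a declared choice. EMG and motion channels are binned as the mean
absolute signal within ±0.5 s of each spectrogram time.

Scoring divides hierarchically at the trough between the two highest KDE
peaks of each metric: EMG splits awake from sleep; broadband PC1 splits
sleep into NREM versus candidate REM; the theta ratio confirms REM; motion
(or EMG) splits awake into RUN versus QUIET. When a metric's distribution
is unimodal that division is undetectable, and the affected bins go to a
single branch (all awake / all NREM / no REM / all QUIET) — a median split
of a unimodal distribution would fabricate a state transition. Epochs
shorter than 10 s merge into their neighbors. Scoring is fully automatic;
there is no manual-review stage, which a production pipeline would add.
Because all metrics are z-transformed or ratio-based, scoring is invariant
to linear amplitude scaling of the LFP.

## DSI (`dsi`)

IPSCs are outward at the −50 mV holding potential. Peak amplitude is
max(trace − baseline) within 100 ms of the stimulus, with a 50 ms
pre-stimulus baseline (both windows declared defaults); non-positive
results are clipped to zero and flagged. The 80→20 % decay time runs from
the last downward crossing of 80 % of peak to the first subsequent
crossing of 20 %, linearly interpolated — for an exponential with time
constant τ this equals τ·ln 4. Suppression is computed per repetition as
100·(1 − post/pre), averaged within cell (≥ 3 complete repetitions, else
the cell is excluded with a logged reason), then across cells;
whether the ratio is formed per trial or on per-cell means is not
dictated by the protocol, and per-trial-then-cell is the declared,
configurable choice. Population statistics use standard two-tailed paired
(pre/post, recovery/post, dp+/dp−) and unpaired (control/AM251) t-tests.
A cell is `recovered` when its mean recovery amplitude exceeds its mean
post amplitude — the direction the recovery-versus-post test checks.

## Synthetic data (`synth`)

The generators define the study conditions; all are deterministic given
(spec, seed).

* **Intracellular cells** are phenomenological, not conductance-based: a
  passive RC response (R, τ from the phenotype spec) plus stereotyped AP
  templates (piecewise-linear rise/fall sized so the measured half-width
  equals the planted one, an AHP dip, exponential recovery) and, for LS
  cells, a slow depolarizing ramp to threshold before the rheobase spike.
  Class targets default to published population means (LS: 188 MΩ, 12 ms,
  139 pA, 805 ms latency, AI 0.76, CV 0.053, 38 Hz, 0.70 ms half-width,
  14.4 mV AHP; IS and BS analogously). Train sweeps realize a planted
  adaptation profile f(t) = A·e^(−t/τ_a) + C solved from the target AI
  and spike count (τ_a = 400 ms for LS, 150 ms for IS/BS so the planted
  regularity remains reachable); spikes sit at equal-mass quantiles of
  the cumulative rate, and Gaussian time jitter is sized so the realized
  last-500 ms ISI CV equals the planted CV (the profile's own ISI drift
  is subtracted in quadrature). Voltage noise is 0.15 mV sd. This
  suffices to validate extraction and classification; it does not emulate
  channel noise, sag, spike-height accommodation, or electrode artifacts,
  so passing tests say nothing about robustness to those.
* **Sessions** run 1800 s with a wake/NREM/REM schedule (all states
  present), 36 units in four classes (15 PC, 6 NW, 4 WW, 11 Id2) as
  inhomogeneous Poisson processes on a 2 ms grid with class-specific base
  rates and state multipliers (PC/NW lower in sleep, Id2 flat with a REM
  increase). Down-states are a renewal process inside NREM (rate 0.5 Hz;
  Gamma durations, mean 150 ms, clipped to 80–180 ms so a down never
  extends into its own post-down analysis window; inter-down gaps floored
  at 0.65 s so one cycle's rebound stays clear of the next cycle's
  baseline window). During downs all rates drop to 2 % of baseline. Seven
  of the eleven Id2 units carry an additive rebound kernel over
  +90…+200 ms sized to exactly `rebound_gain_sd` (default 4) baseline
  standard deviations of the 10 ms peri-down PSTH. Opto pulses (100 ms,
  400 ± 200 ms intervals, 600 by default) are delivered in blocks during
  waking epochs — stimulating during sleep would contaminate the
  down-state analyses with pulse-locked spikes. Id2 units follow pulses
  with 90 % reliability at 5 ± 2 ms; half the PC/NW/WW units are
  suppressed (×0.25, 0–80 ms) and 15 % slowly facilitated (×2.2,
  60–160 ms). Waveform templates give class trough-to-peak of 0.90 /
  0.30 / 0.65 / 0.70 ms (PC/NW/WW/Id2). The LFP carries NREM delta
  (1.5 Hz, amplified during downs), REM theta (7 Hz) and broadband wake
  noise; EMG is high awake / low asleep and a separate motion channel is
  high only during RUN. Real sessions would add 1/f background, state
  transitions with hysteresis, micro-arousals, and unit instability —
  none of which are modeled.
* **DSI cohorts** draw per-cell true suppression from N(mean, cell_sd²) %
  with 5 % multiplicative trial noise and recovery at the pre level. The
  default control cohort plants 16 % (n = 18, cell sd 8.5 — the spread
  implied by the published SEM); the CB1-blocked comparison plants 8 %
  (n = 11, cell sd 3.3).

## Problem sizes and numerical choices

Benchmarks run at the sizes their checks state: 300 cells (100 per class)
for classifier recovery; 100 seeded LS cells for AI/CV recovery; 500 null
Poisson units × 500 shuffle replicates for the tagging type-I property;
11 Id2 units per session (3 replicate sessions in the acceptance script,
since a single 11-unit session's per-unit rebound z carries ~0.6 s.d. of
estimation noise from the 25-bin baseline) ; 50 seeded rank-order
sessions; 20 scored sessions of 900 s. Fits use `scipy.optimize.curve_fit`
with explicit bounds and data-driven initial values; degenerate inputs
(zero-amplitude steps, constant spectrograms, flat waveforms, all-zero
count tables) raise typed errors rather than returning silent numbers.
Empirical p-values carry the +1 correction and can never be exactly zero.

## Known limitations

* The down-state detector and the NW/WW/PC thresholds are reconstructions
  of delegated or unprinted steps; they are parameterized, not inferred
  from the original resources.
* State scoring has no manual-review stage and no micro-arousal handling.
* The intracellular generator cannot be used to study waveform biophysics
  (templates are stereotyped); only the extraction logic is validated.
* IS/BS train generation favors the planted AI over the planted CV when
  the two conflict through the profile's deterministic ISI drift; LS
  trains (the quantitative recovery target) realize both.
* `UnitRecord` waveforms are means; within-unit waveform variability and
  drift are not modeled, so the class thresholds are only exercised near
  their defaults.
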