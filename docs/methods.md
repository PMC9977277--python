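# Methods

This note documents the models, conventions and numerical choices behind
`rhythmxmit`, in the spirit of a methods appendix: enough detail to
reproduce or challenge any number the package prints.

## Signal model and preprocessing

Extracellular population activity from a rhythmic slice is treated as a
noise-like multiunit carrier amplitude-modulated by a slow burst envelope,
sampled at 5 kHz (patch sweeps at 40 kHz). Absolute voltages are arbitrary
(amplifier gain ~10,000×), so every reported metric is a ratio or a rate;
the test suite enforces invariance of transmission, I/O, IrS_AMP and
subnetwork fraction under positive rescaling of any channel.

The **integrated trace** is computed as: subtract the trace mean (AC
coupling in effect; makes the pipeline offset-invariant), full-wave
rectify, then smooth with a centered moving average of width **τ = 50 ms**
(`integrate.tau_s`). The conventional range for integrating respiratory
population traces is 20–100 ms; 50 ms suppresses the carrier while
preserving 300–800 ms bursts at 0.2–0.45 Hz rhythms. The kernel is
edge-truncated and renormalized, so the envelope is unbiased in level at
the trace boundaries. The moving average is evaluated by direct
convolution rather than a running sum: a running sum accumulates
position-dependent rounding, whereas direct convolution returns
bit-identical envelopes for identical burst waveforms anywhere in the
trace — which is what lets the degenerate-recording tests assert exact
(not approximate) identities.

**Baseline** level and spread of the envelope are the sample median and
1.4826 × MAD. Medians tolerate bursts occupying well under half the
record; with ≤10 % burst contamination the level shifts by <5 % (tested).

## Burst detection

Hysteresis thresholding on the integrated trace: a burst opens where the
envelope exceeds `baseline + k_on·spread` and spans the surrounding
contiguous region above `baseline + k_off·spread`. Defaults `k_on = 4`,
`k_off = 2`, minimum duration 100 ms, merge gap 200 ms — all well inside
the burst/period scales of the slice rhythm and configurable
(`detect.*`). Onset and offset are the threshold crossings; peak amplitude
and area are baseline-subtracted. Merging precedes the duration filter.
On synthetic recordings at peak SNR ≥ 8 (peak over baseline spread), the
detector's recall and precision exceed 0.95 over 100 seeds; at SNR ≈ 6 and
below, recall degrades and reported metrics should not be trusted.

## Rhythm metrics

- **f_inst**: reciprocal onset-to-onset interval; the window mean is the
  arithmetic mean of per-cycle values.
- **IrS_AMP**: mean relative successive difference,
  (1/(N−1)) Σ |A(n+1) − A(n)| / A(n), computed on burst **peak amplitude**
  by default (`irs.feature`; area available), unscaled (`irs.scaled`
  multiplies by 100). For an i.i.d. amplitude sequence the score estimates
  E|X₂−X₁|/X₁, which is how it is validated against a resampling oracle.
- **Subnetwork bursts**: events whose integrated burst **area**
  (`subnetwork.feature`; the figure-legend convention — peak amplitude is
  available because the field sometimes states the rule in amplitude
  terms) is ≤ 50 % (`subnetwork.threshold_fraction`) of the reference mean
  area. The reference is the slice's baseline-phase mean when a
  within-slice baseline exists, else the recording's own analysis-window
  mean.

## Cross-site correspondence and the I/O ratio

A downstream burst corresponds to an upstream cycle when onset lag falls
within a tolerance window in **[0.5, 0.75] s** (unsigned by default;
`match.directional` restricts to post-after-pre). The tolerance is
*maximized*: scanning a 10 ms grid downward from 0.75 s, the largest
window at which each upstream burst has at most one candidate and each
downstream burst at most one claimant defines the matching (at that point
the forced matching is simultaneously the maximum-cardinality,
minimum-total-lag assignment). If no window in the range is conflict-free,
the package falls back to an optimal one-to-one assignment at 0.75 s
(Hungarian algorithm): maximum matches first, minimum total |lag| second,
minimum total lag² third. The third criterion matters because when all
lags share a sign the total |lag| is permutation-invariant — ties are
structural — and strict convexity then uniquely selects the non-crossing
pairing. Matching is validated against an exhaustive brute-force
assignment enumerator on a thousand random instances.

Per cycle, with each site's burst area normalized to that site's mean over
the analysis window, IO = normalized XII area / normalized preBötC area,
and 0 for failed cycles. The downstream window mean is taken over detected
downstream bursts only; zeros enter at the ratio stage, not the
normalization. The window mean I/O **includes** the zeros
(`io.include_failures`) — that inclusion is precisely what makes failing
transmission depress mean I/O alongside the transmission percentage.

Analysis windows are the final **120 s** (`window.duration_s`) of each
600 s experimental phase, bounds closed. Heat maps show up to 25
consecutive cycles per slice (`heatmap.max_cycles`), missing cells marked
`NA`. Burst-area histograms bin normalized upstream area at 0.1
(`hist.bin_width`), with transmitted/untransmitted counts as percent of
all cycles; bin assignment uses a 1e-12-tolerant floor so areas sitting
exactly on an edge land in the upper bin. In triple recordings the two
stages (preBötC→premotor, premotor→XIIn) are matched independently: a
cycle can cross the first synapse and still fail the second.

## Patch metrics

- **Drive currents** (voltage clamp, holding −60 mV): per upstream burst,
  the search spans [onset − 0.1 s, onset + 1 s], truncated at the next
  onset. The peak is measured on a 5 ms-smoothed trace; the drive/no-drive
  decision uses a 150 ms-smoothed copy (about half a drive envelope)
  against `k_noise = 4` spreads, because the extreme of ~40,000 raw noise
  samples per window would otherwise cross any fixed threshold routinely.
  The decision spread is the 5 ms-scale robust spread rescaled by
  √(5/150), assuming the noise is white beyond the 5 ms scale — the short
  filter has ~25× more effective quiet samples, so this estimate is much
  better conditioned than a direct MAD of the wide filter. Even so,
  thresholding unbounded noise has a residual false-positive rate
  (~0.5 % per cycle window at these SNRs); no-drive flags on single cycles
  should be read with that in mind.
- **Action potentials per burst** (current clamp): upward crossings of
  −20 mV (`ap.threshold_mv` — conservative for motoneuron spikes from
  resting −55 to −70 mV) with a 2 ms refractory, counted in the same
  burst-aligned window. Counts are invariant to DC offsets below the
  detection level.
- **Rheobase**: from the ramp protocol (−100 pA step of 0.5 s, then a
  122 pA/s ramp to 600 pA), rheobase = ramp rate × (first spike time −
  ramp start), clamped to [0, 600] pA — the commanded-current convention.
  A sweep with no spike before the ramp peak returns a distinct no-spike
  result, not an error. Validated against an adaptively integrated LIF
  first-crossing oracle to within 5 % across a resistance × threshold
  grid; a liquid-junction correction (−12 mV) is assumed applied upstream
  (flag available at load).

## Synthetic data: what it emulates, and what it does not

`generate_recording` draws preBötC onsets from a **gamma renewal process**
(mean rate `f_mean`, interval CV `period_cv`) — positive periods with
controllable variability and no serial correlation. Each burst is a
raised-cosine envelope (duration `burst_duration`) with lognormal peak
amplitude (mean `amp_mean`, CV `amp_cv`), scaled by `subnetwork_scale`
with probability `p_subnetwork`. Each downstream site copies each cycle
with independent Bernoulli survival 1 − `p_fail` per stage
(`p_fail_subnetwork` optionally overrides the rate for subnetwork cycles,
for studying failures conditioned on weak input), onset lag ~
N(`lag_mean`, `lag_sd`), and independently drawn amplitude — independence
makes mean I/O a nontrivial statistic rather than a copy artifact. The raw
trace is band-limited Gaussian noise (300–1500 Hz) amplitude-modulated by
the envelope, plus additive white noise `noise_sd`, so rectify-integrate
is exercised nontrivially. Onsets are snapped to the sample grid (exact at
5 kHz, physically inconsequential), which is what allows bit-exact
identities in degenerate configurations. Everything is deterministic given
`seed`.

Defaults portray a **baseline wild-type slice**: `f_mean = 0.225` Hz,
`period_cv = 0.12`, `burst_duration = 0.5` s, `amp_cv = 0.2`,
`p_fail = 0.06` (≈94 % transmission), `p_subnetwork = 0.05`,
`subnetwork_scale = 0.3`, `lag` ~ N(0.12 s, 0.03 s), `noise_sd = 0.05`.
Intervals are floored at `burst_duration + 0.2 s` so envelopes never
overlap; configurations with `burst_duration` ≥ half the mean period are
rejected outright.

What the generator does **not** model: serial correlation of periods or
amplitudes (real rhythms drift), burst-shape asymmetry (ramping vs
decrementing envelopes), non-stationary baselines, colored recording
noise, or any biophysics of the rhythm generator. Recovery tests passing
on this generator therefore certify the *estimators* (detection, matching,
normalization, ratio statistics) under the stated statistical structure —
they do not certify robustness to drift or non-stationarity in biological
recordings.

The LIF surrogate (`simulate_ramp_response`) integrates
τ·dV/dt = −(V − V_rest) + R·I(t) by forward Euler at the sweep's sampling
rate (step must be < τ/2; at 40 kHz and τ = 20 ms the step is 1/800 of τ),
with spike-and-reset at threshold and a 2 ms refractory. Rendered spikes
are single-sample apexes at +20 mV, so threshold-crossing detection finds
them at the integration step's resolution. The independent oracle solves
the same ODE with adaptive RK45 and a terminal event.

## Statistics

`compare_groups` wraps scipy.stats: paired/unpaired two-tailed t-tests,
Wilcoxon matched-pairs signed-rank, and one-way ANOVA with Dunnett's post
hoc against the control group. Significance at p < 0.05. Edge cases are
made explicit rather than propagated as NaN: identical paired vectors
report statistic 0, p = 1; a constant nonzero paired difference
(zero-variance) raises a degenerate-data error. The paired-t wrapper's
type-I error is verified at ≈5 % under the null over 10⁴ replicates.

## Problem sizes used in validation

The validation suite runs on deliberately compact problems: recordings of
60–200 s (27–45 cycles per 120 s window at the default rhythm), pooled
over 8–20 seeds per condition so that binomial confidence intervals on
transmission and subnetwork rates span a few percent; detection
sensitivity uses 100 × 60 s single-channel recordings; matching is checked
on 1,000 instances of ≤8 events per site (the exhaustive oracle's
enumeration stays small on sparse graphs); the rheobase grid is 5 × 5.
These sizes make the estimators' sampling error the binding constraint,
not the simulation length.

## Known limitations

- Detection onsets are threshold crossings, so they lag true envelope
  onsets by a rise-time-dependent amount (well under the 0.5 s matching
  tolerance at these burst shapes); onset-lag estimates inherit this bias
  at both sites and largely cancel in the lag difference.
- The matching tolerance grid (10 ms) bounds how precisely "the largest
  conflict-free window" is resolved; this only matters in the rare
  configurations where uniqueness flips within a grid step.
- IrS_AMP is formula-specific: the mean relative successive difference,
  forward-referenced, unscaled. Other irregularity variants in the
  literature (×100, symmetric denominators) can be emulated via
  `irs.scaled` but are not separately named.
- The I/O window mean includes failed cycles as zeros by design; excluding
  them (`io.include_failures = False`) yields a conditional-on-success
  I/O that answers a different question.
- Vendor acquisition formats (ABF, Spike2) are out of scope; convert to
  CSV or the HDF5 container first.
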