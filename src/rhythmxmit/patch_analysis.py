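"""Single-neuron excitability metrics from whole-cell patch recordings.

Three measurements mirror the standard characterization of inspiratory
hypoglossal motoneurons:

* **Inspiratory drive currents** (voltage clamp, holding −60 mV): the peak
  inward (most negative, baseline-subtracted) current locked to each
  upstream population burst.  Cycles with no deflection beyond ``k_noise``
  robust spreads are reported as *no-drive*, capturing skipped transmission
  at the cellular level.
* **Action potentials per burst** (current clamp): upward crossings of a
  detection level (default −20 mV) with a refractory period (default 2 ms),
  counted in the burst-aligned window.
* **Rheobase** from a ramp protocol — a hyperpolarizing step (−100 pA)
  followed by a depolarizing ramp (122 pA/s to a 600 pA peak); the rheobase
  is the commanded current at the first action potential,
  ``ramp_rate * (t_spike - t_ramp_start)``, clamped to [0, peak].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burst_analysis import BurstTrain
from .errors import AlignmentError, ParameterError


@dataclass
class PatchSweep:
    """One whole-cell sweep; units follow the recording mode."""

    samples: np.ndarray               # pA (voltage clamp) or mV (current clamp)
    sampling_rate: float
    mode: str                         # "voltage_clamp" | "current_clamp"
    holding: float = 0.0              # mV (VC) or pA (CC)
    sweep_index: int = 0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class RampProtocol:
    """Current-clamp ramp protocol for rheobase determination."""

    hyperpolarizing_step: float = -100.0   # pA
    ramp_rate: float = 122.0               # pA/s
    peak_current: float = 600.0            # pA
    step_duration: float = 0.5             # s, hyperpolarizing step before ramp

    def __post_init__(self) -> None:
        if self.ramp_rate <= 0 or self.peak_current <= 0:
            raise ValueError("ramp_rate and peak_current must be positive")

    @property
    def ramp_duration(self) -> float:
        return self.peak_current / self.ramp_rate

    def command(self, t: np.ndarray, t0: float = 0.0) -> np.ndarray:
        """Commanded current (pA) at times *t*, ramp starting at t0 + step."""
        rel = np.asarray(t, dtype=float) - t0
        out = np.zeros_like(rel)
        in_step = (rel >= 0) & (rel < self.step_duration)
        out[in_step] = self.hyperpolarizing_step
        ramping = rel >= self.step_duration
        out[ramping] = np.minimum(
            self.ramp_rate * (rel[ramping] - self.step_duration),
            self.peak_current)
        return out


@dataclass
class DriveCurrentEvent:
    """Peak inspiratory drive current for one upstream cycle."""

    burst_time: float          # upstream burst onset, s
    peak_current: float        # pA, negative for inward; nan when no drive
    onset_lag: float           # s from burst onset to current peak; nan when no drive
    has_drive: bool


def detect_drive_currents(sweep: PatchSweep, pre_bursts: BurstTrain,
                          search_window: float = 1.0, k_noise: float = 4.0,
                          smooth: float = 0.005,
                          decision_smooth: float = 0.15) -> list[DriveCurrentEvent]:
    """Peak inward current locked to each upstream burst.

    For each upstream onset the search spans [onset − 0.1 s, onset +
    search_window], truncated at the next burst onset.  Peak amplitude is
    measured on a lightly smoothed trace (``smooth``, default 5 ms) to stay
    faithful to the drive envelope; the drive/no-drive decision uses a more
    heavily smoothed copy (``decision_smooth``, default 150 ms — about half
    a synaptic drive envelope) so that the extreme of tens of thousands of
    noise samples per window cannot masquerade as drive.  Baseline and
    noise spread are the median and MAD × 1.4826 of the inter-burst
    samples; a cycle whose sustained deflection stays within ``k_noise``
    decision-scale spreads of baseline is reported as no-drive.
    """
    if sweep.mode != "voltage_clamp":
        raise ParameterError("drive currents require a voltage-clamp sweep")
    if search_window <= 0:
        raise ParameterError("search_window must be positive")
    _check_alignment(sweep, pre_bursts)
    t = sweep.times()
    x = _smooth(sweep.samples, smooth, sweep.sampling_rate)
    x_dec = _smooth(sweep.samples, decision_smooth, sweep.sampling_rate)
    onsets = pre_bursts.onsets()

    in_burst = np.zeros(x.size, dtype=bool)
    for i, onset in enumerate(onsets):
        stop = onset + search_window
        if i + 1 < onsets.size:
            stop = min(stop, onsets[i + 1])
        in_burst |= (t >= onset - 0.1) & (t <= stop)
    quiet = x[~in_burst]
    if quiet.size < 10:
        raise AlignmentError("no inter-burst samples to estimate baseline from")
    baseline = float(np.median(quiet))
    spread = float(1.4826 * np.median(np.abs(quiet - baseline)))
    baseline_dec = float(np.median(x_dec[~in_burst]))
    # the decision spread is the measurement-scale spread rescaled to the
    # wider filter assuming white noise beyond the measurement scale; the
    # short-filter estimate has far more effective quiet samples and is
    # therefore much better conditioned than a direct MAD of the wide filter
    spread_dec = spread * np.sqrt(max(smooth, 1.0 / sweep.sampling_rate)
                                  / decision_smooth)

    events = []
    for i, onset in enumerate(onsets):
        stop = onset + search_window
        if i + 1 < onsets.size:
            stop = min(stop, onsets[i + 1])
        window = (t >= onset - 0.1) & (t <= stop)
        seg = x[window] - baseline
        k = int(np.argmin(seg))
        peak = float(seg[k])
        sustained = float(np.min(x_dec[window]) - baseline_dec)
        if sustained < -k_noise * spread_dec:
            events.append(DriveCurrentEvent(
                burst_time=onset, peak_current=peak,
                onset_lag=float(t[window][k] - onset), has_drive=True))
        else:
            events.append(DriveCurrentEvent(
                burst_time=onset, peak_current=np.nan, onset_lag=np.nan,
                has_drive=False))
    return events


def _smooth(x: np.ndarray, window_s: float, rate: float) -> np.ndarray:
    width = int(round(window_s * rate))
    if width < 2:
        return x
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(x, size=width, mode="nearest")


def detect_spikes(sweep: PatchSweep, threshold: float = -20.0,
                  refractory: float = 0.002) -> np.ndarray:
    """Spike times: upward threshold crossings separated by the refractory."""
    if sweep.mode != "current_clamp":
        raise ParameterError("spike detection requires a current-clamp sweep")
    x = sweep.samples
    crossings = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    t = sweep.t0 + crossings / sweep.sampling_rate
    if t.size == 0:
        return t
    kept = [t[0]]
    for ti in t[1:]:
        if ti - kept[-1] >= refractory:
            kept.append(ti)
    return np.array(kept)


def count_aps_per_burst(sweep: PatchSweep, pre_bursts: BurstTrain,
                        search_window: float = 1.0, threshold: float = -20.0,
                        refractory: float = 0.002) -> tuple[np.ndarray, float]:
    """Action potentials fired in each burst-aligned window, plus the mean."""
    _check_alignment(sweep, pre_bursts)
    spikes = detect_spikes(sweep, threshold=threshold, refractory=refractory)
    onsets = pre_bursts.onsets()
    counts = np.zeros(onsets.size, dtype=int)
    for i, onset in enumerate(onsets):
        stop = onset + search_window
        if i + 1 < onsets.size:
            stop = min(stop, onsets[i + 1])
        counts[i] = int(np.sum((spikes >= onset - 0.1) & (spikes <= stop)))
    return counts, float(counts.mean()) if counts.size else 0.0


def compute_rheobase(sweep: PatchSweep, protocol: RampProtocol,
                     threshold: float = -20.0,
                     refractory: float = 0.002) -> float | None:
    """Commanded current at the first spike of the ramp, or None if no spike.

    Returns the rheobase in pA, clamped to [0, peak_current].  ``None``
    (distinct from an error) signals a neuron whose threshold was not
    reached before the ramp peak.
    """
    spikes = detect_spikes(sweep, threshold=threshold, refractory=refractory)
    ramp_start = sweep.t0 + protocol.step_duration
    ramp_end = ramp_start + protocol.ramp_duration
    during = spikes[(spikes >= ramp_start) & (spikes <= ramp_end)]
    if during.size == 0:
        return None
    current = protocol.ramp_rate * (float(during[0]) - ramp_start)
    return float(np.clip(current, 0.0, protocol.peak_current))


def _check_alignment(sweep: PatchSweep, bursts: BurstTrain) -> None:
    t_end = sweep.t0 + sweep.samples.size / sweep.sampling_rate
    if bursts.events and (bursts.onsets()[0] < sweep.t0 - 1e-9
                          or bursts.onsets()[-1] > t_end + 1e-9):
        raise AlignmentError(
            "burst train extends outside the sweep's time base")
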