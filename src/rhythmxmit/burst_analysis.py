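"""Burst detection and single-site rhythm metrics.

Population bursts are detected on the integrated trace with a hysteresis
threshold expressed in robust-spread multiples above the baseline level: a
burst opens where the envelope exceeds ``baseline + k_on * spread`` and the
event extends over the surrounding contiguous region above
``baseline + k_off * spread``.  Events closer than ``merge_gap`` are merged
and events shorter than ``min_duration`` discarded.

From the resulting burst train the module computes the field's standard
rhythm metrics: instantaneous frequency (f_inst, reciprocal onset-to-onset
interval), burst amplitude and area, the amplitude irregularity score
(IrS_AMP, the mean relative successive difference of burst amplitudes), and
the fraction of "subnetwork" bursts — weak population events whose integrated
area is at or below half the mean burst area of a reference window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientEventsError, NormalizationError, ParameterError
from .preprocessing import IntegratedTrace, estimate_baseline


@dataclass
class BurstEvent:
    """One detected population burst on an integrated trace."""

    onset: float
    offset: float
    peak_amplitude: float   # baseline-subtracted envelope peak
    area: float             # baseline-subtracted integral over [onset, offset]
    site: str
    subnetwork: bool | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


@dataclass
class BurstTrain:
    """Time-ordered, non-overlapping bursts from one site and window."""

    events: list[BurstEvent]
    window_start: float
    window_end: float
    site: str

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be strictly ordered by onset")
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset:
                raise ValueError("events must not overlap")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=float)

    def areas(self) -> np.ndarray:
        return np.array([e.area for e in self.events], dtype=float)

    def peak_amplitudes(self) -> np.ndarray:
        return np.array([e.peak_amplitude for e in self.events], dtype=float)


@dataclass
class RhythmMetrics:
    """Per-recording aggregate of single-site rhythm metrics."""

    f_inst_mean: float
    amplitude_mean: float
    irs_amp: float
    subnetwork_fraction: float
    n_cycles: int


def detect_bursts(itrace: IntegratedTrace, k_on: float = 4.0,
                  k_off: float = 2.0, min_duration: float = 0.1,
                  merge_gap: float = 0.2) -> BurstTrain:
    """Hysteresis burst detection on an integrated trace.

    Returns an empty train (not an error) when nothing crosses the onset
    threshold.  Onset/offset are the boundaries of the contiguous region
    above the off threshold; peak and area are baseline-subtracted.
    """
    if k_on <= k_off:
        raise ParameterError(f"k_on ({k_on}) must exceed k_off ({k_off})")
    if k_off < 0:
        raise ParameterError("k_off must be nonnegative")
    if min_duration <= 0:
        raise ParameterError("min_duration must be positive")
    if itrace.baseline_level is None or itrace.baseline_spread is None:
        estimate_baseline(itrace)
    level = itrace.baseline_level
    spread = itrace.baseline_spread
    on_thr = level + k_on * spread
    off_thr = level + k_off * spread

    x = itrace.samples
    rate = itrace.sampling_rate
    dt = 1.0 / rate

    above_off = x > off_thr
    runs = _runs(above_off)
    # keep only excursions that actually reach the onset threshold
    runs = [(a, b) for a, b in runs if np.max(x[a:b]) > on_thr]

    # merge runs separated by less than merge_gap
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) * dt < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        if (b - a) * dt < min_duration:
            continue
        seg = x[a:b]
        peak = float(np.max(seg) - level)
        area = float(np.sum(seg - level) * dt)
        events.append(BurstEvent(onset=itrace.t0 + a * dt,
                                 offset=itrace.t0 + b * dt,
                                 peak_amplitude=peak, area=area,
                                 site=itrace.source_site))
    return BurstTrain(events=events, window_start=itrace.t0,
                      window_end=itrace.t0 + x.size * dt,
                      site=itrace.source_site)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean mask."""
    padded = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def instantaneous_frequency(train: BurstTrain) -> tuple[np.ndarray, float]:
    """Per-cycle f_inst = 1 / (onset_{n+1} - onset_n), plus its mean."""
    if len(train) < 2:
        raise InsufficientEventsError(
            f"f_inst needs at least 2 events, got {len(train)}")
    intervals = np.diff(train.onsets())
    f_inst = 1.0 / intervals
    return f_inst, float(f_inst.mean())


def irregularity_score_amplitude(train: BurstTrain,
                                 feature: str = "peak_amplitude",
                                 scaled: bool = False) -> float:
    """Amplitude irregularity score: mean of |A_{n+1} - A_n| / A_n.

    ``feature`` selects the burst peak amplitude (default) or integrated
    area.  ``scaled=True`` multiplies by 100.  Identical successive values
    give exactly 0; the score is invariant to rescaling all amplitudes.
    """
    if len(train) < 2:
        raise InsufficientEventsError(
            f"IrS_AMP needs at least 2 events, got {len(train)}")
    values = _feature_values(train, feature)
    if np.any(values <= 0):
        raise ValueError("all feature values must be positive")
    score = float(np.mean(np.abs(np.diff(values)) / values[:-1]))
    return 100.0 * score if scaled else score


def classify_subnetwork(train: BurstTrain, baseline_mean_area: float,
                        threshold_fraction: float = 0.5,
                        feature: str = "area") -> tuple[list[bool], float]:
    """Flag subnetwork bursts and return (flags, percent of total).

    A burst is a subnetwork event when its integrated area (or peak
    amplitude, per ``feature``) is at or below ``threshold_fraction`` times
    the reference mean — by convention the mean burst area of the baseline
    phase of the same slice, or of the recording's own analysis window when
    no within-slice baseline exists.  Flags are also stored on the events.
    """
    if baseline_mean_area <= 0:
        raise NormalizationError("baseline_mean_area must be positive")
    if not 0 < threshold_fraction < 1:
        raise ParameterError("threshold_fraction must lie in (0, 1)")
    if len(train) == 0:
        raise InsufficientEventsError(
            "subnetwork fraction is undefined for an empty train")
    values = _feature_values(train, feature)
    flags = (values <= threshold_fraction * baseline_mean_area).tolist()
    for event, flag in zip(train.events, flags):
        event.subnetwork = bool(flag)
    fraction = 100.0 * sum(flags) / len(flags)
    return flags, fraction


def rhythm_metrics(train: BurstTrain, baseline_mean_area: float | None = None,
                   irs_feature: str = "peak_amplitude",
                   subnetwork_threshold: float = 0.5,
                   subnetwork_feature: str = "area") -> RhythmMetrics:
    """Bundle f_inst, mean amplitude, IrS_AMP and subnetwork % for one train.

    When ``baseline_mean_area`` is None the train's own mean area is the
    subnetwork reference (own-window normalization).
    """
    _, f_mean = instantaneous_frequency(train)
    irs = irregularity_score_amplitude(train, feature=irs_feature)
    if baseline_mean_area is None:
        baseline_mean_area = float(train.areas().mean())
    _, sub_frac = classify_subnetwork(
        train, baseline_mean_area, threshold_fraction=subnetwork_threshold,
        feature=subnetwork_feature)
    return RhythmMetrics(f_inst_mean=f_mean,
                         amplitude_mean=float(train.peak_amplitudes().mean()),
                         irs_amp=irs, subnetwork_fraction=sub_frac,
                         n_cycles=len(train))


def _feature_values(train: BurstTrain, feature: str) -> np.ndarray:
    if feature == "peak_amplitude":
        return train.peak_amplitudes()
    if feature == "area":
        return train.areas()
    raise ParameterError(f"unknown feature {feature!r}")
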