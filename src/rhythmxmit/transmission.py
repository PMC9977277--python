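"""Cross-site burst correspondence, I/O ratios, and transmission statistics.

Each cycle is defined by an upstream (preBötC) burst.  A downstream burst
*corresponds* to it when their onsets lie within a tolerance window of
500–750 ms; the tolerance is widened over that range until the
correspondence is unique — at most one downstream burst per upstream burst
and vice versa.  Cycles with no corresponding downstream burst are
transmission failures.

For each cycle n the input–output ratio is

    IO_n = (∫BA_XII,n / mean ∫BA_XII) / (∫BA_preBotC,n / mean ∫BA_preBotC)

with both burst areas normalized to their site's mean over the analysis
window, and the downstream area set to 0 on failed cycles.  Transmission is
the percentage of upstream cycles with a corresponding downstream burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .burst_analysis import BurstEvent, BurstTrain
from .errors import (InsufficientEventsError, NormalizationError,
                     ParameterError, WindowRangeError)

#: Cost assigned to an infeasible pre/post pairing in the fallback assignment.
_INFEASIBLE = 1e9
#: Weight of the squared-lag tie-break: among assignments with equal total
#: |lag| (structurally common when all lags share a sign), the strictly
#: convex term uniquely selects the non-crossing pairing.
_SQ_EPS = 1e-6
#: Last-resort tie-break favoring earlier downstream bursts.
_TIE_EPS = 1e-12


@dataclass
class CycleRecord:
    """One upstream cycle with its downstream correspondence and I/O fields."""

    cycle_index: int                  # 1-based
    pre_event: BurstEvent
    post_event: BurstEvent | None = None
    lag: float | None = None          # post onset - pre onset, when matched
    transmitted: bool = False
    subnetwork: bool = False
    pre_area_norm: float | None = None
    post_area_norm: float | None = None
    io_ratio: float | None = None

    def to_row(self) -> dict:
        return {
            "cycle_index": self.cycle_index,
            "pre_onset_s": self.pre_event.onset,
            "pre_area": self.pre_event.area,
            "pre_peak": self.pre_event.peak_amplitude,
            "post_onset_s": np.nan if self.post_event is None else self.post_event.onset,
            "post_area": np.nan if self.post_event is None else self.post_event.area,
            "lag_s": np.nan if self.lag is None else self.lag,
            "transmitted": self.transmitted,
            "subnetwork": self.subnetwork,
            "pre_area_norm": np.nan if self.pre_area_norm is None else self.pre_area_norm,
            "post_area_norm": np.nan if self.post_area_norm is None else self.post_area_norm,
            "io_ratio": np.nan if self.io_ratio is None else self.io_ratio,
        }


@dataclass
class TransmissionSummary:
    """Window-level transmission percentage and mean I/O ratio."""

    transmission_pct: float
    io_mean: float
    n_cycles: int
    window: tuple[float, float]

    def to_row(self) -> dict:
        return {"transmission_pct": self.transmission_pct,
                "io_mean": self.io_mean, "n_cycles": self.n_cycles,
                "window_start_s": self.window[0], "window_end_s": self.window[1]}


def match_bursts(pre: BurstTrain, post: BurstTrain, w_min: float = 0.5,
                 w_max: float = 0.75, grid_step: float = 0.01,
                 directional: bool = False) -> list[CycleRecord]:
    """Match downstream bursts to upstream cycles by onset lag.

    The correspondence tolerance is maximized: scanning a ``grid_step`` grid
    downward from ``w_max`` to ``w_min``, the largest window at which every
    upstream burst has at most one candidate (|lag| <= w, or 0 <= lag <= w
    when ``directional``) and every downstream burst is claimed at most once
    defines the matching.  If no window in the range yields a unique
    correspondence, a one-to-one assignment at ``w_max`` maximizing the
    number of matches and minimizing total |lag| (ties broken toward earlier
    downstream bursts) is used instead.
    """
    if not w_max >= w_min > 0:
        raise ParameterError("need w_max >= w_min > 0")
    if not pre.events:
        return []
    pre_onsets = pre.onsets()
    post_onsets = post.onsets()

    assignment: dict[int, int] | None = None
    if post.events:
        lags = post_onsets[None, :] - pre_onsets[:, None]
        for w in _descending_grid(w_min, w_max, grid_step):
            feasible = _feasible(lags, w, directional)
            pre_degree = feasible.sum(axis=1)
            post_degree = feasible.sum(axis=0)
            if np.all(pre_degree <= 1) and np.all(post_degree <= 1):
                pairs = np.argwhere(feasible)
                assignment = {int(i): int(j) for i, j in pairs}
                break
        if assignment is None:
            assignment = _optimal_assignment(lags, w_max, directional)
    else:
        assignment = {}

    records = []
    for i, pre_event in enumerate(pre.events):
        j = assignment.get(i)
        if j is None:
            records.append(CycleRecord(cycle_index=i + 1, pre_event=pre_event))
        else:
            post_event = post.events[j]
            records.append(CycleRecord(
                cycle_index=i + 1, pre_event=pre_event, post_event=post_event,
                lag=post_event.onset - pre_event.onset, transmitted=True))
    return records


def _descending_grid(w_min: float, w_max: float, step: float) -> np.ndarray:
    n = int(np.floor((w_max - w_min) / step + 1e-9))
    grid = w_max - step * np.arange(n + 1)
    if grid[-1] > w_min + 1e-12:
        grid = np.append(grid, w_min)
    return grid


def _feasible(lags: np.ndarray, w: float, directional: bool) -> np.ndarray:
    tol = 1e-12
    if directional:
        return (lags >= -tol) & (lags <= w + tol)
    return np.abs(lags) <= w + tol


def _optimal_assignment(lags: np.ndarray, w: float,
                        directional: bool) -> dict[int, int]:
    """Max-cardinality, min-total-|lag| one-to-one assignment at window w."""
    feasible = _feasible(lags, w, directional)
    cost = np.where(feasible,
                    np.abs(lags) + _SQ_EPS * lags ** 2
                    + _TIE_EPS * np.arange(lags.shape[1])[None, :],
                    _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    return {int(i): int(j) for i, j in zip(rows, cols) if feasible[i, j]}


def compute_io(records: list[CycleRecord], pre_window_mean_area: float,
               post_window_mean_area: float) -> list[CycleRecord]:
    """Set normalized areas and I/O ratios on *records* in place.

    The window means are the site-wise mean burst areas of the analysis
    window; the downstream mean is computed over detected downstream bursts
    (failed cycles contribute a 0 only at the ratio stage).
    """
    if pre_window_mean_area <= 0 or post_window_mean_area <= 0:
        raise NormalizationError("window mean areas must be positive")
    for record in records:
        record.pre_area_norm = record.pre_event.area / pre_window_mean_area
        if record.transmitted and record.post_event is not None:
            record.post_area_norm = record.post_event.area / post_window_mean_area
        else:
            record.post_area_norm = 0.0
        record.io_ratio = record.post_area_norm / record.pre_area_norm
    return records


def transmission_percentage(records: list[CycleRecord]) -> float:
    """Percentage of cycles with a corresponding downstream burst."""
    if not records:
        raise InsufficientEventsError(
            "transmission is undefined with no cycles")
    return 100.0 * sum(r.transmitted for r in records) / len(records)


def io_mean(records: list[CycleRecord], include_failures: bool = True) -> float:
    """Mean I/O ratio over the window.

    Failed cycles enter as 0 by default, which is what lets reduced
    transmission depress the mean I/O.
    """
    if not records:
        raise InsufficientEventsError("io_mean is undefined with no cycles")
    ratios = [r.io_ratio for r in records
              if include_failures or r.transmitted]
    if any(r is None for r in ratios):
        raise ValueError("run compute_io before io_mean")
    if not ratios:
        return 0.0
    return float(np.mean(ratios))


def summarize(records: list[CycleRecord],
              include_failures: bool = True) -> TransmissionSummary:
    onsets = [r.pre_event.onset for r in records]
    return TransmissionSummary(
        transmission_pct=transmission_percentage(records),
        io_mean=io_mean(records, include_failures=include_failures),
        n_cycles=len(records),
        window=(min(onsets), max(onsets)))


def select_analysis_window(obj, phase_end: float, duration: float = 120.0):
    """Restrict a train or record list to onsets in [phase_end - duration, phase_end].

    The lower bound is closed, the upper bound closed as well; the window is
    conventionally the final 120 s of a 600 s experimental phase.
    """
    start = phase_end - duration
    if isinstance(obj, BurstTrain):
        if start < obj.window_start - 1e-9 or phase_end > obj.window_end + 1e-9:
            raise WindowRangeError(
                f"window [{start}, {phase_end}] outside recording "
                f"[{obj.window_start}, {obj.window_end}]")
        kept = [e for e in obj.events if start <= e.onset <= phase_end]
        return BurstTrain(events=kept, window_start=start,
                          window_end=phase_end, site=obj.site)
    records = [r for r in obj if start <= r.pre_event.onset <= phase_end]
    return records


def burst_area_histogram(records: list[CycleRecord],
                         bin_width: float = 0.1) -> pd.DataFrame:
    """Binned distribution of normalized upstream burst areas.

    Bins ``[0, bin_width), [bin_width, 2*bin_width), ...`` over
    ``pre_area_norm``; per-bin transmitted and untransmitted counts are
    expressed as percent of all cycles, so the two series together sum
    to 100%.
    """
    if not records:
        raise InsufficientEventsError("histogram of no cycles")
    values = np.array([r.pre_area_norm for r in records], dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError("run compute_io before burst_area_histogram")
    transmitted = np.array([r.transmitted for r in records])
    # tolerant floor so values sitting on a bin edge land in the upper bin
    idx = np.floor(values / bin_width * (1 + 1e-12) + 1e-12).astype(int)
    n_bins = int(idx.max()) + 1
    edges = bin_width * np.arange(n_bins + 1)
    total = len(records)
    t_counts = np.bincount(idx[transmitted], minlength=n_bins)
    u_counts = np.bincount(idx[~transmitted], minlength=n_bins)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "transmitted_pct": 100.0 * t_counts / total,
        "untransmitted_pct": 100.0 * u_counts / total,
    })


def build_heatmap(per_slice_records: list[list[CycleRecord]],
                  max_cycles: int = 25) -> pd.DataFrame:
    """I/O-ratio heat map: one row per slice, up to *max_cycles* columns.

    Cells beyond a slice's available cycle count are NaN ("non-events",
    rendered gray); the CSV writer emits them as ``NA``.
    """
    if not per_slice_records:
        raise InsufficientEventsError("heat map of no slices")
    matrix = np.full((len(per_slice_records), max_cycles), np.nan)
    for row, records in enumerate(per_slice_records):
        ratios = [r.io_ratio for r in records[:max_cycles]]
        if any(r is None for r in ratios):
            raise ValueError("run compute_io before build_heatmap")
        matrix[row, :len(ratios)] = ratios
    return pd.DataFrame(
        matrix, columns=[f"cycle_{i + 1}" for i in range(max_cycles)],
        index=pd.RangeIndex(len(per_slice_records), name="slice"))


def chain_transmission(pre: BurstTrain, mid: BurstTrain, post: BurstTrain,
                       **match_kwargs) -> tuple[list[CycleRecord], list[CycleRecord]]:
    """Stage-wise correspondence for triple recordings.

    Matches (pre -> mid) and (mid -> post) independently: a cycle can be
    transmitted into the premotor field and still fail between the premotor
    field and the motor nucleus.
    """
    return (match_bursts(pre, mid, **match_kwargs),
            match_bursts(mid, post, **match_kwargs))
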