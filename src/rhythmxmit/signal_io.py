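"""Reading and writing traces and result tables.

Two trace formats are supported:

* **delimited** — CSV with a header row.  An optional ``time`` column (seconds,
  uniformly spaced) sets the sampling rate; the remaining columns are channels
  named by recording site (``preBotC``, ``premotor``, ``XIIn``, ``patch``).
* **container** — HDF5 with one group per site holding a ``samples`` dataset
  and ``sampling_rate`` / ``site_label`` / ``units`` attributes (plus optional
  ``t0`` and ``sweep_index``).  Simultaneously recorded sites stay aligned in a
  single file.

Result tables (cycle records, slice summaries) are plain CSV and round-trip
losslessly through :func:`write_results` / :func:`read_results`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, SamplingError

#: Recognized recording sites.
SITE_LABELS = ("preBotC", "premotor", "XIIn", "patch")

#: Relative tolerance on time-stamp spacing for a column to count as uniform.
_UNIFORMITY_RTOL = 1e-6


@dataclass
class RawTrace:
    """A sampled raw signal from one recording site.

    Amplifier gain makes absolute voltages arbitrary; every downstream metric
    is scale-invariant, so ``units`` is informational only.
    """

    samples: np.ndarray
    sampling_rate: float
    site_label: str
    t0: float = 0.0
    units: str = "mV"
    sweep_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.site_label not in SITE_LABELS:
            raise ValueError(
                f"site_label must be one of {SITE_LABELS}, got {self.site_label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


def read_trace(path: str | Path, format: str = "delimited",
               sampling_rate: float | None = None) -> list[RawTrace]:
    """Read one :class:`RawTrace` per channel from *path*.

    ``sampling_rate`` is required for delimited files without a time column
    and ignored otherwise.
    """
    path = Path(path)
    if format == "delimited":
        return _read_delimited(path, sampling_rate)
    if format == "container":
        return _read_container(path)
    raise FormatError(f"unknown trace format {format!r}")


def _read_delimited(path: Path, sampling_rate: float | None) -> list[RawTrace]:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.empty:
        raise EmptyInputError(f"{path} has a header but no rows")

    columns = list(frame.columns)
    time_cols = [c for c in columns if c.lower() in ("time", "time_s", "t")]
    t0 = 0.0
    if time_cols:
        t = frame[time_cols[0]].to_numpy(dtype=float)
        if t.size < 2:
            raise EmptyInputError(f"{path}: time column has fewer than 2 rows")
        dt = np.diff(t)
        dt_ref = float(np.median(dt))
        if dt_ref <= 0:
            raise SamplingError(f"{path}: time column is not increasing")
        if np.max(np.abs(dt - dt_ref)) > _UNIFORMITY_RTOL * dt_ref:
            raise SamplingError(f"{path}: time column is not uniformly spaced")
        sampling_rate = 1.0 / dt_ref
        t0 = float(t[0])
        channel_cols = [c for c in columns if c != time_cols[0]]
    else:
        if sampling_rate is None:
            raise FormatError(
                f"{path}: no time column; pass sampling_rate explicitly")
        channel_cols = columns
    if not channel_cols:
        raise FormatError(f"{path}: no channel columns found")

    traces = []
    for col in channel_cols:
        if col not in SITE_LABELS:
            raise FormatError(
                f"{path}: channel column {col!r} is not a known site "
                f"(expected one of {SITE_LABELS})")
        traces.append(RawTrace(frame[col].to_numpy(dtype=float),
                               sampling_rate=float(sampling_rate),
                               site_label=col, t0=t0))
    return traces


def _read_container(path: Path) -> list[RawTrace]:
    if not Path(path).exists():
        raise EmptyInputError(f"{path} does not exist")
    traces = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh.keys()):
            group = fh[name]
            if "samples" not in group:
                raise FormatError(f"{path}:{name} has no 'samples' dataset")
            attrs = group.attrs
            for required in ("sampling_rate", "site_label"):
                if required not in attrs:
                    raise FormatError(
                        f"{path}:{name} missing attribute {required!r}")
            sweep = attrs.get("sweep_index")
            traces.append(RawTrace(
                samples=np.asarray(group["samples"][...], dtype=float),
                sampling_rate=float(attrs["sampling_rate"]),
                site_label=str(attrs["site_label"]),
                t0=float(attrs.get("t0", 0.0)),
                units=str(attrs.get("units", "mV")),
                sweep_index=None if sweep is None else int(sweep)))
    if not traces:
        raise EmptyInputError(f"{path} contains no trace groups")
    return traces


def write_trace(traces: Sequence[RawTrace] | RawTrace, path: str | Path) -> None:
    """Write traces to the HDF5 container format (one group per site)."""
    if isinstance(traces, RawTrace):
        traces = [traces]
    if not traces:
        raise EmptyInputError("no traces to write")
    with h5py.File(path, "w") as fh:
        for i, trace in enumerate(traces):
            group = fh.create_group(f"{i:02d}_{trace.site_label}")
            group.create_dataset("samples", data=trace.samples)
            group.attrs["sampling_rate"] = trace.sampling_rate
            group.attrs["site_label"] = trace.site_label
            group.attrs["units"] = trace.units
            group.attrs["t0"] = trace.t0
            if trace.sweep_index is not None:
                group.attrs["sweep_index"] = trace.sweep_index


def write_results(records, path: str | Path) -> None:
    """Write a result table (DataFrame or sequence of dataclass records) as CSV.

    Column order is the dataclass field order (or the frame's own order) so
    output is stable run to run.  Floats use Python's shortest round-trip
    repr, making ``read_results(write_results(x)) == x``.
    """
    frame = _as_frame(records)
    if frame.empty:
        raise EmptyInputError("refusing to write an empty result table")
    frame.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    if frame.empty:
        raise EmptyInputError(f"{path} has no rows")
    return frame


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if not records:
        return pd.DataFrame()
    first = records[0]
    if hasattr(first, "to_row"):
        return pd.DataFrame([r.to_row() for r in records])
    if hasattr(first, "__dataclass_fields__"):
        import dataclasses
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(records)
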