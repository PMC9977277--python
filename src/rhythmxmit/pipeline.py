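"""End-to-end analysis: preprocess -> detect -> window -> match -> metrics.

`analyze_recording` runs the full pipeline on the simultaneously recorded
extracellular channels of one slice and returns cycle records, stage-wise
transmission summaries and per-site rhythm metrics.  All thresholds come
from the flat config (see :mod:`rhythmxmit.config`); the effective config is
carried on the result so a run is reproducible from its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .burst_analysis import (BurstTrain, RhythmMetrics, classify_subnetwork,
                             detect_bursts, rhythm_metrics)
from .config import DEFAULTS, load_config
from .errors import MissingChannelError
from .preprocessing import IntegratedTrace, estimate_baseline, rectify_integrate
from .signal_io import RawTrace
from .transmission import (CycleRecord, TransmissionSummary, compute_io,
                           match_bursts, select_analysis_window, summarize)

#: Transmission chain order for 2- and 3-site recordings.
CHAIN_ORDER = ("preBotC", "premotor", "XIIn")


@dataclass
class RecordingResult:
    """Bundle of everything the pipeline computes for one recording."""

    trains: dict[str, BurstTrain]
    stage_records: list[list[CycleRecord]]   # one list per chain stage
    summaries: list[TransmissionSummary]
    metrics: dict[str, RhythmMetrics]
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def records(self) -> list[CycleRecord]:
        """Cycle records of the first (preBötC -> next site) stage."""
        return self.stage_records[0]


def analyze_recording(traces: Sequence[RawTrace],
                      config: Mapping[str, Any] | None = None,
                      phase_end: float | None = None,
                      baseline_mean_area: float | None = None) -> RecordingResult:
    """Run the full pipeline on one recording's extracellular channels.

    Parameters
    ----------
    traces
        Raw traces; must include ``preBotC`` and ``XIIn`` (optionally
        ``premotor`` for triple recordings, analyzed stage-wise).
    config
        Flat config mapping; missing keys take package defaults.
    phase_end
        End of the experimental phase in seconds; the analysis window is the
        final ``window.duration_s`` (default 120 s) before it.  ``None``
        analyzes the full recording.
    baseline_mean_area
        Upstream mean burst area from the slice's baseline phase, used as the
        subnetwork reference; default is the window's own mean.
    """
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)

    by_site = {t.site_label: t for t in traces}
    chain = [s for s in CHAIN_ORDER if s in by_site]
    for required in ("preBotC", "XIIn"):
        if required not in by_site:
            raise MissingChannelError(
                f"recording lacks required channel {required!r}; "
                f"found {sorted(by_site)}")

    trains: dict[str, BurstTrain] = {}
    for site in chain:
        itrace = rectify_integrate(by_site[site], tau=cfg["integrate.tau_s"],
                                   center=cfg["integrate.center"])
        estimate_baseline(itrace)
        train = detect_bursts(itrace, k_on=cfg["detect.k_on"],
                              k_off=cfg["detect.k_off"],
                              min_duration=cfg["detect.min_duration_s"],
                              merge_gap=cfg["detect.merge_gap_s"])
        if phase_end is not None:
            train = select_analysis_window(train, phase_end,
                                           duration=cfg["window.duration_s"])
        trains[site] = train

    # subnetwork classification on the upstream train
    pre_train = trains[chain[0]]
    if len(pre_train):
        ref = baseline_mean_area
        if ref is None:
            ref = float(pre_train.areas().mean())
        classify_subnetwork(pre_train, ref,
                            threshold_fraction=cfg["subnetwork.threshold_fraction"],
                            feature=cfg["subnetwork.feature"])

    stage_records: list[list[CycleRecord]] = []
    summaries: list[TransmissionSummary] = []
    for up, down in zip(chain, chain[1:]):
        records = match_bursts(trains[up], trains[down],
                               w_min=cfg["match.w_min_s"],
                               w_max=cfg["match.w_max_s"],
                               grid_step=cfg["match.grid_step_s"],
                               directional=cfg["match.directional"])
        if records and len(trains[down]):
            compute_io(records,
                       pre_window_mean_area=float(trains[up].areas().mean()),
                       post_window_mean_area=float(trains[down].areas().mean()))
        for record in records:
            record.subnetwork = bool(record.pre_event.subnetwork) \
                if record.pre_event.subnetwork is not None else False
        stage_records.append(records)
        if records:
            summaries.append(summarize(
                records, include_failures=cfg["io.include_failures"]))

    metrics = {}
    for site, train in trains.items():
        if len(train) >= 2:
            ref = baseline_mean_area if site == chain[0] else None
            metrics[site] = rhythm_metrics(
                train, baseline_mean_area=ref,
                irs_feature=cfg["irs.feature"],
                subnetwork_threshold=cfg["subnetwork.threshold_fraction"],
                subnetwork_feature=cfg["subnetwork.feature"])

    return RecordingResult(trains=trains, stage_records=stage_records,
                           summaries=summaries, metrics=metrics, config=cfg)
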