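import numpy as np
import pytest

from rhythmxmit.burst_analysis import BurstEvent, BurstTrain
from rhythmxmit.preprocessing import IntegratedTrace
from rhythmxmit.synthetic import SynthConfig


def make_train(onsets, areas=None, peaks=None, site="preBotC",
               duration=0.4) -> BurstTrain:
    """Build a burst train directly from onset/feature arrays."""
    onsets = np.asarray(onsets, dtype=float)
    areas = np.ones_like(onsets) if areas is None else np.asarray(areas, float)
    peaks = areas if peaks is None else np.asarray(peaks, float)
    events = [BurstEvent(onset=float(t), offset=float(t) + duration,
                         peak_amplitude=float(p), area=float(a), site=site)
              for t, a, p in zip(onsets, areas, peaks)]
    start = float(onsets.min()) - 1.0 if onsets.size else 0.0
    end = float(onsets.max()) + duration + 1.0 if onsets.size else 1.0
    return BurstTrain(events=events, window_start=start, window_end=end,
                      site=site)


def make_itrace(samples, rate=1000.0, tau=0.01, level=0.0, spread=1.0,
                site="preBotC") -> IntegratedTrace:
    """Integrated trace with a pre-set baseline, for direct detection tests."""
    return IntegratedTrace(samples=np.asarray(samples, dtype=float),
                           sampling_rate=rate, tau=tau, source_site=site,
                           baseline_level=level, baseline_spread=spread)


@pytest.fixture
def degenerate_cfg() -> SynthConfig:
    """Perfectly periodic, identical-burst, failure-free recording.

    The 0.25 Hz period is an exact number of samples at 5 kHz, so every
    burst is bit-identical and ratio metrics are exact.
    """
    return SynthConfig(seed=0, duration=150.0, f_mean=0.25, period_cv=0.0,
                       amp_cv=0.0, p_fail=0.0, p_subnetwork=0.0,
                       lag_mean=0.12, lag_sd=0.0, noise_sd=0.0, carrier=False)
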