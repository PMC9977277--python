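"""Synthetic rhythmic recordings and patch sweeps with ground truth.

The generator emulates the statistical structure of rhythmic brainstem slice
recordings: the upstream (preBötC) site fires population bursts as a gamma
renewal process (controllable mean frequency and period CV); each burst is a
raised-cosine envelope with lognormal peak amplitude, occasionally scaled
down to a "subnetwork" event; each downstream site reproduces surviving
cycles (independent Bernoulli failures per stage) at a jittered onset lag
with independently drawn amplitude.  The raw trace is band-limited noise
amplitude-modulated by the envelope plus additive white noise, so the
rectify–integrate stage is exercised nontrivially.

Burst onsets are snapped to the sample grid.  Everything is deterministic
given the seed, and the per-cycle ground-truth table is the oracle for all
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigError
from .patch_analysis import PatchSweep, RampProtocol
from .signal_io import RawTrace

#: Site labels by position in the transmission chain.
_CHAIN_2 = ("preBotC", "XIIn")
_CHAIN_3 = ("preBotC", "premotor", "XIIn")


@dataclass
class SynthConfig:
    """Generative parameters for a paired/triple rhythmic recording.

    Defaults portray a baseline wild-type slice: a ~0.225 Hz rhythm with
    moderate cycle-to-cycle variability, rare transmission failures
    (baseline transmission ≈ 94%) and few subnetwork events.
    """

    seed: int = 0
    duration: float = 600.0          # s
    sampling_rate: float = 5000.0    # Hz
    f_mean: float = 0.225            # Hz
    period_cv: float = 0.12
    burst_duration: float = 0.5      # s
    amp_mean: float = 1.0            # arbitrary units
    amp_cv: float = 0.2
    p_fail: float = 0.06             # per downstream stage
    p_fail_subnetwork: float | None = None   # overrides p_fail for subnetwork cycles
    p_subnetwork: float = 0.05
    subnetwork_scale: float = 0.3
    lag_mean: float = 0.12           # s, downstream onset lag
    lag_sd: float = 0.03
    noise_sd: float = 0.05           # additive white noise, same units as amp
    n_sites: int = 2                 # 2 (pre->XII) or 3 (pre->premotor->XII)
    carrier: bool = True             # modulate band-limited noise; False emits
                                     # the bare envelope (deterministic shapes)
    carrier_band: tuple[float, float] = (300.0, 1500.0)

    def __post_init__(self) -> None:
        for name in ("p_fail", "p_subnetwork"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_sites not in (2, 3):
            raise ConfigError("n_sites must be 2 or 3")
        if self.f_mean <= 0 or self.duration <= 0:
            raise ConfigError("f_mean and duration must be positive")
        if self.burst_duration >= 0.5 / self.f_mean:
            raise ConfigError(
                "burst_duration must be well below the mean period "
                f"({self.burst_duration} s vs mean period {1 / self.f_mean:.2f} s)")

    @property
    def site_labels(self) -> tuple[str, ...]:
        return _CHAIN_2 if self.n_sites == 2 else _CHAIN_3


def generate_recording(cfg: SynthConfig) -> tuple[list[RawTrace], pd.DataFrame]:
    """Simulate one multi-site recording; returns (traces, ground truth).

    The ground-truth table has one row per upstream cycle with the realized
    onset, peak amplitude, analytic envelope area and subnetwork flag, plus
    per-stage transmitted flags, onsets and amplitudes for downstream sites.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.sampling_rate
    n = int(round(cfg.duration * rate))
    sites = cfg.site_labels

    onsets = _renewal_onsets(cfg, rng)
    n_cycles = onsets.size
    amps = _lognormal(rng, cfg.amp_mean, cfg.amp_cv, n_cycles)
    subnet = rng.random(n_cycles) < cfg.p_subnetwork
    amps = np.where(subnet, amps * cfg.subnetwork_scale, amps)

    truth = pd.DataFrame({
        "cycle": np.arange(1, n_cycles + 1),
        "pre_onset_s": onsets,
        "pre_amp": amps,
        "pre_area": _envelope_area(amps, cfg),
        "subnetwork": subnet,
    })

    per_site_events = [(onsets, amps)]
    survived = np.ones(n_cycles, dtype=bool)
    for site in sites[1:]:
        p_fail = np.full(n_cycles, cfg.p_fail)
        if cfg.p_fail_subnetwork is not None:
            p_fail[subnet] = cfg.p_fail_subnetwork
        survived = survived & (rng.random(n_cycles) >= p_fail)
        lags = rng.normal(cfg.lag_mean, cfg.lag_sd, n_cycles)
        site_onsets = _snap(per_site_events[-1][0] + lags, rate)
        site_amps = _lognormal(rng, cfg.amp_mean, cfg.amp_cv, n_cycles)
        site_amps = np.where(subnet, site_amps * cfg.subnetwork_scale, site_amps)
        truth[f"transmitted_{site}"] = survived
        truth[f"{site}_onset_s"] = np.where(survived, site_onsets, np.nan)
        truth[f"{site}_amp"] = np.where(survived, site_amps, np.nan)
        truth[f"{site}_area"] = np.where(
            survived, _envelope_area(site_amps, cfg), np.nan)
        per_site_events.append((site_onsets, site_amps))

    traces = []
    for k, site in enumerate(sites):
        site_onsets, site_amps = per_site_events[k]
        if k == 0:
            keep = np.ones(n_cycles, dtype=bool)
        else:
            keep = truth[f"transmitted_{site}"].to_numpy()
        envelope = _render_envelope(site_onsets[keep], site_amps[keep], cfg, n)
        if cfg.carrier:
            carrier = _bandlimited_noise(rng, n, rate, cfg.carrier_band)
            raw = envelope * carrier
        else:
            raw = envelope
        if cfg.noise_sd > 0:
            raw = raw + cfg.noise_sd * rng.standard_normal(n)
        traces.append(RawTrace(raw, sampling_rate=rate, site_label=site))
    return traces, truth


def _renewal_onsets(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    mean_period = 1.0 / cfg.f_mean
    n_draw = int(cfg.duration / mean_period * 2) + 10
    if cfg.period_cv == 0:
        intervals = np.full(n_draw, mean_period)
    else:
        shape = 1.0 / cfg.period_cv ** 2
        intervals = rng.gamma(shape, mean_period / shape, n_draw)
    # enforce a refractory floor so envelopes never overlap and downstream
    # correspondence stays well posed
    floor = cfg.burst_duration + 0.2
    intervals = np.maximum(intervals, floor)
    onsets = np.cumsum(intervals)
    margin = cfg.burst_duration + 1.0
    onsets = onsets[onsets < cfg.duration - margin]
    return _snap(onsets, cfg.sampling_rate)


def _snap(t: np.ndarray, rate: float) -> np.ndarray:
    return np.round(np.asarray(t) * rate) / rate


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _burst_template(cfg: SynthConfig) -> np.ndarray:
    length = int(round(cfg.burst_duration * cfg.sampling_rate))
    j = np.arange(length)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * j / length))


def _envelope_area(amps: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Analytic area under the raised-cosine envelope: amp * duration / 2."""
    return np.asarray(amps) * cfg.burst_duration / 2.0


def _render_envelope(onsets: np.ndarray, amps: np.ndarray, cfg: SynthConfig,
                     n: int) -> np.ndarray:
    template = _burst_template(cfg)
    envelope = np.zeros(n)
    for onset, amp in zip(onsets, amps):
        start = int(round(onset * cfg.sampling_rate))
        stop = min(start + template.size, n)
        if start < 0 or start >= n:
            continue
        envelope[start:stop] += amp * template[:stop - start]
    return envelope


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       band: tuple[float, float]) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    shaped = sosfiltfilt(sos, white)
    return shaped / shaped.std()


# ---------------------------------------------------------------------------
# patch-clamp surrogates
# ---------------------------------------------------------------------------

@dataclass
class LIFParams:
    """Leaky integrate-and-fire surrogate for a hypoglossal motoneuron."""

    tau_m: float = 0.02              # s
    resistance: float = 100.0        # MΩ
    v_rest: float = -65.0            # mV
    v_threshold: float = -45.0       # mV
    v_reset: float = -60.0           # mV
    spike_peak: float = 20.0         # mV, rendered spike apex
    refractory: float = 0.002        # s

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.resistance <= 0:
            raise ConfigError("tau_m and resistance must be positive")
        if self.v_threshold <= self.v_rest:
            raise ConfigError("v_threshold must exceed v_rest")


def simulate_ramp_response(neuron: LIFParams, protocol: RampProtocol,
                           sampling_rate: float = 40000.0,
                           tail: float = 0.2) -> tuple[PatchSweep, dict]:
    """Euler-integrate the LIF response to the ramp protocol.

    Returns the current-clamp sweep (spikes rendered as one-sample apexes at
    ``spike_peak``) and a truth dict with the first spike time and the
    commanded current at that instant (None for a no-spike sweep).
    """
    dt = 1.0 / sampling_rate
    if dt >= neuron.tau_m / 2:
        raise ConfigError("integration step too coarse for tau_m")
    duration = protocol.step_duration + protocol.ramp_duration + tail
    n = int(round(duration * sampling_rate))
    t = np.arange(n) * dt
    current = protocol.command(t)
    v = np.empty(n)
    v[0] = neuron.v_rest
    samples = np.empty(n)
    samples[0] = neuron.v_rest
    # R [MΩ] * I [pA] -> mV needs a 1e-3 factor
    gain = neuron.resistance * 1e-3
    refr_n = int(round(neuron.refractory * sampling_rate))
    first_spike: float | None = None
    spike_times = []
    i = 1
    while i < n:
        dv = dt / neuron.tau_m * (-(v[i - 1] - neuron.v_rest)
                                  + gain * current[i - 1])
        vi = v[i - 1] + dv
        if vi >= neuron.v_threshold:
            spike_times.append(t[i])
            if first_spike is None:
                first_spike = t[i]
            samples[i] = neuron.spike_peak
            v[i] = neuron.v_reset
            stop = min(i + 1 + refr_n, n)
            samples[i + 1:stop] = neuron.v_reset
            v[i + 1:stop] = neuron.v_reset
            i = stop
            continue
        v[i] = vi
        samples[i] = vi
        i += 1
    sweep = PatchSweep(samples, sampling_rate=sampling_rate,
                       mode="current_clamp")
    rheobase = None
    if first_spike is not None:
        rheobase = float(np.clip(
            protocol.ramp_rate * (first_spike - protocol.step_duration),
            0.0, protocol.peak_current))
    return sweep, {"first_spike_s": first_spike, "rheobase_pa": rheobase,
                   "spike_times_s": np.array(spike_times)}


def simulate_drive_sweep(onsets: np.ndarray, duration: float,
                         peak_pa: float = -150.0, width: float = 0.3,
                         lag: float = 0.05, noise_sd: float = 5.0,
                         skip: np.ndarray | None = None, seed: int = 0,
                         sampling_rate: float = 40000.0) -> PatchSweep:
    """Voltage-clamp sweep with a raised-cosine inward current per cycle.

    ``skip`` marks cycles that receive no synaptic drive (skipped
    transmission at the cellular level).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    x = np.zeros(n)
    length = int(round(width * sampling_rate))
    kernel = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(length) / length))
    onsets = np.asarray(onsets, dtype=float)
    skip = np.zeros(onsets.size, dtype=bool) if skip is None else np.asarray(skip)
    for onset, skipped in zip(onsets, skip):
        if skipped:
            continue
        start = int(round((onset + lag) * sampling_rate))
        stop = min(start + length, n)
        if 0 <= start < n:
            x[start:stop] += peak_pa * kernel[:stop - start]
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return PatchSweep(x, sampling_rate=sampling_rate, mode="voltage_clamp",
                      holding=-60.0)


def simulate_spiking_sweep(onsets: np.ndarray, duration: float,
                           n_spikes: int = 14, isi: float = 0.015,
                           v_rest: float = -60.0, spike_peak: float = 10.0,
                           subthreshold_mv: float = 0.0,
                           sampling_rate: float = 40000.0) -> PatchSweep:
    """Current-clamp sweep firing ``n_spikes`` per burst (0 = subthreshold).

    Spikes are 1 ms triangular waveforms starting 50 ms after each burst
    onset; ``subthreshold_mv`` adds a depolarizing envelope without spikes.
    """
    n = int(round(duration * sampling_rate))
    x = np.full(n, v_rest)
    spike_len = max(int(round(0.001 * sampling_rate)), 3)
    spike = np.interp(np.arange(spike_len),
                      [0, spike_len // 2, spike_len - 1],
                      [v_rest, spike_peak, v_rest])
    for onset in np.asarray(onsets, dtype=float):
        if subthreshold_mv:
            start = int(round(onset * sampling_rate))
            stop = min(start + int(0.4 * sampling_rate), n)
            x[start:stop] += subthreshold_mv
        for s in range(n_spikes):
            start = int(round((onset + 0.05 + s * isi) * sampling_rate))
            stop = min(start + spike_len, n)
            if 0 <= start < n:
                x[start:stop] = np.maximum(x[start:stop], spike[:stop - start])
    return PatchSweep(x, sampling_rate=sampling_rate, mode="current_clamp",
                      holding=0.0)
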