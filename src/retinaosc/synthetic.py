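"""Forward generator of synthetic MEA recordings with ground truth.

The generator emulates the statistical structure the analysis assumes for
explanted degenerated retina:

* LFP-band Gaussian background noise;
* waxing/waning oscillation *bouts* — trains of stereotyped negative
  deflections (inverted Gaussians, harmonic-rich) repeating at a genotype-
  specific fundamental (~2 Hz RCS rat, 3.4 Hz rd10 mouse) — plus sporadic
  isolated deflections;
* tonic multi-unit spiking with a configurable fraction emitted as bursts
  phase-locked to deflection troughs;
* biphasic stimulation pulses with an artifact transient and Poisson evoked
  spikes;
* a GABA condition modifier that abolishes the oscillation.

Event placement is *stratified* (one bout per duty-cycle frame, one isolated
event per rate-determined stratum) rather than Poisson, so event totals over
a few-hundred-second recording are near-deterministic and per-window mean
counts estimate the preset's closed-form expectation
``5 * (f0 * duty_cycle + iso_rate)`` with only a few percent sampling error.
Every injected event is exported as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .io import Condition, Probe, Recording, StimulusEvent

__all__ = [
    "SimulationPreset",
    "GroundTruth",
    "PRESET_NAMES",
    "make_preset",
    "apply_condition",
    "expected_deflections_per_window",
    "expected_efficiency",
    "simulate_recording",
    "simulate_stim_session",
]

DEFAULT_FS = 10_000.0  # Hz; accepted down to 2.5x the 3 kHz spike-band edge

# generator constants shared by all presets
SPIKE_NOISE_UV = 5.0  # instrument-noise s.d. (band-limited to 3 kHz)
NOISE_BW_HZ = 3000.0  # amplifier anti-aliasing bandwidth
SPIKE_AMP_UV = 60.0  # spike template trough amplitude (12 sigma)
ARTIFACT_AMP_UV = 500.0  # recorded stimulation-artifact amplitude
CYCLE_JITTER = 0.03  # s.d. of within-bout deflection timing, cycles
BURST_MEAN = 3.0  # target mean spikes per trough-locked burst
STIM_POST_S = 0.4
STIM_PRE_S = 8.0
STIM_BLANK_S = 2e-3


@dataclass(frozen=True)
class SimulationPreset:
    """Generative parameters for one genotype/age/condition."""

    name: str
    f0_hz: float  # oscillation fundamental
    duty_cycle: float  # fraction of time inside bouts
    bout_dur_s: float  # bout duration
    iso_rate_hz: float  # isolated (non-bout) deflection rate
    defl_amp_uv: float = -300.0  # deflection trough amplitude
    defl_width_ms: float = 80.0  # deflection FWHM
    noise_sigma_uv: float = 20.0  # LFP-band noise s.d.
    spike_rate_hz: float = 5.0  # total tonic multi-unit rate
    locked_fraction: float = 0.0  # target fraction of spikes in locked bursts
    phase_jitter_cycles: float = 0.05  # s.d. of locked-spike phase
    evoked_mean: float = 0.0  # mean evoked spikes per stimulus
    depth_gain: Optional[Tuple[float, float]] = None  # (shallow, deep) amp scale
    probe: Probe = Probe.PLANAR

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must lie in [0, 1]")
        if self.duty_cycle > 0 and self.f0_hz <= 0:
            raise ValueError("f0_hz must be > 0 when duty_cycle > 0")
        if self.defl_amp_uv >= 0:
            raise ValueError("defl_amp_uv must be negative")
        for name in ("iso_rate_hz", "spike_rate_hz", "evoked_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def deflection_rate_hz(self) -> float:
        return self.f0_hz * self.duty_cycle + self.iso_rate_hz


@dataclass
class GroundTruth:
    """Everything the generator injected, for detector validation."""

    deflection_times: np.ndarray
    bout_intervals: List[Tuple[float, float]]
    spike_times: List[np.ndarray]  # one array per channel
    spike_locked: List[np.ndarray]  # boolean masks, parallel to spike_times
    evoked_counts: Optional[np.ndarray] = None  # [n_channels x n_stimuli]


# ---------------------------------------------------------------------------
# Presets

# Stimulation-efficiency targets per preset (mean spike-rate ratio); the
# evoked-spike mean is calibrated from these in make_preset.
_TARGET_RATIO = {
    "WT_RAT": 3.27,
    "RD10": 1.4,
    "RCS_M3": 1.59,
    "RCS_M6": 1.4,
    "RCS_M11": 1.95,
    "RCS_M19": 1.4,
    "RCS_M6_INTRA": 1.4,
}

_PRESETS = {
    "WT_RAT": dict(
        f0_hz=0.0, duty_cycle=0.0, bout_dur_s=0.0, iso_rate_hz=0.0,
        locked_fraction=0.0,
    ),
    "RD10": dict(
        f0_hz=3.4, duty_cycle=0.8, bout_dur_s=30.0, iso_rate_hz=0.0,
        locked_fraction=0.3,
    ),
    "RCS_M3": dict(  # 0.6 deflections / 5-s window
        f0_hz=2.0, duty_cycle=0.02, bout_dur_s=2.0, iso_rate_hz=0.08,
        locked_fraction=0.3,
    ),
    "RCS_M6": dict(  # 1.9 / 5 s
        f0_hz=2.0, duty_cycle=0.15, bout_dur_s=2.0, iso_rate_hz=0.08,
        locked_fraction=0.3,
    ),
    "RCS_M11": dict(  # 3.25 / 5 s
        f0_hz=2.0, duty_cycle=0.285, bout_dur_s=2.0, iso_rate_hz=0.08,
        locked_fraction=0.3,
    ),
    "RCS_M19": dict(  # 3.9 / 5 s
        f0_hz=2.0, duty_cycle=0.35, bout_dur_s=2.0, iso_rate_hz=0.08,
        locked_fraction=0.3,
    ),
    # intraretinal (penetrating-probe) configuration: fundamental 1.98 Hz,
    # pronounced oscillation with amplitude growing with depth
    "RCS_M6_INTRA": dict(
        f0_hz=1.98, duty_cycle=0.5, bout_dur_s=4.0, iso_rate_hz=0.08,
        locked_fraction=0.3,
        depth_gain=(0.4, 1.0), probe=Probe.PENETRATING,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def _ratio_bias_factor(preset: SimulationPreset, pre_s: float = STIM_PRE_S) -> float:
    """Second-order expectation factor of the per-stimulus rate ratio.

    The mean of ``post_rate / pre_rate`` exceeds the ratio of the mean rates
    by approximately ``1 + Var(pre) / E(pre)^2`` (Jensen inequality on the
    reciprocal of the pre-window count).  The pre-window count is Poisson
    background plus locked bursts that arrive clustered.  Isolated
    deflections carry independent Poisson(m) bursts.  Bout-locked spikes
    cluster at the scale of a bout: for bouts shorter than the window a whole
    bout of ``S = f0 * bout_dur * m`` spikes is one compound-Poisson cluster;
    for bouts longer than the window the window is inside a bout with
    probability ``duty`` (an on/off Bernoulli mixture) with per-burst Poisson
    noise on top.
    """
    b, m = _locked_burst_params(preset)
    d = preset.deflection_rate_hz
    w = pre_s
    mu = (b + d * m) * w
    var = b * w
    if m > 0:
        var += preset.iso_rate_hz * (m + m * m) * w
        duty, bout = preset.duty_cycle, preset.bout_dur_s
        if duty > 0 and bout > 0:
            if bout < w:
                s_bout = preset.f0_hz * bout * m
                var += (duty / bout) * (s_bout + s_bout * s_bout) * w
            else:
                n_locked = preset.f0_hz * w * m  # locked spikes when inside a bout
                var += duty * (1.0 - duty) * n_locked * n_locked
                var += duty * n_locked  # burst-size noise within the bout
    return 1.0 + var / (mu * mu)


def _calibrated_evoked_mean(preset: SimulationPreset, target_ratio: float) -> float:
    """Evoked spikes per stimulus that make the *measured* mean ratio hit target.

    Inverts ``E[ratio] = (1 + evoked / (post_s * rate)) * bias`` for evoked.
    """
    bias = _ratio_bias_factor(preset)
    return STIM_POST_S * preset.spike_rate_hz * (target_ratio / bias - 1.0)


def make_preset(name: str) -> SimulationPreset:
    """Look up a genotype/age preset by name."""
    key = str(name).upper()
    if key not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    base = SimulationPreset(name=key, **_PRESETS[key])
    return replace(
        base, evoked_mean=_calibrated_evoked_mean(base, _TARGET_RATIO[key])
    )


def apply_condition(preset: SimulationPreset, condition: Condition) -> SimulationPreset:
    """Modify a preset for a pharmacology phase.

    GABA abolishes the oscillation (duty cycle and isolated-event rate to 0)
    and halves tonic spiking; the evoked response is unchanged.  WASHOUT and
    PRE_GABA return the baseline preset.
    """
    if condition is Condition.GABA:
        return replace(
            preset,
            duty_cycle=0.0,
            iso_rate_hz=0.0,
            spike_rate_hz=preset.spike_rate_hz / 2.0,
            locked_fraction=0.0,
        )
    return replace(preset)


def expected_deflections_per_window(
    preset: SimulationPreset, window_s: float = 5.0
) -> float:
    """Closed-form expected deflection count per counting window."""
    return window_s * preset.deflection_rate_hz


def expected_efficiency(preset: SimulationPreset, post_s: float = STIM_POST_S) -> float:
    """Closed-form expectation of the measured mean efficiency ratio."""
    return (
        1.0 + preset.evoked_mean / (post_s * preset.spike_rate_hz)
    ) * _ratio_bias_factor(preset)


# ---------------------------------------------------------------------------
# Event placement (stratified, low-dispersion)


def _bout_intervals(
    duration: float, duty: float, bout_dur: float, rng: np.random.Generator
) -> List[Tuple[float, float]]:
    """One bout per duty-cycle frame, uniformly placed, clipped to the record."""
    if duty <= 0 or bout_dur <= 0:
        return []
    frame = bout_dur / duty
    n_frames = int(math.ceil(duration / frame))
    out = []
    for i in range(n_frames):
        f0 = i * frame
        start = f0 + rng.uniform(0.0, max(frame - bout_dur, 0.0))
        end = min(start + bout_dur, duration)
        if end - start > 0:
            out.append((start, end))
    return out


def _bout_deflection_times(
    bouts: Sequence[Tuple[float, float]], f0: float, rng: np.random.Generator
) -> np.ndarray:
    times = []
    period = 1.0 / f0
    for b0, b1 in bouts:
        n = int((b1 - b0) // period)
        for i in range(n):
            t = b0 + (i + 0.5 + rng.normal(0.0, CYCLE_JITTER)) * period
            if b0 <= t < b1:
                times.append(t)
    return np.asarray(sorted(times))


def _iso_event_times(
    duration: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """One event per 1/rate stratum (partial stratum with matching probability)."""
    if rate <= 0:
        return np.empty(0)
    stratum = 1.0 / rate
    n_full = int(duration // stratum)
    times = [i * stratum + rng.uniform(0.0, stratum) for i in range(n_full)]
    rem = duration - n_full * stratum
    if rem > 0 and rng.uniform() < rem / stratum:
        times.append(n_full * stratum + rng.uniform(0.0, rem))
    return np.asarray(sorted(times))


# ---------------------------------------------------------------------------
# Waveform rendering


def _gaussian_deflection(width_ms: float, fs: float) -> np.ndarray:
    """Unit-depth inverted Gaussian of the given FWHM."""
    sigma_s = width_ms * 1e-3 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = int(round(4 * sigma_s * fs))
    t = np.arange(-half, half + 1) / fs
    return -np.exp(-0.5 * (t / sigma_s) ** 2)


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic extracellular spike, ~1 ms, unit trough depth at the center."""
    n = max(int(round(1e-3 * fs)), 6)
    t = np.arange(n) / fs
    tau = 1e-3 / 4.0
    w = -np.sin(np.pi * t / (n / fs)) * np.exp(-t / (2 * tau))
    w[n // 2 :] *= -0.4  # small positive rebound
    peak = np.abs(w).max()
    if peak > 0:
        w = w / peak
    # roll the trough onto the template center so a spike rendered at time t
    # has its trough (the detection timestamp) at t
    return np.roll(w, n // 2 - int(np.argmin(w)))


def _artifact_template(fs: float, phase_us: float = 400.0) -> np.ndarray:
    """Charge-balanced biphasic artifact, cathodic phase first.

    Rendered as one full sine cycle across the two 400-µs phases: the
    amplifier chain smooths the rectangular current pulse, and the smooth,
    zero-mean transient keeps filter ringing confined to the pulse itself.
    """
    n = max(int(round(2 * phase_us * 1e-6 * fs)), 2)
    return -np.sin(2 * np.pi * np.arange(n) / n)


def _add_at(trace: np.ndarray, template: np.ndarray, center_idx: int, gain: float) -> None:
    half = template.size // 2
    i0 = center_idx - half
    j0, j1 = max(i0, 0), min(i0 + template.size, trace.size)
    if j1 <= j0:
        return
    trace[j0:j1] += gain * template[j0 - i0 : j1 - i0]


def _lfp_noise(n: int, fs: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian LFP-band noise: white noise low-passed at 100 Hz, rescaled."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, 100.0, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    s = x.std()
    return x * (sigma / s) if s > 0 else x


def _instrument_noise(
    n: int, fs: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Wide-band instrument noise, band-limited by the amplifier (~3 kHz)."""
    white = rng.standard_normal(n)
    if NOISE_BW_HZ < fs / 2:
        sos = sps.butter(4, NOISE_BW_HZ, btype="lowpass", fs=fs, output="sos")
        white = sps.sosfiltfilt(sos, white)
        s = white.std()
        if s > 0:
            white = white / s
    return sigma * white


def _locked_burst_params(preset: SimulationPreset) -> Tuple[float, float]:
    """(background rate, mean spikes per locked burst); total rate is preserved."""
    defl_rate = preset.deflection_rate_hz
    if defl_rate <= 0 or preset.locked_fraction <= 0:
        return preset.spike_rate_hz, 0.0
    locked_rate = min(preset.locked_fraction * preset.spike_rate_hz, BURST_MEAN * defl_rate)
    return preset.spike_rate_hz - locked_rate, locked_rate / defl_rate


def _channel_spikes(
    preset: SimulationPreset,
    duration: float,
    defl_times: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Tonic background spikes plus trough-locked bursts for one channel."""
    bg_rate, burst_mean = _locked_burst_params(preset)
    n_bg = rng.poisson(bg_rate * duration)
    bg = rng.uniform(0.0, duration, size=n_bg)
    locked = []
    if burst_mean > 0 and preset.f0_hz > 0:
        sigma_t = preset.phase_jitter_cycles / preset.f0_hz
        for t in defl_times:
            for _ in range(rng.poisson(burst_mean)):
                ts = t + rng.normal(0.0, sigma_t)
                if 0.0 <= ts < duration:
                    locked.append(ts)
    times = np.concatenate([bg, np.asarray(locked)])
    mask = np.concatenate([np.zeros(n_bg, bool), np.ones(len(locked), bool)])
    order = np.argsort(times, kind="stable")
    return times[order], mask[order]


def _depth_gains(preset: SimulationPreset, n_channels: int) -> np.ndarray:
    if preset.depth_gain is None or n_channels == 1:
        return np.ones(n_channels)
    lo, hi = preset.depth_gain
    return np.linspace(lo, hi, n_channels)


def _render(
    preset: SimulationPreset,
    duration: float,
    n_channels: int,
    fs: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, GroundTruth]:
    n = int(round(duration * fs))
    bouts = _bout_intervals(duration, preset.duty_cycle, preset.bout_dur_s, rng)
    bout_times = (
        _bout_deflection_times(bouts, preset.f0_hz, rng) if bouts else np.empty(0)
    )
    iso_times = _iso_event_times(duration, preset.iso_rate_hz, rng)
    defl_times = np.sort(np.concatenate([bout_times, iso_times]))

    defl_wave = _gaussian_deflection(preset.defl_width_ms, fs)
    spk_wave = _spike_template(fs)
    gains = _depth_gains(preset, n_channels)

    traces = np.empty((n, n_channels))
    spike_times: List[np.ndarray] = []
    spike_locked: List[np.ndarray] = []
    for ch in range(n_channels):
        tr = _lfp_noise(n, fs, preset.noise_sigma_uv, rng)
        tr += _instrument_noise(n, fs, SPIKE_NOISE_UV, rng)
        for t in defl_times:
            _add_at(tr, defl_wave, int(round(t * fs)), gains[ch] * -preset.defl_amp_uv)
        st, lm = _channel_spikes(preset, duration, defl_times, rng)
        for t in st:
            _add_at(tr, spk_wave, int(round(t * fs)), SPIKE_AMP_UV)
        traces[:, ch] = tr
        spike_times.append(st)
        spike_locked.append(lm)

    truth = GroundTruth(
        deflection_times=defl_times,
        bout_intervals=list(bouts),
        spike_times=spike_times,
        spike_locked=spike_locked,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# Public simulators


def _check_fs(fs: float) -> None:
    if fs < 2.5 * 3000.0:
        raise ValueError(f"fs={fs} Hz below 2.5x the 3 kHz spike-band edge")


def simulate_recording(
    preset: SimulationPreset,
    duration_s: float,
    n_channels: int = 1,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    condition: Condition = Condition.NONE,
) -> Tuple[Recording, GroundTruth]:
    """Simulate a spontaneous-activity recording with ground truth.

    Identical arguments (including ``seed``) give bit-identical output.
    """
    if duration_s < 10.0:
        raise ValueError("duration must be >= 10 s")
    _check_fs(fs)
    rng = np.random.default_rng(seed)
    traces, truth = _render(preset, duration_s, n_channels, fs, rng)
    depth = (
        np.linspace(20.0, 100.0, n_channels)
        if preset.probe is Probe.PENETRATING
        else None
    )
    rec = Recording(
        traces=traces,
        fs=fs,
        channel_ids=[f"ch{i}" for i in range(n_channels)],
        condition=condition,
        probe=preset.probe,
        channel_depth_um=depth,
    )
    return rec, truth


def simulate_stim_session(
    preset: SimulationPreset,
    n_stimuli: int,
    isi_s: float = 10.0,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    n_channels: int = 1,
    condition: Condition = Condition.NONE,
) -> Tuple[Recording, GroundTruth]:
    """Simulate an electrical-stimulation session.

    Biphasic pulses (cathodic first, 400 µs/phase, 100 µA metadata) are
    delivered every ``isi_s`` seconds; each leaves a 0.8-ms artifact
    transient and Poisson(``evoked_mean``) evoked spikes uniform in
    (2 ms, 0.4 s] after the pulse, on top of the preset's spontaneous
    activity.  ``isi_s`` must exceed the 8.4-s pre+post analysis span.
    """
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    if isi_s <= STIM_PRE_S + STIM_POST_S:
        raise ValueError(
            f"isi_s={isi_s} must exceed pre+post window span "
            f"({STIM_PRE_S + STIM_POST_S} s)"
        )
    _check_fs(fs)
    rng = np.random.default_rng(seed)
    stim_times = STIM_PRE_S + isi_s * np.arange(n_stimuli)
    duration = float(stim_times[-1] + STIM_POST_S + 0.2)

    traces, truth = _render(preset, duration, n_channels, fs, rng)
    art = _artifact_template(fs)
    spk_wave = _spike_template(fs)

    evoked_counts = np.zeros((n_channels, n_stimuli), dtype=int)
    new_spike_times: List[np.ndarray] = []
    new_locked: List[np.ndarray] = []
    for ch in range(n_channels):
        extra = []
        for k, t in enumerate(stim_times):
            i = int(round(t * fs))
            traces[i : i + art.size, ch] += ARTIFACT_AMP_UV * art[: traces.shape[0] - i]
            n_ev = rng.poisson(preset.evoked_mean)
            evoked_counts[ch, k] = n_ev
            ev = t + rng.uniform(STIM_BLANK_S, STIM_POST_S, size=n_ev)
            for te in ev:
                _add_at(traces[:, ch], spk_wave, int(round(te * fs)), SPIKE_AMP_UV)
            extra.extend(ev.tolist())
        st = np.concatenate([truth.spike_times[ch], np.asarray(extra)])
        lm = np.concatenate(
            [truth.spike_locked[ch], np.zeros(len(extra), dtype=bool)]
        )
        order = np.argsort(st, kind="stable")
        new_spike_times.append(st[order])
        new_locked.append(lm[order])
    truth.spike_times = new_spike_times
    truth.spike_locked = new_locked
    truth.evoked_counts = evoked_counts

    events = [StimulusEvent(time=float(t)) for t in stim_times]
    rec = Recording(
        traces=traces,
        fs=fs,
        channel_ids=[f"ch{i}" for i in range(n_channels)],
        stim_events=events,
        condition=condition,
        probe=preset.probe,
    )
    return rec, truth
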