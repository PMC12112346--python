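"""Threshold-crossing spike detection on spike-band traces.

Extracellular somatic action potentials are predominantly negative-going, so
detection looks for negative crossings of ``-k * sigma`` where ``sigma`` is a
median-absolute-deviation estimate of the noise floor (robust to the spikes
themselves).  Each spike is timestamped at the trough (local minimum within
1 ms of the crossing), which aligns spikes independently of their amplitude
for the phase-locking analysis.  Samples inside blanking windows — e.g. the
first 2 ms after a stimulation pulse — are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import Band, TraceView

__all__ = [
    "SpikeTrain",
    "RateEstimate",
    "estimate_noise_sigma",
    "detect_spikes",
    "spike_rate",
]

#: MAD-to-sigma conversion for Gaussian noise.
MAD_SCALE = 0.6745

DEFAULT_K = 4.0
DEFAULT_REFRACTORY_MS = 1.0
DEFAULT_BLANK_MS = 2.0


@dataclass
class SpikeTrain:
    """Sorted spike times (s) from one electrode, with the detection context."""

    times: np.ndarray
    channel_id: str
    threshold_uv: float
    noise_sigma_uv: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RateEstimate:
    """Spike rate over a half-open window."""

    rate_hz: float
    window: Tuple[float, float]
    n_spikes: int


def estimate_noise_sigma(trace: TraceView) -> float:
    """Robust noise s.d. in microvolts: ``median(|x|) / 0.6745``.

    Insensitive to sparse large spikes.  Returns 0 with a warning for a
    constant trace.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size < 1000:
        raise ValueError(f"need >= 1000 samples for a noise estimate, got {x.size}")
    sigma = float(np.median(np.abs(x - np.median(x))) / MAD_SCALE)
    if sigma == 0.0:
        warnings.warn("constant trace: noise sigma is 0", stacklevel=2)
    return sigma


def detect_spikes(
    trace: TraceView,
    k: float = DEFAULT_K,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    blank_windows: Optional[Sequence[Tuple[float, float]]] = None,
    sigma_uv: Optional[float] = None,
) -> SpikeTrain:
    """Detect negative-going threshold crossings and timestamp their troughs.

    Parameters
    ----------
    trace
        Spike-band view of one channel.
    k
        Threshold multiplier; detection threshold is ``-k * sigma``.
    refractory_ms
        Minimum spacing between accepted spikes; the earlier spike wins.
    blank_windows
        Half-open ``[start, end)`` intervals (absolute seconds) excluded from
        detection, e.g. stimulation artifacts.
    sigma_uv
        Noise sigma override; estimated from the trace when omitted.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be > 0")
    if refractory_ms <= 0:
        raise ValueError("refractory period must be > 0")
    sigma = estimate_noise_sigma(trace) if sigma_uv is None else float(sigma_uv)
    threshold = -k * sigma
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.fs

    if sigma == 0.0:
        return SpikeTrain(np.empty(0), trace.channel_id, threshold, sigma)

    below = x < threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    trough_win = max(1, int(round(1e-3 * fs)))

    # trough = local minimum within 1 ms of each crossing
    trough_idx = np.empty(crossings.size, dtype=np.int64)
    for j, c in enumerate(crossings):
        seg = x[c : min(c + trough_win + 1, x.size)]
        trough_idx[j] = c + int(np.argmin(seg))
    times = trace.t0 + trough_idx / fs

    if blank_windows:
        keep = np.ones(times.size, dtype=bool)
        for b0, b1 in blank_windows:
            keep &= ~((times >= b0) & (times < b1))
        times = times[keep]

    # greedy refractory enforcement, earliest spike wins
    refr = refractory_ms * 1e-3
    accepted: List[float] = []
    last = -np.inf
    for t in times:
        if t - last >= refr:
            accepted.append(float(t))
            last = t
    return SpikeTrain(np.asarray(accepted), trace.channel_id, threshold, sigma)


def spike_rate(train: SpikeTrain, window: Tuple[float, float]) -> RateEstimate:
    """Spike rate over the half-open window [start, end)."""
    start, end = window
    if end <= start:
        raise ValueError(f"window end must exceed start, got [{start}, {end})")
    n = int(np.count_nonzero((train.times >= start) & (train.times < end)))
    return RateEstimate(rate_hz=n / (end - start), window=(start, end), n_spikes=n)
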