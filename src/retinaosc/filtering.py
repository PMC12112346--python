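"""Zero-phase Butterworth filter cascades separating LFP and spike bands.

Two probe-specific profiles are built in:

* ``PLANAR`` — low-pass 50 Hz for the local field potential, high-pass
  200 Hz for action potentials (order 4 each).
* ``PENETRATING`` — low-pass 100 Hz for LFPs, band-pass 100 Hz – 3 kHz of
  order 6 for spiking activity.

Filters are applied forward–backward (``sosfiltfilt``), so the output has
zero phase shift and the stated cutoffs — the one-pass −3 dB points — sit at
−6 dB after the two passes.  Odd-reflection padding of three times the
effective impulse length suppresses startup transients on short windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal

from .io import Band, Probe, Recording, TraceView

__all__ = [
    "FilterKind",
    "FilterSpec",
    "FilterProfile",
    "PLANAR_PROFILE",
    "PENETRATING_PROFILE",
    "get_profile",
    "apply_filter",
    "extract_lfp",
    "extract_spikeband",
]


class FilterKind(enum.Enum):
    LOWPASS = "lowpass"
    HIGHPASS = "highpass"
    BANDPASS = "bandpass"


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth design; cutoffs are the one-pass −3 dB frequencies."""

    kind: FilterKind
    cutoffs_hz: Tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        cut = tuple(float(c) for c in self.cutoffs_hz)
        object.__setattr__(self, "cutoffs_hz", cut)
        n_expected = 2 if self.kind is FilterKind.BANDPASS else 1
        if len(cut) != n_expected:
            raise ValueError(f"{self.kind.name} needs {n_expected} cutoff(s), got {cut}")
        if any(c <= 0 for c in cut):
            raise ValueError(f"cutoffs must be positive, got {cut}")
        if self.kind is FilterKind.BANDPASS and not cut[0] < cut[1]:
            raise ValueError(f"bandpass needs low < high, got {cut}")
        if self.order < 1:
            raise ValueError("order must be a positive integer")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-section design at sampling rate ``fs``; checks Nyquist."""
        for c in self.cutoffs_hz:
            if c >= fs / 2:
                raise ValueError(
                    f"cutoff {c} Hz is at or above Nyquist ({fs / 2} Hz)"
                )
        wn = self.cutoffs_hz if len(self.cutoffs_hz) > 1 else self.cutoffs_hz[0]
        return signal.butter(self.order, wn, btype=self.kind.value, fs=fs, output="sos")

    def padlen(self, fs: float) -> int:
        """Reflect-pad length: 3x the effective impulse length (~fs / lowest cutoff)."""
        return int(np.ceil(3 * fs / min(self.cutoffs_hz)))


@dataclass(frozen=True)
class FilterProfile:
    """Paired LFP / spike-band filter designs for one probe geometry."""

    name: Probe
    lfp: FilterSpec
    spike: FilterSpec


PLANAR_PROFILE = FilterProfile(
    name=Probe.PLANAR,
    lfp=FilterSpec(FilterKind.LOWPASS, (50.0,), order=4),
    spike=FilterSpec(FilterKind.HIGHPASS, (200.0,), order=4),
)

PENETRATING_PROFILE = FilterProfile(
    name=Probe.PENETRATING,
    lfp=FilterSpec(FilterKind.LOWPASS, (100.0,), order=4),
    spike=FilterSpec(FilterKind.BANDPASS, (100.0, 3000.0), order=6),
)


def get_profile(probe: Probe) -> FilterProfile:
    return PLANAR_PROFILE if probe is Probe.PLANAR else PENETRATING_PROFILE


def apply_filter(
    trace: TraceView, spec: FilterSpec, band: Optional[Band] = None
) -> TraceView:
    """Filter one trace; returns a new view of equal length.

    The output band tag defaults to the input's; filtering roles
    (:func:`extract_lfp` / :func:`extract_spikeband`) set it explicitly.
    """
    sos = spec.sos(trace.fs)
    pad = spec.padlen(trace.fs)
    if trace.n_samples <= pad:
        raise ValueError(
            f"trace of {trace.n_samples} samples too short for filter "
            f"(needs > {pad} samples at fs={trace.fs})"
        )
    x = np.asarray(trace.samples, dtype=np.float64)
    if spec.zero_phase:
        y = signal.sosfiltfilt(sos, x, padtype="odd", padlen=pad)
    else:
        y = signal.sosfilt(sos, x)
    return TraceView(
        samples=y,
        fs=trace.fs,
        t0=trace.t0,
        channel_id=trace.channel_id,
        band=band if band is not None else trace.band,
    )


def _extract(rec: Recording, spec: FilterSpec, band: Band) -> List[TraceView]:
    if rec.n_channels < 1:
        raise ValueError("recording has no channels")
    return [apply_filter(rec.channel(i), spec, band=band) for i in range(rec.n_channels)]


def extract_lfp(
    rec: Recording, profile: Optional[FilterProfile] = None
) -> List[TraceView]:
    """Low-pass every channel into the LFP band; profile follows ``rec.probe``."""
    profile = profile or get_profile(rec.probe)
    return _extract(rec, profile.lfp, Band.LFP)


def extract_spikeband(
    rec: Recording, profile: Optional[FilterProfile] = None
) -> List[TraceView]:
    """Filter every channel into the spike band; profile follows ``rec.probe``."""
    profile = profile or get_profile(rec.probe)
    return _extract(rec, profile.spike, Band.SPIKE)
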