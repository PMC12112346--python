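"""Oscillation metrics for LFP traces.

The pathological rhythm of degenerated retina appears in the local field
potential as trains of stereotyped *negative deflections* recurring at a
fundamental frequency (~2 Hz in the RCS rat, 3–6 Hz in the rd10 mouse).
Because the deflection waveform is far from sinusoidal, the amplitude
spectrum carries strong second and third harmonics; a harmonic-grouping
estimator is therefore needed to report the fundamental rather than the
tallest single peak.

This module provides:

* max-normalized, segment-averaged amplitude spectra over the 0–50 Hz LFP
  band (Hann taper, 10-s windows, 0.1 Hz resolution);
* spectral peak detection with quadratic frequency interpolation;
* fundamental-frequency estimation by harmonic grouping;
* negative-deflection detection (threshold ``-k * sigma_LFP`` with a
  two-pass robust noise estimate) and counting in consecutive 5-s windows;
* oscillation-bout segmentation from regular deflection trains;
* spike–LFP phase locking (vector strength with troughs at phase 0).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .io import TraceView
from .spikes import MAD_SCALE, SpikeTrain

__all__ = [
    "Taper",
    "Spectrum",
    "SpectralPeak",
    "DeflectionEvent",
    "OscillationBout",
    "PhaseLockingResult",
    "compute_spectrum",
    "detect_spectral_peaks",
    "harmonic_groups",
    "fundamental_frequency",
    "detect_deflections",
    "count_deflections_windowed",
    "detect_oscillation_bouts",
    "phase_locking",
    "classify_oscillatory",
]

# defaults fixed for reproducible counting (see docs/methods.md)
DEFAULT_WINDOW_S = 10.0
DEFAULT_DEFL_K = 3.0
DEFAULT_MIN_WIDTH_MS = 20.0
DEFAULT_MIN_SEP_MS = 100.0
DEFAULT_SNR_THRESHOLD = 5.0
DEFAULT_HARMONIC_TOL = 0.1
DEFAULT_COUNT_WINDOW_S = 5.0
LFP_FMAX_HZ = 50.0


class Taper(enum.Enum):
    HANN = "HANN"
    NONE = "NONE"


@dataclass
class Spectrum:
    """Max-normalized amplitude spectrum over the LFP band."""

    freqs_hz: np.ndarray
    amp: np.ndarray
    df_hz: float
    window_s: float
    taper: Taper
    flat: bool = False  # True when the input was constant (zero spectrum)


@dataclass
class SpectralPeak:
    f_hz: float
    amp: float
    prominence: float
    is_harmonic_of: Optional["SpectralPeak"] = None


@dataclass(frozen=True)
class DeflectionEvent:
    """One negative LFP transient, timestamped at its trough."""

    t_trough: float
    amplitude_uv: float  # trough voltage relative to baseline; <= 0
    width_ms: float


@dataclass(frozen=True)
class OscillationBout:
    """A contiguous epoch of regularly repeating deflections."""

    start: float
    end: float
    f0_hz: float
    n_cycles: int


@dataclass(frozen=True)
class PhaseLockingResult:
    vector_strength: float
    n_spikes: int
    mean_phase_rad: float
    defined: bool = True


# ---------------------------------------------------------------------------
# Spectra


def compute_spectrum(
    lfp: TraceView,
    window_s: float = DEFAULT_WINDOW_S,
    taper: Taper = Taper.HANN,
    average: bool = True,
) -> Spectrum:
    """Amplitude spectrum of an LFP trace, max-normalized to 1.

    The trace is cut into non-overlapping ``window_s`` segments (each
    demeaned and tapered); segment amplitude spectra are averaged before
    normalization.  Only the 0–50 Hz band is retained.  A constant input
    yields an all-zero spectrum flagged ``flat``.
    """
    n_win = int(round(window_s * lfp.fs))
    if lfp.n_samples < n_win:
        raise ValueError(
            f"trace of {lfp.duration_s:.2f} s shorter than analysis window "
            f"{window_s} s"
        )
    x = np.asarray(lfp.samples, dtype=float)
    n_seg = x.size // n_win if average else 1
    win = np.hanning(n_win) if taper is Taper.HANN else np.ones(n_win)

    freqs = np.fft.rfftfreq(n_win, d=1.0 / lfp.fs)
    keep = freqs <= LFP_FMAX_HZ
    acc = np.zeros(int(np.count_nonzero(keep)))
    for s in range(n_seg):
        seg = x[s * n_win : (s + 1) * n_win]
        seg = (seg - seg.mean()) * win
        acc += np.abs(np.fft.rfft(seg))[keep]
    acc /= n_seg

    peak = acc.max()
    flat = peak <= 0.0 or not np.any(acc > 1e-12 * max(peak, 1.0))
    amp = acc / peak if peak > 0 else acc
    if peak <= 0.0:
        flat = True
        amp = np.zeros_like(acc)
    return Spectrum(
        freqs_hz=freqs[keep],
        amp=amp,
        df_hz=1.0 / window_s,
        window_s=window_s,
        taper=taper,
        flat=flat,
    )


def detect_spectral_peaks(
    spec: Spectrum,
    band_hz: Tuple[float, float] = (0.5, 20.0),
    min_prominence: float = 0.05,
) -> List[SpectralPeak]:
    """Local spectral maxima in ``band_hz`` with the given prominence.

    Peak frequencies are refined by quadratic interpolation of the three
    bins around each maximum.  Returned sorted by frequency.
    """
    lo, hi = band_hz
    if lo < spec.freqs_hz[0] or hi > spec.freqs_hz[-1]:
        raise ValueError(f"band {band_hz} outside spectrum range")
    if spec.flat:
        return []
    mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    idx_band = np.flatnonzero(mask)
    amp = spec.amp
    locs, props = sps.find_peaks(amp[idx_band], prominence=min_prominence)
    peaks: List[SpectralPeak] = []
    for loc, prom in zip(locs, props["prominences"]):
        i = idx_band[loc]
        f, a = spec.freqs_hz[i], amp[i]
        if 0 < i < amp.size - 1:
            # quadratic (parabolic) interpolation around the peak bin
            y0, y1, y2 = amp[i - 1], amp[i], amp[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                f = f + delta * spec.df_hz
                a = y1 - 0.25 * (y0 - y2) * delta
        peaks.append(SpectralPeak(f_hz=float(f), amp=float(a), prominence=float(prom)))
    peaks.sort(key=lambda p: p.f_hz)
    return peaks


#: highest harmonic index considered when grouping (the deflection waveform
#: carries most energy in the fundamental and its 2nd/3rd harmonics)
MAX_HARMONIC = 4

#: a candidate fundamental must itself carry at least this fraction of its
#: family's largest peak amplitude (guards against sub-harmonic noise peaks
#: adopting the true peaks as "harmonics")
MIN_FUNDAMENTAL_RATIO = 0.25


def harmonic_groups(
    peaks: Sequence[SpectralPeak], harmonic_tol: float = DEFAULT_HARMONIC_TOL
) -> List[Tuple[float, List[SpectralPeak], float]]:
    """Group peaks into harmonic families.

    Every peak is tried as a candidate fundamental; peaks whose frequency is
    an integer multiple (up to ``MAX_HARMONIC``) of the candidate within
    ``harmonic_tol * f_candidate`` join its family, at most one peak (the
    closest) per harmonic index.  A candidate whose own amplitude falls below
    ``MIN_FUNDAMENTAL_RATIO`` of its family's largest peak is rejected — a
    small low-frequency noise peak must not claim the true fundamental and
    its harmonics as its own.  Families are scored by summed amplitude and
    returned sorted by score (ties: lower fundamental first); the reported
    fundamental is the amplitude-weighted mean of ``f_k / k`` over members.
    """
    if not peaks:
        return []
    groups = []
    for cand in peaks:
        by_k: dict = {}
        for p in peaks:
            k = int(round(p.f_hz / cand.f_hz))
            if not 1 <= k <= MAX_HARMONIC:
                continue
            err = abs(p.f_hz - k * cand.f_hz)
            if err <= harmonic_tol * cand.f_hz and (
                k not in by_k or err < by_k[k][1]
            ):
                by_k[k] = (p, err)
        members = [(by_k[k][0], k) for k in sorted(by_k)]
        if not members:
            continue
        max_amp = max(p.amp for p, _ in members)
        if cand.amp < MIN_FUNDAMENTAL_RATIO * max_amp:
            continue
        score = sum(p.amp for p, _ in members)
        wsum = sum(p.amp * p.f_hz / k for p, k in members)
        f0 = wsum / score if score > 0 else cand.f_hz
        groups.append((f0, [p for p, _ in members], score))
    groups.sort(key=lambda g: (-g[2], g[0]))

    # greedy: a family whose peaks are all already claimed by a stronger
    # family (i.e. a pure sub-harmonic-family) is dropped
    claimed: set = set()
    out = []
    for f0, members, score in groups:
        if all(id(m) in claimed for m in members):
            continue
        out.append((f0, members, score))
        claimed.update(id(m) for m in members)
    return out


def fundamental_frequency(
    peaks: Sequence[SpectralPeak], harmonic_tol: float = DEFAULT_HARMONIC_TOL
) -> Optional[float]:
    """Fundamental of the strongest harmonic family, or None without peaks.

    Returns the fundamental even when a harmonic carries the largest single
    amplitude, because the family's *summed* amplitude decides.  Side effect:
    members of the winning family get ``is_harmonic_of`` set to its
    fundamental peak.
    """
    groups = harmonic_groups(peaks, harmonic_tol)
    if not groups:
        return None
    f0, members, _ = groups[0]
    root = min(members, key=lambda p: p.f_hz)
    for p in members:
        if p is not root:
            p.is_harmonic_of = root
    return float(f0)


# ---------------------------------------------------------------------------
# Negative deflections


def _runs_below(below: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of True runs."""
    padded = np.concatenate(([False], below, [False]))
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def robust_lfp_sigma(
    x: np.ndarray, fs: float, k_d: float = DEFAULT_DEFL_K, mask_ms: float = 200.0
) -> float:
    """Two-pass MAD noise estimate with provisional deflections masked out."""
    med = np.median(x)
    sigma = float(np.median(np.abs(x - med)) / MAD_SCALE)
    if sigma == 0.0:
        return 0.0
    below = (x - med) < -k_d * sigma
    if not np.any(below):
        return sigma
    starts, ends = _runs_below(below)
    pad = int(round(mask_ms * 1e-3 * fs))
    keep = np.ones(x.size, dtype=bool)
    for s, e in zip(starts, ends):
        keep[max(0, s - pad) : min(x.size, e + pad)] = False
    if np.count_nonzero(keep) < 1000:
        return sigma
    clean = x[keep]
    med2 = np.median(clean)
    sigma2 = float(np.median(np.abs(clean - med2)) / MAD_SCALE)
    return sigma2 if sigma2 > 0 else sigma


def detect_deflections(
    lfp: TraceView,
    k_d: float = DEFAULT_DEFL_K,
    min_width_ms: float = DEFAULT_MIN_WIDTH_MS,
    min_separation_ms: float = DEFAULT_MIN_SEP_MS,
) -> List[DeflectionEvent]:
    """Detect negative LFP deflections.

    An event is a contiguous excursion below ``-k_d * sigma_LFP`` (baseline =
    trace median, sigma from the two-pass robust estimate) lasting at least
    ``min_width_ms``, timestamped at its minimum.  Events closer than
    ``min_separation_ms`` are merged, keeping the deeper trough.
    """
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    x = np.asarray(lfp.samples, dtype=float)
    fs = lfp.fs
    baseline = float(np.median(x))
    sigma = robust_lfp_sigma(x, fs, k_d=k_d)
    if sigma == 0.0:
        return []
    thr = -k_d * sigma
    below = (x - baseline) < thr
    starts, ends = _runs_below(below)
    min_len = int(round(min_width_ms * 1e-3 * fs))

    events: List[DeflectionEvent] = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        i_min = s + int(np.argmin(x[s:e]))
        events.append(
            DeflectionEvent(
                t_trough=lfp.t0 + i_min / fs,
                amplitude_uv=float(x[i_min] - baseline),
                width_ms=(e - s) / fs * 1e3,
            )
        )

    # merge events closer than min_separation, keep the deeper trough
    min_sep = min_separation_ms * 1e-3
    merged: List[DeflectionEvent] = []
    for ev in events:
        if merged and ev.t_trough - merged[-1].t_trough < min_sep:
            if ev.amplitude_uv < merged[-1].amplitude_uv:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def count_deflections_windowed(
    events: Sequence[DeflectionEvent],
    total_duration: float,
    window_s: float = DEFAULT_COUNT_WINDOW_S,
    t0: float = 0.0,
) -> np.ndarray:
    """Event counts per consecutive half-open ``window_s`` window.

    Only complete windows are counted (``floor(duration / window_s)`` of
    them); the counts sum to the number of events inside the covered span.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    n_win = int(total_duration // window_s)
    counts = np.zeros(n_win, dtype=int)
    for ev in events:
        w = int((ev.t_trough - t0) // window_s)
        if 0 <= w < n_win:
            counts[w] += 1
    return counts


def detect_oscillation_bouts(
    events: Sequence[DeflectionEvent],
    max_gap_factor: float = 2.0,
    min_cycles: int = 3,
) -> List[OscillationBout]:
    """Segment regular deflection trains into oscillation bouts.

    A bout is a maximal run of at least ``min_cycles`` consecutive events
    whose inter-event intervals all lie within ``max_gap_factor`` of the
    run's median interval; its fundamental is 1 / median interval.
    """
    times = np.asarray([ev.t_trough for ev in events], dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("events must be time-sorted")
    bouts: List[OscillationBout] = []

    def close(run: List[float], intervals: List[float]) -> None:
        if len(run) >= min_cycles:
            med = float(np.median(intervals))
            bouts.append(
                OscillationBout(
                    start=run[0], end=run[-1], f0_hz=1.0 / med, n_cycles=len(run)
                )
            )

    run: List[float] = []
    intervals: List[float] = []
    for t in times:
        if not run:
            run = [t]
            continue
        d = t - run[-1]
        if not intervals:
            run.append(t)
            intervals.append(d)
            continue
        med = float(np.median(intervals))
        if med / max_gap_factor <= d <= med * max_gap_factor:
            run.append(t)
            intervals.append(d)
        else:
            close(run, intervals)
            run, intervals = [t], []
    if intervals:
        close(run, intervals)
    return bouts


# ---------------------------------------------------------------------------
# Phase locking


def phase_locking(
    train: SpikeTrain, events: Sequence[DeflectionEvent]
) -> PhaseLockingResult:
    """Spike–LFP phase locking with deflection troughs at phase 0.

    Spike phase is interpolated linearly between consecutive troughs:
    ``phi = 2*pi*(t - t_prev) / (t_next - t_prev)``, wrapped to (-pi, pi].
    Vector strength is the modulus of the mean unit phasor.  The result is
    flagged undefined with fewer than 10 spikes between the first and last
    trough.
    """
    troughs = np.asarray(sorted(ev.t_trough for ev in events), dtype=float)
    if troughs.size < 2:
        raise ValueError("phase locking needs at least 2 deflection events")
    t = train.times
    inside = t[(t >= troughs[0]) & (t < troughs[-1])]
    n = int(inside.size)
    if n == 0:
        return PhaseLockingResult(0.0, 0, 0.0, defined=False)
    idx = np.searchsorted(troughs, inside, side="right") - 1
    t_prev = troughs[idx]
    t_next = troughs[idx + 1]
    phi = 2 * np.pi * (inside - t_prev) / (t_next - t_prev)
    z = np.exp(1j * phi).mean()
    mean_phase = float(np.angle(z))  # in (-pi, pi]
    return PhaseLockingResult(
        vector_strength=float(np.abs(z)),
        n_spikes=n,
        mean_phase_rad=mean_phase,
        defined=n >= 10,
    )


# ---------------------------------------------------------------------------
# Oscillatory classification


def classify_oscillatory(
    spec: Spectrum,
    band_hz: Tuple[float, float] = (0.5, 20.0),
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    harmonic_tol: float = DEFAULT_HARMONIC_TOL,
) -> bool:
    """True iff the spectrum carries a fundamental clearly above the floor.

    Criterion: a harmonic-grouped fundamental exists and the in-band peak
    amplitude exceeds ``snr_threshold`` times the median in-band amplitude.
    A flat (constant-input) spectrum is non-oscillatory.
    """
    if spec.flat:
        return False
    lo, hi = band_hz
    mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    band = spec.amp[mask]
    if band.size == 0:
        return False
    med = float(np.median(band))
    if med <= 0:
        return False
    peaks = detect_spectral_peaks(spec, band_hz=band_hz)
    f0 = fundamental_frequency(peaks, harmonic_tol=harmonic_tol)
    return f0 is not None and float(band.max()) / med >= snr_threshold
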