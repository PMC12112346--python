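"""Recording containers and on-disk serialization.

A :class:`Recording` is the universal input of the analysis: an
``[n_samples x n_channels]`` extracellular voltage matrix in microvolts with
a sampling rate, per-channel ids, optional electrical-stimulation events and
an experimental condition label (control / GABA bath / washout).

Two file dialects are supported:

* ``ASCII`` — a plain-text matrix, one row per sample, with a single header
  line ``# fs=<Hz> channels=<id,id,...>``.  Lossy (traces only, fixed
  decimal precision), mirroring the role of acquisition-software ASCII
  exports.
* ``CONTAINER`` — an HDF5 file with named arrays (``traces``, ``fs``,
  ``channel_ids``, ``stim_times``, ``stim_meta``, ``condition``, ``probe``,
  ``t0``, ``channel_depth_um``).  Exact round-trip.

All intervals in the package are half-open ``[start, end)``; times are in
seconds, voltages in microvolts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np

__all__ = [
    "Condition",
    "Probe",
    "Band",
    "Dialect",
    "StimulusEvent",
    "TraceView",
    "Recording",
    "read_recording",
    "write_recording",
    "slice_recording",
]


class Condition(enum.Enum):
    """Experimental phase of the pharmacology protocol."""

    PRE_GABA = "PRE_GABA"
    GABA = "GABA"
    WASHOUT = "WASHOUT"
    NONE = "NONE"


class Probe(enum.Enum):
    """Electrode geometry: planar surface grid or penetrating shanks."""

    PLANAR = "PLANAR"
    PENETRATING = "PENETRATING"


class Band(enum.Enum):
    """Frequency band a trace currently represents."""

    RAW = "RAW"
    LFP = "LFP"
    SPIKE = "SPIKE"


class Dialect(enum.Enum):
    ASCII = "ASCII"
    CONTAINER = "CONTAINER"


@dataclass(frozen=True)
class StimulusEvent:
    """A single biphasic current pulse delivered through a stimulation electrode."""

    time: float
    amplitude_uA: float = 100.0
    phase_duration_us: float = 400.0
    polarity: str = "CATHODIC_FIRST"

    def __post_init__(self) -> None:
        if self.amplitude_uA <= 0:
            raise ValueError(f"stimulus amplitude must be > 0, got {self.amplitude_uA}")
        if self.phase_duration_us <= 0:
            raise ValueError(
                f"stimulus phase duration must be > 0, got {self.phase_duration_us}"
            )


@dataclass
class TraceView:
    """A single-channel view of a recording in a declared frequency band.

    ``band`` is ``RAW`` on load and is set exactly once by a filtering
    operation (``LFP`` or ``SPIKE``).
    """

    samples: np.ndarray
    fs: float
    t0: float
    channel_id: str
    band: Band = Band.RAW

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class Recording:
    """Multichannel extracellular voltage time series in microvolts."""

    traces: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    t0: float = 0.0
    stim_events: list = field(default_factory=list)
    condition: Condition = Condition.NONE
    probe: Probe = Probe.PLANAR
    channel_depth_um: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D [n_samples x n_channels]")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        n_samples, n_channels = self.traces.shape
        if n_samples < 1 or n_channels < 1:
            raise ValueError("recording must have at least one sample and one channel")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != n_channels:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {n_channels} channels"
            )
        if not np.all(np.isfinite(self.traces)):
            bad = np.argwhere(~np.isfinite(self.traces))[0]
            raise ValueError(
                f"non-finite sample at index {bad[0]} on channel "
                f"{self.channel_ids[bad[1]]}"
            )
        end = self.t0 + n_samples / self.fs
        for ev in self.stim_events:
            if not (self.t0 <= ev.time < end):
                raise ValueError(
                    f"stimulus at t={ev.time} s outside recording [{self.t0}, {end})"
                )
        if self.channel_depth_um is not None:
            self.channel_depth_um = np.asarray(self.channel_depth_um, dtype=float)
            if self.channel_depth_um.shape != (n_channels,):
                raise ValueError("channel_depth_um must have one entry per channel")

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def end_time(self) -> float:
        return self.t0 + self.duration_s

    def channel(self, key: Union[int, str]) -> TraceView:
        """Return a RAW-band view of one channel (by index or id)."""
        idx = key if isinstance(key, int) else self.channel_ids.index(key)
        return TraceView(
            samples=self.traces[:, idx],
            fs=self.fs,
            t0=self.t0,
            channel_id=self.channel_ids[idx],
            band=Band.RAW,
        )


def slice_recording(rec: Recording, t_start: float, t_end: float) -> Recording:
    """Return the sub-recording covering the half-open interval [t_start, t_end).

    Stimulus events are filtered to the interval and ``t0`` is updated.
    """
    if not (rec.t0 <= t_start < t_end <= rec.end_time + 0.5 / rec.fs):
        raise ValueError(
            f"slice [{t_start}, {t_end}) outside recording "
            f"[{rec.t0}, {rec.end_time})"
        )
    i0 = int(round((t_start - rec.t0) * rec.fs))
    i1 = int(round((t_end - rec.t0) * rec.fs))
    if i1 <= i0:
        raise ValueError("empty slice interval")
    events = [ev for ev in rec.stim_events if t_start <= ev.time < t_end]
    return Recording(
        traces=rec.traces[i0:i1].copy(),
        fs=rec.fs,
        channel_ids=list(rec.channel_ids),
        t0=rec.t0 + i0 / rec.fs,
        stim_events=events,
        condition=rec.condition,
        probe=rec.probe,
        channel_depth_um=None
        if rec.channel_depth_um is None
        else rec.channel_depth_um.copy(),
    )


# ---------------------------------------------------------------------------
# ASCII dialect


def _write_ascii(rec: Recording, path: Path, precision: int = 6) -> None:
    header = f"# fs={rec.fs!r} channels={','.join(rec.channel_ids)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rec.traces, fmt=f"%.{precision}f")


def _read_ascii(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: line 1: missing '#' header line")
        fields = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        if "fs" not in fields or "channels" not in fields:
            raise ValueError(f"{path}: line 1: header must declare fs= and channels=")
        try:
            fs = float(fields["fs"])
        except ValueError as exc:
            raise ValueError(f"{path}: line 1: bad fs value {fields['fs']!r}") from exc
        channel_ids = fields["channels"].split(",")
        n_ch = len(channel_ids)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != n_ch:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_ch} fields, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    traces = np.asarray(rows, dtype=np.float64)
    if not np.all(np.isfinite(traces)):
        bad = np.argwhere(~np.isfinite(traces))[0]
        raise ValueError(
            f"{path}: non-finite sample at row {bad[0]} channel {channel_ids[bad[1]]}"
        )
    return Recording(traces=traces, fs=fs, channel_ids=channel_ids)


# ---------------------------------------------------------------------------
# HDF5 container dialect

_STIM_META_FIELDS = ("amplitude_uA", "phase_duration_us")


def _write_container(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("t0", data=float(rec.t0))
        f.create_dataset(
            "channel_ids",
            data=np.array(rec.channel_ids, dtype=h5py.string_dtype()),
        )
        f.create_dataset(
            "stim_times", data=np.array([ev.time for ev in rec.stim_events])
        )
        meta = np.array(
            [[getattr(ev, k) for k in _STIM_META_FIELDS] for ev in rec.stim_events]
        ).reshape(len(rec.stim_events), len(_STIM_META_FIELDS))
        f.create_dataset("stim_meta", data=meta)
        f.create_dataset("condition", data=rec.condition.value)
        f.create_dataset("probe", data=rec.probe.value)
        if rec.channel_depth_um is not None:
            f.create_dataset("channel_depth_um", data=rec.channel_depth_um)


def _read_container(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        traces = f["traces"][()]
        fs = float(f["fs"][()])
        t0 = float(f["t0"][()])
        channel_ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_ids"][()]]
        stim_times = f["stim_times"][()]
        stim_meta = f["stim_meta"][()]
        events = [
            StimulusEvent(
                time=float(t),
                amplitude_uA=float(m[0]),
                phase_duration_us=float(m[1]),
            )
            for t, m in zip(stim_times, stim_meta)
        ]
        cond = Condition(f["condition"][()].decode())
        probe = Probe(f["probe"][()].decode())
        depth = f["channel_depth_um"][()] if "channel_depth_um" in f else None
    return Recording(
        traces=traces,
        fs=fs,
        channel_ids=channel_ids,
        t0=t0,
        stim_events=events,
        condition=cond,
        probe=probe,
        channel_depth_um=depth,
    )


def read_recording(path, dialect: Dialect = Dialect.CONTAINER) -> Recording:
    """Load a recording from disk in the declared dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is Dialect.ASCII:
        return _read_ascii(path)
    return _read_container(path)


def write_recording(
    rec: Recording, path, dialect: Dialect = Dialect.CONTAINER, precision: int = 6
) -> None:
    """Write a recording; CONTAINER round-trips exactly, ASCII to ``precision`` decimals."""
    path = Path(path)
    if dialect is Dialect.ASCII:
        _write_ascii(rec, path, precision=precision)
    else:
        _write_container(rec, path)
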