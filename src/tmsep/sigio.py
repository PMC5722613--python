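"""Containers and I/O for TMS-evoked extracellular recording sessions.

The on-disk session container is a small HDF5 layout::

    /recording/samples      float64, microvolts
    /recording/excluded     (n, 2) float64, seconds  [t0, t1) blanking intervals
    /stimlog/onsets         float64, seconds
    /stimlog/intensity      float64, %MT per stimulus
    /spikes/timestamps      float64, seconds (optional)
    /emg/contra, /emg/ipsi  float64, microvolts (optional)
    /lgm/samples            float64, volts (optional low-gain monitor trace)

All times are stored in seconds (64-bit float) with time 0 at recording
start; peri-stimulus quantities elsewhere in the package are expressed in
milliseconds relative to stimulus onset.  Windows and bins follow the
half-open convention [t0, t1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ContinuousRecording",
    "StimulusLog",
    "SpikeTrain",
    "Session",
    "write_session",
    "read_session",
    "write_events_csv",
    "read_events_csv",
]

EVENT_CSV_COLUMNS = [
    "label",
    "polarity",
    "onset_ms",
    "offset_ms",
    "duration_ms",
    "peak_normalized_fr",
    "peak_time_ms",
]


class SchemaError(ValueError):
    """A session file is missing a mandatory attribute or dataset."""


@dataclass
class ContinuousRecording:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples : array of µV (or V for low-gain monitor traces; see ``units``)
    fs : sampling rate in Hz
    start_time : time of the first sample, seconds
    channel_id : free-form channel label
    excluded_intervals : list of (t0, t1) in seconds; sorted, non-overlapping
        half-open intervals during which the amplifier input was grounded
        (stimulus blanking) and samples carry no signal.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    channel_id: str = ""
    excluded_intervals: list = field(default_factory=list)
    units: str = "uV"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.excluded_intervals = [(float(a), float(b)) for a, b in self.excluded_intervals]
        t_end = self.start_time + len(self.samples) / self.fs
        prev_end = -np.inf
        for (a, b) in self.excluded_intervals:
            if not (a < b):
                raise ValueError(f"empty or inverted excluded interval ({a}, {b})")
            if a < prev_end:
                raise ValueError("excluded intervals must be sorted and non-overlapping")
            if a < self.start_time or b > t_end + 1.0 / self.fs:
                raise ValueError(f"excluded interval ({a}, {b}) outside the record")
            prev_end = b

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(len(self.samples)) / self.fs

    def excluded_mask(self, pad_s: float = 0.0) -> np.ndarray:
        """Boolean mask over samples that fall in (optionally padded) excluded intervals."""
        t = self.times()
        mask = np.zeros(len(t), dtype=bool)
        for (a, b) in self.excluded_intervals:
            mask |= (t >= a - pad_s) & (t < b + pad_s)
        return mask


@dataclass
class StimulusLog:
    """Stimulus onsets with per-stimulus intensity and session-level tags."""

    onsets: np.ndarray
    intensity_pct_mt: np.ndarray
    orientation: str = "ML"
    pulse_type: str = "monophasic"
    animal_id: str = ""
    intensity_pct_mso: Optional[np.ndarray] = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.intensity_pct_mt = np.broadcast_to(
            np.asarray(self.intensity_pct_mt, dtype=float), self.onsets.shape
        ).copy()
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("stimulus onsets must be strictly increasing")
        if self.orientation not in ("ML", "PA"):
            raise ValueError(f"unknown orientation {self.orientation!r} (expected 'ML' or 'PA')")
        if self.intensity_pct_mso is not None:
            self.intensity_pct_mso = np.asarray(self.intensity_pct_mso, dtype=float)

    @property
    def n_trials(self) -> int:
        return len(self.onsets)


@dataclass
class SpikeTrain:
    """Detected (or simulated) spike timestamps in seconds, sorted ascending."""

    timestamps: np.ndarray
    source_channel: str = ""

    def __post_init__(self):
        self.timestamps = np.sort(np.asarray(self.timestamps, dtype=float))

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class Session:
    """A bundle of everything recorded in one stimulation session."""

    recording: Optional[ContinuousRecording] = None
    stimlog: Optional[StimulusLog] = None
    spikes: Optional[SpikeTrain] = None
    emg_contra: Optional[ContinuousRecording] = None
    emg_ipsi: Optional[ContinuousRecording] = None
    lgm: Optional[ContinuousRecording] = None


def _write_recording(group: h5py.Group, rec: ContinuousRecording) -> None:
    group.create_dataset("samples", data=rec.samples)
    group.attrs["fs"] = rec.fs
    group.attrs["start_time"] = rec.start_time
    group.attrs["channel_id"] = rec.channel_id
    group.attrs["units"] = rec.units
    group.create_dataset("excluded", data=np.array(rec.excluded_intervals, dtype=float).reshape(-1, 2))


def _read_recording(group: h5py.Group, where: str) -> ContinuousRecording:
    if "samples" not in group:
        raise SchemaError(f"missing dataset {where}/samples")
    if "fs" not in group.attrs:
        raise SchemaError(f"missing mandatory attribute {where}/fs")
    excluded = group["excluded"][()] if "excluded" in group else np.empty((0, 2))
    return ContinuousRecording(
        samples=group["samples"][()],
        fs=float(group.attrs["fs"]),
        start_time=float(group.attrs.get("start_time", 0.0)),
        channel_id=str(group.attrs.get("channel_id", "")),
        units=str(group.attrs.get("units", "uV")),
        excluded_intervals=[tuple(row) for row in excluded],
    )


def write_session(path, session: Session) -> None:
    """Write a session container; round-trips losslessly with :func:`read_session`."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = 1
        if session.recording is not None:
            _write_recording(f.create_group("recording"), session.recording)
        if session.stimlog is not None:
            g = f.create_group("stimlog")
            g.create_dataset("onsets", data=session.stimlog.onsets)
            g.create_dataset("intensity", data=session.stimlog.intensity_pct_mt)
            g.attrs["orientation"] = session.stimlog.orientation
            g.attrs["pulse_type"] = session.stimlog.pulse_type
            g.attrs["animal_id"] = session.stimlog.animal_id
            if session.stimlog.intensity_pct_mso is not None:
                g.create_dataset("intensity_mso", data=session.stimlog.intensity_pct_mso)
        if session.spikes is not None:
            g = f.create_group("spikes")
            g.create_dataset("timestamps", data=session.spikes.timestamps)
            g.attrs["source_channel"] = session.spikes.source_channel
        if session.emg_contra is not None or session.emg_ipsi is not None:
            g = f.create_group("emg")
            if session.emg_contra is not None:
                _write_recording(g.create_group("contra"), session.emg_contra)
            if session.emg_ipsi is not None:
                _write_recording(g.create_group("ipsi"), session.emg_ipsi)
        if session.lgm is not None:
            _write_recording(f.create_group("lgm"), session.lgm)


def read_session(path) -> Session:
    """Read a session container written by :func:`write_session`.

    Raises
    ------
    SchemaError
        If a mandatory attribute or dataset (e.g. ``fs``, ``onsets``) is absent.
    """
    out = Session()
    with h5py.File(path, "r") as f:
        if "recording" in f:
            out.recording = _read_recording(f["recording"], "recording")
        if "stimlog" in f:
            g = f["stimlog"]
            if "onsets" not in g:
                raise SchemaError("missing mandatory dataset stimlog/onsets")
            mso = g["intensity_mso"][()] if "intensity_mso" in g else None
            out.stimlog = StimulusLog(
                onsets=g["onsets"][()],
                intensity_pct_mt=g["intensity"][()] if "intensity" in g else np.full(len(g["onsets"]), np.nan),
                orientation=str(g.attrs.get("orientation", "ML")),
                pulse_type=str(g.attrs.get("pulse_type", "monophasic")),
                animal_id=str(g.attrs.get("animal_id", "")),
                intensity_pct_mso=mso,
            )
        if "spikes" in f:
            g = f["spikes"]
            out.spikes = SpikeTrain(
                timestamps=g["timestamps"][()],
                source_channel=str(g.attrs.get("source_channel", "")),
            )
        if "emg" in f:
            g = f["emg"]
            if "contra" in g:
                out.emg_contra = _read_recording(g["contra"], "emg/contra")
            if "ipsi" in g:
                out.emg_ipsi = _read_recording(g["ipsi"], "emg/ipsi")
        if "lgm" in f:
            out.lgm = _read_recording(f["lgm"], "lgm")
    return out


def write_events_csv(events: Sequence, path) -> None:
    """Write detected phasic events to CSV, one row per event.

    ``events`` may be any sequence of objects exposing the attributes in
    ``EVENT_CSV_COLUMNS`` (duck-typed so the event dataclass can live in the
    analysis layer).  An empty list produces a header-only file.
    """
    rows = []
    for ev in events:
        rows.append({c: getattr(ev, c) for c in EVENT_CSV_COLUMNS})
    pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    """Read a phasic-event CSV back into a DataFrame (full-precision floats)."""
    return pd.read_csv(path)
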