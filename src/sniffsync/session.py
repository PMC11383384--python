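"""Session containers and on-disk I/O.

A recording session bundles four synchronized physiology channels
(EEG1, EEG2, EMG, Resp) at a common sample rate (canonically 400 Hz) with
behavioral events and a 25 Hz video-tracking trace.  The native on-disk
format is one HDF5 file for the signals plus a JSON sidecar for the
manifest/events and a CSV for tracking coordinates; EDF import is
supported read-only (EDF has no standard home for event/cue metadata).

Time convention: seconds, zero-based at record start; all intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import h5py
import numpy as np
import pandas as pd

CANONICAL_CHANNELS = ("EEG1", "EEG2", "EMG", "Resp")
CONDITIONS = ("open_arena", "novel_object", "novel_odor", "food", "sleep_odor")
EVENT_KINDS = ("exploration_bout", "odor_introduction", "sensor_on")
CUE_CLASSES = ("object", "odor", "food")


@dataclass
class SignalRecord:
    """Synchronized multichannel time series with a telemetry gap mask.

    Parameters
    ----------
    channel_names : tuple of str
        Ordered channel labels, canonically ``("EEG1", "EEG2", "EMG", "Resp")``.
    samples : ndarray, shape (p, n)
        Per-channel series in acquisition units.
    sample_rate : float
        Sampling rate in Hz.
    start_time : float
        Session-clock time of the first sample, seconds.
    gap_mask : ndarray of bool, shape (n,)
        True where the Resp telemetry was off; masked samples are excluded
        from all downstream epoching.
    """

    channel_names: tuple[str, ...]
    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but "
                f"{self.samples.shape[0]} sample rows"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.samples.shape[1], dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != (self.samples.shape[1],):
            raise ValueError("gap_mask length must equal sample length")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channel_names:
            raise KeyError(f"channel {name} missing")
        return self.samples[self.channel_names.index(name)]

    def select(self, names: tuple[str, ...]) -> "SignalRecord":
        """Return a record with channels reordered/subset to `names`."""
        idx = [self.channel_names.index(n) for n in names]
        return replace(self, channel_names=tuple(names), samples=self.samples[idx])

    def valid_segments(self, min_duration: float = 0.0) -> list[tuple[int, int]]:
        """Contiguous unmasked runs as half-open sample-index pairs.

        Segments shorter than `min_duration` seconds are dropped (they cannot
        hold a full locally-stationary bin).
        """
        valid = ~self.gap_mask
        if not valid.any():
            return []
        edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
        starts = [0] if valid[0] else []
        starts += [int(e) + 1 for e in edges if valid[e + 1]]
        ends = [int(e) + 1 for e in edges if valid[e]]
        if valid[-1]:
            ends.append(self.n_samples)
        min_n = int(math.ceil(min_duration * self.sample_rate))
        return [(a, b) for a, b in zip(starts, ends) if b - a >= min_n]


def apply_gap_mask(record: SignalRecord) -> list[tuple[int, int]]:
    """Enumerate the valid (unmasked) segments of a record.

    Returns half-open ``(start_index, end_index)`` pairs.  All downstream
    epoching is anchored at these segment starts, so no epoch ever straddles
    a masked run.  Raises if the whole record is masked.
    """
    segments = record.valid_segments()
    if not segments:
        raise ValueError("no valid data: the entire record is masked")
    return segments


@dataclass(frozen=True)
class Event:
    kind: str
    start: float
    end: float | None = None
    cue_class: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end is not None and not self.start < self.end:
            raise ValueError("event start must precede end")
        if self.cue_class is not None and self.cue_class not in CUE_CLASSES:
            raise ValueError(f"unknown cue class {self.cue_class!r}")


@dataclass
class EventTrack:
    """Time-sorted behavioral/stimulus events."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> "EventTrack":
        return EventTrack([e for e in self.events if e.kind == kind])

    @property
    def bouts(self) -> list[Event]:
        return [e for e in self.events if e.kind == "exploration_bout"]


@dataclass
class TrackingTrace:
    """Nose/center/tail planar coordinates (cm) per video frame."""

    frame_times: np.ndarray
    nose: np.ndarray
    center: np.ndarray
    tail: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        for attr in ("nose", "center", "tail"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (self.frame_times.size, 2):
                raise ValueError(f"{attr} must have shape (n_frames, 2)")
            setattr(self, attr, arr)
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass
class SessionManifest:
    """Where a session lives on disk and how its channels are named."""

    animal_id: str
    condition: str
    signals_path: str
    stimulus_label: str = ""
    events_path: str | None = None
    tracking_path: str | None = None
    #: canonical name -> name used in the file
    channel_map: dict[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_CHANNELS}
    )

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise ValueError("animal_id must be nonempty")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )


class Session(NamedTuple):
    record: SignalRecord
    events: EventTrack
    tracking: TrackingTrace | None
    manifest: SessionManifest


# ---------------------------------------------------------------------------
# native HDF5 + JSON sidecar format


def save_session(
    signals_path: str | Path,
    record: SignalRecord,
    events: EventTrack | None = None,
    tracking: TrackingTrace | None = None,
    manifest: SessionManifest | None = None,
) -> None:
    """Write a session in the native layout.

    Signals go to `signals_path` (HDF5); events/manifest to a
    ``<stem>.json`` sidecar; tracking to ``<stem>.tracking.csv``.
    Datasets are written with ``track_times=False`` so repeated writes of
    identical content are byte-identical.
    """
    signals_path = Path(signals_path)
    with h5py.File(signals_path, "w") as f:
        f.create_dataset("signals", data=record.samples, track_times=False)
        f.create_dataset("gap_mask", data=record.gap_mask, track_times=False)
        f.attrs["channel_names"] = list(record.channel_names)
        f.attrs["sample_rate"] = record.sample_rate
        f.attrs["start_time"] = record.start_time

    sidecar: dict = {
        "events": [
            {
                "kind": e.kind,
                "start": e.start,
                "end": e.end,
                "cue_class": e.cue_class,
            }
            for e in (events or EventTrack())
        ]
    }
    if manifest is not None:
        sidecar["manifest"] = {
            "animal_id": manifest.animal_id,
            "condition": manifest.condition,
            "stimulus_label": manifest.stimulus_label,
            "channel_map": manifest.channel_map,
        }
    signals_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )

    if tracking is not None:
        df = pd.DataFrame(
            {
                "time": tracking.frame_times,
                "nose_x": tracking.nose[:, 0],
                "nose_y": tracking.nose[:, 1],
                "center_x": tracking.center[:, 0],
                "center_y": tracking.center[:, 1],
                "tail_x": tracking.tail[:, 0],
                "tail_y": tracking.tail[:, 1],
            }
        )
        df.to_csv(
            signals_path.with_suffix("").as_posix() + ".tracking.csv",
            index=False,
        )


def _load_tracking_csv(path: str | Path, frame_rate: float = 25.0) -> TrackingTrace:
    df = pd.read_csv(path)
    return TrackingTrace(
        frame_times=df["time"].to_numpy(),
        nose=df[["nose_x", "nose_y"]].to_numpy(),
        center=df[["center_x", "center_y"]].to_numpy(),
        tail=df[["tail_x", "tail_y"]].to_numpy(),
        frame_rate=frame_rate,
    )


def load_session(manifest: SessionManifest) -> Session:
    """Load and synchronize a session described by a manifest.

    Channels are re-ordered to the canonical ``(EEG1, EEG2, EMG, Resp)``
    order via the manifest's channel map; a missing channel is a hard error
    naming the channel.
    """
    path = Path(manifest.signals_path)
    if path.suffix.lower() == ".edf":
        record = read_edf(path, channel_map=manifest.channel_map)
    else:
        with h5py.File(path, "r") as f:
            stored_names = tuple(str(n) for n in f.attrs["channel_names"])
            record = SignalRecord(
                channel_names=stored_names,
                samples=f["signals"][()],
                sample_rate=float(f.attrs["sample_rate"]),
                start_time=float(f.attrs["start_time"]),
                gap_mask=f["gap_mask"][()],
            )
        record = _to_canonical(record, manifest.channel_map)

    events = EventTrack()
    sidecar = (
        Path(manifest.events_path)
        if manifest.events_path
        else path.with_suffix(".json")
    )
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        events = EventTrack(
            [
                Event(
                    kind=e["kind"],
                    start=e["start"],
                    end=e.get("end"),
                    cue_class=e.get("cue_class"),
                )
                for e in payload.get("events", [])
            ]
        )

    tracking = None
    tracking_path = (
        Path(manifest.tracking_path)
        if manifest.tracking_path
        else Path(path.with_suffix("").as_posix() + ".tracking.csv")
    )
    if tracking_path.exists():
        tracking = _load_tracking_csv(tracking_path)

    return Session(record, events, tracking, manifest)


def _to_canonical(record: SignalRecord, channel_map: dict[str, str]) -> SignalRecord:
    stored = []
    for canon in CANONICAL_CHANNELS:
        name = channel_map.get(canon, canon)
        if name not in record.channel_names:
            raise ValueError(f"channel {canon} missing (looked for {name!r})")
        stored.append(name)
    rec = record.select(tuple(stored))
    return replace(rec, channel_names=CANONICAL_CHANNELS)


def read_edf(path: str | Path, channel_map: dict[str, str] | None = None) -> SignalRecord:
    """Read a four-channel EDF file (read-only import path).

    Requires :mod:`mne`.  Channels are re-ordered to canonical order using
    `channel_map` (canonical name -> EDF channel label).
    """
    import mne  # deferred: EDF import is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    record = SignalRecord(
        channel_names=tuple(raw.ch_names),
        samples=raw.get_data(),
        sample_rate=float(raw.info["sfreq"]),
    )
    return _to_canonical(record, channel_map or {c: c for c in CANONICAL_CHANNELS})


def align_video_frames(trace: TrackingTrace, ttl_times: np.ndarray) -> TrackingTrace:
    """Re-stamp video frames with TTL pulse times on the signal clock.

    The camera emits one TTL per frame; a count mismatch beyond one frame is
    an error.  TTL times are taken as authoritative.
    """
    ttl_times = np.asarray(ttl_times, dtype=float)
    n_frames, n_ttl = trace.n_frames, ttl_times.size
    if abs(n_frames - n_ttl) > 1:
        raise ValueError(
            f"TTL/frame count mismatch: {n_frames} frames vs {n_ttl} TTL pulses"
        )
    n = min(n_frames, n_ttl)
    return TrackingTrace(
        frame_times=ttl_times[:n],
        nose=trace.nose[:n],
        center=trace.center[:n],
        tail=trace.tail[:n],
        frame_rate=trace.frame_rate,
    )
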