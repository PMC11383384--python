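"""Behavioral measures: velocity, exploration-bout detection, EMG-based
movement classification, and the respiration-vs-running cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .respiration import RespirationFrequencySeries
from .session import Event, EventTrack, TrackingTrace


@dataclass
class VelocitySeries:
    """Center-point instantaneous speed (cm/s) per video frame."""

    frame_times: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")


@dataclass
class MovementTrack:
    """Sliding 2-s EMG RMS bins with a relative moving/still call."""

    bin_centers: np.ndarray
    emg_rms: np.ndarray
    moving: np.ndarray
    threshold: float
    threshold_fraction: float


def compute_velocity(trace: TrackingTrace) -> VelocitySeries:
    """Instantaneous speed from consecutive center-point displacements.

    The center (not nose) point is used to avoid head-bobbing inflation;
    the first frame copies the second.
    """
    if trace.n_frames < 2:
        raise ValueError("need at least two frames")
    if not np.all(np.diff(trace.frame_times) > 0):
        raise ValueError("frame times must be strictly increasing")
    disp = np.linalg.norm(np.diff(trace.center, axis=0), axis=1)
    speed = disp / np.diff(trace.frame_times)
    speed = np.concatenate([[speed[0]], speed])
    return VelocitySeries(trace.frame_times, speed)


def detect_exploration_bouts(
    trace: TrackingTrace,
    object_position,
    radius: float = 2.0,
    cue_class: str | None = None,
) -> EventTrack:
    """Exploration bouts: nose inside a 2-cm perimeter around the object.

    A bout starts at the first frame with nose-object distance <= radius
    (inclusive boundary) and ends at the next frame where the nose has
    moved out; consecutive in-perimeter frame runs are merged.
    """
    obj = np.asarray(object_position, dtype=float)
    dist = np.linalg.norm(trace.nose - obj, axis=1)
    inside = dist <= radius
    if not inside.any():
        return EventTrack()
    padded = np.concatenate([[False], inside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    t = trace.frame_times
    dt = 1.0 / trace.frame_rate
    events = []
    for a, b in zip(starts, ends):
        # end = time of the first out-of-perimeter frame
        end = t[b] if b < t.size else t[-1] + dt
        events.append(Event("exploration_bout", t[a], end, cue_class=cue_class))
    return EventTrack(events)


def classify_movement(
    emg: np.ndarray,
    fs: float,
    bin_length: float = 2.0,
    step: float = 0.5,
    threshold_fraction: float = 0.15,
) -> MovementTrack:
    """Moving/still classification from sliding-bin EMG RMS.

    RMS is computed over sliding 2-s bins (0.5-s step); the animal-specific
    threshold is `threshold_fraction` (10-20%, conservatively low) of the
    session-maximum bin RMS, so classification is invariant to rescaling
    the whole EMG channel.

    Degenerate case: a threshold relative to the session maximum only
    separates anything when movement bursts exist.  If the session has no
    burst structure at all (maximum bin RMS under twice the median), the
    muscle tone never rose above its resting band and every bin is still.
    """
    if not 0.10 <= threshold_fraction <= 0.20:
        raise ValueError("threshold_fraction must be within [0.10, 0.20]")
    emg = np.asarray(emg, dtype=float)
    n_bin = int(round(bin_length * fs))
    n_step = int(round(step * fs))
    if emg.size < n_bin:
        raise ValueError("record shorter than one bin")
    starts = np.arange(0, emg.size - n_bin + 1, n_step)
    sq = np.concatenate([[0.0], np.cumsum(emg**2)])
    rms = np.sqrt((sq[starts + n_bin] - sq[starts]) / n_bin)
    threshold = threshold_fraction * rms.max()
    if rms.max() < 2.0 * np.median(rms):
        moving = np.zeros(rms.size, dtype=bool)
    else:
        moving = rms > threshold
    return MovementTrack(
        bin_centers=(starts + n_bin / 2.0) / fs,
        emg_rms=rms,
        moving=moving,
        threshold=float(threshold),
        threshold_fraction=threshold_fraction,
    )


def still_intervals(track: MovementTrack, bin_length: float = 2.0) -> list[tuple[float, float]]:
    """Merge still bins into half-open time intervals."""
    still = ~track.moving
    out = []
    half = bin_length / 2.0
    start = None
    for c, s in zip(track.bin_centers, still):
        if s and start is None:
            start = c - half
        elif not s and start is not None:
            out.append((start, c - half))
            start = None
    if start is not None:
        out.append((start, track.bin_centers[-1] + half))
    return out


def freq_velocity_crosstab(
    freq: RespirationFrequencySeries,
    vel: VelocitySeries,
    freq_bands=((1.0, 5.0), (9.0, 13.0)),
    vel_bands=((1.0, 10.0), (35.0, 45.0)),
) -> dict:
    """Cross-tabulate respiration frequency against running speed.

    Velocity is resampled to the frequency-window centers.  Reports the
    mean velocity within the two prominent frequency bands, the mean
    frequency within the two prominent velocity bands (each compared by an
    unpaired t test), and the Pearson correlation across all windows.
    An empty band is reported as NaN with a note.
    """
    t = freq.window_centers
    ok = np.isfinite(freq.dominant_frequency)
    lo, hi = vel.frame_times[0], vel.frame_times[-1]
    ok &= (t >= lo) & (t <= hi)
    if not ok.any():
        raise ValueError("series do not overlap in time")
    f = freq.dominant_frequency[ok]
    v = np.interp(t[ok], vel.frame_times, vel.speed)

    notes = []

    def band_mean(values, cond_values, band):
        sel = (cond_values >= band[0]) & (cond_values < band[1])
        if not sel.any():
            notes.append(f"band {band} empty")
            return np.nan, np.zeros(0)
        return float(values[sel].mean()), values[sel]

    vel_by_freq, samples_vf = {}, []
    for band in freq_bands:
        m, vals = band_mean(v, f, band)
        vel_by_freq[band] = m
        samples_vf.append(vals)
    freq_by_vel, samples_fv = {}, []
    for band in vel_bands:
        m, vals = band_mean(f, v, band)
        freq_by_vel[band] = m
        samples_fv.append(vals)

    def utest(a, b):
        if a.size < 2 or b.size < 2:
            return np.nan
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    r, r_p = stats.pearsonr(f, v) if f.size > 2 else (np.nan, np.nan)
    return {
        "velocity_by_freq_band": vel_by_freq,
        "freq_by_velocity_band": freq_by_vel,
        "velocity_comparison_p": utest(*samples_vf),
        "frequency_comparison_p": utest(*samples_fv),
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "n_windows": int(f.size),
        "notes": notes,
    }
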