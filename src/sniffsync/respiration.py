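"""Respiration analyses: rolling dominant-frequency estimation, inhalation
peak detection, sensor-agreement metrics, bout-aligned frequency trials and
intersniff statistics.

The dominant-frequency estimator follows the classic autocorrelation
recipe: each 1-s window is standardized and linearly detrended, its
autocorrelation computed, and the reciprocal lag of the first qualifying
autocorrelation peak taken as the window's frequency.  "First qualifying"
means the first local maximum after the first zero crossing, at a lag of at
least 1/15 s (capping detectable frequency at 15 Hz) and with
autocorrelation value of at least 0.2 — a floor that stops the lag-0 lobe
and noise peaks from being picked up.  The peak lag is refined by parabolic
interpolation, which keeps the error of a pure tone well below one lag
quantum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .vigilance import Hypnogram

logger = logging.getLogger(__name__)

MAX_SNIFF_HZ = 15.0
MIN_AUTOCORR_PEAK = 0.2


@dataclass
class RespirationFrequencySeries:
    """Rolling dominant-frequency estimates (NaN where no qualifying peak)."""

    window_centers: np.ndarray
    dominant_frequency: np.ndarray
    window_length: float = 1.0
    window_shift: float = 0.05

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.dominant_frequency = np.asarray(self.dominant_frequency, dtype=float)
        if self.window_centers.shape != self.dominant_frequency.shape:
            raise ValueError("centers and frequencies must align")
        with np.errstate(invalid="ignore"):
            if np.any(self.dominant_frequency <= 0):
                raise ValueError("frequencies must be positive where present")

    def interp(self, t: np.ndarray) -> np.ndarray:
        ok = np.isfinite(self.dominant_frequency)
        return np.interp(t, self.window_centers[ok], self.dominant_frequency[ok])


@dataclass
class InhalationPeakTrain:
    """Strictly increasing inhalation (trough) times in seconds."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_times.size


@dataclass
class RelativeErrorSummary:
    """Per-trial mean relative error and its population statistics."""

    per_trial_mean_error: np.ndarray
    population_mean: float
    population_sd: float
    n_excluded_windows: int = 0


@dataclass
class TrialAlignedFrequency:
    """Per-trial frequency traces aligned to bout start (t = 0)."""

    trial_times: np.ndarray  # relative to bout start
    traces: np.ndarray  # (n_trials, n_windows)
    baseline_frequency: np.ndarray  # mean over first 500 ms of each trial
    exploration_frequency: np.ndarray  # mean over first 1 s of each bout
    delta_traces: np.ndarray  # baseline-subtracted
    cue_classes: list = field(default_factory=list)
    n_discarded: int = 0

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    def mean_delta_trace(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.delta_traces, axis=0)


@dataclass
class IntersniffDistribution:
    """Per-state intersniff interval samples and mean frequency.

    The per-state mean frequency is the reciprocal of the mean interval.
    """

    intervals: dict[str, np.ndarray]
    mean_frequency: dict[str, float]
    omitted_states: list[str] = field(default_factory=list)


def estimate_frequency(
    signal: np.ndarray,
    fs: float,
    window: float = 1.0,
    shift: float = 0.05,
    max_freq: float = MAX_SNIFF_HZ,
    min_peak: float = MIN_AUTOCORR_PEAK,
) -> RespirationFrequencySeries:
    """Rolling autocorrelation estimate of the dominant respiration frequency.

    Windows of `window` seconds advance by `shift`; each is standardized and
    linearly detrended before autocorrelation.  A window with no qualifying
    peak (or zero variance) yields NaN.
    """
    x = np.asarray(signal, dtype=float)
    n_win = int(round(window * fs))
    n_shift = max(1, int(round(shift * fs)))
    if x.size < n_win:
        raise ValueError("signal shorter than one window")

    views = sliding_window_view(x, n_win)[::n_shift].copy()
    views = sps.detrend(views, axis=1, type="linear")
    sd = views.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d constant windows yielded no frequency estimate", flat.sum())
    sd[flat] = 1.0
    views = (views - views.mean(axis=1, keepdims=True)) / sd[:, None]

    # batched energy-normalized autocorrelation: each lag's product sum is
    # divided by the energies of BOTH overlapping segments, so a periodic
    # window scores exactly 1 at its period and the triangular envelope /
    # boundary ripple of the plain estimate (which drags the peak off the
    # true lag) cancels
    nfft = int(2 ** np.ceil(np.log2(2 * n_win)))
    spec = np.fft.rfft(views, nfft, axis=1)
    num = np.fft.irfft(spec * spec.conj(), nfft, axis=1)[:, :n_win]
    acf_raw = num / num[:, :1]
    csum = np.concatenate(
        [np.zeros((views.shape[0], 1)), np.cumsum(views**2, axis=1)], axis=1
    )
    lags = np.arange(n_win)
    e_head = csum[:, n_win - lags]            # energy of x[0 : N-l]
    e_tail = csum[:, [n_win]] - csum[:, lags]  # energy of x[l : N]
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = num / np.sqrt(e_head * e_tail)

    # require at least a quarter of the window to overlap: caps the slowest
    # detectable rhythm (~1.3 Hz for a 1-s window at 400 Hz) and keeps the
    # normalized estimate's variance bounded
    max_lag = n_win - n_win // 4
    min_lag = int(np.ceil(fs / max_freq))
    freqs = np.full(views.shape[0], np.nan)
    for i in range(views.shape[0]):
        if flat[i]:
            continue
        lag = _first_qualifying_peak(
            acf[i, :max_lag], acf_raw[i, :max_lag], min_lag, min_peak
        )
        if lag is not None:
            freqs[i] = fs / lag

    centers = (np.arange(views.shape[0]) * n_shift + (n_win - 1) / 2.0) / fs
    return RespirationFrequencySeries(centers, freqs, window, shift)


def _first_qualifying_peak(
    acf: np.ndarray, acf_raw: np.ndarray, min_lag: int, min_peak: float
):
    """Sub-sample lag of the first qualifying autocorrelation peak.

    Peaks are located and interpolated on the energy-normalized score
    `acf`, whose maxima sit at the true period, but qualified on the plain
    normalized value `acf_raw`, which stays near zero for aperiodic
    windows (the energy-normalized score is noisy at long lags and would
    let white noise through).  The integer-lag peak is refined by cosine
    interpolation — exact when the local peak is a sampled sinusoid, as
    the autocorrelation of a periodic signal is — with a parabolic
    fallback.
    """
    below = np.flatnonzero(acf <= 0)
    if below.size == 0:
        return None
    start = max(int(below[0]) + 1, min_lag, 1)
    seg = acf[start:]
    if seg.size < 3:
        return None
    maxima = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
    for m in maxima:
        k = start + m
        if acf_raw[k] >= min_peak:
            if k + 1 >= acf.size:
                return float(k)
            y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
            cos_w = (y0 + y2) / (2 * y1) if y1 != 0 else np.nan
            if np.isfinite(cos_w) and -1 < cos_w < 1:
                w = np.arccos(cos_w)
                offset = np.arctan2(y0 - y2, 2 * y1 * np.sin(w)) / w
            else:
                denom = y0 - 2 * y1 + y2
                offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return k + float(np.clip(offset, -0.5, 0.5))
    return None


def detect_inhalation_peaks(
    signal: np.ndarray,
    fs: float,
    min_freq: float = 1.0,
    max_freq: float = MAX_SNIFF_HZ,
    prominence_fraction: float = 0.25,
) -> InhalationPeakTrain:
    """Trough times of the sniff cycle (inhalation peaks, thoracic convention).

    The signal is band-passed (zero-phase) to the sniffing range, then local
    minima are located with a minimum spacing of one maximal-rate cycle and
    a prominence of at least `prominence_fraction` of the median cycle
    depth.  Because a relative prominence threshold cannot by itself tell
    noise troughs from sniff troughs, candidate minima are additionally
    gated on the rolling autocorrelation estimator: a trough only counts
    where the surrounding second of signal has a qualifying rhythmic peak.
    A flat or non-oscillatory signal therefore yields an empty train.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < int(2 * fs / min_freq) or np.ptp(x) == 0:
        return InhalationPeakTrain(np.empty(0))
    nyq = fs / 2.0
    if not 0 < min_freq < max_freq < nyq:
        raise ValueError("bandwidth bounds must lie inside (0, Nyquist)")
    sos = sps.butter(4, (min_freq, max_freq), btype="bandpass", fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)

    distance = max(1, int(fs / max_freq))
    cand, _ = sps.find_peaks(-xf, distance=distance)
    if cand.size == 0:
        return InhalationPeakTrain(np.empty(0))
    prom = sps.peak_prominences(-xf, cand)[0]
    threshold = prominence_fraction * np.median(prom[prom > 0]) if np.any(prom > 0) else np.inf
    peaks = cand[prom >= threshold]

    # sub-sample trough time by parabolic interpolation of the filtered signal
    interior = peaks[(peaks > 0) & (peaks < xf.size - 1)]
    y0, y1, y2 = xf[interior - 1], xf[interior], xf[interior + 1]
    denom = y0 - 2 * y1 + y2
    offset = np.where(denom != 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    times = (interior + np.clip(offset, -0.5, 0.5)) / fs

    # rhythmicity gate: keep troughs whose neighborhood shows a dominant
    # frequency (coarse 0.25-s shift is plenty for a boolean gate)
    est = estimate_frequency(x, fs, window=1.0, shift=0.25, max_freq=max_freq)
    ok_centers = est.window_centers[np.isfinite(est.dominant_frequency)]
    if ok_centers.size == 0:
        return InhalationPeakTrain(np.empty(0))
    near = np.abs(times[:, None] - ok_centers[None, :]).min(axis=1) <= 0.75
    return InhalationPeakTrain(times[near])


def relative_error(
    freq_thoracic: RespirationFrequencySeries | list[RespirationFrequencySeries],
    freq_flow: RespirationFrequencySeries | list[RespirationFrequencySeries],
) -> RelativeErrorSummary:
    """Relative error (f_thoracic - f_flow) / f_flow, per window then per trial.

    Accepts a single trial or matched lists of trials; windows where the
    flow estimate is missing or zero are excluded (their count is
    reported).  Population mean and SD are computed across trial means.
    """
    th = freq_thoracic if isinstance(freq_thoracic, list) else [freq_thoracic]
    fl = freq_flow if isinstance(freq_flow, list) else [freq_flow]
    if len(th) != len(fl):
        raise ValueError("trial lists must match")
    per_trial = []
    excluded = 0
    for a, b in zip(th, fl):
        if a.window_centers.size != b.window_centers.size or not np.allclose(
            a.window_centers, b.window_centers
        ):
            raise ValueError("series must share a window grid")
        with np.errstate(invalid="ignore", divide="ignore"):
            err = (a.dominant_frequency - b.dominant_frequency) / b.dominant_frequency
        ok = np.isfinite(err)
        excluded += int((~ok).sum())
        per_trial.append(float(err[ok].mean()) if ok.any() else np.nan)
    per_trial = np.asarray(per_trial)
    valid = per_trial[np.isfinite(per_trial)]
    return RelativeErrorSummary(
        per_trial_mean_error=per_trial,
        population_mean=float(valid.mean()),
        population_sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        n_excluded_windows=excluded,
    )


def peak_lag(
    flow_peaks: InhalationPeakTrain, thoracic_peaks: InhalationPeakTrain
) -> dict:
    """Time differences between near-simultaneous flow and thoracic peaks.

    Each flow peak is paired with its nearest thoracic peak within half the
    median flow cycle; the lag is ``flow_time - thoracic_time``, so a
    negative mean means flow precedes thoracic pressure.  Unpaired peaks are
    dropped and counted.
    """
    if len(flow_peaks) == 0 or len(thoracic_peaks) == 0:
        raise ValueError("both peak trains must be nonempty")
    f = flow_peaks.peak_times
    th = thoracic_peaks.peak_times
    tol = 0.5 * float(np.median(np.diff(f))) if f.size > 1 else np.inf

    idx = np.searchsorted(th, f)
    lags = []
    used = set()
    unpaired = 0
    for i, tf in enumerate(f):
        cand = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < th.size]
        cand = [j for j in cand if abs(tf - th[j]) <= tol and j not in used]
        if not cand:
            unpaired += 1
            continue
        j = min(cand, key=lambda j: abs(tf - th[j]))
        used.add(j)
        lags.append(tf - th[j])
    if not lags:
        raise ValueError("trains not concurrent: no peak pairs within tolerance")
    lags = np.asarray(lags)
    return {
        "lags": lags,
        "mean": float(lags.mean()),
        "sd": float(lags.std(ddof=1)) if lags.size > 1 else 0.0,
        "n_unpaired_flow": unpaired,
    }


def extract_bout_trials(
    freq: RespirationFrequencySeries,
    bouts,
    pre: float = 3.0,
    post: float = 3.0,
    baseline_window: float = 0.5,
    exploration_window: float = 1.0,
    max_missing_baseline: float = 0.5,
) -> TrialAlignedFrequency:
    """Bout-aligned frequency trials with baseline subtraction.

    Each surviving bout yields a trial covering ``[start - pre, start +
    post)``; bouts with less than `pre` seconds of prior recording are
    discarded.  The baseline is the mean frequency over the first
    `baseline_window` seconds of the trial, the exploration frequency the
    mean over the first `exploration_window` seconds of the bout, and the
    delta trace is the trace minus its baseline.  Trials whose baseline
    window is more than half missing are discarded (count logged).
    """
    centers = freq.window_centers
    step = freq.window_shift
    rel = np.arange(-pre, post, step)
    traces, baselines, explos, cues = [], [], [], []
    discarded = 0
    events = bouts.bouts if hasattr(bouts, "bouts") else list(bouts)
    for ev in events:
        start = ev.start
        if start - pre < centers[0] - step / 2:
            discarded += 1
            continue
        grid = start + rel
        inside = (grid >= centers[0] - step / 2) & (grid <= centers[-1] + step / 2)
        trace = np.full(rel.size, np.nan)
        idx = np.clip(
            np.round((grid[inside] - centers[0]) / step).astype(int), 0, centers.size - 1
        )
        trace[inside] = freq.dominant_frequency[idx]
        base_sel = rel < -pre + baseline_window
        base_vals = trace[base_sel]
        if np.mean(~np.isfinite(base_vals)) > max_missing_baseline:
            discarded += 1
            continue
        baseline = float(np.nanmean(base_vals))
        explo_sel = (rel >= 0) & (rel < exploration_window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            explo = float(np.nanmean(trace[explo_sel]))
        traces.append(trace)
        baselines.append(baseline)
        explos.append(explo)
        cues.append(getattr(ev, "cue_class", None))
    if discarded:
        logger.warning("%d bouts discarded (insufficient baseline)", discarded)
    if not traces:
        warnings.warn("no surviving bouts", RuntimeWarning, stacklevel=2)
        empty = np.empty((0, rel.size))
        return TrialAlignedFrequency(rel, empty, np.empty(0), np.empty(0), empty,
                                     [], discarded)
    traces = np.vstack(traces)
    baselines = np.asarray(baselines)
    return TrialAlignedFrequency(
        trial_times=rel,
        traces=traces,
        baseline_frequency=baselines,
        exploration_frequency=np.asarray(explos),
        delta_traces=traces - baselines[:, None],
        cue_classes=cues,
        n_discarded=discarded,
    )


def intersniff_stats(
    peaks: InhalationPeakTrain, hypnogram: Hypnogram
) -> IntersniffDistribution:
    """Intersniff intervals split by vigilance state.

    An interval is assigned to the state of the epoch containing its
    earlier peak; a state with fewer than two peaks is omitted with a note.
    The per-state mean frequency is 1 / mean(interval).
    """
    t = peaks.peak_times
    if t.size and (t[0] < hypnogram.epoch_starts[0] or t[-1] >= hypnogram.end):
        raise ValueError("hypnogram does not cover the peak train")
    intervals: dict[str, list[float]] = {}
    labels = hypnogram.label_at(t[:-1]) if t.size > 1 else np.empty(0, dtype=object)
    for dt, state in zip(np.diff(t), labels):
        intervals.setdefault(state, []).append(float(dt))
    omitted = [s for s, v in intervals.items() if len(v) < 1]
    out_int = {s: np.asarray(v) for s, v in intervals.items() if len(v) >= 1}
    mean_freq = {s: 1.0 / float(v.mean()) for s, v in out_int.items()}
    return IntersniffDistribution(out_int, mean_freq, omitted)
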