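"""Rule-based wake/NREM/REM scoring in 5-s epochs, and sleep-odor trial
bookkeeping.

Scoring emulates semi-automated hypnogram construction with explicit,
reproducible rules: per 5-s epoch we compute delta (1-4 Hz) power, theta
(4-10 Hz) power (both from the mean of the two EEG channels) and EMG RMS.
An epoch with EMG tone above threshold is wake; otherwise high delta power
means NREM; otherwise a theta/delta ratio above threshold means REM; the
remainder is wake.  Thresholds are relative to session medians, which makes
labels exactly invariant to common positive rescaling of the signals.

Note the scoring bands (delta 1-4, theta 4-10 Hz) are deliberately distinct
from the coherence-analysis bands; see :mod:`sniffsync.bands`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .bands import SCORING_DELTA, SCORING_THETA

WAKE, NREM, REM = "wake", "NREM", "REM"


@dataclass
class Hypnogram:
    """Contiguous 5-s epoch labels with the features behind each call."""

    epoch_starts: np.ndarray
    labels: np.ndarray
    epoch_length: float = 5.0
    delta_power: np.ndarray | None = None
    theta_power: np.ndarray | None = None
    emg_rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epoch_starts.shape != self.labels.shape:
            raise ValueError("one label per epoch required")
        if self.epoch_starts.size > 1 and not np.allclose(
            np.diff(self.epoch_starts), self.epoch_length
        ):
            raise ValueError("epochs must be contiguous")

    @property
    def end(self) -> float:
        return float(self.epoch_starts[-1] + self.epoch_length)

    def label_at(self, t) -> np.ndarray:
        idx = np.clip(
            ((np.asarray(t) - self.epoch_starts[0]) / self.epoch_length).astype(int),
            0,
            self.labels.size - 1,
        )
        return self.labels[idx]

    def rem_to_nrem_count(self) -> int:
        """QC flag: REM->NREM transitions (physiologically atypical).

        Reported, never enforced.
        """
        a, b = self.labels[:-1], self.labels[1:]
        return int(np.sum((a == REM) & (b == NREM)))


@dataclass(frozen=True)
class ScoringThresholds:
    """Relative thresholds for the state-calling rule.

    EMG tone threshold is `emg_factor` times the session median epoch EMG
    RMS; the delta threshold `delta_factor` times the median epoch delta
    power; REM requires a theta/delta ratio above `theta_delta_ratio`.
    """

    emg_factor: float = 2.0
    delta_factor: float = 1.5
    theta_delta_ratio: float = 1.0

    def __post_init__(self) -> None:
        if min(self.emg_factor, self.delta_factor, self.theta_delta_ratio) <= 0:
            raise ValueError("thresholds must be positive")


def _epoch_band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Mean PSD inside `band` for each row of x (epochs)."""
    nper = min(x.shape[-1], int(2 * fs))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nper, axis=-1)
    sel = (freqs >= band[0]) & (freqs < band[1])
    return psd[..., sel].mean(axis=-1)


def score_states(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    epoch: float = 5.0,
    thresholds: ScoringThresholds | None = None,
    smooth: bool = False,
) -> Hypnogram:
    """Score wake/NREM/REM per 5-s epoch from EEG band power and EMG tone.

    `eeg` may be a single channel or a (2, n) pair (averaged for scoring).
    With `smooth`, a 3-epoch median filter is applied to the label sequence
    (off by default: raw epochs are scored).
    """
    thresholds = thresholds or ScoringThresholds()
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float)).mean(axis=0)
    emg = np.asarray(emg, dtype=float)
    n_ep = int(len(eeg) // (epoch * fs))
    if n_ep < 1:
        raise ValueError("record shorter than one epoch")
    n = int(epoch * fs)
    eeg_ep = eeg[: n_ep * n].reshape(n_ep, n)
    emg_ep = emg[: n_ep * n].reshape(n_ep, n)

    delta = _epoch_band_power(eeg_ep, fs, SCORING_DELTA)
    theta = _epoch_band_power(eeg_ep, fs, SCORING_THETA)
    emg_rms = np.sqrt((emg_ep**2).mean(axis=1))

    emg_thr = thresholds.emg_factor * np.median(emg_rms)
    delta_thr = thresholds.delta_factor * np.median(delta)

    labels = np.full(n_ep, WAKE, dtype=object)
    asleep = emg_rms <= emg_thr
    labels[asleep & (delta > delta_thr)] = NREM
    rem = asleep & (delta <= delta_thr) & (theta / np.maximum(delta, 1e-300) > thresholds.theta_delta_ratio)
    labels[rem] = REM

    if smooth and n_ep >= 3:
        codes = np.array([(WAKE, NREM, REM).index(l) for l in labels])
        med = sps.medfilt(codes.astype(float), kernel_size=3).astype(int)
        labels = np.array([(WAKE, NREM, REM)[c] for c in med], dtype=object)

    return Hypnogram(
        epoch_starts=np.arange(n_ep) * epoch,
        labels=labels,
        epoch_length=epoch,
        delta_power=delta,
        theta_power=theta,
        emg_rms=emg_rms,
    )


# ---------------------------------------------------------------------------
# sleep-odor trials


@dataclass(frozen=True)
class SleepTrialWindows:
    """Standard timing of one sleep-odor trial.

    The respiration sensor turns on 10 s after NREM onset (for 1 min), the
    odor arrives 10 s later, and state transitions are counted in the 20 s
    after odor introduction; respiration/EEG comparisons use the 5-s
    windows just before and just after the odor.
    """

    nrem_onset: float
    sensor_on: float = field(init=False)
    odor_time: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensor_on", self.nrem_onset + 10.0)
        object.__setattr__(self, "odor_time", self.sensor_on + 10.0)

    @property
    def transition_window(self) -> tuple[float, float]:
        return (self.odor_time, self.odor_time + 20.0)

    @property
    def pre_window(self) -> tuple[float, float]:
        return (self.odor_time - 5.0, self.odor_time)

    @property
    def post_window(self) -> tuple[float, float]:
        return (self.odor_time, self.odor_time + 5.0)


def sleep_trial_outcomes(
    hypnogram: Hypnogram, trials: list[SleepTrialWindows]
) -> dict:
    """First state change inside each trial's 20-s transition window.

    A trial where the animal is not in NREM at odor time is excluded (odor
    placement itself woke the animal).  Returns per-trial outcomes
    ("remained_nrem", "to_wake", "to_rem") and their proportions.
    """
    outcomes = []
    excluded = 0
    for w in trials:
        lo, hi = w.transition_window
        if hi > hypnogram.end:
            raise ValueError("hypnogram does not cover the transition window")
        if hypnogram.label_at(w.odor_time) != NREM:
            excluded += 1
            continue
        sel = (hypnogram.epoch_starts + hypnogram.epoch_length > lo) & (
            hypnogram.epoch_starts < hi
        )
        changed = hypnogram.labels[sel][hypnogram.labels[sel] != NREM]
        if changed.size == 0:
            outcomes.append("remained_nrem")
        else:
            outcomes.append("to_wake" if changed[0] == WAKE else "to_rem")
    n = len(outcomes)
    props = {
        k: (outcomes.count(k) / n if n else np.nan)
        for k in ("remained_nrem", "to_wake", "to_rem")
    }
    return {"outcomes": outcomes, "proportions": props, "n_excluded": excluded}


def windowed_comparison(
    times: np.ndarray,
    values: np.ndarray,
    trials: list[SleepTrialWindows],
    measure: str = "resp_frequency",
) -> dict:
    """Paired pre/post 5-s means around odor introduction, with paired t test.

    `values` is any per-time series (respiration frequency, delta power,
    theta power); the test is omitted (NaN) with fewer than two trials.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    pre, post = [], []
    for w in trials:
        for (lo, hi), acc in ((w.pre_window, pre), (w.post_window, post)):
            if lo < times[0] or hi > times[-1] + 1e-9:
                raise ValueError("series does not cover the comparison windows")
            sel = (times >= lo) & (times < hi)
            acc.append(float(np.nanmean(values[sel])))
    pre, post = np.asarray(pre), np.asarray(post)
    result = {
        "measure": measure,
        "pre_means": pre,
        "post_means": post,
        "mean_difference": float((post - pre).mean()) if pre.size else np.nan,
    }
    if pre.size >= 2:
        if np.allclose(post, pre):
            result["t"], result["p"] = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(post, pre)
            result["t"], result["p"] = float(t), float(p)
    else:
        result["t"] = result["p"] = np.nan
    return result
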