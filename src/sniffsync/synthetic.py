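"""Synthetic session generator with exported ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* respiration as a phase-continuous oscillation whose instantaneous
  frequency and regularity depend on vigilance state (wake fast and
  variable, NREM slow and regular, REM slow and slightly irregular) and on
  exploration bouts (configurable frequency increment at bout onset);
* two EEG channels built as shared band-limited components derived from the
  respiration channel (weighted to hit a target coherence at the band
  midpoint) plus independent band-limited and broadband noise;
* EMG as broadband noise whose RMS rises inside movement intervals and
  varies with vigilance state;
* arena trajectories producing nose approach/retraction bouts around an
  object position.

Every generator draws from its own counter-derived stream of one global
seed, so components are individually reproducible.  A small VAR generator
with a closed-form spectral matrix is also provided, solely as an
independent oracle for the partial-coherence estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .bands import BandDefinition, COHERENCE_BANDS
from .session import (
    CANONICAL_CHANNELS,
    Event,
    EventTrack,
    Session,
    SessionManifest,
    SignalRecord,
    TrackingTrace,
    save_session,
)
from .spectral import bandpass_array

STATES = ("wake", "NREM", "REM")

# per-component sub-stream labels of the global seed
_COMPONENTS = ("respiration", "coupling", "emg", "tracking", "var")


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent, reproducible stream for one generator component."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_COMPONENTS.index(component),))
    )


# ---------------------------------------------------------------------------
# state schedule


@dataclass(frozen=True)
class StateParams:
    """Respiration parameters of one vigilance state."""

    freq_hz: float
    freq_jitter_sd: float
    amplitude: float
    amplitude_jitter: float

    def __post_init__(self) -> None:
        if self.freq_hz <= 0:
            raise ValueError("state frequency must be positive")


# Wake sniffing is fast and variable, NREM slow/regular and low amplitude,
# REM slow with doubled frequency jitter plus amplitude jitter.
DEFAULT_STATE_PARAMS: dict[str, StateParams] = {
    "wake": StateParams(7.0, 1.2, 1.0, 0.30),
    "NREM": StateParams(3.0, 0.25, 0.4, 0.05),
    "REM": StateParams(3.3, 0.50, 0.7, 0.30),
}


@dataclass
class StateSchedule:
    """Vigilance-state segments tiling a session, with per-state respiration."""

    segments: list[tuple[str, float, float]]
    params: dict[str, StateParams] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PARAMS)
    )

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s[1])
        t = segs[0][1]
        for state, a, b in segs:
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if a != t or b <= a:
                raise ValueError("segments must tile the session without overlap")
            t = b
        self.segments = segs

    @property
    def start(self) -> float:
        return self.segments[0][1]

    @property
    def end(self) -> float:
        return self.segments[-1][2]

    def state_per_sample(self, fs: float) -> np.ndarray:
        n = int(round((self.end - self.start) * fs))
        out = np.empty(n, dtype=object)
        for state, a, b in self.segments:
            i0 = int(round((a - self.start) * fs))
            i1 = int(round((b - self.start) * fs))
            out[i0:i1] = state
        return out

    @classmethod
    def constant(
        cls, state: str, duration: float, params: dict[str, StateParams] | None = None
    ) -> "StateSchedule":
        sched = cls([(state, 0.0, duration)])
        if params:
            sched.params.update(params)
        return sched


# ---------------------------------------------------------------------------
# respiration


@dataclass
class RespirationTruth:
    """Exact generative state of the respiration channel."""

    frequency: np.ndarray  # instantaneous frequency per sample, Hz
    inhalation_times: np.ndarray  # phase-trough crossing times, s
    states: np.ndarray  # state label per sample
    bout_intervals: list[tuple[float, float]]
    seed: int


def _truncated_normal(rng: np.random.Generator, sd: float) -> float:
    """Gaussian draw truncated at +-3 SD (by rejection)."""
    if sd == 0:
        return 0.0
    while True:
        v = rng.normal(0.0, sd)
        if abs(v) <= 3 * sd:
            return v


def generate_respiration(
    schedule: StateSchedule,
    bouts: EventTrack | None,
    fs: float,
    seed: int,
    bout_increment_hz: float = 3.0,
    freq_boosts: list[tuple[float, float, float]] | None = None,
    shape_skew: float = -0.3,
) -> tuple[np.ndarray, RespirationTruth]:
    """Phase-continuous thoracic-pressure oscillation plus exact truth.

    The waveform is ``a_c * sin(phi - pi/2 - skew * sin(phi))`` for a phase
    phi that advances at the instantaneous frequency: negative deflection is
    inhalation (thoracic convention) and the warp makes the cycle shape
    asymmetric while keeping the minimum exactly at each ``phi = 2 pi k``
    crossing, whose interpolated times are exported as inhalation times.
    Frequency jitter is drawn once per cycle (Gaussian truncated at 3 SD);
    inside exploration bouts the instantaneous frequency is raised by
    `bout_increment_hz`, and `freq_boosts` adds arbitrary (start, end,
    delta_hz) modulations (e.g. sleep odor responses).
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if not 0 <= abs(shape_skew) < 1:
        raise ValueError("shape_skew magnitude must be < 1")
    duration = schedule.end - schedule.start
    n = int(round(duration * fs))
    states = schedule.state_per_sample(fs)

    base = np.empty(n)
    amp = np.empty(n)
    jit_sd = np.empty(n)
    amp_jit = np.empty(n)
    for state in STATES:
        m = states == state
        if not m.any():
            continue
        p = schedule.params[state]
        base[m], amp[m] = p.freq_hz, p.amplitude
        jit_sd[m], amp_jit[m] = p.freq_jitter_sd, p.amplitude_jitter

    bout_intervals = []
    for ev in (bouts.bouts if bouts is not None else []):
        end = ev.end if ev.end is not None else ev.start
        if ev.start < schedule.start or end > schedule.end:
            raise ValueError(f"bout [{ev.start}, {end}) outside the session")
        i0, i1 = int(round(ev.start * fs)), int(round(end * fs))
        base[i0:i1] += bout_increment_hz
        bout_intervals.append((ev.start, end))
    for a, b, dhz in freq_boosts or []:
        base[int(round(a * fs)) : int(round(b * fs))] += dhz

    rng = component_rng(seed, "respiration")
    phase = np.empty(n)
    freq = np.empty(n)
    amp_cycle = np.empty(n)
    inhalations: list[float] = []
    phi = np.pi  # start mid-cycle so the first trough is interior
    next_trough = 2.0 * np.pi
    jitter = _truncated_normal(rng, jit_sd[0])

    def draw_amp(i: int) -> float:
        return amp[i] * max(0.05, 1.0 + _truncated_normal(rng, amp_jit[i]))

    # amplitude is interpolated within each cycle by a smoothstep whose
    # slope vanishes at the cycle boundaries, so the waveform minimum stays
    # exactly at each trough even when amplitude jitters between cycles
    a_prev, a_next = draw_amp(0), draw_amp(0)
    dt = 1.0 / fs
    for i in range(n):
        f = max(base[i] + jitter, 0.2)
        freq[i] = f
        phase[i] = phi
        u = (phi - (next_trough - 2.0 * np.pi)) / (2.0 * np.pi)
        u = min(max(u, 0.0), 1.0)
        amp_cycle[i] = a_prev + (a_next - a_prev) * u * u * (3.0 - 2.0 * u)
        phi_next = phi + 2.0 * np.pi * f * dt
        if phi_next >= next_trough:
            # exact crossing time by linear interpolation of the phase ramp
            inhalations.append((i + (next_trough - phi) / (phi_next - phi)) * dt)
            next_trough += 2.0 * np.pi
            jitter = _truncated_normal(rng, jit_sd[i])
            a_prev, a_next = a_next, draw_amp(i)
        phi = phi_next

    wave = amp_cycle * np.sin(phase - np.pi / 2.0 - shape_skew * np.sin(phase))
    truth = RespirationTruth(
        frequency=freq,
        inhalation_times=np.asarray(inhalations),
        states=states,
        bout_intervals=bout_intervals,
        seed=seed,
    )
    return wave, truth


# ---------------------------------------------------------------------------
# coupled EEG / EMG


@dataclass(frozen=True)
class CouplingTarget:
    """Target coherence for one band and channel pair, with bout modulation."""

    band: str
    pair: tuple[str, str]
    level: float
    bout_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.band not in COHERENCE_BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if not 0 <= self.level < 1:
            raise ValueError(
                "target level must be in [0, 1); level 1 is unattainable with "
                "nonzero independent noise"
            )
        if not 0 <= self.level + self.bout_delta < 1:
            raise ValueError("modulated level must stay in [0, 1)")
        pair = tuple(sorted(self.pair))
        allowed = {("EEG1", "Resp"), ("EEG2", "Resp"), ("EEG1", "EEG2")}
        if pair not in allowed:
            raise ValueError(f"unsupported coupling pair {self.pair}")
        object.__setattr__(self, "pair", pair)


@dataclass
class CouplingSpec:
    targets: list[CouplingTarget] = field(default_factory=list)

    def for_band(self, band: str) -> list[CouplingTarget]:
        return [t for t in self.targets if t.band == band]


@dataclass
class CouplingTruth:
    """Mixing weights and implied coherence/partial coherence per target."""

    weights: dict  # (band, pair) -> {"base": w, "bout": w}
    coherence: dict  # (band, pair) -> {"base": c, "bout": c}
    implied_pcoh: dict  # (band, pair) -> {"base": c, "bout": c}
    emg_rms_profile: np.ndarray | None = None


# default per-state gain of the independent band-limited EEG noise,
# giving NREM its delta dominance and REM its theta dominance
DEFAULT_STATE_EEG_GAINS: dict[str, dict[str, float]] = {
    "wake": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0},
    "NREM": {"delta": 4.0, "theta": 1.0, "alpha": 0.7, "beta": 0.5},
    "REM": {"delta": 0.7, "theta": 3.0, "alpha": 0.8, "beta": 0.6},
}

DEFAULT_STATE_EMG_RMS: dict[str, float] = {"wake": 1.0, "NREM": 0.3, "REM": 0.05}


def _psd_at(x: np.ndarray, fs: float, band: BandDefinition, K: int = 6) -> float:
    """Multitaper-smoothed PSD of x at the band midpoint.

    Uses the band's own five-cycle epoch length and the analysis taper
    count, so the generator's coherence calibration is expressed in the
    same spectral resolution the estimator sees (a pointwise PSD would
    overstate the coherence of a narrowband component against broadband
    noise once the estimator smooths over its taper bandwidth).
    """
    from .bands import epoch_length_for_band
    from .spectral import band_bin_indices, epoch_spectral_matrices

    n = int(round(epoch_length_for_band(band) * fs))
    E = x.size // n
    epochs = x[: E * n].reshape(E, 1, n)
    bins = band_bin_indices(n, fs, band)
    _, S = epoch_spectral_matrices(epochs, fs, bins, K=K)
    return float(S[:, :, 0, 0].real.mean())


def _interval_mask(n: int, fs: float, intervals) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    for a, b in intervals:
        m[int(round(a * fs)) : int(round(b * fs))] = True
    return m


def generate_coupled_eeg_emg(
    resp: np.ndarray,
    spec: CouplingSpec,
    movement: EventTrack | None,
    fs: float,
    seed: int,
    schedule: StateSchedule | None = None,
    bout_intervals: list[tuple[float, float]] | None = None,
    burst_gain: float = 10.0,
    broadband_sd: float = 0.1,
    state_eeg_gains: dict[str, dict[str, float]] | None = None,
    state_emg_rms: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, CouplingTruth]:
    """EEG1, EEG2 coupled to the respiration channel, plus burst EMG.

    Each EEG channel is a sum over bands of a shared band-limited component
    (the band-filtered respiration channel for Resp pairs, an independent
    band-limited source for the EEG1-EEG2 pair) weighted to achieve the
    target coherence at the band midpoint, plus independent band-limited
    noise and weak broadband noise.  The weight for target level c is

        w = sqrt(c / (1 - c) * N(f_c) / S(f_c)),

    where S and N are the Welch PSDs of the shared component and of the
    channel's total independent noise at the band midpoint, so the achieved
    magnitude-squared coherence at f_c is c by construction.  Inside
    exploration bouts the weight switches to the bout-modulated level.

    EMG is white noise whose RMS follows the vigilance state and is
    multiplied by `burst_gain` inside movement intervals.
    """
    n = resp.size
    rng = component_rng(seed, "coupling")
    states = (
        schedule.state_per_sample(fs)
        if schedule is not None
        else np.full(n, "wake", dtype=object)
    )
    eeg_gains = state_eeg_gains or DEFAULT_STATE_EEG_GAINS
    gains_per_sample = {
        bname: np.array([eeg_gains[s][bname] for s in states])
        for bname in COHERENCE_BANDS
    }

    # independent noise floor of each EEG channel
    noise = {}
    for ch in ("EEG1", "EEG2"):
        total = broadband_sd * rng.standard_normal(n)
        for bname, band in COHERENCE_BANDS.items():
            nb = bandpass_array(rng.standard_normal(n), fs, band.f_lo, band.f_hi)
            nb /= nb.std()
            total = total + gains_per_sample[bname] * nb
        noise[ch] = total

    bout_mask = _interval_mask(n, fs, bout_intervals or [])

    shared_cache: dict[tuple[str, str], np.ndarray] = {}

    def shared_component(band: BandDefinition, pair: tuple[str, str]) -> np.ndarray:
        source = "resp" if "Resp" in pair else "common"
        key = (band.name, source)
        if key not in shared_cache:
            base = resp if source == "resp" else rng.standard_normal(n)
            s = bandpass_array(base, fs, band.f_lo, band.f_hi)
            shared_cache[key] = s / s.std()
        return shared_cache[key]

    weights: dict = {}
    coh: dict = {}
    eeg = {"EEG1": noise["EEG1"].copy(), "EEG2": noise["EEG2"].copy()}
    model: dict = {}  # (band, channel) -> (w_base, w_bout, S_fc, N_fc) for Resp pairs
    for target in spec.targets:
        band = COHERENCE_BANDS[target.band]
        s = shared_component(band, target.pair)
        S_fc = _psd_at(s, fs, band)

        def weight_for(level: float, N_fc: float) -> float:
            return float(np.sqrt(level / (1.0 - level) * N_fc / S_fc)) if level else 0.0

        chans = (
            [p for p in target.pair if p != "Resp"]
            if "Resp" in target.pair
            else list(target.pair)
        )
        for ch in chans:
            N_fc = _psd_at(noise[ch], fs, band)
            w0 = weight_for(target.level, N_fc)
            w1 = weight_for(target.level + target.bout_delta, N_fc)
            w_t = np.where(bout_mask, w1, w0)
            eeg[ch] = eeg[ch] + w_t * s
            weights[(target.band, target.pair)] = {"base": w0, "bout": w1}
            if "Resp" in target.pair:
                model[(target.band, ch)] = (w0, w1, S_fc, N_fc)

        def achieved(w: float, N_fc: float) -> float:
            return w**2 * S_fc / (w**2 * S_fc + N_fc)

        N_ref = _psd_at(noise[chans[0]], fs, band)
        coh[(target.band, target.pair)] = {
            "base": achieved(weights[(target.band, target.pair)]["base"], N_ref),
            "bout": achieved(weights[(target.band, target.pair)]["bout"], N_ref),
        }

    implied = _implied_partial_coherence(model)

    # EMG
    emg_rms = np.empty(n)
    rms_by_state = state_emg_rms or DEFAULT_STATE_EMG_RMS
    for state in STATES:
        m = states == state
        if m.any():
            emg_rms[m] = rms_by_state[state]
    if movement is not None:
        move_mask = _interval_mask(
            n, fs, [(e.start, e.end if e.end is not None else e.start) for e in movement]
        )
        emg_rms[move_mask] *= burst_gain
    emg = emg_rms * rng.standard_normal(n)

    truth = CouplingTruth(
        weights=weights, coherence=coh, implied_pcoh=implied, emg_rms_profile=emg_rms
    )
    return eeg["EEG1"], eeg["EEG2"], emg, truth


def _implied_partial_coherence(model: dict) -> dict:
    """Closed-form partial coherence implied by Resp-pair mixing weights.

    With E_i = w_i s + n_i and Resp carrying s at the band midpoint, the
    partial coherence of (E_i, Resp) given the other EEG channel (EMG is
    independent and drops out) is

        w_i^2 S / (w_i^2 S + N_i (1 + w_j^2 S / N_j)).
    """
    out: dict = {}
    by_band: dict[str, dict[str, tuple]] = {}
    for (band, ch), vals in model.items():
        by_band.setdefault(band, {})[ch] = vals
    for band, chans in by_band.items():
        for ch, (w0, w1, S, N) in chans.items():
            other = [c for c in chans if c != ch]
            res = {}
            for cond, wi in (("base", w0), ("bout", w1)):
                extra = 0.0
                if other:
                    wo = chans[other[0]][0 if cond == "base" else 1]
                    extra = wo**2 * chans[other[0]][2] / chans[other[0]][3]
                num = wi**2 * S
                res[cond] = num / (num + N * (1.0 + extra)) if num else 0.0
            out[(band, tuple(sorted((ch, "Resp"))))] = res
    return out


# ---------------------------------------------------------------------------
# tracking


@dataclass
class TrackingTruth:
    bout_intervals: list[tuple[float, float]]
    object_position: tuple[float, float]
    seed: int


def generate_tracking_and_bouts(
    arena_radius: float = 25.0,
    object_position: tuple[float, float] = (10.0, 0.0),
    approach_plan: list[tuple[float, float]] | None = None,
    duration: float = 300.0,
    frame_rate: float = 25.0,
    seed: int = 0,
    cue_class: str = "object",
    perimeter: float = 2.0,
    wander: bool = True,
) -> tuple[TrackingTrace, EventTrack, TrackingTruth]:
    """Smooth nose trajectory with planned approach/dwell bouts.

    `approach_plan` lists (approach_time, dwell_s) pairs; around each, the
    nose-to-object distance descends linearly through the bout perimeter,
    dwells inside, and retreats, so the exact perimeter-crossing times are
    known and exported as truth bout intervals.  Between approaches the
    mouse wanders at 8-16 cm from the object (or sits still if not
    `wander`).  Body center and tail trail the nose toward the arena center.
    """
    obj = np.asarray(object_position, dtype=float)
    if np.hypot(*obj) >= arena_radius - perimeter:
        raise ValueError("object must sit inside the arena")
    rng = component_rng(seed, "tracking")
    plan = sorted(approach_plan or [])

    # control points of the nose-object distance profile
    far_hi = min(16.0, arena_radius - np.hypot(*obj) - 1.0)
    far_lo = min(8.0, 0.6 * far_hi)

    def far() -> float:
        return rng.uniform(far_lo, far_hi) if wander else 12.0

    pts = [(0.0, far())]
    truth_bouts = []
    for t_a, dwell in plan:
        t_end = t_a + dwell
        if t_a - 1.5 <= pts[-1][0] or t_end + 1.5 >= duration:
            raise ValueError(f"approach at {t_a} s does not fit the session")
        pts += [
            (t_a - 1.0, 6.0),
            (t_a, perimeter),          # crossing *into* the perimeter
            (t_a + 0.3, 0.9),
            (max(t_a + 0.3, t_end - 0.3), 0.9),
            (t_end, perimeter),        # last instant inside
            (t_end + 1.0, 6.0),
        ]
        truth_bouts.append((t_a, t_end))
    pts.append((duration, far()))
    if wander:
        # extra waypoints so the inter-approach path meanders
        extras = []
        times = sorted(rng.uniform(0, duration, size=max(3, int(duration / 20))))
        occupied = [(a - 2.5, b + 2.5) for a, b in truth_bouts]
        for t in times:
            if all(not a <= t <= b for a, b in occupied):
                extras.append((t, far()))
        pts = sorted(pts + extras)

    t_ctrl = np.array([p[0] for p in pts])
    d_ctrl = np.array([p[1] for p in pts])
    frame_times = np.arange(int(round(duration * frame_rate))) / frame_rate
    dist = np.interp(frame_times, t_ctrl, d_ctrl)
    theta = 0.4 + 0.03 * frame_times
    if wander:
        drift = np.cumsum(rng.normal(0, 0.004, size=frame_times.size))
        theta = theta + drift
    u = np.c_[np.cos(theta), np.sin(theta)]
    nose = obj + dist[:, None] * u

    def trail(points: np.ndarray, back: float) -> np.ndarray:
        r = np.hypot(points[:, 0], points[:, 1])
        inward = points / np.maximum(r, 1e-9)[:, None]
        return points - back * inward

    trace = TrackingTrace(
        frame_times=frame_times,
        nose=nose,
        center=trail(nose, 4.0),
        tail=trail(nose, 9.0),
        frame_rate=frame_rate,
    )
    events = EventTrack(
        [
            Event("exploration_bout", a, b, cue_class=cue_class)
            for a, b in truth_bouts
        ]
    )
    return trace, events, TrackingTruth(truth_bouts, tuple(obj), seed)


# ---------------------------------------------------------------------------
# whole sessions


@dataclass
class SyntheticGroundTruth:
    """Everything the generators know, for recovery tests."""

    seed: int
    respiration: RespirationTruth
    coupling: CouplingTruth
    tracking: TrackingTruth | None
    schedule: StateSchedule
    events: EventTrack
    sleep_windows: list[dict] = field(default_factory=list)


_CONFIG_KEYS = {
    "animal_id", "condition", "stimulus_label", "duration_s", "fs", "seed",
    "states", "state_params", "bout_plan", "bout_increment_hz", "couplings",
    "burst_gain", "broadband_sd", "state_emg_rms", "arena_radius",
    "object_position", "cue_class", "gaps", "odor_response_hz",
    "movement_from_wake",
}


@dataclass
class SessionConfig:
    """Validated configuration of one synthetic session."""

    animal_id: str = "M1"
    condition: str = "open_arena"
    stimulus_label: str = ""
    duration_s: float = 300.0
    fs: float = 400.0
    seed: int = 0
    #: list of (state, start, end); default: all wake
    states: list[tuple[str, float, float]] | None = None
    state_params: dict[str, StateParams] | None = None
    #: list of (approach_time, dwell_s)
    bout_plan: list[tuple[float, float]] = field(default_factory=list)
    bout_increment_hz: float = 3.0
    couplings: list[CouplingTarget] = field(default_factory=list)
    burst_gain: float = 10.0
    broadband_sd: float = 0.1
    state_emg_rms: dict[str, float] | None = None
    arena_radius: float = 25.0
    object_position: tuple[float, float] = (10.0, 0.0)
    cue_class: str = "object"
    #: telemetry-off intervals, (start, end)
    gaps: list[tuple[float, float]] = field(default_factory=list)
    #: respiration step after sleep odor introduction
    odor_response_hz: float = 2.0
    #: treat wake segments as movement intervals for the EMG burst profile
    movement_from_wake: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "SessionConfig":
        unknown = sorted(set(raw) - _CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        raw = dict(raw)
        if "state_params" in raw and raw["state_params"] is not None:
            raw["state_params"] = {
                k: v if isinstance(v, StateParams) else StateParams(**v)
                for k, v in raw["state_params"].items()
            }
        if "couplings" in raw:
            raw["couplings"] = [
                c if isinstance(c, CouplingTarget)
                else CouplingTarget(
                    band=c["band"],
                    pair=tuple(c["pair"]),
                    level=c["level"],
                    bout_delta=c.get("bout_delta", 0.0),
                )
                for c in raw["couplings"]
            ]
        if "states" in raw and raw["states"] is not None:
            raw["states"] = [tuple(s) for s in raw["states"]]
        if "bout_plan" in raw:
            raw["bout_plan"] = [tuple(b) for b in raw["bout_plan"]]
        if "object_position" in raw:
            raw["object_position"] = tuple(raw["object_position"])
        if "gaps" in raw:
            raw["gaps"] = [tuple(g) for g in raw["gaps"]]
        return cls(**raw)


def load_config(path: str | Path) -> SessionConfig:
    """Read a YAML session configuration."""
    return SessionConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def generate_session(
    config: SessionConfig, out_dir: str | Path | None = None
) -> tuple[Session, SyntheticGroundTruth]:
    """Compose the generators on a shared clock; optionally write to disk.

    For ``condition = "sleep_odor"`` every NREM segment of at least 60 s
    receives the standard trial layout: the respiration sensor turns on for
    one minute starting 10 s after NREM onset, and the odor is introduced
    10 s after that (20 s after onset) with the configured respiration
    response.
    """
    seed = config.seed
    schedule = StateSchedule(
        config.states or [("wake", 0.0, config.duration_s)],
        params={**DEFAULT_STATE_PARAMS, **(config.state_params or {})},
    )
    if schedule.end != config.duration_s or schedule.start != 0.0:
        raise ValueError("state segments must tile [0, duration_s)")

    tracking = None
    tracking_truth = None
    events = EventTrack()
    if config.condition != "sleep_odor":
        tracking, events, tracking_truth = generate_tracking_and_bouts(
            arena_radius=config.arena_radius,
            object_position=config.object_position,
            approach_plan=config.bout_plan,
            duration=config.duration_s,
            seed=seed,
            cue_class=config.cue_class,
        )

    sleep_windows: list[dict] = []
    freq_boosts: list[tuple[float, float, float]] = []
    if config.condition == "sleep_odor":
        extra = []
        for state, a, b in schedule.segments:
            if state == "NREM" and b - a >= 60.0:
                sensor_on = a + 10.0
                odor_time = sensor_on + 10.0
                extra.append(Event("sensor_on", sensor_on, sensor_on + 60.0))
                extra.append(Event("odor_introduction", odor_time, cue_class="odor"))
                freq_boosts.append((odor_time, min(odor_time + 10.0, b), config.odor_response_hz))
                sleep_windows.append(
                    {
                        "nrem_onset": a,
                        "sensor_on": sensor_on,
                        "odor_time": odor_time,
                        "transition_window": (odor_time, odor_time + 20.0),
                    }
                )
        events = EventTrack(list(events) + extra)

    resp, resp_truth = generate_respiration(
        schedule,
        events,
        config.fs,
        seed,
        bout_increment_hz=config.bout_increment_hz,
        freq_boosts=freq_boosts,
    )

    movement = EventTrack(
        [
            Event("exploration_bout", a, b)
            for state, a, b in schedule.segments
            if state == "wake" and config.movement_from_wake
        ]
    )
    eeg1, eeg2, emg, coupling_truth = generate_coupled_eeg_emg(
        resp,
        CouplingSpec(config.couplings),
        movement,
        config.fs,
        seed,
        schedule=schedule,
        bout_intervals=resp_truth.bout_intervals,
        burst_gain=config.burst_gain,
        broadband_sd=config.broadband_sd,
        state_emg_rms=config.state_emg_rms,
    )

    gap_mask = _interval_mask(resp.size, config.fs, config.gaps)
    record = SignalRecord(
        channel_names=CANONICAL_CHANNELS,
        samples=np.stack([eeg1, eeg2, emg, resp]),
        sample_rate=config.fs,
        gap_mask=gap_mask,
    )
    manifest = SessionManifest(
        animal_id=config.animal_id,
        condition=config.condition,
        stimulus_label=config.stimulus_label,
        signals_path="",
    )
    truth = SyntheticGroundTruth(
        seed=seed,
        respiration=resp_truth,
        coupling=coupling_truth,
        tracking=tracking_truth,
        schedule=schedule,
        events=events,
        sleep_windows=sleep_windows,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        h5_path = out_dir / "session.h5"
        manifest.signals_path = str(h5_path)
        save_session(h5_path, record, events, tracking, manifest)
        (out_dir / "truth.json").write_text(json.dumps(_truth_payload(truth), indent=1))

    return Session(record, events, tracking, manifest), truth


def _truth_payload(truth: SyntheticGroundTruth) -> dict:
    return {
        "seed": truth.seed,
        "inhalation_times": truth.respiration.inhalation_times.tolist(),
        "bout_intervals": truth.respiration.bout_intervals,
        "states": [list(s) for s in truth.schedule.segments],
        "coupling_weights": {
            f"{band}:{'-'.join(pair)}": v
            for (band, pair), v in truth.coupling.weights.items()
        },
        "coupling_coherence": {
            f"{band}:{'-'.join(pair)}": v
            for (band, pair), v in truth.coupling.coherence.items()
        },
        "implied_pcoh": {
            f"{band}:{'-'.join(pair)}": v
            for (band, pair), v in truth.coupling.implied_pcoh.items()
        },
        "tracking_bouts": truth.tracking.bout_intervals if truth.tracking else [],
        "sleep_windows": truth.sleep_windows,
    }


# ---------------------------------------------------------------------------
# VAR oracle (for partial-coherence tests only)


def simulate_var(
    A: np.ndarray, Sigma: np.ndarray, n: int, seed: int, burn: int = 1000
) -> np.ndarray:
    """Simulate a stationary VAR(1) process x_t = A x_{t-1} + e_t.

    Returns a (p, n) array.  Used exclusively as an independent oracle: its
    spectral matrix has the closed form implemented in
    :func:`var_spectral_matrix`.
    """
    A = np.asarray(A, dtype=float)
    p = A.shape[0]
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1:
        raise ValueError("VAR(1) coefficient matrix must be stable")
    rng = component_rng(seed, "var")
    L = np.linalg.cholesky(np.asarray(Sigma, dtype=float))
    e = rng.standard_normal((n + burn, p)) @ L.T
    x = np.zeros((n + burn, p))
    for t in range(1, n + burn):
        x[t] = A @ x[t - 1] + e[t]
    return x[burn:].T


def var_spectral_matrix(
    A: np.ndarray, Sigma: np.ndarray, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """Analytic spectral matrix S(f) = H(f) Sigma H(f)^H / f_Nyquist.

    H(f) = (I - A e^{-i omega})^{-1} with omega = 2 pi f / fs; the scale
    matches the estimator's one-sided density convention (irrelevant for
    coherence, which is scale-free).
    """
    A = np.asarray(A, dtype=float)
    p = A.shape[0]
    out = np.empty((len(freqs), p, p), dtype=complex)
    eye = np.eye(p)
    for i, f in enumerate(np.atleast_1d(freqs)):
        H = np.linalg.inv(eye - A * np.exp(-2j * np.pi * f / fs))
        out[i] = H @ Sigma @ H.conj().T / (fs / 2.0)
    return out
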