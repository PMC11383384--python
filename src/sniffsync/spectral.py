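"""Locally-stationary spectral core: sine-taper multitaper spectral matrices,
shrinkage regularization, partial coherence with null p-values, FDR control,
and normalized band power.

The analysis treats a p-channel record as locally stationary over short
epochs sized to hold about five cycles of the band of interest
(:func:`sniffsync.bands.epoch_length_for_band`).  Within each epoch the
p x p spectral matrix S(f) is estimated with K = ceil(1.5 p) orthonormal
sine tapers.  Partial coherence between channels j and k given all others
is computed from the inverse G(f) = S(f)^{-1} as

    pcoh_jk(f) = |G_jk(f)|^2 / (G_jj(f) G_kk(f)),

a scale-free measure of direct (conditional) linear association in [0, 1].

Band evaluation
---------------
Because the five-cycle epoch rule makes the K-taper spectral bandwidth at
the band midpoint span essentially the whole band, the per-epoch band value
is taken at the FFT bin nearest the band midpoint (``band_mode="center"``).
This keeps the Goodman null law exact: under H0 (no conditional coupling)
the estimate is Beta(1, nu-1) with nu = K - (p - 2) effective complex
degrees of freedom, so ``p = (1 - c)^(nu - 1)``.  Averaging across in-band
bins is available via ``band_mode="mean"`` but its null law is only
approximate (the in-band estimates are strongly correlated).

Small-sample debiasing
----------------------
The raw per-epoch estimate is biased upward (E[c_hat] = 1/nu under H0).
:func:`debias_partial_coherence` inverts the exact finite-sample mean
function of the estimator so that event-locked *changes* in partial
coherence are recovered on the correct scale; p-values always use the raw
estimate, for which the null law is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.special import hyp2f1
from statsmodels.stats.multitest import multipletests

from .bands import BandDefinition, DELTA, epoch_length_for_band, taper_count_rule
from .session import SignalRecord

__all__ = [
    "TaperBasis",
    "SpectralMatrixEstimate",
    "sine_tapers",
    "bandpass",
    "bandpass_array",
    "epoch_slices",
    "multitaper_spectral_matrix",
    "epoch_spectral_matrices",
    "regularize",
    "partial_coherence",
    "partial_coherence_matrix",
    "coherence_matrix",
    "band_bin_indices",
    "pcoh_pvalue",
    "pcoh_dof",
    "debias_partial_coherence",
    "fdr_adjust",
    "band_power",
    "BandPowerSpectrum",
]


# ---------------------------------------------------------------------------
# tapers


@dataclass(frozen=True)
class TaperBasis:
    """K orthonormal sine tapers of a given epoch sample length."""

    tapers: np.ndarray  # (K, N)

    @property
    def K(self) -> int:
        return self.tapers.shape[0]

    @property
    def N(self) -> int:
        return self.tapers.shape[1]


def sine_tapers(N: int, K: int) -> TaperBasis:
    """The K sinusoidal tapers v_k(t) = sqrt(2/(N+1)) sin(pi k (t+1)/(N+1)).

    These form an orthonormal family; unlike Slepian tapers they need no
    bandwidth parameter, and K of them concentrate the estimate over about
    (K+1)/2 Rayleigh resolutions around each frequency.
    """
    if K < 1 or N < K:
        raise ValueError(f"need N >= K >= 1, got N={N}, K={K}")
    t = np.arange(N)
    k = np.arange(1, K + 1)[:, None]
    return TaperBasis(np.sqrt(2.0 / (N + 1)) * np.sin(np.pi * k * (t + 1) / (N + 1)))


# ---------------------------------------------------------------------------
# filtering and epoching


def bandpass_array(
    x: np.ndarray, fs: float, f_lo: float, f_hi: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = fs / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(
            f"band ({f_lo}, {f_hi}) must lie strictly inside (0, {nyq}) Hz"
        )
    sos = sps.butter(order, (f_lo, f_hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass(
    record: SignalRecord, f_lo: float, f_hi: float, order: int = 4
) -> SignalRecord:
    """Band-pass every channel of a record (forward-backward, zero phase).

    The gap mask is carried through unchanged.
    """
    return replace(
        record,
        samples=bandpass_array(record.samples, record.sample_rate, f_lo, f_hi, order),
    )


def epoch_stack(x: np.ndarray, fs: float, epoch_length: float) -> np.ndarray:
    """Cut a (p, n) array into non-overlapping (E, p, N) epochs."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = int(round(epoch_length * fs))
    E = x.shape[1] // n
    if E == 0:
        raise ValueError("array shorter than one epoch")
    return x[:, : E * n].T.reshape(E, n, x.shape[0]).transpose(0, 2, 1)


def epoch_slices(record: SignalRecord, epoch_length: float) -> list[tuple[int, int]]:
    """Non-overlapping epoch index ranges that avoid masked samples.

    Epochs are anchored at the start of each contiguous valid segment;
    incomplete trailing epochs (and segments shorter than one epoch) are
    dropped rather than padded, so no epoch ever straddles a gap.
    """
    n = int(round(epoch_length * record.sample_rate))
    out = []
    for a, b in record.valid_segments(min_duration=epoch_length):
        out.extend((s, s + n) for s in range(a, b - n + 1, n))
    return out


# ---------------------------------------------------------------------------
# multitaper spectral matrices


@dataclass
class SpectralMatrixEstimate:
    """p x p Hermitian spectral matrices on a frequency grid.

    `matrices` has shape (F, p, p); the diagonal is the one-sided PSD
    (density sigma^2 / f_Nyquist for white noise of variance sigma^2).
    `weight` records the shrinkage weight applied (0 = unregularized) and
    `n_epochs` the number of epochs pooled into the estimate (taper
    degrees of freedom are K * n_epochs).
    """

    frequencies: np.ndarray
    matrices: np.ndarray
    K: int
    weight: float = 0.0
    n_epochs: int = 1
    epoch_index: int | None = None

    @property
    def p(self) -> int:
        return self.matrices.shape[-1]


def _tapered_rfft(x: np.ndarray, tapers: TaperBasis) -> np.ndarray:
    """rfft of each taper-windowed channel.  x: (..., p, N) -> (..., K, p, F)."""
    xt = x[..., None, :, :] * tapers.tapers[:, None, :]
    return np.fft.rfft(xt, axis=-1)


def multitaper_spectral_matrix(
    x: np.ndarray, fs: float, tapers: TaperBasis | None = None, K: int | None = None
) -> SpectralMatrixEstimate:
    """Multitaper estimate of the p x p spectral matrix of one epoch.

    Parameters
    ----------
    x : ndarray, shape (p, N)
        One locally-stationary epoch, p >= 2 channels.
    fs : float
        Sampling rate in Hz.
    tapers, K :
        Taper basis, or taper count (default ``ceil(1.5 p)``).

    Returns
    -------
    SpectralMatrixEstimate
        One-sided estimate; Hermitian with real non-negative diagonal at
        every frequency.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p, N = x.shape
    if p < 2:
        raise ValueError("need at least two channels")
    if tapers is None:
        tapers = sine_tapers(N, K if K is not None else taper_count_rule(p))
    if N < tapers.K:
        raise ValueError(f"epoch of {N} samples is shorter than K={tapers.K} tapers")
    X = _tapered_rfft(x, tapers)  # (K, p, F)
    S = np.einsum("kpf,kqf->fpq", X, X.conj()) / (tapers.K * fs)
    # one-sided: double everything except DC (and Nyquist when N is even)
    S[1:] *= 2.0
    if N % 2 == 0:
        S[-1] /= 2.0
    freqs = np.fft.rfftfreq(N, 1.0 / fs)
    return SpectralMatrixEstimate(freqs, S, K=tapers.K)


def epoch_spectral_matrices(
    epochs: np.ndarray, fs: float, bins: np.ndarray, K: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral matrices of many epochs at selected frequency bins.

    Computes the tapered DFT directly at the requested bins, which is far
    cheaper than a full FFT when only one or two bins per band are needed.

    Parameters
    ----------
    epochs : ndarray, shape (E, p, N)
    bins : ndarray of int
        rfft bin indices.

    Returns
    -------
    freqs : ndarray, shape (m,)
    S : ndarray, shape (E, m, p, p)
    """
    epochs = np.asarray(epochs, dtype=float)
    E, p, N = epochs.shape
    tapers = sine_tapers(N, K if K is not None else taper_count_rule(p))
    bins = np.atleast_1d(bins)
    t = np.arange(N)
    # (K, N) tapers * (m, N) Fourier kernels -> (m, K, N)
    kernel = np.exp(-2j * np.pi * bins[:, None] * t / N)
    basis = tapers.tapers[None, :, :] * kernel[:, None, :]  # (m, K, N)
    X = np.einsum("epn,mkn->emkp", epochs, basis, optimize=True)
    S = np.einsum("emkp,emkq->empq", X, X.conj(), optimize=True) / (tapers.K * fs)
    nonedge = (bins != 0) & ~((N % 2 == 0) & (bins == N // 2))
    S[:, nonedge] *= 2.0
    freqs = bins * fs / N
    return freqs, S


def regularize(
    est: SpectralMatrixEstimate, weight: float = 0.05, mode: str = "correlation"
) -> SpectralMatrixEstimate:
    """Convex shrinkage of the spectral matrix toward a diagonal target.

    ``mode="correlation"`` (default) shrinks the spectral *coherency*
    matrix toward the identity while keeping each channel's own power:
    ``S_reg = D^{1/2} [(1-w) C + w I] D^{1/2}`` with ``C = D^{-1/2} S
    D^{-1/2}`` and ``D = diag(S)``.  Because coherence is scale-free this
    perturbs every pair equally, however unequal the channel powers are.

    ``mode="identity"`` is the naive alternative ``(1 - w) S + w (tr S / p)
    I``; with strongly unequal channel powers (a narrowband respiration
    channel against broadband EEG) the trace term swamps the weaker
    diagonals and crushes their coherences, so it is not the default.

    Both are invertible for any w > 0 whenever the diagonal is positive;
    the weight used is recorded on the result.
    """
    if not 0 <= weight <= 1:
        raise ValueError("weight must be in [0, 1]")
    out = shrink_matrices(est.matrices, weight, mode)
    return replace(est, matrices=out, weight=weight)


def shrink_matrices(
    S: np.ndarray, weight: float, mode: str = "correlation"
) -> np.ndarray:
    """Apply shrinkage to an (..., p, p) stack of matrices (see regularize)."""
    if weight == 0:
        return S
    p = S.shape[-1]
    eye = np.eye(p)
    if mode == "correlation":
        d = np.sqrt(np.maximum(np.einsum("...ii->...i", S).real, 1e-300))
        C = S / (d[..., :, None] * d[..., None, :])
        C = (1.0 - weight) * C + weight * eye
        return C * (d[..., :, None] * d[..., None, :])
    if mode == "identity":
        tr = np.einsum("...ii->...", S).real / p
        return (1.0 - weight) * S + weight * tr[..., None, None] * eye
    raise ValueError(f"unknown shrinkage mode {mode!r}")


# ---------------------------------------------------------------------------
# partial coherence


def band_bin_indices(
    N: int, fs: float, band: BandDefinition, band_mode: str = "center"
) -> np.ndarray:
    """rfft bin indices representing a band for an epoch of N samples.

    ``"center"`` (default) returns the single bin nearest the band midpoint;
    ``"mean"`` returns every bin whose center lies in [f_lo, f_hi).
    """
    freqs = np.fft.rfftfreq(N, 1.0 / fs)
    if band_mode == "center":
        return np.array([int(np.argmin(np.abs(freqs - band.center)))])
    if band_mode == "mean":
        idx = np.flatnonzero((freqs >= band.f_lo) & (freqs < band.f_hi))
        if idx.size == 0:
            raise ValueError(f"no frequency bins inside band {band.name}")
        return idx
    raise ValueError(f"unknown band_mode {band_mode!r}")


def partial_coherence_matrix(S: np.ndarray) -> np.ndarray:
    """All-pairs partial coherence from (..., p, p) spectral matrices.

    Entry (j, k) is |G_jk|^2 / (G_jj G_kk) with G = S^{-1}; the diagonal is
    set to zero.  Raises if S is not invertible (regularize first).
    """
    try:
        G = np.linalg.inv(S)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular spectral matrix; apply regularize() with weight > 0"
        ) from err
    d = np.einsum("...ii->...i", G).real
    pc = np.abs(G) ** 2 / (d[..., :, None] * d[..., None, :])
    idx = np.arange(S.shape[-1])
    pc[..., idx, idx] = 0.0
    return np.clip(pc.real, 0.0, 1.0)


def coherence_matrix(S: np.ndarray) -> np.ndarray:
    """Ordinary magnitude-squared coherence |S_jk|^2 / (S_jj S_kk)."""
    d = np.einsum("...ii->...i", S).real
    c = np.abs(S) ** 2 / (d[..., :, None] * d[..., None, :])
    idx = np.arange(S.shape[-1])
    c[..., idx, idx] = 1.0
    return np.clip(c.real, 0.0, 1.0)


def partial_coherence(
    est: SpectralMatrixEstimate,
    band: BandDefinition,
    band_mode: str = "center",
) -> np.ndarray:
    """Band-level p x p partial-coherence matrix of one spectral estimate.

    With p = 2 this equals ordinary magnitude-squared coherence (there is
    nothing to condition on).
    """
    freqs = est.frequencies
    if band_mode == "center":
        sel = [int(np.argmin(np.abs(freqs - band.center)))]
    else:
        sel = np.flatnonzero((freqs >= band.f_lo) & (freqs < band.f_hi))
    pc = partial_coherence_matrix(est.matrices[sel])
    return pc.mean(axis=0)


def pcoh_dof(K: int, p: int) -> int:
    """Effective complex dof of a partial-coherence estimate.

    K tapered samples minus one per conditioned channel: nu = K - (p - 2).
    """
    nu = K - (p - 2)
    if nu < 2:
        raise ValueError(
            f"K={K} tapers cannot support partial coherence among p={p} channels"
        )
    return nu


def pcoh_pvalue(estimate, K: int, p: int):
    """p-value for H0: partial coherence = 0.

    Under H0 the raw estimate follows Beta(1, nu - 1) with
    nu = K - (p - 2), the classical coherence null law with taper dof
    reduced by the number of conditioned channels, giving
    ``p = (1 - c)^(nu - 1)``.
    """
    nu = pcoh_dof(K, p)
    c = np.clip(np.asarray(estimate, dtype=float), 0.0, 1.0)
    out = (1.0 - c) ** (nu - 1)
    return float(out) if np.isscalar(estimate) else out


@lru_cache(maxsize=8)
def _mean_function_table(nu: int) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated finite-sample mean E[c_hat | c] of the coherence estimator.

    The sampling density of the magnitude-squared (partial) coherence
    estimate with nu complex dof and population value c is

        f(x) = (nu - 1) (1 - c)^nu (1 - x)^(nu - 2) 2F1(nu, nu; 1; c x).

    The mean is evaluated on a grid of population values by Gauss-Legendre
    quadrature; the table is strictly increasing, so it can be inverted by
    interpolation.
    """
    nodes, wts = np.polynomial.legendre.leggauss(256)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * wts
    grid = np.linspace(0.0, 0.995, 400)
    means = np.empty_like(grid)
    for i, c in enumerate(grid):
        pdf = (nu - 1) * (1 - c) ** nu * (1 - x) ** (nu - 2) * hyp2f1(nu, nu, 1, c * x)
        norm = np.sum(w * pdf)
        means[i] = np.sum(w * x * pdf) / norm
    return grid, means


def debias_partial_coherence(estimate, K: int, p: int):
    """Invert the estimator's finite-sample mean function.

    Maps a raw estimate c_hat to the population value whose expected
    estimate equals c_hat; estimates below the null mean 1/nu map to 0.
    Used when comparing partial-coherence *levels or changes* on the
    population scale (e.g. event-locked regression); not used for p-values.
    """
    nu = pcoh_dof(K, p)
    grid, means = _mean_function_table(nu)
    c = np.clip(np.asarray(estimate, dtype=float), 0.0, 1.0)
    out = np.interp(c, means, grid)
    return float(out) if np.isscalar(estimate) else out


def fdr_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over a pooled family of p-values.

    The family is everything passed in (conventionally all pairs x all
    epochs of an experiment); returns a boolean significance flag per entry.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


# ---------------------------------------------------------------------------
# band power


@dataclass
class BandPowerSpectrum:
    """Per-channel normalized power over a frequency range.

    Power is the diagonal of unregularized multitaper spectral matrices
    averaged over epochs, normalized so the average over the range is 1.
    """

    channel_names: tuple[str, ...]
    frequencies: np.ndarray
    power: np.ndarray  # (p, F)


def band_power(
    record: SignalRecord,
    f_range: tuple[float, float] = (0.5, 20.0),
    epoch_length: float | None = None,
) -> BandPowerSpectrum:
    """Normalized spectral power per channel over `f_range`.

    Epochs default to the delta-band epoch length (the longest bin, giving
    the finest frequency grid); power at each frequency is normalized
    against the total average power over the same range.
    """
    if epoch_length is None:
        epoch_length = epoch_length_for_band(DELTA)
    slices = epoch_slices(record, epoch_length)
    if not slices:
        raise ValueError("record shorter than one epoch")
    n = slices[0][1] - slices[0][0]
    epochs = np.stack([record.samples[:, a:b] for a, b in slices])
    tapers = sine_tapers(n, taper_count_rule(record.n_channels))
    X = _tapered_rfft(epochs, tapers)  # (E, K, p, F)
    psd = (np.abs(X) ** 2).mean(axis=(0, 1)) / record.sample_rate  # (p, F)
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / record.sample_rate)
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    power = psd[:, sel]
    power = power / power.mean(axis=1, keepdims=True)
    return BandPowerSpectrum(record.channel_names, freqs[sel], power)

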