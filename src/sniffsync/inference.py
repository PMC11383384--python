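"""Event-locked inference on evolving partial coherence, baseline
connectivity graphs, and the EMG-respiration confound check.

The evolving pipeline composes: band-pass filter -> epoching at the band's
five-cycle length -> multitaper spectral matrix per epoch -> shrinkage
regularization -> partial coherence -> null p-values -> FDR over the pooled
pairs x epochs family.  Event-locked changes are then estimated by
regressing the per-epoch estimates on lag indicators at -3..+3 epochs
around each event (exploration-bout starts, or odor introduction during
sleep), with baseline defined as all epochs more than three epochs away
from every event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bands import BandDefinition, epoch_length_for_band, taper_count_rule
from .session import EventTrack, SignalRecord
from .spectral import (
    band_bin_indices,
    bandpass,
    debias_partial_coherence,
    epoch_slices,
    epoch_spectral_matrices,
    fdr_adjust,
    partial_coherence_matrix,
    pcoh_dof,
    pcoh_pvalue,
    shrink_matrices,
)

#: pairs reported by the analysis: the [EEG1, EEG2, Resp] triangle,
#: conditioned on the remaining channel(s) including EMG
REPORTED_PAIRS = (("EEG1", "EEG2"), ("EEG1", "Resp"), ("EEG2", "Resp"))


def evolving_pcoh_series(
    record: SignalRecord,
    band: BandDefinition,
    pairs=REPORTED_PAIRS,
    weight: float = 0.0,
    q: float = 0.05,
    band_mode: str = "center",
    prefilter: bool = False,
) -> pd.DataFrame:
    """Per-epoch partial coherence for the reported channel pairs.

    Returns a tidy frame with one row per (epoch, pair): raw ``estimate``,
    bias-corrected ``estimate_debiased``, ``p_value`` (H0: partial
    coherence 0), and ``fdr_significant`` (Benjamini-Hochberg at `q` over
    all rows).  Epochs never overlap masked samples.

    By default the spectral matrices are estimated on the unfiltered
    record: with the five-cycle epoch rule the K sine tapers at the band
    midpoint are already band-local, and band-pass prefiltering would
    empty the outer tapers (all channels lose power exactly where those
    tapers look), shrinking the effective degrees of freedom and inflating
    every pairwise estimate.  `prefilter=True` restores an explicit
    zero-phase band-pass stage for diagnostic use.
    """
    epoch_len = epoch_length_for_band(band)
    filtered = bandpass(record, band.f_lo, band.f_hi) if prefilter else record
    slices = epoch_slices(filtered, epoch_len)
    if not slices:
        raise ValueError("no valid epochs: record too short or fully masked")
    epochs = np.stack([filtered.samples[:, a:b] for a, b in slices])
    E, p, N = epochs.shape
    K = taper_count_rule(p)
    bins = band_bin_indices(N, record.sample_rate, band, band_mode)
    _, S = epoch_spectral_matrices(epochs, record.sample_rate, bins, K=K)
    S = shrink_matrices(S, weight)
    pc = partial_coherence_matrix(S).mean(axis=1)  # (E, p, p)

    names = record.channel_names
    rows = []
    for a, b in slices:
        rows.append(a / record.sample_rate)
    frames = []
    for pair in pairs:
        i, j = names.index(pair[0]), names.index(pair[1])
        est = pc[:, i, j]
        frames.append(
            pd.DataFrame(
                {
                    "epoch_start": rows,
                    "epoch_index": np.arange(E),
                    "band": band.name,
                    "pair": "-".join(pair),
                    "estimate": est,
                    "estimate_debiased": debias_partial_coherence(est, K, p),
                    "p_value": pcoh_pvalue(est, K, p),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["fdr_significant"] = fdr_adjust(df["p_value"].to_numpy(), q=q)
    df.attrs.update(
        {"K": K, "p": p, "epoch_length": epoch_len, "weight": weight, "q": q}
    )
    return df


@dataclass
class LagRegressionResult:
    band: str
    pair: str
    lag: int
    coefficient: float
    standard_error: float
    p_value: float


def lagged_event_regression(
    series: pd.DataFrame,
    events: EventTrack,
    n_lags: int = 3,
    scale: str = "population",
) -> pd.DataFrame:
    """Change from baseline in partial coherence around events.

    The epoch containing each event start is lag 0; epochs at -3..+3 get
    lag-indicator variables, and the pooled regression coefficient of each
    indicator estimates the change from baseline (all epochs outside every
    +-`n_lags` window).  Events without full lag context are dropped with a
    count recorded in ``df.attrs["n_dropped_events"]``.  The same design
    applies to exploration bouts and to sleep odor-introduction events.

    With ``scale="population"`` (default) the regression runs on the raw
    estimates and the fitted cell means are then mapped through the inverse
    of the estimator's finite-sample mean function: because the raw cell
    mean converges to that mean function exactly, the transformed
    coefficients estimate the change in *population* partial coherence
    without the estimator's upward small-sample bias.  Standard errors are
    delta-method rescaled; p-values are from the raw-scale regression,
    where the equal-bias null is exact.  ``scale="raw"`` reports the
    raw-scale coefficients.
    """
    if scale not in ("population", "raw"):
        raise ValueError("scale must be 'population' or 'raw'")
    epoch_len = series.attrs.get("epoch_length")
    K, p = series.attrs.get("K"), series.attrs.get("p")
    results = []
    n_dropped = 0
    for pair, sub in series.groupby("pair", sort=False):
        sub = sub.sort_values("epoch_index")
        starts = sub["epoch_start"].to_numpy()
        if epoch_len is None:
            epoch_len = float(np.median(np.diff(starts)))
        E = len(sub)
        lag_of_epoch = np.full(E, np.nan)
        dropped = 0
        for ev in events:
            # tiny tolerance so an event at an exact epoch boundary lands in
            # the epoch it opens rather than the one before
            e0 = int(np.searchsorted(starts, ev.start + 1e-9, side="right") - 1)
            if e0 - n_lags < 0 or e0 + n_lags >= E:
                dropped += 1
                continue
            for lag in range(-n_lags, n_lags + 1):
                if np.isnan(lag_of_epoch[e0 + lag]):
                    lag_of_epoch[e0 + lag] = lag
        n_dropped = dropped
        baseline = np.isnan(lag_of_epoch)
        if not baseline.any():
            raise ValueError("no baseline epochs outside the event windows")

        lags = np.arange(-n_lags, n_lags + 1)
        X = np.column_stack(
            [np.ones(E)] + [(lag_of_epoch == l).astype(float) for l in lags]
        )
        y = sub["estimate"].to_numpy()
        fit = sm.OLS(y, X).fit()
        band = sub["band"].iloc[0]
        b0 = float(fit.params[0])
        for k, lag in enumerate(lags, start=1):
            coef, se = float(fit.params[k]), float(fit.bse[k])
            if scale == "population":
                lo = debias_partial_coherence(b0, K, p)
                hi = debias_partial_coherence(b0 + coef, K, p)
                slope = _debias_slope(b0 + coef, K, p)
                coef, se = hi - lo, se * slope
            results.append(
                LagRegressionResult(
                    band, pair, int(lag), coef, se, float(fit.pvalues[k])
                )
            )
    df = pd.DataFrame([r.__dict__ for r in results])
    df.attrs["n_dropped_events"] = n_dropped
    return df


def _debias_slope(raw: float, K: int, p: int, eps: float = 1e-4) -> float:
    """Numerical derivative of the debiasing map at a raw estimate."""
    lo = debias_partial_coherence(max(raw - eps, 0.0), K, p)
    hi = debias_partial_coherence(min(raw + eps, 1.0), K, p)
    return (hi - lo) / (2 * eps)


# ---------------------------------------------------------------------------
# connectivity graphs


def edge_class(
    estimate: float, p_value: float, threshold: float = 0.15, alpha: float = 0.05
):
    """Edge-drawing rule: edge iff estimate > threshold; solid iff p < alpha.

    Returns ``None`` (no edge), ``"solid"`` (significant) or ``"dashed"``.
    """
    if not estimate > threshold:
        return None
    return "solid" if p_value < alpha else "dashed"


def build_connectivity_graph(
    still_series: pd.DataFrame,
    threshold: float = 0.15,
    alpha: float = 0.05,
) -> nx.Graph:
    """Baseline connectivity graph from still-epoch partial coherences.

    The pooled estimate per pair is the mean raw estimate over still epochs
    mapped through the inverse of the estimator's finite-sample mean
    function (population scale); the pooled p-value tests the mean raw
    estimate against its exact null distribution (mean of Beta(1, nu-1)
    variates, normal approximation).  Edges follow :func:`edge_class`; the
    edge weight is the pooled estimate.
    """
    if len(still_series) == 0:
        raise ValueError("no still epochs available")
    K, p = still_series.attrs["K"], still_series.attrs["p"]
    nu = pcoh_dof(K, p)
    mu0 = 1.0 / nu
    var0 = (nu - 1.0) / (nu**2 * (nu + 1.0))

    G = nx.Graph()
    for pair, sub in still_series.groupby("pair", sort=False):
        a, b = pair.split("-")
        G.add_nodes_from((a, b))
        raw_mean = float(sub["estimate"].mean())
        pooled = float(debias_partial_coherence(raw_mean, K, p))
        n = len(sub)
        z = (raw_mean - mu0) / np.sqrt(var0 / n)
        p_pooled = float(stats.norm.sf(z))
        cls = edge_class(pooled, p_pooled, threshold, alpha)
        if cls is not None:
            G.add_edge(a, b, weight=pooled, p_value=p_pooled,
                       significant=cls == "solid", style=cls)
    return G


def graph_to_dot(G: nx.Graph) -> str:
    """Minimal DOT export (solid/dashed styling, width by weight)."""
    lines = ["graph connectivity {"]
    for node in G.nodes:
        lines.append(f'  "{node}";')
    for a, b, data in G.edges(data=True):
        lines.append(
            f'  "{a}" -- "{b}" [style={data["style"]}, '
            f'penwidth={1 + 6 * data["weight"]:.2f}, label="{data["weight"]:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines)


def restrict_to_still(
    series: pd.DataFrame, still: list[tuple[float, float]]
) -> pd.DataFrame:
    """Keep epochs fully contained in a still interval."""
    epoch_len = series.attrs["epoch_length"]
    starts = series["epoch_start"].to_numpy()
    keep = np.zeros(len(series), dtype=bool)
    for a, b in still:
        keep |= (starts >= a) & (starts + epoch_len <= b)
    out = series[keep].copy()
    out.attrs.update(series.attrs)
    return out


# ---------------------------------------------------------------------------
# EMG-respiration mixed model


@dataclass
class MixedModelResult:
    """Random-intercept regression of sniff rate on EMG RMS."""

    coefficient: float
    correlation: float
    p_value: float
    subset: str
    n_bins: int
    n_animals: int


def emg_resp_mixed_model(
    sniff_rate: np.ndarray,
    emg_rms: np.ndarray,
    animal_ids: np.ndarray,
    subset: str = "all",
) -> MixedModelResult:
    """Sniff_rate ~ EMG_RMS + (1 | Animal_ID).

    The derived correlation is the fixed-effect coefficient rescaled by
    SD(EMG) / SD(sniff rate), with its p-value from the regression.  The
    SDs are within-animal (group-demeaned): the model adjusts for
    individual animal variation, so its coefficient is on the
    within-animal scale, and rescaling by pooled SDs would re-import the
    between-animal spread it removed.  With a single animal the model
    degrades to ordinary least squares (with a warning), whose slope it
    then matches exactly.
    """
    sniff = np.asarray(sniff_rate, dtype=float)
    emg = np.asarray(emg_rms, dtype=float)
    animals = np.asarray(animal_ids)
    ok = np.isfinite(sniff) & np.isfinite(emg)
    sniff, emg, animals = sniff[ok], emg[ok], animals[ok]
    if emg.std() == 0:
        raise ValueError("EMG predictor is constant")
    X = sm.add_constant(emg)
    uniq = np.unique(animals)
    if uniq.size < 2:
        warnings.warn(
            "single animal: falling back to ordinary least squares",
            RuntimeWarning,
            stacklevel=2,
        )
        fit = sm.OLS(sniff, X).fit()
        coef, pval = float(fit.params[1]), float(fit.pvalues[1])
    else:
        model = sm.MixedLM(sniff, X, groups=animals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        coef, pval = float(np.asarray(fit.fe_params)[1]), float(
            np.asarray(fit.pvalues)[1]
        )
    # within-animal SDs: demean each animal before rescaling
    _, inv = np.unique(animals, return_inverse=True)
    counts = np.bincount(inv)
    emg_w = emg - (np.bincount(inv, weights=emg) / counts)[inv]
    sniff_w = sniff - (np.bincount(inv, weights=sniff) / counts)[inv]
    corr = coef * emg_w.std() / sniff_w.std()
    return MixedModelResult(
        coefficient=coef,
        correlation=float(np.clip(corr, -1.0, 1.0)),
        p_value=pval,
        subset=subset,
        n_bins=int(sniff.size),
        n_animals=int(uniq.size),
    )


def emg_resp_mixed_model_by_movement(
    sniff_rate: np.ndarray,
    emg_rms: np.ndarray,
    animal_ids: np.ndarray,
    moving: np.ndarray,
) -> dict[str, MixedModelResult]:
    """The confound check run three ways: all bins, still only, moving only."""
    moving = np.asarray(moving, dtype=bool)
    out = {"all": emg_resp_mixed_model(sniff_rate, emg_rms, animal_ids, "all")}
    for name, mask in (("still", ~moving), ("moving", moving)):
        out[name] = emg_resp_mixed_model(
            np.asarray(sniff_rate)[mask],
            np.asarray(emg_rms)[mask],
            np.asarray(animal_ids)[mask],
            name,
        )
    return out
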