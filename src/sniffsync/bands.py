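"""EEG frequency-band definitions and the five-cycle epoching rule.

Two distinct band tables exist on purpose: the coherence analysis uses
delta 0.5-4, theta 4-8, alpha 8-12, beta 12-30 Hz, while vigilance-state
scoring uses delta 1-4 and theta 4-10 Hz.  They are kept as separate,
separately named constants so neither silently stands in for the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band for the locally-stationary coherence analysis.

    The epoch used to treat the multichannel series as locally stationary is
    sized so that one epoch holds approximately five full cycles of the band's
    midpoint frequency.
    """

    name: str
    f_lo: float
    f_hi: float
    #: optional override of the five-cycle rule (seconds)
    epoch_override: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")

    @property
    def center(self) -> float:
        """Arithmetic midpoint of the band edges in Hz."""
        return 0.5 * (self.f_lo + self.f_hi)


N_CYCLES_PER_EPOCH = 5


def epoch_length_for_band(band: BandDefinition) -> float:
    """Epoch length in seconds holding ~5 cycles of the band midpoint.

    The rule is ``5 / center`` rounded to two decimals; a band may carry an
    explicit override (the beta band conventionally uses 0.25 s, slightly
    longer than the 0.24 s the rounding rule would give).
    """
    if band.epoch_override is not None:
        return band.epoch_override
    return round(N_CYCLES_PER_EPOCH / band.center, 2)


#: Coherence-analysis bands.
DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 12.0, 30.0, epoch_override=0.25)

COHERENCE_BANDS: dict[str, BandDefinition] = {
    b.name: b for b in (DELTA, THETA, ALPHA, BETA)
}

#: Vigilance-state scoring bands (distinct from the coherence bands above).
SCORING_DELTA = (1.0, 4.0)
SCORING_THETA = (4.0, 10.0)


def taper_count_rule(p: int) -> int:
    """Number of sine tapers for a p-channel record: K = ceil(1.5 * p).

    For the canonical four-channel montage this gives K = 6.
    """
    if p < 1:
        raise ValueError("need at least one channel")
    return -(-3 * p // 2)  # ceil(1.5 p) with integer arithmetic


def n_channel_pairs(p: int) -> int:
    """Number of unordered channel pairs, p*(p-1)/2 (6 for p = 4)."""
    return p * (p - 1) // 2
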