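import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FS = 400.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def wake_session():
    """Ten-minute stationary wake session with one theta-coupled EEG."""
    import sniffsync as ss

    cfg = ss.SessionConfig(
        duration_s=600.0,
        seed=3,
        bout_plan=[],
        couplings=[ss.CouplingTarget("theta", ("EEG1", "Resp"), 0.4)],
        state_params={"wake": ss.StateParams(6.0, 0.8, 1.0, 0.2)},
    )
    return ss.generate_session(cfg)


@pytest.fixture(scope="session")
def sleep_session():
    """Planted wake/NREM/REM schedule for scoring and intersniff tests."""
    import sniffsync as ss

    states = [
        ("wake", 0.0, 120.0),
        ("NREM", 120.0, 300.0),
        ("REM", 300.0, 360.0),
        ("NREM", 360.0, 480.0),
        ("wake", 480.0, 600.0),
    ]
    cfg = ss.SessionConfig(duration_s=600.0, seed=5, states=states, bout_plan=[])
    return ss.generate_session(cfg)


def write_minimal_edf(path, channels: dict[str, np.ndarray], fs: float) -> None:
    """Write a small EDF file from scratch (synthetic test fixture).

    One-second data records, int16 samples, physical = digital range.
    """
    names = list(channels)
    ns = len(names)
    n = len(next(iter(channels.values())))
    spr = int(fs)
    n_rec = n // spr

    def pad(text, width):
        return str(text)[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8), pad("X X X X", 80), pad("X X X X", 80),
            pad("01.01.20", 8), pad("00.00.00", 8),
            pad(256 * (1 + ns), 8), pad("", 44),
            pad(n_rec, 8), pad("1", 8), pad(ns, 4),
        ]
    )
    header += b"".join(pad(nm, 16) for nm in names)
    header += b"".join(pad("", 80) for _ in names)      # transducer
    header += b"".join(pad("", 8) for _ in names)       # physical dimension
    header += b"".join(pad("-32768", 8) for _ in names)
    header += b"".join(pad("32767", 8) for _ in names)
    header += b"".join(pad("-32768", 8) for _ in names)
    header += b"".join(pad("32767", 8) for _ in names)
    header += b"".join(pad("", 80) for _ in names)      # prefiltering
    header += b"".join(pad(spr, 8) for _ in names)
    header += b"".join(pad("", 32) for _ in names)

    scaled = {
        nm: np.clip(np.round(x * 1000.0), -32768, 32767).astype("<i2")
        for nm, x in channels.items()
    }
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for nm in names:
                f.write(scaled[nm][r * spr : (r + 1) * spr].tobytes())
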