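import numpy as np
import pytest

from wearqc import IntervalSet, ScenarioConfig
from wearqc.synthetic import generate_recording

START = 1_600_000_000.0


@pytest.fixture(scope="session")
def bout_scenario():
    """30-min recording with a 10-min non-wear bout in the middle."""
    cfg = ScenarioConfig(
        duration_s=1800.0,
        wear_bouts=IntervalSet("wear", [[0.0, 600.0], [1200.0, 1800.0]]),
        seed=42,
    )
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def allwear_scenario():
    """10-min recording worn throughout."""
    cfg = ScenarioConfig(duration_s=600.0, seed=7)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


def brute_force_rolling_sd(x: np.ndarray, w: int, ddof: int = 1) -> np.ndarray:
    """Independent reference for the centered shrinking-window rolling SD."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        lo = max(i - (w - 1) // 2, 0)
        hi = min(i + w // 2 + 1, n)
        win = x[lo:hi]
        out[i] = np.std(win, ddof=ddof) if len(win) > ddof else 0.0
    return out


def brute_force_rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        lo = max(i - (w - 1) // 2, 0)
        hi = min(i + w // 2 + 1, n)
        out[i] = np.mean(x[lo:hi])
    return out
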