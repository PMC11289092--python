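"""Seeded generator of E4-like recordings with ground-truth wear structure.

The generator emulates the signal behaviour that wrist-worn devices show
around removal: skin temperature relaxes exponentially toward ambient, skin
conductance collapses to a near-zero off-body level, and the accelerometer
flattens to static sensor noise.  During wear, temperature sits near skin
temperature, EDA carries a tonic baseline plus skin-conductance-response
(SCR) bumps, and the accelerometer alternates quiet periods with motion
bursts.  Every draw flows from a single seed, so identical configurations
produce bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._rolling import rolling_mean
from .events import EventEntry, EventLog
from .timebase import E4_RATES, IntervalSet, Recording, UniformSeries, ValidationError

__all__ = [
    "ScenarioConfig",
    "generate_recording",
    "generate_event_log",
    "scenario_from_dict",
    "EventLog",
    "EventEntry",
]

#: Linear cross-fade length at wear/non-wear boundaries (s) — detectors see
#: realistic ramps, not steps.
CROSSFADE_S = 10.0
#: SCR bump shape: difference of exponentials with these time constants (s).
SCR_RISE_S = 1.0
SCR_DECAY_S = 4.0


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic wear/non-wear scenario.

    ``wear_bouts`` holds the ground-truth on-body intervals in seconds
    relative to the scenario start; everything outside them is non-wear.
    """

    duration_s: float = 3600.0
    wear_bouts: IntervalSet | None = None
    start_time: float = 1_600_000_000.0
    ambient_temp_c: float = 24.0
    skin_temp_c: float = 34.0
    temp_decay_tau_s: float = 120.0
    eda_on_body_us: float = 1.0
    eda_off_body_us: float = 0.01
    scr_rate_per_min: float = 2.0
    activity_burst_fraction: float = 0.3
    acc_noise_sd_g: float = 0.004
    temp_noise_sd_c: float = 0.05
    eda_noise_sd_us: float = 0.003
    burst_sd_g: float = 0.3
    seed: int = 0
    include_bvp: bool = True

    def __post_init__(self) -> None:
        if self.wear_bouts is None:
            self.wear_bouts = IntervalSet("wear", [[0.0, self.duration_s]])
        if self.duration_s < 1.0 / max(E4_RATES.values()):
            raise ValidationError("duration shorter than one sample period")
        if self.temp_decay_tau_s <= 0:
            raise ValidationError("temp_decay_tau_s must be positive")
        if not 0.0 <= self.activity_burst_fraction <= 1.0:
            raise ValidationError("activity_burst_fraction must be in [0, 1]")
        for name in ("eda_on_body_us", "eda_off_body_us", "scr_rate_per_min",
                     "acc_noise_sd_g"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        iv = self.wear_bouts.intervals
        if len(iv) and (iv[0, 0] < 0 or iv[-1, 1] > self.duration_s):
            raise ValidationError("wear_bouts must lie within [0, duration_s)")


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a config from a plain dict (e.g. a loaded YAML document)."""
    d = dict(d)
    bouts = d.pop("wear_bouts", None)
    if bouts is not None:
        d["wear_bouts"] = IntervalSet("wear", np.asarray(bouts, dtype=float))
    return ScenarioConfig(**d)


def _wear_fraction(cfg: ScenarioConfig, rate: float, n: int) -> np.ndarray:
    """Wear indicator at the channel rate, cross-faded at bout boundaries."""
    t = np.arange(n) / rate
    ind = cfg.wear_bouts.contains(t).astype(float)
    w = max(int(round(CROSSFADE_S * rate)), 1)
    return rolling_mean(ind, w)


def _first_order_track(target: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exponential relaxation toward a (piecewise) target, one pole, exact
    per-step integration: ``y[i] = t[i] + (y[i-1] - t[i]) * exp(-dt/tau)``."""
    a = float(np.exp(-dt / tau))
    y = sps.lfilter([1.0 - a], [1.0, -a], target, zi=np.array([target[0] * a]))[0]
    return y


def _scr_train(rng: np.random.Generator, cfg: ScenarioConfig,
               rate: float, n: int) -> np.ndarray:
    """Poisson train of asymmetric SCR bumps over the wear bouts."""
    out = np.zeros(n)
    wear_s = cfg.wear_bouts.total_duration
    lam = cfg.scr_rate_per_min * wear_s / 60.0
    n_events = rng.poisson(lam) if lam > 0 else 0
    if n_events == 0:
        return out
    # event times uniform over the union of wear bouts
    u = rng.uniform(0.0, wear_s, size=n_events)
    amps = rng.uniform(0.1, 1.0, size=n_events)
    starts = np.concatenate([[0.0], np.cumsum(
        cfg.wear_bouts.intervals[:, 1] - cfg.wear_bouts.intervals[:, 0])])
    kern_t = np.arange(0, int(round(6 * SCR_DECAY_S * rate))) / rate
    kern = np.exp(-kern_t / SCR_DECAY_S) - np.exp(-kern_t / SCR_RISE_S)
    kern /= kern.max()
    for ui, amp in zip(u, amps):
        k = np.searchsorted(starts, ui, side="right") - 1
        k = min(k, len(cfg.wear_bouts) - 1)
        t_event = cfg.wear_bouts.intervals[k, 0] + (ui - starts[k])
        i0 = int(round(t_event * rate))
        seg = min(len(kern), n - i0)
        if seg > 0:
            out[i0:i0 + seg] += amp * kern[:seg]
    return out


def _band_limited_noise(rng: np.random.Generator, rate: float, n: int,
                        sd: float, shape: tuple = ()) -> np.ndarray:
    """Gaussian noise band-passed to human-movement frequencies (~0.5–8 Hz)."""
    white = rng.standard_normal((n,) + shape)
    if n < 30:
        return sd * white
    sos = sps.butter(2, [0.5, min(8.0, 0.45 * rate)], btype="band",
                     fs=rate, output="sos")
    band = sps.sosfiltfilt(sos, white, axis=0)
    band_sd = band.std(axis=0, keepdims=True)
    band_sd[band_sd == 0] = 1.0
    return sd * band / band_sd


def generate_recording(cfg: ScenarioConfig) -> tuple[Recording, IntervalSet]:
    """Generate an E4-like recording plus its ground-truth wear intervals.

    Returns
    -------
    (Recording, IntervalSet)
        The recording carries ACC (32 Hz, g), EDA (4 Hz, μS), TEMP (4 Hz,
        °C) and optionally BVP (64 Hz, a.u.); the interval set holds the
        wear bouts in epoch seconds.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- TEMP: first-order tracking of a wear-dependent target -------------
    rate = E4_RATES["TEMP"]
    n = int(round(cfg.duration_s * rate))
    f = _wear_fraction(cfg, rate, n)
    target = cfg.ambient_temp_c + (cfg.skin_temp_c - cfg.ambient_temp_c) * f
    temp = _first_order_track(target, 1.0 / rate, cfg.temp_decay_tau_s)
    temp = temp + rng.normal(0.0, cfg.temp_noise_sd_c, size=n)
    temp_series = UniformSeries("TEMP", cfg.start_time, rate, temp, "°C")

    # --- EDA: tonic baseline + SCR bumps, collapsing off body ---------------
    rate = E4_RATES["EDA"]
    n = int(round(cfg.duration_s * rate))
    f = _wear_fraction(cfg, rate, n)
    on_body = cfg.eda_on_body_us + _scr_train(rng, cfg, rate, n)
    eda = cfg.eda_off_body_us + (on_body - cfg.eda_off_body_us) * f
    eda = eda + rng.normal(0.0, cfg.eda_noise_sd_us, size=n)
    eda = np.clip(eda, 1e-4, None)
    eda_series = UniformSeries("EDA", cfg.start_time, rate, eda, "μS")

    # --- ACC: gravity + sensor noise + motion bursts during wear ------------
    rate = E4_RATES["ACC"]
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) / rate
    acc = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    acc += rng.normal(0.0, cfg.acc_noise_sd_g, size=(n, 3))
    wear_mask = cfg.wear_bouts.contains(t)
    block = int(round(10 * rate))  # 10-s activity blocks
    n_blocks = -(-n // block)
    burst_blocks = rng.random(n_blocks) < cfg.activity_burst_fraction
    burst_mask = np.repeat(burst_blocks, block)[:n] & wear_mask
    if burst_mask.any():
        motion = _band_limited_noise(rng, rate, n, cfg.burst_sd_g, (3,))
        acc[burst_mask] += motion[burst_mask]
    acc_series = UniformSeries("ACC", cfg.start_time, rate, acc, "g")

    channels = {"ACC": acc_series, "EDA": eda_series, "TEMP": temp_series}

    if cfg.include_bvp:
        rate = E4_RATES["BVP"]
        n = int(round(cfg.duration_s * rate))
        t = np.arange(n) / rate
        f = _wear_fraction(cfg, rate, n)
        bvp = 50.0 * np.sin(2 * np.pi * 1.1 * t) * f
        bvp += rng.normal(0.0, 2.0, size=n)
        channels["BVP"] = UniformSeries("BVP", cfg.start_time, rate, bvp, "a.u.")

    rec = Recording(participant_id="synthetic", session_id=f"seed{cfg.seed}",
                    channels=channels)
    truth = cfg.wear_bouts.shift(cfg.start_time)
    return rec, truth


def generate_event_log(
    n_days: int,
    prompts_per_day: int,
    answer_prob: float,
    seed: int,
    start_time: float = 1_600_000_000.0,
) -> EventLog:
    """Prompted questionnaires over ``n_days`` with Bernoulli answering.

    Exactly ``n_days * prompts_per_day`` prompted entries are produced, at
    random daytime moments (08:00–22:00 of each day relative to
    ``start_time``); each prompt is independently answered with probability
    ``answer_prob`` within at most ten minutes.
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    if not 0.0 <= answer_prob <= 1.0:
        raise ValidationError("answer_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    entries = []
    for day in range(n_days):
        day_start = start_time + day * 86400.0
        times = np.sort(rng.uniform(8 * 3600.0, 22 * 3600.0, size=prompts_per_day))
        answered = rng.random(prompts_per_day) < answer_prob
        delays = rng.uniform(30.0, 600.0, size=prompts_per_day)
        for j, (tt, ans, dl) in enumerate(zip(times, answered, delays)):
            t = day_start + tt
            tag = f"prompt-d{day}-{j}"
            entries.append(EventEntry(t, t, "questionnaire_prompted", payload=tag))
            if ans:
                entries.append(
                    EventEntry(t + dl, t, "questionnaire_answered", payload=tag)
                )
    entries.sort(key=lambda e: e.entry_time)
    return EventLog(entries)
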