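"""Seeded generators for labeled regime-change series and a distortion battery.

Everything here is deterministic per seed and emits ground-truth boundary
labels alongside the data, so the rest of the package is testable without
any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import sawtooth

from .mp_core import TimeSeries
from .regimes import RegimeBoundaries

__all__ = [
    "RegimeSpec",
    "DistortionSpec",
    "PATTERN_KINDS",
    "DISTORTION_KINDS",
    "make_regime_series",
    "make_transition_gap",
    "distort",
]

PATTERN_KINDS = ("sine", "square", "sawtooth", "pulse", "noise_walk")

DISTORTION_KINDS = (
    "downsample_2x",
    "bitdepth_8",
    "linear_trend_10deg",
    "white_noise_20db",
    "smooth",
    "delete3pct_interp",
)


@dataclass(frozen=True)
class RegimeSpec:
    """One quasi-periodic regime: pattern shape, period, amplitude, duration, SNR."""

    pattern_kind: str
    period: int
    duration: int
    amplitude: float = 1.0
    noise_db: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_kind not in PATTERN_KINDS:
            raise ValueError(
                f"unknown pattern_kind {self.pattern_kind!r}; choose from {PATTERN_KINDS}"
            )
        if self.period < 2:
            raise ValueError("period must be at least 2 samples")
        if self.duration < 4 * self.period:
            raise ValueError(
                "duration must be at least 4 periods: segmentation assumes each "
                "regime contains multiple pattern repetitions"
            )
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class DistortionSpec:
    kind: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DISTORTION_KINDS:
            raise ValueError(
                f"unknown distortion {self.kind!r}; choose from {DISTORTION_KINDS}"
            )


def _pattern(kind: str, period: int, duration: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(duration, dtype=np.float64)
    phase = 2.0 * np.pi * t / period
    if kind == "sine":
        return np.sin(phase)
    if kind == "square":
        return np.tanh(4.0 * np.sin(phase))  # square-ish but band-limited
    if kind == "sawtooth":
        return sawtooth(phase)
    if kind == "pulse":
        frac = (t % period) / period
        return np.exp(-0.5 * ((frac - 0.25) / 0.08) ** 2) * 2.0 - 1.0
    if kind == "noise_walk":
        walk = np.cumsum(rng.standard_normal(duration))
        walk -= walk.mean()
        peak = np.abs(walk).max()
        return walk / peak if peak > 0 else walk
    raise ValueError(kind)


def _add_noise_snr(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(snr_db):
        return x
    signal_power = float(np.var(x))
    if signal_power == 0.0:
        return x
    noise_power = signal_power / (10.0 ** (snr_db / 10.0))
    return x + rng.standard_normal(x.size) * np.sqrt(noise_power)


def make_regime_series(
    specs: Sequence[RegimeSpec], sampling_rate_hz: Optional[float] = None
) -> tuple[TimeSeries, RegimeBoundaries]:
    """Concatenate regimes and return the series with its true boundaries.

    Boundaries sit at the cumulative regime durations.  Adjacent regimes
    must differ in pattern kind or period, otherwise there is no regime
    change to find.
    """
    if len(specs) < 2:
        raise ValueError("need at least two regimes")
    for a, b in zip(specs, specs[1:]):
        if a.pattern_kind == b.pattern_kind and a.period == b.period:
            raise ValueError("adjacent regimes must differ in pattern_kind or period")
    chunks = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        clean = spec.amplitude * _pattern(spec.pattern_kind, spec.period, spec.duration, rng)
        chunks.append(_add_noise_snr(clean, spec.noise_db, rng))
    boundaries = np.cumsum([s.duration for s in specs])[:-1]
    series = TimeSeries(np.concatenate(chunks), sampling_rate_hz=sampling_rate_hz)
    truth = RegimeBoundaries(positions=boundaries, num_requested=len(specs) - 1)
    return series, truth


def make_transition_gap(
    series: "TimeSeries | np.ndarray", at: int, gap_len: int, seed: int = 0
) -> TimeSeries:
    """Insert an unstructured low-amplitude stretch at ``at``.

    Emulates transition periods (resting between activities): a small random
    walk with amplitude well below the surrounding signal.  ``gap_len = 0``
    returns the input unchanged (as a TimeSeries).
    """
    x = np.asarray(series, dtype=np.float64)
    rate = series.sampling_rate_hz if isinstance(series, TimeSeries) else None
    if not (0 <= at <= x.size):
        raise ValueError("gap position outside the series")
    if gap_len < 0:
        raise ValueError("gap_len must be non-negative")
    if gap_len == 0:
        return TimeSeries(x.copy(), sampling_rate_hz=rate)
    rng = np.random.default_rng(seed)
    scale = 0.05 * (float(np.std(x)) or 1.0)
    gap = np.cumsum(rng.standard_normal(gap_len)) * scale / np.sqrt(gap_len)
    gap += rng.standard_normal(gap_len) * scale
    return TimeSeries(np.concatenate((x[:at], gap, x[at:])), sampling_rate_hz=rate)


def distort(series: "TimeSeries | np.ndarray", spec: DistortionSpec) -> TimeSeries:
    """Apply one named distortion from the robustness battery.

    Kinds: halve the sampling rate; quantize to 8-bit; add a linear trend of
    ten visual degrees; add white noise at 20 dB SNR; smooth with a
    5-sample moving average; delete a random 3% of samples and refill by
    linear interpolation (length preserved).
    """
    x = np.asarray(series, dtype=np.float64)
    rate = series.sampling_rate_hz if isinstance(series, TimeSeries) else None
    n = x.size
    kind = spec.kind
    rng = np.random.default_rng(spec.seed)

    if kind == "downsample_2x":
        out_rate = rate / 2.0 if rate else None
        return TimeSeries(x[::2].copy(), sampling_rate_hz=out_rate)
    if kind == "bitdepth_8":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return TimeSeries(x.copy(), sampling_rate_hz=rate)
        levels = np.round((x - lo) / (hi - lo) * 255.0)
        return TimeSeries(lo + levels * (hi - lo) / 255.0, sampling_rate_hz=rate)
    if kind == "linear_trend_10deg":
        # ten degrees on a unit-aspect plot: rise = tan(10 deg) * value range
        rise = np.tan(np.deg2rad(10.0)) * (x.max() - x.min())
        return TimeSeries(x + np.linspace(0.0, rise, n), sampling_rate_hz=rate)
    if kind == "white_noise_20db":
        noise_power = float(np.var(x)) / 100.0  # SNR = 20 dB
        return TimeSeries(
            x + rng.standard_normal(n) * np.sqrt(noise_power), sampling_rate_hz=rate
        )
    if kind == "smooth":
        return TimeSeries(uniform_filter1d(x, size=5, mode="nearest"), sampling_rate_hz=rate)
    if kind == "delete3pct_interp":
        k = max(1, int(round(0.03 * n)))
        drop = rng.choice(n, size=k, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        if keep.size < 2:
            raise ValueError("series too short for deletion distortion")
        filled = np.interp(np.arange(n), keep, x[keep])
        return TimeSeries(filled, sampling_rate_hz=rate)
    raise ValueError(f"unknown distortion {kind!r}")
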