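"""Arc curves and their null-model normalization.

The nearest-neighbor index defines one "arc" per subsequence, from its own
position to its neighbor's.  The Arc Curve (AC) counts, for every position
``x``, the arcs whose span covers ``x`` under the half-open convention
``min(i, j) <= x < max(i, j)``.  Dividing by the expected count under a
structureless null — the Idealized Arc Curve (IAC) — and clamping to [0, 1]
yields the Corrected Arc Curve (CAC), whose deep minima mark candidate
regime boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mp_core import MatrixProfile, SubseqParams, TimeSeries, compute_matrix_profile

__all__ = [
    "ArcCurve",
    "IdealizedArcCurve",
    "CorrectedArcCurve",
    "compute_arc_curve",
    "idealized_arc_curve",
    "compute_cac",
    "fuse_cacs",
    "fluss",
]

#: positions whose expected crossing count falls below this are treated as
#: uninformative edges and the CAC is set to 1 there.
IAC_FLOOR = 1.0

#: width, in subsequence lengths, of the hard-coded CAC=1 guard at each end
#: of the curve.  Arcs only start at subsequence positions, so the raw count
#: decays to zero over the last L positions regardless of structure; without
#: a guard that ramp always beats any true boundary minimum.
EDGE_GUARD_FACTOR = 5

_IAC_MODELS = ("parabola", "one_directional", "constrained_uniform")

# Monte-Carlo null curves are deterministic per (n, model, trials, seed, tc);
# cache them so streaming / grid searches pay the simulation once.
_iac_cache: dict = {}


@dataclass(frozen=True)
class ArcCurve:
    """Integer arc-crossing counts, one per series position."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class IdealizedArcCurve:
    """Expected crossing counts under a structureless null model."""

    expected: np.ndarray
    model: str
    trials: int = 0
    seed: int = 0
    tc_samples: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "expected", np.asarray(self.expected, dtype=np.float64))

    @property
    def n(self) -> int:
        return int(self.expected.size)

    @property
    def edge_region(self) -> Optional[tuple[int, int]]:
        """(left, right) hard-coded edge widths for the constrained model."""
        if self.model == "constrained_uniform" and self.tc_samples is not None:
            return (self.tc_samples, self.tc_samples)
        return None


@dataclass(frozen=True)
class CorrectedArcCurve:
    """AC / IAC clamped to [0, 1]; low values flag candidate boundaries."""

    values: np.ndarray
    direction: str = "both"
    tc_samples: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


def compute_arc_curve(mp_index: Sequence[int], n: int) -> ArcCurve:
    """Count arc crossings via the increment/decrement sweep.

    Each valid arc ``(i, j)`` increments position ``min(i, j)`` and
    decrements ``max(i, j)``; the cumulative sum then counts arcs with
    ``min <= x < max``.  Sentinel entries (negative) are skipped.
    """
    idx = np.asarray(mp_index, dtype=np.int64)
    if idx.ndim != 1:
        raise ValueError("mp_index must be 1-D")
    if n < idx.size:
        raise ValueError("n must be at least the index length")
    bad = np.flatnonzero(idx >= n)
    if bad.size:
        raise ValueError(
            f"mp_index[{bad[0]}] = {idx[bad[0]]} is out of range for n = {n}"
        )
    i = np.arange(idx.size)
    valid = idx >= 0
    lo = np.minimum(i[valid], idx[valid])
    hi = np.maximum(i[valid], idx[valid])
    mark = np.zeros(n + 1, dtype=np.int64)
    np.add.at(mark, lo, 1)
    np.add.at(mark, hi, -1)
    counts = np.cumsum(mark[:n])
    return ArcCurve(counts=counts)


def _null_arc_curve_bidirectional(n: int, rng: np.random.Generator) -> np.ndarray:
    """One draw of uniformly random arcs: each i points to j != i."""
    j = rng.integers(0, n - 1, size=n)
    j[j >= np.arange(n)] += 1  # uniform over [0, n) \ {i}
    return compute_arc_curve(j, n).counts


def _null_arc_curve_left(n: int, rng: np.random.Generator) -> np.ndarray:
    """One draw of uniformly random one-directional arcs: i points to j < i."""
    idx = np.full(n, -1, dtype=np.int64)
    i = np.arange(1, n)
    idx[1:] = (rng.random(n - 1) * i).astype(np.int64)
    return compute_arc_curve(idx, n).counts


def _null_arc_curve_constrained(n: int, tc: int, rng: np.random.Generator) -> np.ndarray:
    """Random arcs of length <= tc (both directions, excluding self)."""
    i = np.arange(n)
    lo = np.maximum(0, i - tc)
    hi = np.minimum(n - 1, i + tc)
    width = hi - lo  # choices excluding self
    j = lo + (rng.random(n) * width).astype(np.int64)
    j[j >= i] += 1
    return compute_arc_curve(np.minimum(j, n - 1), n).counts


def idealized_arc_curve(
    n: int,
    model: str = "parabola",
    trials: int = 200,
    seed: int = 0,
    tc_samples: Optional[int] = None,
) -> IdealizedArcCurve:
    """Expected arc-crossing curve under a structureless null.

    ``parabola``
        Closed form ``2 i (n - i) / n`` for uniformly random bidirectional
        arcs (peak n/2 at the center; after area normalization this is the
        beta(2, 2) density on [0, n]).
    ``one_directional``
        Empirical Monte-Carlo mean over ``trials`` seeded draws of uniformly
        random backward-pointing arcs (right-skewed, lower peak).
    ``constrained_uniform``
        Constant interior level estimated empirically under random arcs of
        length at most ``tc_samples``; the first/last ``tc_samples``
        positions are flagged as hard-coded edges.
    """
    if model not in _IAC_MODELS:
        raise ValueError(f"unknown IAC model {model!r}; choose from {_IAC_MODELS}")
    if n < 4:
        raise ValueError("n must be at least 4")
    if model == "parabola":
        i = np.arange(n, dtype=np.float64)
        return IdealizedArcCurve(expected=2.0 * i * (n - i) / n, model=model)

    key = (n, model, trials, seed, tc_samples)
    cached = _iac_cache.get(key)
    if cached is not None:
        return cached

    rng = np.random.default_rng(seed)
    acc = np.zeros(n, dtype=np.float64)
    if model == "one_directional":
        for _ in range(trials):
            acc += _null_arc_curve_left(n, rng)
        expected = acc / trials
        out = IdealizedArcCurve(expected=expected, model=model, trials=trials, seed=seed)
    else:  # constrained_uniform
        if tc_samples is None:
            raise ValueError("constrained_uniform requires tc_samples")
        tc = int(tc_samples)
        for _ in range(trials):
            acc += _null_arc_curve_constrained(n, tc, rng)
        emp = acc / trials
        interior = emp[tc : n - tc] if n > 2 * tc else emp
        level = float(interior.mean()) if interior.size else float(emp.mean())
        out = IdealizedArcCurve(
            expected=np.full(n, level),
            model=model,
            trials=trials,
            seed=seed,
            tc_samples=tc,
        )
    _iac_cache[key] = out
    return out


def default_edge_guard(n: int, L: int) -> int:
    """Edge-guard width: 5 subsequence lengths, capped at a quarter of the curve."""
    return max(L, min(EDGE_GUARD_FACTOR * L, n // 4))


def compute_cac(
    ac: ArcCurve,
    iac: IdealizedArcCurve,
    direction: str = "both",
    edge_guard: int = 0,
) -> CorrectedArcCurve:
    """Elementwise ``min(AC / IAC, 1)``.

    Positions where the expected count falls below ``IAC_FLOOR`` are set to
    1 (uninformative edges), as are the hard-coded edge regions of the
    temporally constrained null and, when ``edge_guard`` > 0, the first and
    last ``edge_guard`` positions (where no arc can exist because arcs only
    start at subsequence positions).
    """
    if ac.n != iac.n:
        raise ValueError(f"length mismatch: AC has {ac.n}, IAC has {iac.n}")
    n = ac.n
    expected = iac.expected
    informative = expected >= IAC_FLOOR
    vals = np.ones(n, dtype=np.float64)
    vals[informative] = np.minimum(ac.counts[informative] / expected[informative], 1.0)
    np.clip(vals, 0.0, 1.0, out=vals)
    edges = iac.edge_region
    if edges is not None:
        left, right = edges
        vals[: min(left, n)] = 1.0
        if right > 0:
            vals[max(0, n - right) :] = 1.0
    if edge_guard > 0:
        g = min(edge_guard, n)
        vals[:g] = 1.0
        vals[n - g :] = 1.0
    return CorrectedArcCurve(values=vals, direction=direction, tc_samples=iac.tc_samples)


def fuse_cacs(cacs: Sequence[CorrectedArcCurve]) -> CorrectedArcCurve:
    """Pointwise mean of index-aligned corrected curves (multi-channel fusion)."""
    if len(cacs) < 1:
        raise ValueError("need at least one curve to fuse")
    n = cacs[0].n
    for k, c in enumerate(cacs):
        if c.n != n:
            raise ValueError(
                f"curve {k} has length {c.n}, expected {n}; "
                "resample channels to a common index grid before fusing"
            )
    stacked = np.vstack([c.values for c in cacs])
    return CorrectedArcCurve(
        values=stacked.mean(axis=0),
        direction=cacs[0].direction,
        tc_samples=cacs[0].tc_samples,
    )


def cac_from_profile(
    mp: MatrixProfile,
    n: int,
    iac: Optional[IdealizedArcCurve] = None,
    trials: int = 200,
    seed: int = 0,
) -> CorrectedArcCurve:
    """AC -> CAC for one matrix profile, choosing the matching null model."""
    ac = compute_arc_curve(mp.index, n)
    if iac is None:
        if mp.params.tc_samples is not None:
            iac = idealized_arc_curve(
                n, "constrained_uniform", trials=trials, seed=seed,
                tc_samples=mp.params.tc_samples,
            )
        elif mp.direction == "left":
            iac = idealized_arc_curve(n, "one_directional", trials=trials, seed=seed)
        else:
            iac = idealized_arc_curve(n, "parabola")
    direction = "left-only" if mp.direction == "left" else "both"
    guard = default_edge_guard(n, mp.params.L)
    return compute_cac(ac, iac, direction=direction, edge_guard=guard)


def fluss(
    series: "TimeSeries | np.ndarray | Sequence",
    params: SubseqParams,
    trials: int = 200,
    seed: int = 0,
) -> CorrectedArcCurve:
    """Batch segmentation curve: matrix profile -> AC -> CAC, fused over channels.

    ``series`` may be a single channel or a list of equal-length channels;
    each channel's CAC is computed independently and the curves are averaged.
    Deterministic given the input and parameters.
    """
    channels = _as_channels(series)
    n = len(channels[0])
    cacs = []
    for ch in channels:
        if len(ch) != n:
            raise ValueError("all channels must have equal length")
        mp = compute_matrix_profile(ch, params, direction="both")
        cacs.append(cac_from_profile(mp, n, trials=trials, seed=seed))
    return fuse_cacs(cacs)


def _as_channels(series) -> list[np.ndarray]:
    if isinstance(series, TimeSeries):
        return [series.values]
    if isinstance(series, np.ndarray):
        if series.ndim == 1:
            return [series]
        if series.ndim == 2:
            return [series[:, k] for k in range(series.shape[1])]
        raise ValueError("series array must be 1-D or 2-D")
    if isinstance(series, (list, tuple)):
        if len(series) == 0:
            raise ValueError("empty series")
        if np.ndim(series[0]) == 0:  # list of scalars: one channel
            return [np.asarray(series, dtype=np.float64)]
        return [np.asarray(ch, dtype=np.float64) for ch in series]
    return [np.asarray(series, dtype=np.float64)]
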