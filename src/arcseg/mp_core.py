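"""z-normalized nearest-neighbor structure for time series.

Provides MASS-style distance profiles, the batch Matrix Profile (bidirectional
or left-only) and the sliding-window streaming state used for online
segmentation.

Conventions (shared across the package):

* indexing is 0-based; subsequence ``i`` covers samples ``[i, i + L)``;
* the trivial-match exclusion zone is ``|i - j| <= exclusion_halfwidth``
  (default ``L // 2``);
* a left-only entry with no admissible neighbor stores index ``-1`` and
  distance ``+inf``.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

__all__ = [
    "TimeSeries",
    "SubseqParams",
    "MatrixProfile",
    "StreamState",
    "distance_profile",
    "compute_matrix_profile",
    "stream_ingress",
    "stream_egress",
    "seconds_to_samples",
]

#: below this series length the naive sliding-dot-product path is used
#: (FFT round-off on tiny inputs hurts test determinism).
FFT_MIN_N = 256

#: above this profile length the Gram-matrix batch path would need too much
#: memory; fall back to a per-query MASS loop.
_GRAM_MAX_M = 4096

#: relative zero-variance threshold: sigma <= _FLAT_TOL * (1 + |mu|).
_FLAT_TOL = 1e-12

_SENTINEL = -1


def seconds_to_samples(seconds: float, sampling_rate_hz: float) -> int:
    """Convert a wall-clock duration to a sample count: floor(seconds * rate)."""
    if seconds <= 0:
        raise ValueError("seconds must be positive")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    return int(np.floor(seconds * sampling_rate_hz))


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled, single-channel, real-valued series.

    Multi-channel data is represented as a list of equal-length TimeSeries.
    NaN / infinite values are rejected at construction.
    """

    values: np.ndarray
    sampling_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("TimeSeries requires a 1-D sequence of samples")
        if arr.size < 1:
            raise ValueError("TimeSeries must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            bad = np.flatnonzero(~np.isfinite(arr))
            raise ValueError(
                f"non-finite samples at positions {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )
        if self.sampling_rate_hz is not None and self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)


@dataclass(frozen=True)
class SubseqParams:
    """Subsequence length plus exclusion-zone / temporal-constraint settings."""

    L: int
    exclusion_halfwidth: Optional[int] = None
    tc_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if int(self.L) != self.L or self.L < 3:
            raise ValueError("subsequence length L must be an integer >= 3")
        object.__setattr__(self, "L", int(self.L))
        excl = self.exclusion_halfwidth
        if excl is None:
            excl = self.L // 2
        excl = int(excl)
        if excl < 1:
            raise ValueError("exclusion_halfwidth must be >= 1")
        object.__setattr__(self, "exclusion_halfwidth", excl)
        if self.tc_samples is not None:
            tc = int(self.tc_samples)
            if tc <= self.L:
                raise ValueError("tc_samples must exceed the subsequence length L")
            object.__setattr__(self, "tc_samples", tc)


@dataclass
class MatrixProfile:
    """Nearest-neighbor distances and indices for every subsequence.

    ``direction`` is ``"both"`` (full search) or ``"left"`` (neighbors
    restricted to earlier positions).  Sentinel entries (left-only, no
    admissible neighbor) carry index -1 and distance +inf.
    """

    values: np.ndarray
    index: np.ndarray
    direction: str
    params: SubseqParams

    @property
    def m(self) -> int:
        return int(self.values.size)


def _rolling_mean_sigma(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csq = np.concatenate(([0.0], np.cumsum(x * x)))
    mu = (csum[L:] - csum[:-L]) / L
    var = (csq[L:] - csq[:-L]) / L - mu * mu
    sigma = np.sqrt(np.maximum(var, 0.0))
    return mu, sigma


def _flat_mask(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return sigma <= _FLAT_TOL * (1.0 + np.abs(mu))


def distance_profile(
    query: np.ndarray, series: "TimeSeries | np.ndarray", params: Optional[SubseqParams] = None
) -> np.ndarray:
    """z-normalized Euclidean distance from ``query`` to every subsequence.

    Entry ``j`` is the distance between the query and ``series[j:j+L]`` with
    both windows z-normalized.  Flat (zero-variance) windows are treated as
    the all-zeros normalized vector, so the output never contains NaN.
    Uses FFT cross-correlation for long series, a direct sliding dot product
    otherwise; results are clipped below at 0.
    """
    q = np.asarray(query, dtype=np.float64)
    x = np.asarray(series, dtype=np.float64)
    if q.ndim != 1 or x.ndim != 1:
        raise ValueError("query and series must be 1-D")
    if not np.all(np.isfinite(q)):
        raise ValueError("query contains non-finite values")
    L = q.size
    n = x.size
    if params is not None and params.L != L:
        raise ValueError(f"query length {L} != params.L {params.L}")
    if L < 1 or L > n:
        raise ValueError("query length must satisfy 1 <= L <= len(series)")

    mu_q = q.mean()
    sigma_q = q.std()
    q_flat = bool(sigma_q <= _FLAT_TOL * (1.0 + abs(mu_q)))
    if q_flat:
        warnings.warn("zero-variance query window; treated as all-zeros", RuntimeWarning)

    mu_t, sigma_t = _rolling_mean_sigma(x, L)
    t_flat = _flat_mask(mu_t, sigma_t)

    if n >= FFT_MIN_N:
        qt = fftconvolve(x, q[::-1], mode="valid")
    else:
        qt = sliding_window_view(x, L) @ q

    d2 = np.full(n - L + 1, float(L))  # one side flat, the other not
    if q_flat:
        d2[t_flat] = 0.0
    else:
        ok = ~t_flat
        if np.any(ok):
            denom = L * sigma_q * sigma_t[ok]
            corr = (qt[ok] - L * mu_q * mu_t[ok]) / denom
            d2[ok] = 2.0 * L * (1.0 - corr)
    return np.sqrt(np.clip(d2, 0.0, None))


def _znorm_subsequences(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Matrix of z-normalized subsequences (flat rows zeroed) + squared norms."""
    W = sliding_window_view(x, L)
    mu, sigma = _rolling_mean_sigma(x, L)
    flat = _flat_mask(mu, sigma)
    safe = np.where(flat, 1.0, sigma)
    Z = (W - mu[:, None]) / safe[:, None]
    Z[flat] = 0.0
    sq = np.where(flat, 0.0, float(L))
    return Z, sq


def _admissible_mask_row(
    i: int, m: int, excl: int, tc: Optional[int], direction: str
) -> np.ndarray:
    j = np.arange(m)
    ok = np.abs(j - i) > excl
    if tc is not None:
        ok &= np.abs(j - i) <= tc
    if direction == "left":
        ok &= j < i
    return ok


def compute_matrix_profile(
    series: "TimeSeries | np.ndarray",
    params: SubseqParams,
    direction: str = "both",
) -> MatrixProfile:
    """Exact all-pairs one-nearest-neighbor search over all subsequences.

    ``direction="both"`` searches the whole series (outside the exclusion
    zone and, if set, within ``tc_samples``); ``direction="left"`` restricts
    neighbors to strictly earlier subsequences.  Ties break to the smallest
    admissible index.
    """
    if direction not in ("both", "left"):
        raise ValueError("direction must be 'both' or 'left'")
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    L = params.L
    if n < 2 * L:
        raise ValueError(f"series too short for L: need n >= {2 * L}, got {n}")
    m = n - L + 1
    excl = params.exclusion_halfwidth
    tc = params.tc_samples

    if m <= _GRAM_MAX_M:
        values, index = _mp_gram(x, L, excl, tc, direction)
    else:
        values, index = _mp_mass_loop(x, L, excl, tc, direction)
    return MatrixProfile(values=values, index=index, direction=direction, params=params)


def _mp_gram(x, L, excl, tc, direction):
    Z, sq = _znorm_subsequences(x, L)
    m = Z.shape[0]
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.clip(D2, 0.0, None, out=D2)
    D = np.sqrt(D2)

    offs = np.abs(np.arange(m)[None, :] - np.arange(m)[:, None])
    bad = offs <= excl
    if tc is not None:
        bad |= offs > tc
    if direction == "left":
        bad |= np.arange(m)[None, :] >= np.arange(m)[:, None]
    D[bad] = np.inf

    index = np.argmin(D, axis=1)
    values = D[np.arange(m), index]
    no_nbr = ~np.isfinite(values)
    index = index.astype(np.int64)
    index[no_nbr] = _SENTINEL
    return values, index


def _mp_mass_loop(x, L, excl, tc, direction):
    m = x.size - L + 1
    values = np.full(m, np.inf)
    index = np.full(m, _SENTINEL, dtype=np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(m):
            dp = distance_profile(x[i : i + L], x)
            ok = _admissible_mask_row(i, m, excl, tc, direction)
            if not ok.any():
                continue
            dp = np.where(ok, dp, np.inf)
            j = int(np.argmin(dp))
            values[i] = dp[j]
            index[i] = j
    return values, index


@dataclass
class StreamState:
    """Sliding-window state maintaining the left-only (one-directional)
    nearest-neighbor profile online.

    Arcs always point strictly backward in time, so ingress never modifies
    existing entries.  Egress drops the head profile entry in O(1); the rare
    arcs that pointed *to* the evicted subsequence are repaired on the spot
    via a reverse index (no routine rescan of the whole profile).
    """

    w: int
    params: SubseqParams
    count_ingested: int = 0
    _buf: np.ndarray = field(init=False, repr=False)
    _size: int = field(default=0, repr=False)
    _left_global: deque = field(default_factory=deque, repr=False)
    _left_dist: deque = field(default_factory=deque, repr=False)
    _rev: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.w < 2 * self.params.L:
            raise ValueError("window capacity w must be at least 2 * L")
        self._buf = np.empty(self.w, dtype=np.float64)

    # -- views -------------------------------------------------------------

    @property
    def size(self) -> int:
        return self._size

    @property
    def is_full(self) -> bool:
        return self._size == self.w

    @property
    def oldest_global(self) -> int:
        """Global stream position of the first sample currently in the window."""
        return self.count_ingested - self._size

    @property
    def window(self) -> np.ndarray:
        """Contiguous copy of the current window contents (oldest first)."""
        start = self.count_ingested % self.w - self._size
        if start >= 0:
            return self._buf[start : start + self._size].copy()
        return np.concatenate((self._buf[start:], self._buf[: start + self._size]))

    @property
    def left_index(self) -> np.ndarray:
        """Window-relative left nearest-neighbor index (sentinel -1)."""
        origin = self.oldest_global
        out = np.fromiter(
            (g - origin if g != _SENTINEL else _SENTINEL for g in self._left_global),
            dtype=np.int64,
            count=len(self._left_global),
        )
        return out

    @property
    def left_values(self) -> np.ndarray:
        return np.fromiter(self._left_dist, dtype=np.float64, count=len(self._left_dist))

    # -- internals ---------------------------------------------------------

    def _store(self, value: float) -> None:
        self._buf[self.count_ingested % self.w] = value
        self.count_ingested += 1
        self._size += 1

    def _find_left_neighbor(self, win: np.ndarray, rel: int) -> tuple[int, float]:
        """Left NN of the subsequence starting at window-relative ``rel``."""
        L = self.params.L
        excl = self.params.exclusion_halfwidth
        tc = self.params.tc_samples
        hi = rel - excl  # admissible j < hi
        lo = 0 if tc is None else max(0, rel - tc)
        if hi <= lo:
            return _SENTINEL, np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dp = distance_profile(win[rel : rel + L], win)
        seg = dp[lo:hi]
        j = int(np.argmin(seg)) + lo
        return j, float(dp[j])

    def _link(self, i_global: int, j_global: int) -> None:
        if j_global != _SENTINEL:
            self._rev.setdefault(j_global, set()).add(i_global)

    def _unlink(self, i_global: int, j_global: int) -> None:
        if j_global != _SENTINEL:
            peers = self._rev.get(j_global)
            if peers is not None:
                peers.discard(i_global)
                if not peers:
                    del self._rev[j_global]


def stream_ingress(state: StreamState, value: float) -> StreamState:
    """Ingest one sample; evicts the oldest first when the window is full.

    The newest subsequence's left neighbor is found with one distance-profile
    call over the current window; no existing entry is modified.
    """
    if not np.isfinite(value):
        raise ValueError("ingested value must be finite")
    if state.is_full:
        stream_egress(state)
    state._store(float(value))
    L = state.params.L
    if state._size >= L:
        win = state.window
        rel = state._size - L
        j_rel, dist = state._find_left_neighbor(win, rel)
        origin = state.oldest_global
        s_global = origin + rel
        j_global = _SENTINEL if j_rel == _SENTINEL else origin + j_rel
        state._left_global.append(j_global)
        state._left_dist.append(dist)
        state._link(s_global, j_global)
    return state


def stream_egress(state: StreamState) -> StreamState:
    """Evict the oldest sample from a full window.

    Drops the head profile entry in O(1) and repairs only those surviving
    arcs that pointed at the evicted subsequence.
    """
    if not state.is_full:
        raise ValueError("egress requires a full window")
    evicted = state.oldest_global  # global position of the departing sample
    # the subsequence starting at the evicted sample leaves the profile
    if state._left_global:
        j_head = state._left_global.popleft()
        state._left_dist.popleft()
        state._unlink(evicted, j_head)
    state._size -= 1  # head sample gone; buffer slot will be overwritten

    dangling = state._rev.pop(evicted, None)
    if dangling:
        win = state.window
        origin = state.oldest_global
        first_sub = origin  # profile entries now start at this global position
        for i_global in sorted(dangling):
            rel = i_global - origin
            j_rel, dist = state._find_left_neighbor(win, rel)
            j_global = _SENTINEL if j_rel == _SENTINEL else origin + j_rel
            k = i_global - first_sub
            state._left_global[k] = j_global
            state._left_dist[k] = dist
            state._link(i_global, j_global)
    return state
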