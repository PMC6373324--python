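"""Online segmentation driver: maintain the one-directional corrected arc
curve over a sliding window and emit boundary events / alerts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .mp_core import StreamState, SubseqParams, stream_ingress
from .regimes import REA_EXCLUSION_FACTOR, AlertThreshold
from .segmentation import (
    CorrectedArcCurve,
    compute_arc_curve,
    compute_cac,
    default_edge_guard,
    idealized_arc_curve,
)

__all__ = ["FlossConfig", "FlossEvent", "run_floss", "window_cac_from_state"]


@dataclass(frozen=True)
class FlossConfig:
    """Streaming run settings: window size, subsequence length, cadence."""

    window_w: int
    L: int
    report_every: int = 1
    threshold: Optional[AlertThreshold] = None
    tc_samples: Optional[int] = None
    iac_trials: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_w < 4 * self.L:
            raise ValueError("window_w must be at least 4 * L")
        if self.report_every < 1:
            raise ValueError("report_every must be >= 1")

    @property
    def params(self) -> SubseqParams:
        return SubseqParams(L=self.L, tc_samples=self.tc_samples)


@dataclass(frozen=True)
class FlossEvent:
    """One checkpoint report: where the window curve bottoms out."""

    global_position: int
    cac_min: float
    is_alert: bool = False
    window_cac: Optional[CorrectedArcCurve] = None


def window_cac_from_state(
    state: StreamState, iac, edge_guard: int
) -> CorrectedArcCurve:
    """One-directional corrected curve for the window currently in ``state``."""
    ac = compute_arc_curve(state.left_index, state.size)
    return compute_cac(ac, iac, direction="left-only", edge_guard=edge_guard)


def run_floss(
    source: Iterable[float], config: FlossConfig, keep_window_cac: bool = False
) -> Iterator[FlossEvent]:
    """Stream samples through the sliding window and yield checkpoint events.

    Each sample is ingested (with automatic egress once the window is full);
    every ``report_every`` steps after the window first fills, the arc curve
    of the left-only index is normalized by the empirical one-directional
    null (computed once, seeded) and the minimizing position is reported in
    global stream coordinates.  When a threshold is configured, events below
    it are flagged as alerts, with successive alerts within 5L of each other
    merged into one.
    """
    params = config.params
    state = StreamState(w=config.window_w, params=params)
    iac = idealized_arc_curve(
        config.window_w,
        "one_directional",
        trials=config.iac_trials,
        seed=config.seed,
    )
    if config.tc_samples is not None:
        iac = idealized_arc_curve(
            config.window_w,
            "constrained_uniform",
            trials=config.iac_trials,
            seed=config.seed,
            tc_samples=config.tc_samples,
        )
    debounce = REA_EXCLUSION_FACTOR * config.L
    last_alert: Optional[int] = None
    full_steps = 0

    for value in source:
        stream_ingress(state, value)
        if not state.is_full:
            continue
        full_steps += 1
        if (full_steps - 1) % config.report_every != 0:
            continue
        cac = window_cac_from_state(state, iac, edge_guard=default_edge_guard(state.size, config.L))
        rel = int(np.argmin(cac.values))
        cac_min = float(cac.values[rel])
        global_pos = rel + state.oldest_global
        is_alert = False
        if config.threshold is not None and cac_min < config.threshold.value:
            if last_alert is None or abs(global_pos - last_alert) > debounce:
                is_alert = True
                last_alert = global_pos
        yield FlossEvent(
            global_position=global_pos,
            cac_min=cac_min,
            is_alert=is_alert,
            window_cac=cac if keep_window_cac else None,
        )
    if full_steps == 0:
        warnings.warn(
            "stream ended before the window filled; no events emitted", RuntimeWarning
        )
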