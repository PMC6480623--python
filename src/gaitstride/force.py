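"""Gold-standard gait event detection from vertical ground reaction force.

Initial contact is the first sample at or above 10 N after a below-threshold
interval; toe off is the last sample at or above 25 N within the same
stance.  Stances shorter than 0.1 s are treated as noise and dropped whole,
and consecutive initial contacts must respect the cadence floor (0.25 s for
a plate that sees both feet; 0.5 s in single-foot mode).  Event times are
sample times: no sub-sample interpolation, so force and accelerometer
events share one discrete time base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    EventTable,
    ForceTrial,
    GaitEvent,
    MIN_CONTRALATERAL_INTERVAL,
    MIN_IPSILATERAL_INTERVAL,
    MIN_STANCE,
)

__all__ = ["ForceThresholds", "detect_force_events", "force_candidates"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForceThresholds:
    """vGRF thresholds: 10 N for initial contact, 25 N for toe off."""

    ic_threshold: float = 10.0
    to_threshold: float = 25.0

    def __post_init__(self) -> None:
        if self.ic_threshold <= 0 or self.to_threshold <= 0:
            raise ValueError("force thresholds must be positive")


DEFAULT_THRESHOLDS = ForceThresholds()
_EPS = 1e-9


def _stance_regions(vgrf: np.ndarray, ic_threshold: float) -> list:
    """Contiguous runs of vgrf >= ic_threshold as (start, stop) index pairs,
    stop exclusive."""
    above = vgrf >= ic_threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[above[edges + 1]] + 1)
    stops = list(edges[~above[edges + 1]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(vgrf))
    return list(zip(starts, stops))


def detect_force_events(
    trial: ForceTrial,
    thresholds: ForceThresholds = DEFAULT_THRESHOLDS,
    min_ic_separation: float | None = None,
    min_stance: float = MIN_STANCE,
    single_foot: bool = False,
    apply_cadence_constraint: bool = True,
    drop_boundary_stances: bool = True,
) -> EventTable:
    """Detect IC/TO events over a whole force trial.

    Parameters
    ----------
    single_foot : bool
        When the plate records one foot only (e.g. one belt of a split-belt
        treadmill assigned per foot), the IC separation floor doubles to the
        ipsilateral 0.5 s.
    drop_boundary_stances : bool
        Discard loaded regions that touch the first or last sample: their
        true IC or TO lies outside the recording.
    """
    if min_ic_separation is None:
        min_ic_separation = (
            MIN_IPSILATERAL_INTERVAL if single_foot else MIN_CONTRALATERAL_INTERVAL
        )
    v = trial.vgrf
    if v.shape[0] == 0:
        raise ValueError("empty force signal")
    regions = _stance_regions(v, thresholds.ic_threshold)
    if regions and len(regions) == 1 and regions[0] == (0, trial.n):
        log.warning("vGRF never drops below the IC threshold; no swing phase found")
        return EventTable(events=[], source="force", fs=trial.fs)

    events = []
    last_ic_t = None
    for start, stop in regions:
        if drop_boundary_stances and (start == 0 or stop == trial.n):
            continue
        seg = v[start:stop]
        loaded = np.flatnonzero(seg >= thresholds.to_threshold)
        if loaded.size == 0:
            continue
        to_idx = start + int(loaded[-1])
        t_ic = trial.t0 + start / trial.fs
        t_to = trial.t0 + to_idx / trial.fs
        if t_to < t_ic + min_stance - _EPS:
            continue  # too short to be a true stance
        if (
            apply_cadence_constraint
            and last_ic_t is not None
            and t_ic - last_ic_t < min_ic_separation - _EPS
        ):
            continue
        events.append(
            GaitEvent(kind="IC", t=t_ic, magnitude=float(v[start]), source="force")
        )
        events.append(
            GaitEvent(kind="TO", t=t_to, magnitude=float(v[to_idx]), source="force")
        )
        last_ic_t = t_ic
    return EventTable(events=events, source="force", fs=trial.fs)


def force_candidates(
    window: ForceTrial, thresholds: ForceThresholds = DEFAULT_THRESHOLDS
):
    """Per-window IC/TO candidates for the sliding-window engine.

    Only stance regions whose rise and fall are both observed inside the
    window are emitted: a region truncated by a window edge would yield a
    bogus crossing time there.  Candidate times are absolute; magnitudes are
    the vGRF values at the crossing samples.  Cadence and minimum-stance
    screening is left to consolidation.
    """
    v = window.vgrf
    ics, tos = [], []
    for start, stop in _stance_regions(v, thresholds.ic_threshold):
        if start == 0 or stop == v.shape[0]:
            continue
        loaded = np.flatnonzero(v[start:stop] >= thresholds.to_threshold)
        if loaded.size == 0:
            continue
        to_idx = start + int(loaded[-1])
        ics.append(
            GaitEvent(
                kind="IC",
                t=window.t0 + start / window.fs,
                magnitude=float(v[start]),
                source="force",
            )
        )
        tos.append(
            GaitEvent(
                kind="TO",
                t=window.t0 + to_idx / window.fs,
                magnitude=float(v[to_idx]),
                source="force",
            )
        )
    return ics, tos
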