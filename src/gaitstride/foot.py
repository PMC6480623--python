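"""Candidate gait event detection from the foot-mounted accelerometer.

The foot sensor is worn on one (the right) shoe and is never rotated, so
the detector works on rotation-invariant features: an initial contact shows
as a prominent impact peak of the acceleration resultant
sqrt(ML^2 + AP^2 + VT^2), and toe off as the most negative VT-axis
acceleration after the stance.  Because the sensor sees only ipsilateral
steps, consecutive foot ICs are assumed 0.5-1.0 s apart (twice the
contralateral bounds).  Detection is deliberately permissive - it emits
*candidates*, including pairs closer than the cadence floor - and leaves
the cadence- and magnitude-based arbitration to the consolidation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._peaks import admission_level, prominent_peaks
from .core import (
    GaitEvent,
    MAX_IPSILATERAL_INTERVAL,
    MIN_IPSILATERAL_INTERVAL,
    MIN_STANCE,
    TriaxialTrial,
)

__all__ = ["FootDetectorConfig", "foot_candidates"]

MIN_WINDOW_S = 1.0


@dataclass(frozen=True)
class FootDetectorConfig:
    """Tunables of the foot candidate detector.

    ``peak_prominence_factor`` scales the adaptive (MAD-based) prominence
    level; ``quiescence_window`` implements the swing-quiescence check: an
    admitted impact peak must be preceded, within this many seconds, by a
    resultant that drops at least the admission level below the peak,
    which rejects mid-stance oscillation peaks riding on a loaded signal.
    ``search_back`` bounds the toe-off search region as a fraction of the
    maximum plausible stance.
    """

    min_ic_separation: float = MIN_IPSILATERAL_INTERVAL
    max_ic_separation: float = MAX_IPSILATERAL_INTERVAL
    min_ic_to_gap: float = MIN_STANCE
    peak_prominence_factor: float = 1.0
    search_back: float = 1.0
    quiescence_window: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.min_ic_separation < self.max_ic_separation:
            raise ValueError("need 0 < min_ic_separation < max_ic_separation")
        if self.min_ic_to_gap <= 0:
            raise ValueError("min_ic_to_gap must be positive")


DEFAULT_FOOT_CONFIG = FootDetectorConfig()


def _quiescent_before(x: np.ndarray, idx: int, span: int, drop: float) -> bool:
    """True when the signal dips at least ``drop`` below the peak within the
    look-back span (truncated at the window start)."""
    lo = max(0, idx - span)
    if lo == idx:
        return False  # no look-back available inside this window
    return bool(np.min(x[lo:idx]) <= x[idx] - drop)


def foot_candidates(
    window: TriaxialTrial, cfg: FootDetectorConfig = DEFAULT_FOOT_CONFIG
):
    """IC/TO candidate events for one window of foot accelerometer data.

    Returns ``(ic_candidates, to_candidates)`` with absolute event times.
    IC candidate magnitude is the resultant value at the peak; TO candidate
    magnitude is the negative-VT value (larger = deeper deceleration).
    Windows shorter than 1 s yield empty lists with a warning.
    """
    if window.site != "foot":
        raise ValueError("foot_candidates expects a foot trial")
    if window.duration < MIN_WINDOW_S - 1e-9:
        warnings.warn("window shorter than 1 s; no candidates emitted")
        return [], []

    fs = window.fs
    k = cfg.peak_prominence_factor
    r = window.resultant
    level = admission_level(r, k)
    span = int(round(cfg.quiescence_window * fs))
    ics = []
    for idx in prominent_peaks(r, k):
        if not _quiescent_before(r, int(idx), span, level):
            continue
        ics.append(
            GaitEvent(
                kind="IC",
                t=window.t0 + idx / fs,
                magnitude=float(r[idx]),
                source="foot",
            )
        )

    neg_vt = -window.vt
    tos = [
        GaitEvent(
            kind="TO",
            t=window.t0 + idx / fs,
            magnitude=float(neg_vt[idx]),
            source="foot",
        )
        for idx in prominent_peaks(neg_vt, k)
    ]
    return ics, tos
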