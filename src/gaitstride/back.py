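"""Candidate gait event detection and step-side assignment from the
low-back accelerometer.

The low back (near the sacrum) feels the impact of every step, so the
sensor is bilateral: consecutive initial contacts are assumed 0.25-0.50 s
apart.  After gravity alignment an initial contact shows as a prominent
impact peak of the VT axis and toe off as a VT minimum; the step side is
read from the sign of the mediolateral acceleration around the initial
contact (by default, ML toward +right means a right step).  The side rule
is a heuristic - real trunk kinematics make it imperfect and sensitive to
the sign convention, which is therefore configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._peaks import prominent_peaks
from .core import (
    GaitEvent,
    MAX_CONTRALATERAL_INTERVAL,
    MIN_CONTRALATERAL_INTERVAL,
    MIN_STANCE,
    TriaxialTrial,
)
from .foot import MIN_WINDOW_S

__all__ = ["BackDetectorConfig", "back_candidates", "assign_step_side"]


@dataclass(frozen=True)
class BackDetectorConfig:
    """Tunables of the back candidate detector and side assignment.

    ``side_window`` is the half-width (s) of the ML averaging interval
    around an IC; ``side_sign_right`` maps the ML sign to the right side
    (+1: positive ML acceleration at contact means a right step).
    """

    min_ic_separation: float = MIN_CONTRALATERAL_INTERVAL
    max_ic_separation: float = MAX_CONTRALATERAL_INTERVAL
    min_ic_to_gap: float = MIN_STANCE
    peak_prominence_factor: float = 1.0
    side_window: float = 0.05
    side_sign_right: int = +1

    def __post_init__(self) -> None:
        if not 0 < self.min_ic_separation < self.max_ic_separation:
            raise ValueError("need 0 < min_ic_separation < max_ic_separation")
        if self.side_sign_right not in (-1, 1):
            raise ValueError("side_sign_right must be +1 or -1")


DEFAULT_BACK_CONFIG = BackDetectorConfig()


def back_candidates(
    window: TriaxialTrial, cfg: BackDetectorConfig = DEFAULT_BACK_CONFIG
):
    """IC/TO candidate events for one window of aligned back data.

    IC candidates are prominent VT impact peaks (magnitude = VT value);
    TO candidates are VT minima (magnitude = negative-VT value).  Sides are
    left ``unknown`` here; :func:`assign_step_side` fills them in once
    consolidation has settled the final ICs.
    """
    if window.site != "back":
        raise ValueError("back_candidates expects a back trial")
    if not window.aligned:
        raise ValueError("back trial must be gravity aligned before detection")
    if window.duration < MIN_WINDOW_S - 1e-9:
        warnings.warn("window shorter than 1 s; no candidates emitted")
        return [], []

    fs = window.fs
    k = cfg.peak_prominence_factor
    vt = window.vt
    ics = [
        GaitEvent(
            kind="IC",
            t=window.t0 + idx / fs,
            magnitude=float(vt[idx]),
            source="back",
        )
        for idx in prominent_peaks(vt, k)
    ]
    neg_vt = -vt
    tos = [
        GaitEvent(
            kind="TO",
            t=window.t0 + idx / fs,
            magnitude=float(neg_vt[idx]),
            source="back",
        )
        for idx in prominent_peaks(neg_vt, k)
    ]
    return ics, tos


def assign_step_side(
    trial: TriaxialTrial, ic: GaitEvent, cfg: BackDetectorConfig = DEFAULT_BACK_CONFIG
) -> str:
    """Side of the step at ``ic`` from the mean ML acceleration around it.

    Returns ``'right'`` when the mean ML over [t - side_window,
    t + side_window] carries the configured right-side sign, ``'left'``
    otherwise (an exactly zero mean is deterministically 'left'), and
    ``'unknown'`` when the interval falls outside the trial.
    """
    if trial.site != "back" or not trial.aligned:
        raise ValueError("side assignment needs an aligned back trial")
    fs = trial.fs
    lo = int(round((ic.t - cfg.side_window - trial.t0) * fs))
    hi = int(round((ic.t + cfg.side_window - trial.t0) * fs))
    if lo < 0 or hi >= trial.n:
        return "unknown"
    mean_ml = float(np.mean(trial.ml[lo : hi + 1]))
    return "right" if cfg.side_sign_right * mean_ml > 0 else "left"
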