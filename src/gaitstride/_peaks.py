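"""Shared adaptive peak admission used by the accelerometer detectors.

No fixed acceleration threshold appears anywhere: peaks are admitted when
their prominence exceeds an adaptive level computed from the window itself,
which makes candidate *times* invariant to any positive rescaling of the
signal.  Admission combines two scale-free rules: the peak's prominence
must exceed ``k`` times a robust (MAD-based) spread of the window - the
median is used rather than the mean because impact peaks inflate the mean
and standard deviation but barely move the median - and its height above
the window median must be a substantial fraction of the window's maximum
excursion.  The height rule suppresses the ringing sidelobes of the
zero-lag Butterworth filter, which can be quite prominent (peak-to-valley)
around a narrow impact transient yet barely rise above the baseline,
whereas genuine impact peaks define the window's excursion.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

#: minimum peak height above the window median, as a fraction of the
#: window's (max - median) excursion; filter ringing stays below ~0.1,
#: genuine impact peaks sit near 1.0
_HEIGHT_FLOOR_REL = 0.2
#: last-resort prominence floor for pathologically clean windows
_PROMINENCE_FLOOR_REL = 1e-6


def robust_spread(x: np.ndarray) -> float:
    """1.4826 * median absolute deviation (consistent with sigma for
    Gaussian data)."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def admission_level(x: np.ndarray, k: float) -> float:
    """Adaptive prominence level for this window (zero for a flat window)."""
    ptp = float(np.ptp(x))
    if ptp == 0.0:
        return 0.0
    return max(k * robust_spread(x), _PROMINENCE_FLOOR_REL * ptp)


def prominent_peaks(x: np.ndarray, k: float) -> np.ndarray:
    """Indices of local maxima passing both adaptive admission rules."""
    level = admission_level(x, k)
    if level == 0.0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(x, prominence=level)
    if peaks.size == 0:
        return peaks
    med = float(np.median(x))
    height_floor = _HEIGHT_FLOOR_REL * (float(np.max(x)) - med)
    return peaks[x[peaks] - med >= height_floor]
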