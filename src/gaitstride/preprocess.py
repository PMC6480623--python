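"""Gravity alignment, zero-lag low-pass filtering and trial trimming.

The processing chain applied before event detection is: align the back
sensor with gravity (the foot sensor is never rotated; its detector works on
the rotation-invariant resultant), low-pass every channel with a 4th-order
zero-lag Butterworth at 10 Hz, and trim the unsteady beginning and end of
each trial (a fixed 15 s per end for constant-speed treadmill trials, 5 %
per end for overground trials at self-selected speed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import ForceTrial, TriaxialTrial

__all__ = ["FilterSpec", "AlignmentError", "align_back_to_gravity", "lowpass", "trim_trial"]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag Butterworth low-pass specification (order 4, 10 Hz)."""

    order: int = 4
    cutoff_hz: float = 10.0
    zero_lag: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie below Nyquist ({fs / 2} Hz)"
            )


DEFAULT_FILTER = FilterSpec()


class AlignmentError(ValueError):
    """Raised when the trial-mean acceleration cannot be gravity."""


def _rotation_to_vt(v: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector ``v`` onto +VT (0, 0, 1)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(v, z), -1.0, 1.0))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        # antipodal: rotate 180 degrees about the ML axis
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    axis = axis / np.linalg.norm(axis)
    angle = np.arccos(c)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def align_back_to_gravity(
    trial: TriaxialTrial, min_gravity: float = 0.5, max_gravity: float = 1.5
) -> TriaxialTrial:
    """Rotate a back trial so its mean acceleration lies on +VT (= +1 g).

    The trial-wide mean acceleration is used as the gravity estimate: over
    whole strides the movement component averages out and the mean is
    dominated by gravity.  The raw back AP axis points posteriorly and is
    sign-flipped into the body convention (+anterior) before the minimal
    rotation (axis-angle, determinant +1) is applied; heading about VT is
    left untouched because detection uses only VT and the ML sign.

    Applying the function to an already-aligned trial skips the sign flip
    and converges to the identity rotation, so it is a no-op.

    Raises
    ------
    AlignmentError
        If the mean acceleration magnitude is outside [0.5, 1.5] g, i.e. the
        sensor was plainly not observing gravity.
    """
    if trial.site != "back":
        raise ValueError("gravity alignment applies to the back sensor only")
    x = np.array(trial.samples, dtype=float)
    if not trial.aligned:
        x[:, 1] = -x[:, 1]  # AP: +posterior (raw) -> +anterior (body)
    mean = x.mean(axis=0)
    gmag = float(np.linalg.norm(mean))
    if not min_gravity <= gmag <= max_gravity:
        raise AlignmentError(
            f"trial-mean acceleration magnitude {gmag:.3f} g outside "
            f"[{min_gravity}, {max_gravity}] g; cannot identify gravity"
        )
    rot = _rotation_to_vt(mean / gmag)
    return replace(trial, samples=x @ rot.T, aligned=True)


def lowpass(obj, fs: float | None = None, spec: FilterSpec = DEFAULT_FILTER):
    """Forward-backward Butterworth low-pass of a series or a whole trial.

    Zero phase by construction: features such as symmetric peaks keep their
    timing.  DC is preserved exactly for constant input.  Accepts a 1-D/2-D
    array (``fs`` required) or a trial object (``fs`` taken from it).
    """
    if isinstance(obj, TriaxialTrial):
        return replace(obj, samples=lowpass(obj.samples, obj.fs, spec))
    if isinstance(obj, ForceTrial):
        v = lowpass(obj.vgrf, obj.fs, spec)
        return replace(obj, vgrf=np.maximum(v, 0.0))
    if fs is None:
        raise ValueError("fs is required when filtering a bare array")
    spec.validate(fs)
    x = np.asarray(obj, dtype=float)
    n = x.shape[0]
    if n <= 3 * (spec.order + 1):
        raise ValueError(
            f"series of {n} samples is too short for an order-{spec.order} "
            "zero-lag filter"
        )
    sos = butter(spec.order, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=0, padtype="even")


def trim_trial(trial, mode: str, amount: float):
    """Remove ``amount`` seconds (mode='seconds') or a fraction of samples
    (mode='fraction') from each end of a trial; t0 is reset to 0.

    Seconds mode matches fixed-speed treadmill handling (e.g. 15 s per end of
    a 90 s trial leaves 60 s); fraction mode matches self-paced overground
    handling (e.g. 5 % per end).
    """
    if amount < 0:
        raise ValueError("trim amount must be non-negative")
    n = trial.n
    if mode == "seconds":
        k = int(round(amount * trial.fs))
    elif mode == "fraction":
        if amount >= 0.5:
            raise ValueError("fractional trim must be < 0.5 per end")
        k = int(round(amount * n))
    else:
        raise ValueError("mode must be 'seconds' or 'fraction'")
    if 2 * k >= n:
        raise ValueError("trimming would consume the whole trial")
    if k == 0:
        return replace(trial, t0=0.0)
    if isinstance(trial, ForceTrial):
        return replace(trial, vgrf=trial.vgrf[k : n - k], t0=0.0)
    return replace(trial, samples=trial.samples[k : n - k], t0=0.0)
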