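"""Containers and text I/O for running-gait sensor trials and gait events.

Conventions used throughout the package: acceleration is expressed in g,
force in newtons, and time in seconds with ``t = t0 + index / fs`` (first
sample at ``t0``, which is 0 for a freshly loaded trial).  Tri-axial samples
are stored column-ordered (ML, AP, VT):

* foot sensor: ML +right, AP +posterior, VT +superior (device frame, never
  rotated);
* back sensor, raw: ML +right, AP +posterior, VT +superior, ``aligned=False``;
* back sensor, aligned: ML +right, AP +anterior, VT +superior,
  ``aligned=True`` (set by :func:`gaitstride.preprocess.align_back_to_gravity`).

Event timing constraints shared by every detector live here as module
constants: contralateral initial contacts (both feet observed, as for the
low-back sensor or a force plate) are assumed 0.25-0.50 s apart, ipsilateral
contacts (a single instrumented foot) twice that, and toe off can occur no
earlier than 0.1 s after the initial contact of the same step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "G0",
    "AXES",
    "MIN_CONTRALATERAL_INTERVAL",
    "MAX_CONTRALATERAL_INTERVAL",
    "MIN_IPSILATERAL_INTERVAL",
    "MAX_IPSILATERAL_INTERVAL",
    "MIN_STANCE",
    "cadence_to_step_interval",
    "step_interval_to_cadence",
    "TriaxialTrial",
    "ForceTrial",
    "GaitEvent",
    "EventTable",
    "read_trial_csv",
    "write_trial_csv",
    "read_events_csv",
    "write_events_csv",
    "resample_trial",
]

G0 = 9.80665  # m/s^2 per g
AXES = ("ml", "ap", "vt")
SITES = ("foot", "back")
SOURCES = ("force", "foot", "back")
EVENT_KINDS = ("IC", "TO")
SIDES = ("left", "right", "unknown")

#: cadence bounds of 120-240 steps/min expressed as step intervals (s)
MIN_CONTRALATERAL_INTERVAL = 0.25
MAX_CONTRALATERAL_INTERVAL = 0.50
MIN_IPSILATERAL_INTERVAL = 0.50
MAX_IPSILATERAL_INTERVAL = 1.00
#: toe off occurs no earlier than this after the same step's initial contact
MIN_STANCE = 0.1

_TIME_TOL = 1e-6


def cadence_to_step_interval(cadence: float) -> float:
    """Contralateral step interval (s) for a cadence in steps/min."""
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    return 60.0 / cadence


def step_interval_to_cadence(interval: float) -> float:
    """Cadence (steps/min) for a contralateral step interval in seconds."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    return 60.0 / interval


def min_ic_separation_for(source: str) -> float:
    """Minimum plausible spacing of consecutive ICs seen by ``source``.

    The foot sensor observes ipsilateral steps only, so its floor is twice
    the contralateral one used for the back sensor and the force plate.
    """
    return (
        MIN_IPSILATERAL_INTERVAL if source == "foot" else MIN_CONTRALATERAL_INTERVAL
    )


# ---------------------------------------------------------------------------
# trial containers


@dataclass
class TriaxialTrial:
    """A tri-axial accelerometer recording from one sensor site.

    Parameters
    ----------
    site : {'foot', 'back'}
    fs : float
        Sampling rate in Hz.
    samples : ndarray, shape (n, 3)
        Acceleration in g, columns ordered (ML, AP, VT).
    aligned : bool
        True once a back trial has been gravity aligned into the body frame.
    t0 : float
        Time of the first sample (s); event times are absolute.
    """

    site: str
    fs: float
    samples: np.ndarray
    aligned: bool = False
    t0: float = 0.0
    trial_id: str = ""
    labels: dict = field(default_factory=dict)
    axis_map: tuple = AXES

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown sensor site {self.site!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if tuple(sorted(self.axis_map)) != tuple(sorted(AXES)):
            raise ValueError("axis_map must be a bijection onto (ml, ap, vt)")
        a = np.asarray(self.samples, dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if a.shape[0] < 2:
            raise ValueError("a trial needs at least two samples")
        if not np.all(np.isfinite(a)):
            raise ValueError("samples contain non-finite values")
        self.samples = a

    # -- geometry -----------------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def ml(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def ap(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def vt(self) -> np.ndarray:
        return self.samples[:, 2]

    @property
    def resultant(self) -> np.ndarray:
        """Euclidean norm of the three axes; rotation invariant."""
        return np.linalg.norm(self.samples, axis=1)

    def segment(self, t_start: float, t_stop: float) -> "TriaxialTrial":
        """View of the trial between two absolute times, t0 carried along."""
        i0 = max(0, int(round((t_start - self.t0) * self.fs)))
        i1 = min(self.n, int(round((t_stop - self.t0) * self.fs)))
        if i1 - i0 < 2:
            i1 = min(self.n, i0 + 2)
        return replace(
            self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs
        )


@dataclass
class ForceTrial:
    """Vertical ground-reaction-force magnitude series (N)."""

    fs: float
    vgrf: np.ndarray
    t0: float = 0.0
    trial_id: str = ""
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        v = np.asarray(self.vgrf, dtype=float)
        if v.ndim != 1 or v.shape[0] < 2:
            raise ValueError("vgrf must be a 1-D array of at least two samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("vgrf contains non-finite values")
        if v.min() < -1e-6:
            raise ValueError("vgrf must be a non-negative magnitude series")
        self.vgrf = np.maximum(v, 0.0)

    @property
    def n(self) -> int:
        return self.vgrf.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def segment(self, t_start: float, t_stop: float) -> "ForceTrial":
        i0 = max(0, int(round((t_start - self.t0) * self.fs)))
        i1 = min(self.n, int(round((t_stop - self.t0) * self.fs)))
        if i1 - i0 < 2:
            i1 = min(self.n, i0 + 2)
        return replace(self, vgrf=self.vgrf[i0:i1], t0=self.t0 + i0 / self.fs)


# ---------------------------------------------------------------------------
# events


@dataclass
class GaitEvent:
    """One detected gait event.

    ``magnitude`` is the signal value the consolidation stage compares:
    resultant acceleration (g) for foot ICs, VT acceleration (g) for back
    ICs, the negative-VT value (g) for TOs from either accelerometer, and
    the vGRF value (N) for force-plate events.  ``provisional`` marks events
    too close to a trial edge to be trusted in method comparisons.
    """

    kind: str
    t: float
    side: str = "unknown"
    magnitude: float = 0.0
    source: str = "force"
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not (math.isfinite(self.t) and self.t >= -_TIME_TOL):
            raise ValueError("event time must be finite and non-negative")
        if not math.isfinite(self.magnitude):
            raise ValueError("event magnitude must be finite")


@dataclass
class EventTable:
    """Time-ordered IC/TO events from one detection method.

    Invariants enforced on construction: globally non-decreasing times,
    strictly increasing times within each kind, every TO paired to exactly
    one preceding IC with ``TO.t >= IC.t + 0.1 s``, and consecutive ICs at
    least 0.5 s apart for the foot source or 0.25 s for back/force.
    Steps may be IC-only (no viable TO was found).
    """

    events: list
    source: str
    fs: float

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.events = list(self.events)
        self.validate()

    def validate(self) -> None:
        min_sep = min_ic_separation_for(self.source)
        last_t = -np.inf
        last = {"IC": None, "TO": None}
        open_ic = None
        for ev in self.events:
            if ev.t < last_t - _TIME_TOL:
                raise ValueError("events must be sorted by time")
            last_t = max(last_t, ev.t)
            prev = last[ev.kind]
            if prev is not None and ev.t <= prev + _TIME_TOL:
                raise ValueError(f"{ev.kind} times must be strictly increasing")
            last[ev.kind] = ev.t
            if ev.kind == "IC":
                if prev is not None and ev.t - prev < min_sep - _TIME_TOL:
                    raise ValueError(
                        f"consecutive {self.source} ICs closer than {min_sep} s"
                    )
                open_ic = ev
            else:
                if open_ic is None:
                    raise ValueError("TO without a preceding unpaired IC")
                if ev.t < open_ic.t + MIN_STANCE - _TIME_TOL:
                    raise ValueError("TO earlier than IC + 0.1 s")
                open_ic = None

    # -- access helpers -----------------------------------------------------
    def ics(self, include_provisional: bool = True) -> list:
        return [
            e
            for e in self.events
            if e.kind == "IC" and (include_provisional or not e.provisional)
        ]

    def tos(self, include_provisional: bool = True) -> list:
        return [
            e
            for e in self.events
            if e.kind == "TO" and (include_provisional or not e.provisional)
        ]

    def steps(self) -> list:
        """(IC, TO-or-None) pairs in time order."""
        out = []
        for ev in self.events:
            if ev.kind == "IC":
                out.append([ev, None])
            else:
                out[-1][1] = ev
        return [tuple(p) for p in out]

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self.events],
                "t": [e.t for e in self.events],
                "side": [e.side for e in self.events],
                "magnitude": [e.magnitude for e in self.events],
                "source": [e.source for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Trial CSV dialect: header ``time,ml,ap,vt`` (acceleration, g) or
# ``time,vgrf`` (N); the time column is optional and ignored on read (the
# sampling rate argument is authoritative).  Event CSV dialect: header
# ``kind,t,side,magnitude,source`` with t printed to 6 decimals.


def _numeric_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, data row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value in column {col!r}, data row {row}")
        out[col] = coerced.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_trial_csv(
    path,
    kind: str,
    fs: float,
    axis_map: dict | None = None,
    units: str = "g",
    trial_id: str = "",
    labels: dict | None = None,
):
    """Read a trial CSV into a :class:`TriaxialTrial` or :class:`ForceTrial`.

    Parameters
    ----------
    kind : {'foot', 'back', 'force'}
    fs : float
        Sampling rate (authoritative; any ``time`` column is ignored).
    axis_map : dict, optional
        Mapping of CSV column name -> axis ('ml'/'ap'/'vt') for accelerometer
        files whose header differs from the default ``ml,ap,vt``.
    units : {'g', 'ms2'}
        Acceleration unit of the file; 'ms2' values are divided by 9.80665.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    df = df.drop(columns=[c for c in df.columns if c.lower() == "time"])
    df = _numeric_frame(df, path)
    labels = dict(labels or {})
    if kind == "force":
        if "vgrf" not in df.columns:
            raise ValueError(f"{path}: expected a 'vgrf' column")
        return ForceTrial(fs=fs, vgrf=df["vgrf"].to_numpy(), trial_id=trial_id, labels=labels)
    if kind not in SITES:
        raise ValueError(f"unknown trial kind {kind!r}")
    if axis_map is None:
        axis_map = {a: a for a in AXES}
    if sorted(axis_map.values()) != sorted(AXES):
        raise ValueError("axis_map must cover exactly ml, ap, vt")
    missing = [c for c in axis_map if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    cols = {axis: df[col].to_numpy() for col, axis in axis_map.items()}
    samples = np.column_stack([cols["ml"], cols["ap"], cols["vt"]])
    if units == "ms2":
        samples = samples / G0
    elif units != "g":
        raise ValueError("units must be 'g' or 'ms2'")
    return TriaxialTrial(
        site=kind, fs=fs, samples=samples, trial_id=trial_id, labels=labels
    )


def write_trial_csv(trial, path, time_column: bool = True) -> None:
    path = Path(path)
    if isinstance(trial, ForceTrial):
        df = pd.DataFrame({"vgrf": trial.vgrf})
    else:
        df = pd.DataFrame(
            {"ml": trial.ml, "ap": trial.ap, "vt": trial.vt}
        )
    if time_column:
        df.insert(0, "time", np.round(trial.times, 6))
    df.to_csv(path, index=False, float_format="%.9g")


def write_events_csv(table: EventTable, path) -> None:
    """Write one row per event: kind, t (6 decimals), side, magnitude, source."""
    df = table.to_frame()
    df["t"] = df["t"].map(lambda v: f"{v:.6f}")
    df["magnitude"] = df["magnitude"].map(lambda v: f"{v:.9g}")
    df.to_csv(path, index=False)


def read_events_csv(path, fs: float = 200.0) -> EventTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(
        path, dtype={"kind": str, "side": str, "source": str}
    )
    expected = ["kind", "t", "side", "magnitude", "source"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    events = [
        GaitEvent(
            kind=row.kind,
            t=float(row.t),
            side=row.side,
            magnitude=float(row.magnitude),
            source=row.source,
        )
        for row in df.itertuples()
    ]
    source = events[0].source if events else "force"
    return EventTable(events=events, source=source, fs=fs)


# ---------------------------------------------------------------------------
# resampling


def resample_trial(trial, target_fs: float):
    """Resample a trial to ``target_fs`` with polyphase anti-alias filtering.

    The rational resampling ratio is resolved to within 1/10000 of the
    requested rate; duration is preserved within one sample period.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if abs(target_fs - trial.fs) < 1e-9:
        return replace(trial)
    ratio = Fraction(target_fs / trial.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    if isinstance(trial, ForceTrial):
        v = resample_poly(trial.vgrf, up, down, padtype="line")
        return replace(trial, fs=target_fs, vgrf=np.maximum(v, 0.0))
    samples = resample_poly(trial.samples, up, down, axis=0, padtype="line")
    return replace(trial, fs=target_fs, samples=samples)
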