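"""Synthetic steady-state running trials with exact ground-truth events.

The simulator produces a co-registered triplet - foot accelerometer, raw
(unaligned) back accelerometer and vertical GRF - plus a ground-truth event
table, reproducing the signal structure the detectors assume:

* step times on a lightly jittered grid at the requested cadence (1 % of
  the step period, so sliding windows never phase-lock to events), sides
  alternating right/left, steps running over the whole trial as in a
  steady-state excerpt trimmed from continuous running;
* vGRF per stance: a double-bump (rearfoot) or single-bump (forefoot)
  profile scaled to body weight, exactly zero in swing, constructed so the
  first sample at/above 10 N falls on the true IC sample and the last
  sample at/above 25 N on the true TO sample;
* foot sensor (right steps only): 1 g VT baseline, an impact transient
  (VT + AP Gaussian pulses, so the resultant peaks at IC) and a negative-VT
  dip at TO;
* back sensor (both sides): VT impact peak at every IC, negative-VT dip at
  every TO, and an ML pulse at IC whose sign encodes the step side; the
  emitted trial is tilted in the sagittal plane and put in the raw back
  axis convention (AP +posterior), so gravity alignment has real work to do;
* independent white Gaussian noise per accelerometer channel.

All randomness flows from a single seeded generator; the same spec gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .core import EventTable, ForceTrial, GaitEvent, TriaxialTrial

__all__ = ["GaitSimSpec", "SimulatedTrial", "simulate_trial", "simulate_cohort"]

#: ground-truth events closer than this to a trial edge are not part of the
#: truth table (their stance cannot be fully observed / compared)
TRUTH_EDGE_MARGIN = 0.15


@dataclass(frozen=True)
class GaitSimSpec:
    """Conditions of one simulated running trial.

    Defaults describe a typical steady treadmill run: 170 steps/min (inside
    the 150-192 steps/min preferred range), 0.25 s ground contact time,
    60 s of data at 200 Hz with the plate sampled at 1000 Hz, 0.05 g sensor
    noise, ~6 g foot impact peaks and a 700 N body weight.
    ``back_foot_offset_ic``/``_to`` shift the back sensor's pulses by a
    known amount for offset-recovery experiments.
    """

    cadence: float = 170.0
    gct: float = 0.25
    duration: float = 60.0
    fs: float = 200.0
    force_fs: float = 1000.0
    noise_sd: float = 0.05
    impact_amp: float = 6.0
    to_dip_amp: float = 1.5
    ml_amp: float = 0.4
    body_weight: float = 700.0
    foot_strike: str = "rearfoot"
    back_tilt_deg: float = 8.0
    back_foot_offset_ic: float = 0.0
    back_foot_offset_to: float = 0.0
    seed: int = 0
    trial_id: str = "sim"
    labels: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 120.0 <= self.cadence <= 240.0:
            raise ValueError("cadence must lie in 120-240 steps/min")
        if self.gct < 0.11 or self.gct >= 60.0 / self.cadence:
            raise ValueError("gct must be >= 0.11 s and below the step period")
        if self.fs < 50 or self.duration <= 0 or self.noise_sd < 0:
            raise ValueError("need fs >= 50, duration > 0, noise_sd >= 0")
        if self.foot_strike not in ("rearfoot", "forefoot"):
            raise ValueError("foot_strike must be 'rearfoot' or 'forefoot'")
        if self.force_fs < self.fs:
            raise ValueError("force_fs must be >= fs")


class SimulatedTrial(NamedTuple):
    spec: GaitSimSpec
    foot: TriaxialTrial
    back: TriaxialTrial
    force: ForceTrial
    truth: EventTable


def _add_pulse(x: np.ndarray, fs: float, center: float, amp: float, sigma: float):
    """Add a Gaussian pulse in place, evaluated out to 5 sigma."""
    i0 = max(0, int(math.floor((center - 5 * sigma) * fs)))
    i1 = min(x.shape[0], int(math.ceil((center + 5 * sigma) * fs)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    x[i0:i1] += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


# stance-profile geometry (fractions of stance / multiples of body weight)
_EDGE_FORCE_N = 35.0  # boundary samples; >= 25 N so the last loaded sample is the TO
_EDGE_TAPER_FRAC = 0.08


def _stance_profile(n_samples: int, body_weight: float, foot_strike: str) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n_samples)
    if foot_strike == "rearfoot":
        bump = 1.5 * np.exp(-(((s - 0.22) / 0.10) ** 2)) + 2.4 * np.exp(
            -(((s - 0.55) / 0.16) ** 2)
        )
    else:
        bump = 2.5 * np.exp(-(((s - 0.50) / 0.17) ** 2))
    taper = np.minimum(1.0, np.minimum(s, 1.0 - s) / _EDGE_TAPER_FRAC)
    return _EDGE_FORCE_N + body_weight * bump * taper


def simulate_trial(spec: GaitSimSpec) -> SimulatedTrial:
    """Generate one co-registered foot/back/force triplet with ground truth.

    The truth table contains every *complete* step: IC and TO both at least
    0.12 s inside the trial.  The signals additionally contain partial
    steps at the edges (as a trimmed excerpt of continuous running would),
    which detectors are expected to flag or drop rather than report.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs, ffs = spec.fs, spec.force_fs
    period = 60.0 / spec.cadence

    def snap(t: float) -> float:
        return round(t * fs) / fs

    # step grid: jittered, alternating sides, covering the whole duration
    steps = []  # (ic, to, side)
    t = 0.5 * period * rng.uniform(0.2, 1.0)
    k = 0
    while t < spec.duration:
        ic = snap(t)
        gct = spec.gct * (1.0 + 0.01 * rng.standard_normal())
        to = snap(ic + max(gct, 0.105))
        side = "right" if k % 2 == 0 else "left"
        steps.append((ic, to, side))
        t += period * (1.0 + 0.01 * rng.standard_normal())
        k += 1

    # ---- vertical GRF (exact threshold crossings at truth samples) -------
    nf = int(round(spec.duration * ffs))
    vgrf = np.zeros(nf)
    for ic, to, _ in steps:
        i0 = int(round(ic * ffs))
        i1 = int(round(to * ffs))
        profile = _stance_profile(i1 - i0 + 1, spec.body_weight, spec.foot_strike)
        j0, j1 = max(0, i0), min(nf, i1 + 1)
        vgrf[j0:j1] = profile[j0 - i0 : j1 - i0]

    # ---- accelerometers ---------------------------------------------------
    n = int(round(spec.duration * fs))
    sig_ic = 0.012 if spec.foot_strike == "rearfoot" else 0.025

    foot = np.zeros((n, 3))
    foot[:, 2] = 1.0  # VT baseline: gravity
    for ic, to, side in steps:
        if side != "right":
            continue
        _add_pulse(foot[:, 2], fs, ic, 0.9 * spec.impact_amp, sig_ic)
        _add_pulse(foot[:, 1], fs, ic, 0.45 * spec.impact_amp, sig_ic)
        _add_pulse(foot[:, 2], fs, to, -spec.to_dip_amp, 0.020)

    back = np.zeros((n, 3))
    back[:, 2] = 1.0
    for ic, to, side in steps:
        icb = snap(ic + spec.back_foot_offset_ic)
        tob = snap(to + spec.back_foot_offset_to)
        _add_pulse(back[:, 2], fs, icb, 0.5 * spec.impact_amp, 0.015)
        _add_pulse(back[:, 2], fs, tob, -0.8 * spec.to_dip_amp, 0.020)
        sign = 1.0 if side == "right" else -1.0
        _add_pulse(back[:, 0], fs, icb, sign * spec.ml_amp, 0.020)

    foot += rng.normal(0.0, spec.noise_sd, foot.shape) if spec.noise_sd else 0.0
    back += rng.normal(0.0, spec.noise_sd, back.shape) if spec.noise_sd else 0.0

    # tilt the back sensor in the sagittal plane and emit the raw axis
    # convention (AP +posterior), undone later by gravity alignment
    th = math.radians(spec.back_tilt_deg)
    ap_tilt = math.cos(th) * back[:, 1] - math.sin(th) * back[:, 2]
    vt_tilt = math.sin(th) * back[:, 1] + math.cos(th) * back[:, 2]
    back_raw = np.column_stack([back[:, 0], -ap_tilt, vt_tilt])

    # ---- ground truth -----------------------------------------------------
    events = []
    for ic, to, side in steps:
        if ic < TRUTH_EDGE_MARGIN or to > spec.duration - TRUTH_EDGE_MARGIN:
            continue
        events.append(GaitEvent(kind="IC", t=ic, side=side, source="force"))
        events.append(GaitEvent(kind="TO", t=to, side=side, source="force"))
    truth = EventTable(events=events, source="force", fs=fs)

    labels = dict(spec.labels)
    return SimulatedTrial(
        spec=spec,
        foot=TriaxialTrial(
            site="foot", fs=fs, samples=foot,
            trial_id=f"{spec.trial_id}-foot", labels=labels,
        ),
        back=TriaxialTrial(
            site="back", fs=fs, samples=back_raw, aligned=False,
            trial_id=f"{spec.trial_id}-back", labels=labels,
        ),
        force=ForceTrial(
            fs=ffs, vgrf=vgrf, trial_id=f"{spec.trial_id}-force", labels=labels,
        ),
        truth=truth,
    )


DEFAULT_COHORT_RANGES = {"cadence": (150.0, 192.0)}


def simulate_cohort(
    n_subjects: int,
    ranges: dict | None = None,
    seed: int = 0,
    base: GaitSimSpec = GaitSimSpec(),
) -> list:
    """Simulate ``n_subjects`` trials with per-subject parameters drawn
    uniformly from ``ranges`` (field name -> (low, high)); reproducible
    under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    for name, bounds in ranges.items():
        if not hasattr(base, name):
            raise ValueError(f"unknown spec field {name!r}")
        if not bounds or bounds[0] > bounds[1]:
            raise ValueError(f"empty range for {name!r}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        draws = {k: float(rng.uniform(*b)) for k, b in ranges.items()}
        sub = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            trial_id=f"{base.trial_id}-s{i:02d}",
            **draws,
        )
        out.append(simulate_trial(sub))
    return out
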