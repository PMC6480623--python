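"""Cross-method validation: event matching, skipped steps, timing
differences and Bland-Altman agreement.

Two event tables are compared by greedily matching initial contacts within
a tolerance (default 0.25 s, half the minimum contralateral step interval,
which makes assignments unambiguous at any plausible cadence).  Toe offs
inherit their step's pairing.  A step present in one table but absent from
the other is a *skipped step* charged to the method that missed it.  Signed
per-step time differences (A - B) for IC, TO and ground contact time
GCT = TO - IC feed Bland-Altman statistics: mean difference, SD, and 95 %
limits of agreement (mean +/- 1.96 SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventTable

__all__ = [
    "MatchedSteps",
    "AgreementReport",
    "match_events",
    "differences",
    "condition_summary",
    "bland_altman",
]

log = logging.getLogger(__name__)

DEFAULT_MATCH_TOL = 0.25


@dataclass
class MatchedSteps:
    """Step correspondences between two event tables.

    ``pairs`` holds (ic_a, ic_b, to_a, to_b) per matched step (TOs may be
    None).  ``skipped_a`` counts steps method B found that A missed, and
    vice versa: a skipped step is charged to the deficient method.
    ``side_mismatches`` counts matched steps whose
    assigned sides disagree (with an unknown side read as 'right' in
    right-only comparisons, since the instrumented foot is the right one).
    """

    pairs: list = field(default_factory=list)
    skipped_a: int = 0
    skipped_b: int = 0
    side_mismatches: int = 0

    @property
    def n(self) -> int:
        return len(self.pairs)


def _to_lookup(table: EventTable) -> dict:
    return {id(ic): to for ic, to in table.steps()}


def match_events(
    table_a: EventTable,
    table_b: EventTable,
    tol: float = DEFAULT_MATCH_TOL,
    right_only: bool = False,
) -> MatchedSteps:
    """Greedy nearest-neighbour IC matching within ``+/- tol`` seconds.

    Candidate pairs are taken in order of |time difference| (ties to the
    earlier A event); each event joins at most one pair.  Provisional
    events (trial edges) stay out of both matching and the skip counts.

    With ``right_only=True`` (comparisons against the foot sensor, which
    records right steps only) left-side steps still take part in matching -
    a bilateral method's left steps must not steal a right match - but
    unmatched left-side steps are not charged as skips, and a matched step
    assigned 'left' counts as a side mismatch.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be positive")

    a_ics = table_a.ics(include_provisional=False)
    b_ics = table_b.ics(include_provisional=False)
    to_a = _to_lookup(table_a)
    to_b = _to_lookup(table_b)

    cand = []
    for i, ea in enumerate(a_ics):
        for j, eb in enumerate(b_ics):
            dt = abs(ea.t - eb.t)
            if dt <= tol:
                cand.append((dt, ea.t, i, j))
    cand.sort()
    used_a, used_b = set(), set()
    matched = []
    for _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    matched.sort()

    result = MatchedSteps()
    for i, j in matched:
        ic_a, ic_b = a_ics[i], b_ics[j]
        ta = to_a.get(id(ic_a))
        tb = to_b.get(id(ic_b))
        if ta is not None and ta.provisional:
            ta = None
        if tb is not None and tb.provisional:
            tb = None
        result.pairs.append((ic_a, ic_b, ta, tb))
        sides = {ic_a.side, ic_b.side}
        if right_only:
            sides.discard("unknown")
            if "left" in sides:
                result.side_mismatches += 1
        elif "unknown" not in sides and ic_a.side != ic_b.side:
            result.side_mismatches += 1

    def _countable(ev):
        return not (right_only and ev.side == "left")

    result.skipped_a = sum(
        1 for j, eb in enumerate(b_ics) if j not in used_b and _countable(eb)
    )
    result.skipped_b = sum(
        1 for i, ea in enumerate(a_ics) if i not in used_a and _countable(ea)
    )
    return result


def bland_altman(deltas) -> dict:
    """Mean difference, SD (ddof=1) and 95 % limits of agreement.

    Fewer than two values flag SD and the limits as undefined (NaN).
    """
    d = np.asarray(deltas, dtype=float)
    out = {"n": int(d.size)}
    if d.size == 0:
        out.update(mean=float("nan"), sd=float("nan"))
    else:
        out["mean"] = float(d.mean())
        out["sd"] = float(d.std(ddof=1)) if d.size >= 2 else float("nan")
    out["loa_low"] = out["mean"] - 1.96 * out["sd"]
    out["loa_high"] = out["mean"] + 1.96 * out["sd"]
    return out


@dataclass
class AgreementReport:
    """Per-event timing differences (method A - method B) and their
    Bland-Altman summaries."""

    ic_delta: np.ndarray
    to_delta: np.ndarray
    gct_delta: np.ndarray
    ic: dict = field(default_factory=dict)
    to: dict = field(default_factory=dict)
    gct: dict = field(default_factory=dict)
    skipped_a: int = 0
    skipped_b: int = 0
    side_mismatches: int = 0

    @property
    def n(self) -> int:
        return int(self.ic_delta.size)


def differences(matched: MatchedSteps) -> AgreementReport:
    """Signed A - B timing differences per matched step.

    GCT differences use only steps where both methods produced a toe off:
    GCTdelta = (TO_a - IC_a) - (TO_b - IC_b) = TOdelta - ICdelta.
    """
    ic_d, to_d, gct_d = [], [], []
    for ic_a, ic_b, to_a, to_b in matched.pairs:
        ic_d.append(ic_a.t - ic_b.t)
        if to_a is not None and to_b is not None:
            to_d.append(to_a.t - to_b.t)
            gct_d.append((to_a.t - ic_a.t) - (to_b.t - ic_b.t))
    ic_d = np.asarray(ic_d)
    to_d = np.asarray(to_d)
    gct_d = np.asarray(gct_d)
    return AgreementReport(
        ic_delta=ic_d,
        to_delta=to_d,
        gct_delta=gct_d,
        ic=bland_altman(ic_d),
        to=bland_altman(to_d),
        gct=bland_altman(gct_d),
        skipped_a=matched.skipped_a,
        skipped_b=matched.skipped_b,
        side_mismatches=matched.side_mismatches,
    )


def condition_summary(groups: dict) -> pd.DataFrame:
    """Pooled mean and SD of timing differences per condition and event kind.

    ``groups`` maps a condition label to a list of :class:`AgreementReport`
    (one per trial).  The per-step difference arrays of all trials in a
    condition are pooled *before* the mean and SD are computed, so every
    step carries equal weight regardless of which trial it came from.
    Empty groups are omitted with a warning.
    """
    rows = []
    for condition, reports in groups.items():
        arrays = {
            "IC": [r.ic_delta for r in reports],
            "TO": [r.to_delta for r in reports],
            "GCT": [r.gct_delta for r in reports],
        }
        pooled_any = False
        for kind, parts in arrays.items():
            pooled = np.concatenate(parts) if parts else np.array([])
            if pooled.size == 0:
                continue
            pooled_any = True
            stats = bland_altman(pooled)
            rows.append(
                {
                    "condition": condition,
                    "event": kind,
                    "n": stats["n"],
                    "mean": stats["mean"],
                    "sd": stats["sd"],
                }
            )
        if not pooled_any:
            log.warning("condition %r has no matched steps; omitted", condition)
    return pd.DataFrame(rows, columns=["condition", "event", "n", "mean", "sd"])
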