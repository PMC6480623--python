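"""Sliding-window collection, consolidation and the full pipeline."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstride.core import (
    GaitEvent,
    MIN_STANCE,
    TriaxialTrial,
    min_ic_separation_for,
)
from gaitstride.engine import (
    CandidatePool,
    WindowParams,
    collect_candidates,
    consolidate,
    detect_trial,
    iter_windows,
    measure_output_rate,
    table_to_pool,
)
from gaitstride.foot import foot_candidates
from gaitstride.simulate import GaitSimSpec, simulate_trial


class TestWindows:
    def test_window_count_arithmetic(self):
        wins = list(iter_windows(10.0, WindowParams(window_size=2.0, shift=1.0)))
        full = [w for w in wins if w[1] - w[0] == 2.0]
        assert len(full) == 9
        assert len(wins) == 10  # plus one 1 s partial tail window

    def test_partial_tail_window_needs_one_second(self):
        wins = list(iter_windows(2.5, WindowParams(window_size=2.0, shift=2.0)))
        assert wins == [(0.0, 2.0)]  # 0.5 s leftover is dropped

    def test_nonoverlapping_windows_allowed(self):
        params = WindowParams(window_size=1.0, shift=1.0)
        assert len(list(iter_windows(5.0, params))) == 5

    def test_pool_has_no_duplicate_candidates(self, sim_noisy):
        from gaitstride.preprocess import lowpass

        trial = lowpass(sim_noisy.foot)
        pool = collect_candidates(trial, foot_candidates, WindowParams(shift=0.1))
        keys = [(round(e.t * trial.fs)) for e in pool.ic]
        assert len(keys) == len(set(keys))


def _pool(ic_spec, to_spec, source="back"):
    return CandidatePool(
        ic=[GaitEvent(kind="IC", t=t, magnitude=m, source=source) for t, m in ic_spec],
        to=[GaitEvent(kind="TO", t=t, magnitude=m, source=source) for t, m in to_spec],
    )


def _consolidate(pool, source="back", min_sep=0.25, max_sep=0.5):
    return consolidate(
        pool, source=source, fs=200.0,
        min_ic_separation=min_sep, max_ic_separation=max_sep,
    )


class TestConsolidation:
    def test_greater_magnitude_wins_close_conflict(self):
        table = _consolidate(_pool([(1.0, 1.8), (1.1, 2.3)], []))
        assert [ic.t for ic in table.ics()] == [1.1]
        assert table.ics()[0].magnitude == 2.3

    def test_to_before_min_stance_dropped(self):
        table = _consolidate(_pool([(1.0, 2.0)], [(1.05, 0.9), (1.30, 0.5)]))
        (step,) = table.steps()
        assert step[1].t == 1.30

    def test_equal_magnitude_tie_keeps_earlier(self):
        table = _consolidate(_pool([(1.0, 2.0), (1.1, 2.0)], []))
        assert [ic.t for ic in table.ics()] == [1.0]

    def test_truth_pool_is_fixed_point(self, sim_clean):
        truth = sim_clean.truth
        table = _consolidate(table_to_pool(truth), source="force")
        assert [(e.kind, e.t) for e in table.events] == [
            (e.kind, e.t) for e in truth.events
        ]

    def test_largest_negative_vt_to_retained(self):
        table = _consolidate(_pool([(1.0, 2.0)], [(1.2, 0.4), (1.3, 0.9), (1.4, 0.2)]))
        (step,) = table.steps()
        assert step[1].t == 1.3


# randomized candidate pools: frames on a 5 ms grid over 30 s
_ic_lists = st.lists(
    st.tuples(st.integers(0, 6000), st.floats(0.0, 10.0, allow_nan=False)),
    min_size=0,
    max_size=60,
)
_to_lists = st.lists(
    st.tuples(st.integers(0, 6000), st.floats(0.0, 10.0, allow_nan=False)),
    min_size=0,
    max_size=60,
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(ic=_ic_lists, to=_to_lists, source=st.sampled_from(["back", "foot", "force"]))
def test_consolidation_invariants_and_idempotence(ic, to, source):
    """Final ICs respect the per-source cadence floor, every TO lies in
    [IC + 0.1 s, next IC), and re-consolidating the output changes nothing."""
    ic = sorted({f: m for f, m in ic}.items())
    to = sorted({f: m for f, m in to}.items())
    pool = _pool(
        [(f * 0.005, m) for f, m in ic], [(f * 0.005, m) for f, m in to], source=source
    )
    min_sep = min_ic_separation_for(source)
    max_sep = 2 * min_sep
    table = consolidate(
        pool, source=source, fs=200.0,
        min_ic_separation=min_sep, max_ic_separation=max_sep,
    )
    table.validate()
    ics = table.ics()
    for a, b in zip(ics, ics[1:]):
        assert b.t - a.t >= min_sep - 1e-9
    steps = table.steps()
    for i, (ic_ev, to_ev) in enumerate(steps):
        if to_ev is None:
            continue
        assert to_ev.t >= ic_ev.t + MIN_STANCE - 1e-9
        if i + 1 < len(steps):
            assert to_ev.t < steps[i + 1][0].t
        gct = to_ev.t - ic_ev.t
        assert gct == pytest.approx(to_ev.t - ic_ev.t)
    again = consolidate(
        table_to_pool(table), source=source, fs=200.0,
        min_ic_separation=min_sep, max_ic_separation=max_sep,
    )
    assert [(e.kind, e.t, e.magnitude) for e in again.events] == [
        (e.kind, e.t, e.magnitude) for e in table.events
    ]


class TestDetectTrial:
    def test_noise_free_foot_recovers_right_steps(self, sim_clean):
        table = detect_trial(sim_clean.foot)
        truth_right = [e.t for e in sim_clean.truth.ics() if e.side == "right"]
        got = [ic.t for ic in table.ics(include_provisional=False)]
        for t in truth_right:
            if 0.5 < t < sim_clean.foot.duration - 0.5:
                assert min(abs(g - t) for g in got) <= 1.0 / 200.0 + 1e-9

    def test_noise_free_back_recovers_all_steps_with_sides(self, sim_clean):
        table = detect_trial(sim_clean.back)
        truth = [(e.t, e.side) for e in sim_clean.truth.ics()]
        got = table.ics(include_provisional=False)
        hits = 0
        for t, side in truth:
            near = [ic for ic in got if abs(ic.t - t) <= 1.5 / 200.0]
            if near:
                assert near[0].side == side
                hits += 1
        assert hits >= len(truth) - 1

    def test_very_short_trial_empty_with_warning(self):
        t = TriaxialTrial(site="foot", fs=200.0, samples=np.ones((100, 3)))
        with pytest.warns(UserWarning, match="shorter than 1 s"):
            table = detect_trial(t)
        assert len(table) == 0

    def test_output_satisfies_event_table_invariants(self, sim_noisy):
        for trial in (sim_noisy.foot, sim_noisy.back, sim_noisy.force):
            detect_trial(trial).validate()


class TestOutputRate:
    def test_rates_positive_and_larger_shift_faster(self, sim_clean):
        trial = sim_clean.force
        slow_rates, slow_mean = measure_output_rate(
            trial, WindowParams(window_size=1.0, shift=0.01)
        )
        fast_rates, fast_mean = measure_output_rate(
            trial, WindowParams(window_size=1.0, shift=1.0)
        )
        assert np.all(slow_rates > 0) and np.all(fast_rates > 0)
        assert fast_mean > slow_mean
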