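"""Container invariants, CSV round trips and resampling."""

import numpy as np
import pytest

from gaitstride.core import (
    EventTable,
    ForceTrial,
    GaitEvent,
    TriaxialTrial,
    cadence_to_step_interval,
    read_events_csv,
    read_trial_csv,
    resample_trial,
    step_interval_to_cadence,
    write_events_csv,
    write_trial_csv,
)


def _trial(n=400, fs=200.0, site="foot"):
    rng = np.random.default_rng(0)
    return TriaxialTrial(site=site, fs=fs, samples=rng.normal(0, 1, (n, 3)))


class TestTrialContainers:
    def test_duration_arithmetic(self):
        assert _trial(400, 200.0).duration == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(site="head"),
            dict(fs=0.0),
            dict(samples=np.zeros((1, 3))),
            dict(samples=np.zeros((10, 2))),
            dict(samples=np.full((10, 3), np.nan)),
        ],
    )
    def test_invalid_trials_rejected(self, kwargs):
        base = dict(site="foot", fs=200.0, samples=np.zeros((10, 3)))
        base.update(kwargs)
        with pytest.raises(ValueError):
            TriaxialTrial(**base)

    def test_force_trial_rejects_negative_magnitudes(self):
        with pytest.raises(ValueError):
            ForceTrial(fs=1000.0, vgrf=np.array([0.0, -5.0, 1.0]))

    def test_resultant_is_rotation_invariant(self):
        t = _trial()
        th = 0.7
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        rotated = TriaxialTrial(site="foot", fs=t.fs, samples=t.samples @ rot.T)
        assert np.allclose(t.resultant, rotated.resultant)


class TestTrialCsv:
    def test_round_trip_accel(self, tmp_path):
        t = _trial(400)
        path = tmp_path / "trial.csv"
        write_trial_csv(t, path)
        back = read_trial_csv(path, kind="foot", fs=200.0)
        assert back.n == 400 and back.duration == pytest.approx(2.0)
        assert np.allclose(back.samples, t.samples, atol=1e-6)

    def test_round_trip_force(self, tmp_path):
        t = ForceTrial(fs=1000.0, vgrf=np.abs(np.random.default_rng(1).normal(100, 30, 500)))
        path = tmp_path / "force.csv"
        write_trial_csv(t, path)
        back = read_trial_csv(path, kind="force", fs=1000.0)
        assert back.n == 500
        assert np.allclose(back.vgrf, t.vgrf, atol=1e-4)

    def test_non_numeric_cell_reported_with_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ml,ap,vt\n0.1,0.2,0.3\n0.1,oops,0.3\n")
        with pytest.raises(ValueError, match="ap.*row 1"):
            read_trial_csv(path, kind="foot", fs=200.0)

    def test_axis_map_must_cover_axes(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("x,y,z\n0,0,1\n0,0,1\n")
        with pytest.raises(ValueError):
            read_trial_csv(path, kind="back", fs=200.0, axis_map={"x": "ml", "y": "ml", "z": "vt"})
        t = read_trial_csv(
            path, kind="back", fs=200.0, axis_map={"x": "ml", "y": "ap", "z": "vt"}
        )
        assert np.allclose(t.vt, 1.0)

    def test_ms2_units_converted_to_g(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("ml,ap,vt\n0,0,9.80665\n0,0,9.80665\n")
        t = read_trial_csv(path, kind="foot", fs=100.0, units="ms2")
        assert np.allclose(t.vt, 1.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_trial_csv(tmp_path / "nope.csv", kind="foot", fs=200.0)


class TestEventTable:
    def _events(self):
        return [
            GaitEvent(kind="IC", t=1.0, magnitude=2.0, source="back"),
            GaitEvent(kind="TO", t=1.25, magnitude=0.5, source="back"),
            GaitEvent(kind="IC", t=1.35, side="left", magnitude=2.2, source="back"),
            GaitEvent(kind="TO", t=1.60, magnitude=0.4, source="back"),
        ]

    def test_valid_table_accepted(self):
        table = EventTable(events=self._events(), source="back", fs=200.0)
        assert len(table.steps()) == 2

    def test_to_before_min_stance_rejected(self):
        ev = self._events()
        ev[1] = GaitEvent(kind="TO", t=1.05, magnitude=0.5, source="back")
        with pytest.raises(ValueError, match="0.1"):
            EventTable(events=ev, source="back", fs=200.0)

    def test_ic_spacing_per_source(self):
        ev = self._events()
        with pytest.raises(ValueError, match="0.5"):
            EventTable(events=ev, source="foot", fs=200.0)

    def test_to_without_ic_rejected(self):
        ev = [GaitEvent(kind="TO", t=0.5, source="back")]
        with pytest.raises(ValueError):
            EventTable(events=ev, source="back", fs=200.0)

    def test_events_round_trip(self, tmp_path):
        table = EventTable(events=self._events(), source="back", fs=200.0)
        path = tmp_path / "events.csv"
        write_events_csv(table, path)
        back = read_events_csv(path, fs=200.0)
        assert [(e.kind, e.t, e.side) for e in back.events] == [
            (e.kind, e.t, e.side) for e in table.events
        ]
        assert np.allclose(
            [e.magnitude for e in back.events], [e.magnitude for e in table.events]
        )

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_events_csv(EventTable(events=[], source="foot", fs=200.0), path)
        assert path.read_text().strip() == "kind,t,side,magnitude,source"
        assert len(read_events_csv(path)) == 0

    def test_unknown_side_literal(self, tmp_path):
        table = EventTable(
            events=[GaitEvent(kind="IC", t=0.5, source="foot")], source="foot", fs=200.0
        )
        path = tmp_path / "e.csv"
        write_events_csv(table, path)
        assert "unknown" in path.read_text()


class TestResample:
    def test_downsample_length(self):
        t = ForceTrial(fs=1000.0, vgrf=np.abs(np.sin(np.arange(10000) / 500)))
        out = resample_trial(t, 200.0)
        assert out.n == 2000
        assert abs(out.duration - t.duration) <= 1.0 / 200.0

    def test_constant_preserved(self):
        t = TriaxialTrial(site="foot", fs=200.0, samples=np.full((1000, 3), 0.7))
        out = resample_trial(t, 50.0)
        assert np.allclose(out.samples.mean(axis=0), 0.7, atol=1e-6)

    def test_sub_nyquist_sinusoid_amplitude_preserved(self):
        fs, f = 200.0, 5.0
        n = 2000
        x = np.sin(2 * np.pi * f * np.arange(n) / fs)
        t = TriaxialTrial(site="foot", fs=fs, samples=np.column_stack([x, x, x]))
        out = resample_trial(t, 50.0)
        core = out.samples[50:-50, 0]  # away from edge transients
        # amplitude from RMS: samples need not land on the crest at 50 Hz
        assert np.sqrt(2) * core.std() == pytest.approx(1.0, rel=0.01)

    def test_bad_rate_rejected(self):
        t = _trial()
        with pytest.raises(ValueError):
            resample_trial(t, 0.0)


def test_cadence_bound_arithmetic():
    """Cadence limits of 240 and 120 steps/min correspond to contralateral
    step intervals of 0.25 s and 0.50 s; ipsilateral intervals double."""
    assert cadence_to_step_interval(240.0) == pytest.approx(0.25)
    assert cadence_to_step_interval(120.0) == pytest.approx(0.50)
    assert step_interval_to_cadence(0.25) == pytest.approx(240.0)
    assert 2 * cadence_to_step_interval(240.0) == pytest.approx(0.5)
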