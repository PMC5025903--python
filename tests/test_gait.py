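import numpy as np
import pytest

import synergait as sg
from synergait.errors import InvalidParameterError, SequenceViolationError
from synergait.gait import (
    GaitEvent,
    GaitEventStream,
    PhaseDurationEstimator,
    phases_from_events,
    simulate_session,
    warp_profile,
)
from synergait.synthetic import make_event_stream

BOUNDS = (0.12, 0.19, 0.19, 0.12, 0.19, 0.19)


def _uniform_stream(gap=0.2, n_strides=3):
    return make_event_stream([gap] * 6, 0.0, n_strides)


class TestPhasesFromEvents:
    def test_canonical_cycle_durations(self):
        tl = phases_from_events(_uniform_stream())
        assert tl.n_strides == 3
        assert np.allclose(tl.durations_by_stride(), 0.2)
        assert [p.phase_id for p in tl.phases[:6]] == [1, 2, 3, 4, 5, 6]

    def test_missing_event_raises_naming_expected(self):
        events = [
            GaitEvent(0.0, "IC", "paretic"),
            GaitEvent(0.2, "EC", "nonparetic"),
            # nonparetic MS missing
            GaitEvent(0.6, "IC", "nonparetic"),
        ]
        with pytest.raises(SequenceViolationError, match="nonparetic MS"):
            phases_from_events(GaitEventStream(events))

    def test_generator_round_trip_exact(self):
        means = [0.15, 0.22, 0.18, 0.11, 0.25, 0.19]
        tl = phases_from_events(make_event_stream(means, 0.0, 4))
        assert np.allclose(tl.durations_by_stride(), np.tile(means, (4, 1)))

    def test_no_paretic_ic_raises(self):
        with pytest.raises(SequenceViolationError):
            phases_from_events(GaitEventStream([GaitEvent(0.0, "IC", "nonparetic")]))


class TestDurationEstimator:
    def test_mean_of_constant_history(self):
        est = PhaseDurationEstimator()
        for _ in range(5):
            est.update(1, 1.0)
        assert est.update(1, 1.0) == pytest.approx(1.0)

    def test_mean_of_last_five(self):
        est = PhaseDurationEstimator()
        for d in (0.2, 0.3, 0.4, 0.5):
            est.update(2, d)
        assert est.update(2, 0.6) == pytest.approx(0.4)

    def test_window_evicts_oldest(self):
        est = PhaseDurationEstimator()
        for d in (1, 2, 3, 4, 5, 6):
            est.update(3, float(d))
        assert len(est.history[3]) == 5
        assert est.estimate(3) == pytest.approx(np.mean([2, 3, 4, 5, 6]))

    def test_estimate_within_history_range(self, rng):
        est = PhaseDurationEstimator()
        ds = rng.uniform(0.1, 0.5, 9)
        for d in ds:
            est.update(1, float(d))
        h = list(est.history[1])
        assert min(h) <= est.estimate(1) <= max(h)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhaseDurationEstimator().update(1, 0.0)


class TestWarpProfile:
    def test_output_length_is_sum_of_segment_counts(self, template, rng):
        profile = template.H[1]
        durations = rng.uniform(0.1, 0.4, 6)
        out = warp_profile(profile, BOUNDS, durations, out_rate=60.0)
        assert out.size == int(np.sum(np.rint(durations * 60.0)))

    def test_uniform_speed_consistency(self, template):
        # durations proportional to the bounds at a rate that reproduces each
        # segment's sample count give back the template exactly
        profile = template.H[0]
        durations = np.asarray(BOUNDS)  # 1 s cycle
        out = warp_profile(profile, BOUNDS, durations, out_rate=100.0)
        assert out.size == 100
        assert np.allclose(out, profile)

    def test_doubling_one_phase_is_local(self, template):
        profile = template.H[2]
        base = np.asarray(BOUNDS)
        out1 = warp_profile(profile, BOUNDS, base, out_rate=100.0)
        longer = base.copy()
        longer[0] *= 2
        out2 = warp_profile(profile, BOUNDS, longer, out_rate=100.0)
        n1 = int(round(base[0] * 100))
        assert out2.size == out1.size + n1
        # segments 2..6 are bit-identical
        assert np.array_equal(out1[n1:], out2[2 * n1 :])

    def test_round_trip_close_for_smooth_template(self, template):
        profile = template.H[0]  # smooth raised cosine
        durations = np.array([0.20, 0.15, 0.25, 0.10, 0.18, 0.22])
        rate = 200.0
        warped = warp_profile(profile, BOUNDS, durations, rate)
        cuts = np.concatenate([[0], np.rint(np.cumsum(BOUNDS) * 100).astype(int)])
        cuts[-1] = 100
        counts = np.rint(durations * rate).astype(int)
        pos = 0
        rebuilt = []
        for p in range(6):
            seg = warped[pos : pos + counts[p]]
            pos += counts[p]
            m = cuts[p + 1] - cuts[p]
            rebuilt.append(np.interp(np.linspace(0, len(seg) - 1, m), np.arange(len(seg)), seg))
        rebuilt = np.concatenate(rebuilt)
        assert np.max(np.abs(rebuilt - profile)) < 0.02

    def test_zero_sample_phase_warns_and_skips(self, template):
        durations = np.array([1e-4, 0.2, 0.2, 0.2, 0.2, 0.2])
        with pytest.warns(RuntimeWarning):
            out = warp_profile(template.H[0], BOUNDS, durations, out_rate=20.0)
        assert out.size == int(np.sum(np.rint(durations[1:] * 20.0)))

    def test_intensities_stay_in_unit_interval(self, template, rng):
        out = warp_profile(template.H[3], BOUNDS, rng.uniform(0.05, 0.5, 6), 80.0)
        assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12


class TestSimulateSession:
    @pytest.fixture()
    def strategy(self, template):
        return sg.build_strategy(template, ["WA", "PO", "FC", "LD"])

    def test_constant_timing_repeats_commands_after_warmup(self, strategy):
        stream = _uniform_stream(gap=0.2, n_strides=9)
        log = simulate_session(strategy, stream)
        per_stride = [
            log[log.stride == k].pulse_width_us.to_numpy() for k in range(9)
        ]
        for k in range(6, 9):
            assert np.array_equal(per_stride[k], per_stride[5])

    def test_speedup_reduces_command_count(self, template, strategy):
        # cycle time decreases linearly; after the 5-stride warm-up the
        # moving-average estimates, hence command counts, strictly decrease
        phases = [np.full(6, (4.8 - 0.36 * k) / 6) for k in range(12)]
        events = [GaitEvent(0.0, "IC", "paretic")]
        t = 0.0
        from synergait.gait import _PHASE_END_EVENTS

        for durs in phases:
            for p, (side, etype) in enumerate(_PHASE_END_EVENTS):
                t += durs[p]
                events.append(GaitEvent(t, etype, side))
        log = simulate_session(strategy, GaitEventStream(events))
        counts = [int((log.stride == k).sum()) for k in range(12)]
        for k in range(6, 12):
            assert counts[k] < counts[k - 1]

    def test_empty_strategy_gives_empty_log(self, template):
        strat = sg.build_strategy(template, [])
        log = simulate_session(strat, _uniform_stream())
        assert len(log) == 0

    def test_log_reproducible(self, strategy):
        stream = make_event_stream(variability_sd=0.02, n_strides=6, seed=3)
        a = simulate_session(strategy, stream)
        b = simulate_session(strategy, stream)
        assert a.equals(b)

    def test_pulse_widths_bounded(self, strategy):
        log = simulate_session(strategy, _uniform_stream(n_strides=4))
        assert log.pulse_width_us.between(0, strategy.pw_max_us).all()
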