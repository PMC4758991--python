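"""Pulse formation and discriminator behaviour against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from petcrt import (
    PhotodetectorSpec,
    TriggerKind,
    TriggerTable,
    default_cf_table,
    pulse_amplitude,
    pulse_maximum,
    trigger_times,
)
from petcrt.physics import ser_amplitude, ser_peak_amplitude, ser_peak_time


@pytest.fixture(scope="module")
def pd_spec():
    return PhotodetectorSpec(jitter_fwhm_ns=0.0, ser_rise_ns=0.2, ser_decay_ns=2.0)


class TestPulseAmplitude:
    def test_zero_before_first_photoelectron(self, pd_spec):
        assert pulse_amplitude(np.array([1.0, 2.0]), 0.5, pd_spec) == 0.0

    def test_single_photoelectron_peaks_at_one(self, pd_spec):
        t1 = 3.0
        tpk = t1 + ser_peak_time(pd_spec)
        assert pulse_amplitude(np.array([t1]), tpk, pd_spec) == pytest.approx(1.0)
        assert pulse_maximum(np.array([t1]), pd_spec) == pytest.approx(1.0)

    def test_linearity_under_duplication(self, pd_spec, rng):
        train = np.sort(rng.exponential(5.0, 20))
        t = np.linspace(0.1, 30, 50)
        single = pulse_amplitude(train, t, pd_spec)
        double = pulse_amplitude(np.sort(np.concatenate([train, train])), t, pd_spec)
        np.testing.assert_allclose(double, 2 * single, rtol=1e-12)

    def test_coincident_photoelectrons_scale_maximum(self, pd_spec):
        train = np.zeros(7)
        assert pulse_maximum(train, pd_spec) == pytest.approx(7.0)


class TestPulseMaximum:
    def test_matches_dense_grid_oracle(self, pd_spec, rng):
        train = np.sort(rng.exponential(37.0, 1000))
        grid = np.arange(0.0, train.max() + 25.0, 1e-4)
        peak = ser_peak_amplitude(pd_spec)
        dense = np.zeros_like(grid)
        for ti in train:
            mask = grid > ti
            dense[mask] += ser_amplitude(grid[mask] - ti, pd_spec)
        oracle = dense.max() / peak
        assert pulse_maximum(train, pd_spec) == pytest.approx(oracle, abs=1e-3)

    def test_empty_train_rejected(self, pd_spec):
        with pytest.raises(ValueError):
            pulse_maximum(np.array([]), pd_spec)


class TestTriggerTimes:
    def test_single_pe_half_fraction_crossing(self, pd_spec):
        # oracle: root of S(t) = 0.5 S(t*) on the rising edge
        half = 0.5 * ser_peak_amplitude(pd_spec)
        root = brentq(
            lambda t: ser_amplitude(t, pd_spec) - half, 1e-9, ser_peak_time(pd_spec)
        )
        assert root == pytest.approx(0.1015, abs=1e-4)
        t1 = 2.0
        table = TriggerTable(TriggerKind.CONSTANT_FRACTION, np.array([0.5]))
        res = trigger_times(np.array([t1]), pd_spec, table)
        assert res.trigger_times_ns[0] == pytest.approx(t1 + root, abs=1e-6)

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_shift_equivariance(self, pd_spec, shift):
        rng = np.random.default_rng(77)
        train = np.sort(rng.exponential(10.0, 50)) + 100.0  # keep times positive
        table = default_cf_table(n=10)
        base = trigger_times(train, pd_spec, table).trigger_times_ns
        moved = trigger_times(train + shift, pd_spec, table).trigger_times_ns
        np.testing.assert_allclose(moved, base + shift, atol=1e-6)

    def test_cf_invariant_under_duplication(self, pd_spec, rng):
        train = np.sort(rng.exponential(8.0, 40))
        table = default_cf_table(n=15)
        base = trigger_times(train, pd_spec, table)
        doubled = trigger_times(np.repeat(train, 2), pd_spec, table)
        assert doubled.pulse_max == pytest.approx(2 * base.pulse_max, rel=1e-9)
        np.testing.assert_allclose(
            doubled.trigger_times_ns, base.trigger_times_ns, atol=1e-6
        )

    def test_first_crossing_contract(self, pd_spec, rng):
        train = np.sort(rng.exponential(20.0, 200))
        table = default_cf_table(n=20)
        res = trigger_times(train, pd_spec, table)
        for level, t_trig in zip(table.levels, res.trigger_times_ns):
            target = level * res.pulse_max
            # pulse equals the target at the trigger time...
            assert pulse_amplitude(train, t_trig, pd_spec) == pytest.approx(
                target, rel=1e-5
            )
            # ...and stays below it on a scan before the crossing
            before = np.arange(train[0], t_trig - 1e-4, 0.01)
            if len(before):
                assert np.all(pulse_amplitude(train, before, pd_spec) < target)

    def test_times_nondecreasing_with_level(self, pd_spec, rng):
        train = np.sort(rng.exponential(15.0, 120))
        res = trigger_times(train, pd_spec, default_cf_table())
        assert np.all(np.diff(res.trigger_times_ns) >= 0)
        assert np.all(res.trigger_times_ns >= train[0])

    def test_unreachable_leading_edge_level_absent(self, pd_spec):
        train = np.array([0.0, 50.0])  # pulses never overlap enough to reach 2
        table = TriggerTable(TriggerKind.LEADING_EDGE, np.array([0.5, 2.0]))
        res = trigger_times(train, pd_spec, table)
        assert np.isfinite(res.trigger_times_ns[0])
        assert np.isnan(res.trigger_times_ns[1])


class TestTriggerTable:
    def test_cf_levels_must_be_fractions(self):
        with pytest.raises(ValueError):
            TriggerTable(TriggerKind.CONSTANT_FRACTION, np.array([0.5, 1.5]))

    def test_levels_must_ascend(self):
        with pytest.raises(ValueError):
            TriggerTable(TriggerKind.LEADING_EDGE, np.array([2.0, 1.0]))
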