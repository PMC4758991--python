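"""Double-ended pipeline: DOI estimation, calibration, combined estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petcrt import (
    DoubleEndedRun,
    OpticalTransportSpec,
    PhotodetectorSpec,
    ScintillatorSpec,
    SimulationConfig,
    combine_estimates,
    estimate_doi,
    run_double_ended,
)
from petcrt.physics import FWHM_PER_SIGMA, signal_fractions
from petcrt.pulse import default_cf_table


@pytest.fixture(scope="module")
def small_lso():
    return ScintillatorSpec(1.2, 1.82, 3.0, 0.0, 37.0, 2000)


@pytest.fixture(scope="module")
def small_run(small_lso):
    """One shared double-ended run (LSO, 2000 pe, J=0.2) at modest size."""
    run = DoubleEndedRun(
        small_lso,
        OpticalTransportSpec(),
        PhotodetectorSpec(jitter_fwhm_ns=0.2),
        sim=SimulationConfig(n_events=4000, seed=101, calibration_n_events=4000),
    )
    return run, run_double_ended(run)


class TestDoiEstimate:
    def test_symmetric_split_is_midpoint(self, optics):
        assert estimate_doi(500, 500, optics, 3.0) == pytest.approx(1.5)

    def test_entrance_surface_split(self, optics):
        assert estimate_doi(700, 300, optics, 2.0) == pytest.approx(0.0)

    @given(
        z=st.floats(0, 1),
        a=st.floats(0.55, 0.95),
        length=st.floats(0.5, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_exactly_inverts_light_sharing(self, z, a, length):
        # noiseless counts m = N f(Z) recover Z exactly for any yield
        opt = OpticalTransportSpec(near_end_fraction=a)
        fa, fb = signal_fractions(z * length, opt, length)
        assert estimate_doi(1000 * fa, 1000 * fb, opt, length) == pytest.approx(
            z * length, abs=1e-9 * length
        )

    def test_no_doi_sensitivity_rejected(self):
        opt = OpticalTransportSpec(near_end_fraction=0.5)
        with pytest.raises(ValueError):
            estimate_doi(500, 500, opt, 3.0)

    def test_empty_event_rejected(self, optics):
        with pytest.raises(ValueError):
            estimate_doi(0, 0, optics, 3.0)

    def test_clamped_to_crystal(self, optics):
        # extreme fluctuation beyond the invertible range clamps to [0, L]
        assert estimate_doi(1000, 1, optics, 3.0) == 0.0
        assert estimate_doi(1, 1000, optics, 3.0) == 3.0


class TestCombineEstimates:
    def test_equal_variances_reduce_to_simple_average(self):
        e_ab, e_wab = combine_estimates(0.2, 0.6, 2.0, 2.0)
        assert e_ab == e_wab == pytest.approx(0.4)

    def test_infinite_variance_degenerates_to_other_estimate(self):
        _, e_wab = combine_estimates(0.1, 9.9, 1.0, 1e12)
        assert e_wab == pytest.approx(0.1, abs=1e-8)

    def test_worked_example(self):
        _, e_wab = combine_estimates(0.1, 0.4, 1.0, 3.0)
        assert e_wab == pytest.approx(0.175)

    @given(
        e_a=st.floats(-1, 1),
        e_b=st.floats(-1, 1),
        v_a=st.floats(0.01, 10),
        v_b=st.floats(0.01, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_weighted_average_is_convex(self, e_a, e_b, v_a, v_b):
        _, e_wab = combine_estimates(e_a, e_b, v_a, v_b)
        lo, hi = min(e_a, e_b), max(e_a, e_b)
        assert lo - 1e-12 <= e_wab <= hi + 1e-12

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            combine_estimates(0.1, 0.2, 0.0, 1.0)


class TestCalibration:
    def test_delay_grows_with_depth_on_entrance_detector(self, small_run):
        # deeper interactions disperse the photons more, slowing the pulse
        _, result = small_run
        calib = result.calibration
        mid = len(default_cf_table().levels) // 2
        assert calib.delay_a[-1, mid] > calib.delay_a[0, mid]

    def test_entrance_variance_smaller_for_shallow_bands(self, small_run):
        # detector A receives more light for shallow interactions
        run, result = small_run
        calib = result.calibration
        idx = result.w_wab.optimal_index
        assert calib.var_a[0, idx] < calib.var_b[0, idx]

    def test_mismatched_configuration_rejected(self, small_run, small_lso):
        run, result = small_run
        other = DoubleEndedRun(
            small_lso,
            OpticalTransportSpec(),
            PhotodetectorSpec(jitter_fwhm_ns=0.4),  # different jitter
            sim=SimulationConfig(n_events=100, seed=1),
        )
        with pytest.raises(ValueError, match="different configuration"):
            run_double_ended(other, result.calibration)

    def test_tables_roundtrip_json(self, small_run, tmp_path):
        _, result = small_run
        path = tmp_path / "calib.json"
        result.calibration.to_json(path)
        from petcrt import CalibrationTables

        loaded = CalibrationTables.from_json(path)
        np.testing.assert_allclose(loaded.delay_a, result.calibration.delay_a)
        assert loaded.fingerprint == result.calibration.fingerprint


class TestRunResults:
    def test_corrected_estimates_centred_on_zero(self, small_run):
        # E_A estimates the entrance time, defined as 0 in simulation time
        run, result = small_run
        s = result.w_ea
        sigma = s.crt_at_optimum_ns / 3.33006
        se = sigma / np.sqrt(s.n_events_used)
        # calibration consistency: population mean within a few SE of zero
        # (checked via the optimum-level CRT being finite and the summary
        # mean recomputed below)
        assert abs(result.mean_entrance_a) < 4 * se

    def test_estimator_ordering(self, small_run):
        _, r = small_run
        se = np.hypot(r.w_wab.standard_error_ns, r.w_eab.standard_error_ns)
        assert r.w_wab.crt_at_optimum_ns <= r.w_eab.crt_at_optimum_ns + 3 * se
        se2 = np.hypot(r.w_eab.standard_error_ns, r.w_dab.standard_error_ns)
        assert r.w_eab.crt_at_optimum_ns <= r.w_dab.crt_at_optimum_ns + 3 * se2

    def test_entrance_detector_more_accurate(self, small_run):
        # for a > 0.5 the entrance detector sees more light: W_EA < W_EB
        _, r = small_run
        se = np.hypot(r.w_ea.standard_error_ns, r.w_eb.standard_error_ns)
        assert r.w_ea.crt_at_optimum_ns < r.w_eb.crt_at_optimum_ns + 3 * se

    def test_doi_resolution_matches_error_propagation(self, small_run, small_lso):
        # propagate count noise through the estimator:
        # W_Z ~ 2.3548 (L/2) / ((2a-1) sqrt(N_pe)); clamping makes the
        # simulated value slightly smaller
        _, r = small_run
        n_pe = small_lso.photoelectron_yield
        closed = FWHM_PER_SIGMA * (3.0 / 2) / (0.4 * np.sqrt(n_pe))
        assert r.w_z_fwhm_cm == pytest.approx(closed, rel=0.10)

    def test_doi_estimate_unbiased(self, small_run):
        _, r = small_run
        assert abs(r.mean_doi_error_cm) < 4 * r.w_z_fwhm_cm / (
            FWHM_PER_SIGMA * np.sqrt(r.n_events_used)
        )

    def test_band_count_insensitive(self, small_lso):
        base = dict(
            scint=small_lso,
            opt=OpticalTransportSpec(),
            pd=PhotodetectorSpec(jitter_fwhm_ns=0.2),
        )
        runs = []
        for bands in (15, 30):
            sim = SimulationConfig(
                n_events=3000, seed=301, calibration_n_events=3000,
                depth_band_count=bands,
            )
            runs.append(run_double_ended(DoubleEndedRun(sim=sim, **base)))
        a, b = runs
        assert abs(
            a.w_wab.crt_at_optimum_ns - b.w_wab.crt_at_optimum_ns
        ) < a.w_wab.standard_error_ns

    def test_pulse_height_doi_variant_close_to_count_doi(self, small_lso):
        base = dict(
            scint=small_lso,
            opt=OpticalTransportSpec(),
            pd=PhotodetectorSpec(jitter_fwhm_ns=0.2),
            sim=SimulationConfig(n_events=3000, seed=401, calibration_n_events=3000),
        )
        counts = run_double_ended(DoubleEndedRun(**base))
        heights = run_double_ended(
            DoubleEndedRun(doi_from_pulse_heights=True, **base)
        )
        se = np.hypot(
            counts.w_wab.standard_error_ns, heights.w_wab.standard_error_ns
        )
        assert abs(
            counts.w_wab.crt_at_optimum_ns - heights.w_wab.crt_at_optimum_ns
        ) < 5 * se
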