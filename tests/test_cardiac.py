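"""Cardiac performance and rhythm: beats, volumes, Poincaré, A–V timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zebraphys import (
    AcquisitionConfig,
    BeatSeries,
    ChamberTrace,
    av_intervals,
    detect_beats,
    ellipsoid_volume,
    heart_rate,
    poincare_sd,
    volumetric_endpoints,
)
from zebraphys.errors import InsufficientDataError, PairingError, ValidationError

from conftest import sinusoid_trace


class TestDetectBeats:
    def test_sinusoid_recovers_all_beats(self, cardiac_config):
        beats = detect_beats(sinusoid_trace(freq_hz=2.5), cardiac_config)
        assert len(beats) == 25
        assert heart_rate(beats) == pytest.approx(150.0, abs=0.5)

    def test_noisy_sinusoid_recovers_beats(self, cardiac_config):
        # Gaussian noise sigma = 2% of the 10 um peak-to-trough amplitude
        beats = detect_beats(sinusoid_trace(freq_hz=2.5, noise_sd=0.2, seed=4), cardiac_config)
        assert len(beats) == 25

    def test_flat_trace_errors(self, cardiac_config):
        frames = np.arange(2000)
        flat = ChamberTrace("f", "ventricle", frames, np.full(2000, 100.0), np.full(2000, 50.0))
        with pytest.raises(InsufficientDataError):
            detect_beats(flat, cardiac_config)

    @pytest.mark.parametrize("hr", [120.0, 150.0, 300.0])
    def test_simulated_hr_recovered_within_one_bpm(self, hr, cardiac_config):
        from zebraphys.simulate import sim_heart

        _, vent, _ = sim_heart(hr_mean_bpm=hr, ibi_sd_ms=0.0, seed=1)
        assert heart_rate(detect_beats(vent, cardiac_config)) == pytest.approx(hr, abs=1.0)


class TestHeartRate:
    def test_regular_beats_closed_form(self):
        beats = BeatSeries("ventricle", np.arange(0, 9.61, 0.4))
        assert heart_rate(beats) == pytest.approx(150.0)

    def test_two_beats_one_second(self):
        assert heart_rate(BeatSeries("atrium", [0.0, 1.0])) == pytest.approx(60.0)

    def test_mean_ibi_400ms_simulation(self):
        rng = np.random.default_rng(5)
        ibis = rng.normal(0.4, 0.01, 100)
        beats = BeatSeries("ventricle", np.concatenate([[0.0], np.cumsum(ibis)]))
        assert heart_rate(beats) == pytest.approx(150.0, abs=2.0)


class TestEllipsoidVolume:
    def test_reference_geometry(self):
        assert ellipsoid_volume(100.0, 50.0) == pytest.approx(130.90, abs=0.005)

    def test_sphere_limit(self):
        L = 80.0
        assert ellipsoid_volume(L, L) == pytest.approx(np.pi / 6 * L**3 / 1000.0)

    def test_degenerate_axis_errors(self):
        with pytest.raises(ValidationError):
            ellipsoid_volume(100.0, 0.0)

    def test_volume_scales_cubically(self):
        k = 1.7
        assert ellipsoid_volume(k * 100, k * 50) == pytest.approx(k**3 * ellipsoid_volume(100, 50))


class TestVolumetricEndpoints:
    def test_simulated_geometry_closed_form(self, cardiac_config):
        from zebraphys.simulate import sim_heart

        _, vent, truth = sim_heart(hr_mean_bpm=150.0, ibi_sd_ms=0.0, seed=2)
        beats = detect_beats(vent, cardiac_config)
        ep = volumetric_endpoints(vent, beats, cardiac_config)
        assert ep.edv == pytest.approx(130.90, rel=0.01)
        assert ep.esv == pytest.approx(75.40, rel=0.01)
        assert ep.sv == pytest.approx(55.50, rel=0.01)
        assert ep.ef == pytest.approx(42.4, rel=0.01)
        assert ep.sf == pytest.approx(20.0, rel=0.01)
        assert ep.co == pytest.approx(8325.0, rel=0.01)

    def test_co_is_sv_times_hr_exactly(self, cardiac_config):
        from zebraphys.simulate import sim_heart

        _, vent, _ = sim_heart(hr_mean_bpm=140.0, ibi_sd_ms=15.0, seed=3)
        beats = detect_beats(vent, cardiac_config)
        ep = volumetric_endpoints(vent, beats, cardiac_config)
        assert ep.co == ep.sv * ep.hr

    def test_constant_geometry_gives_zero_sv(self, cardiac_config):
        frames = np.arange(2000)
        trace = ChamberTrace("c", "ventricle", frames, np.full(2000, 100.0), np.full(2000, 50.0))
        beats = BeatSeries("ventricle", np.arange(0.3, 9.5, 0.4))
        ep = volumetric_endpoints(trace, beats, cardiac_config)
        assert ep.sv == 0.0 and ep.ef == 0.0 and ep.sf == 0.0

    def test_ef_definition(self):
        # SV = 100 pL on EDV = 200 pL -> EF 50%: direct from the definition
        assert 100.0 * 100.0 / 200.0 == pytest.approx(50.0)

    def test_scaling_axes_by_k_scales_volumes_cubically(self, cardiac_config):
        from zebraphys.simulate import sim_heart

        k = 1.3
        _, vent, _ = sim_heart(hr_mean_bpm=150.0, ibi_sd_ms=0.0, seed=2)
        scaled = ChamberTrace(
            "k", "ventricle", vent.frames, k * vent.long_axis, k * vent.short_axis
        )
        b1 = detect_beats(vent, cardiac_config)
        b2 = detect_beats(scaled, cardiac_config)
        e1 = volumetric_endpoints(vent, b1, cardiac_config)
        e2 = volumetric_endpoints(scaled, b2, cardiac_config)
        assert e2.sv == pytest.approx(k**3 * e1.sv, rel=1e-6)
        assert e2.ef == pytest.approx(e1.ef, rel=1e-6)
        assert e2.sf == pytest.approx(e1.sf, rel=1e-6)


class TestPoincare:
    def test_constant_ibis_are_zero_zero(self):
        assert poincare_sd(np.full(50, 420.0)) == (0.0, 0.0)

    def test_alternating_oracle(self):
        # brute-force oracle over the lag-1 pair set: diffs +-200, sums 1000
        x = np.tile([400.0, 600.0], 50)
        a, b = x[:-1], x[1:]
        sd1_oracle = np.sqrt(np.var(b - a) / 2)
        sd2_oracle = np.sqrt(np.var(b + a) / 2)
        sd1, sd2 = poincare_sd(x)
        assert sd1 == pytest.approx(sd1_oracle, abs=1e-12)
        assert sd2 == pytest.approx(sd2_oracle, abs=1e-12)
        assert sd1 == pytest.approx(141.42, abs=0.1)
        assert sd2 == pytest.approx(0.0, abs=1e-9)

    def test_iid_gaussian_sd1_equals_sd2(self):
        rng = np.random.default_rng(8)
        x = rng.normal(400.0, 10.0, 10_000)
        sd1, sd2 = poincare_sd(x)
        assert sd1 == pytest.approx(10.0, rel=0.05)
        assert sd2 == pytest.approx(10.0, rel=0.05)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sum_of_squares_identity(self, seed):
        # SD1^2 + SD2^2 = Var(x_i) + Var(x_{i+1}) over the pair set, exactly
        rng = np.random.default_rng(seed)
        x = rng.uniform(200, 800, rng.integers(3, 200))
        sd1, sd2 = poincare_sd(x)
        lhs = sd1**2 + sd2**2
        rhs = np.var(x[:-1]) + np.var(x[1:])
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_positive_autocorrelation_widens_sd2(self):
        from zebraphys.simulate import sim_heart

        _, _, truth = sim_heart(hr_mean_bpm=150, ibi_sd_ms=20.0, ibi_rho=0.8, duration_s=60.0, seed=9)
        assert truth["sd2_ms"] > truth["sd1_ms"]

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            poincare_sd([400.0, 410.0])


class TestAVIntervals:
    def test_constructed_fixture(self):
        a = BeatSeries("atrium", [0.0, 0.4, 0.8])
        v = BeatSeries("ventricle", [0.1, 0.5, 0.9])
        av, va = av_intervals(a, v)
        assert av == pytest.approx(100.0)
        assert va == pytest.approx(300.0)

    def test_simulated_delay_recovered(self, cardiac_config):
        from zebraphys.simulate import sim_heart

        atr, vent, _ = sim_heart(hr_mean_bpm=150.0, ibi_sd_ms=10.0, av_delay_ms=80.0, seed=6)
        av, va = av_intervals(detect_beats(atr, cardiac_config), detect_beats(vent, cardiac_config))
        assert av == pytest.approx(80.0, abs=5.0)

    def test_av_plus_va_is_mean_atrial_ibi(self, cardiac_config):
        from zebraphys.simulate import sim_heart

        atr, vent, _ = sim_heart(hr_mean_bpm=150.0, ibi_sd_ms=10.0, seed=7)
        a = detect_beats(atr, cardiac_config)
        v = detect_beats(vent, cardiac_config)
        av, va = av_intervals(a, v)
        assert av + va == pytest.approx(a.ibis.mean(), abs=5.0)

    def test_missing_ventricular_beat_skips_cycle(self):
        a = BeatSeries("atrium", [0.0, 0.4, 0.8, 1.2])
        v = BeatSeries("ventricle", [0.1, 0.9])  # beat in (0.4, 0.8) missing
        av, va = av_intervals(a, v)
        assert av == pytest.approx(100.0)
        assert va == pytest.approx(300.0)

    def test_desynchronized_chambers_error(self):
        a = BeatSeries("atrium", [0.0, 0.1, 0.2])
        v = BeatSeries("ventricle", [5.0, 5.1])
        with pytest.raises(PairingError):
            av_intervals(a, v)
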