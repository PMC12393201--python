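"""Waveform physics: effective gradient, moments, b-value, Maxwell terms,
hardware validation, amplitude scaling and the first-order flow phase."""

import numpy as np
import pytest

from mcdpmrf import (
    GradientWaveform,
    HardwareLimits,
    bvalue,
    concomitant_residual,
    effective_gradient,
    flow_phase,
    moment,
    read_waveform,
    scale_to_b,
    validate,
    write_waveform,
)
from mcdpmrf.constants import GAMMA
from mcdpmrf.gradwave import InvalidTimingError

DT = 6.4e-6
XDIR = np.array([1.0, 0.0, 0.0])


def make_wave(samples, refocus=(), direction=None, dt=DT):
    return GradientWaveform(
        samples=np.asarray(samples, dtype=float),
        dt=dt,
        refocus_times=refocus,
        direction=direction if direction is not None else np.ones(3) / np.sqrt(3),
    )


def rect_lobe(n_total, start, width, amp, dt=DT):
    g = np.zeros(n_total)
    i0, i1 = int(round(start / dt)), int(round((start + width) / dt))
    g[i0:i1] = amp
    return g


class TestEffectiveGradient:
    def test_no_refocusing_is_identity(self):
        w = make_wave(np.sin(np.linspace(0, np.pi, 100)))
        assert np.array_equal(effective_gradient(w), w.samples)

    def test_single_refocus_flips_second_half(self):
        n = 101
        w = make_wave(np.full(n, 5.0), refocus=((n - 1) // 2 * DT,))
        g = effective_gradient(w)
        mid = (n - 1) // 2
        assert np.all(g[: mid + 1] == 5.0)  # sign toggles after the pulse center
        assert np.all(g[mid + 1 :] == -5.0)

    def test_two_refocus_brute_force_sign_count(self, rng):
        n = 400
        samples = rng.normal(size=n)
        refocus = (0.3 * (n - 1) * DT, 0.7 * (n - 1) * DT)
        w = make_wave(samples, refocus=refocus)
        g = effective_gradient(w)
        t = np.arange(n) * DT
        expected = samples * np.array(
            [(-1.0) ** sum(1 for r in refocus if r < ti) for ti in t]
        )
        assert np.allclose(g, expected)

    def test_refocus_outside_duration_raises(self):
        with pytest.raises(InvalidTimingError):
            make_wave(np.ones(10), refocus=(1.0,))


class TestMoments:
    def test_zero_waveform(self):
        w = make_wave(np.zeros(50))
        assert moment(w, 0) == 0.0
        assert moment(w, 1) == 0.0

    def test_rectangular_lobe_closed_form(self):
        n = 1001
        amp, width = 30.0, 200 * DT
        w = make_wave(rect_lobe(n, 100 * DT, width, amp))
        assert moment(w, 0) == pytest.approx(amp * width, rel=1e-2)

    def test_bipolar_m0_null_and_m1_fine_grid_oracle(self):
        n = 2001
        g = rect_lobe(n, 50 * DT, 300 * DT, 25.0) - rect_lobe(
            n, 900 * DT, 300 * DT, 25.0
        )
        w = make_wave(g)
        assert abs(moment(w, 0)) < 1e-10 * 25.0 * w.duration
        # independent fine-grid quadrature oracle (dt/16)
        fine = 16
        tf = np.arange((n - 1) * fine + 1) * (DT / fine)
        gf = np.interp(tf, w.times, g)
        m1_oracle = np.trapezoid(tf * gf, dx=DT / fine)
        assert moment(w, 1) == pytest.approx(m1_oracle, rel=1e-6, abs=1e-18)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_linearity_in_amplitude(self, order, rng):
        g = rng.normal(size=300)
        w = make_wave(g)
        w2 = make_wave(3.7 * g)
        assert moment(w2, order) == pytest.approx(3.7 * moment(w, order), rel=1e-12)


class TestBValue:
    def test_zero_waveform(self):
        assert bvalue(make_wave(np.zeros(100))) == 0.0

    def test_pgse_matches_stejskal_tanner(self):
        # raster-aligned lobes, long relative to the dwell so the sampled
        # rectangle's edge error is negligible
        delta, Delta, G = 3000 * DT, 3900 * DT, 30.0
        n = 7100
        g = rect_lobe(n, 100 * DT, delta, G) + rect_lobe(n, 100 * DT + Delta, delta, G)
        w = GradientWaveform(g, DT, refocus_times=(3550 * DT,), direction=XDIR)
        b_st = GAMMA**2 * (G * 1e-3) ** 2 * delta**2 * (Delta - delta / 3) * 1e-6
        # single-axis direction carries the sqrt(3) axis scale -> 3x shape b
        assert bvalue(w) == pytest.approx(3 * b_st, rel=1e-3)

    def test_quadratic_amplitude_scaling(self, rng):
        g = rng.normal(size=500)
        w = make_wave(g)
        assert bvalue(make_wave(2.0 * g)) == pytest.approx(4.0 * bvalue(w), rel=1e-9)

    def test_three_axis_rule(self, rng):
        g = np.abs(rng.normal(size=300))
        iso = make_wave(g)  # [1,1,1]/sqrt(3): full shape on each axis
        assert np.allclose(iso.axis_scales, 1.0)
        single = GradientWaveform(g, DT, direction=XDIR)
        # one axis at sqrt(3) amplitude gives the same total b
        assert bvalue(iso) == pytest.approx(bvalue(single), rel=1e-9)
        b_shape = bvalue(iso) / 3.0
        w_half = GradientWaveform(g, DT, direction=np.array([0.0, 1.0, 0.0]))
        assert bvalue(w_half) == pytest.approx(3 * b_shape, rel=1e-9)


class TestConcomitant:
    def test_symmetric_segments_cancel(self):
        n = 1201
        lobe = rect_lobe(n, 100 * DT, 200 * DT, 20.0)
        mirrored = lobe + lobe[::-1]
        w = make_wave(mirrored, refocus=((n - 1) / 2 * DT,))
        assert abs(concomitant_residual(w)) < 1e-12

    def test_single_segment_no_cancellation(self):
        n = 1201
        w = make_wave(
            rect_lobe(n, 50 * DT, 100 * DT, 20.0),
            refocus=(0.4 * (n - 1) * DT, 0.7 * (n - 1) * DT),
        )
        expected = 20.0**2 * 100 * DT
        assert concomitant_residual(w) == pytest.approx(expected, rel=1e-2)

    def test_random_waveform_per_sample_oracle(self, rng):
        n = 500
        g = rng.normal(size=n)
        refocus = (0.31 * (n - 1) * DT, 0.73 * (n - 1) * DT)
        w = make_wave(g, refocus=refocus)
        t = np.arange(n) * DT
        signs = np.array([(-1.0) ** sum(1 for r in refocus if r < ti) for ti in t])
        oracle = np.trapezoid(signs * g**2, dx=DT)
        assert concomitant_residual(w) == pytest.approx(oracle, rel=1e-12)


class TestValidate:
    def test_slew_violation_flagged(self):
        g = np.zeros(100)
        g[50] = 2 * 62.0  # a full-range step in one dwell
        report = validate(make_wave(g), HardwareLimits())
        assert not report.slew_ok

    def test_amplitude_violation_flagged(self):
        report = validate(make_wave(np.full(100, 80.0)), HardwareLimits())
        assert not report.amplitude_ok

    def test_rf_window_violation_flagged(self):
        w = GradientWaveform(
            np.full(100, 1.0), DT, rf_windows=((20 * DT, 40 * DT),)
        )
        assert not validate(w).rf_windows_ok


class TestScaleToB:
    def test_half_amplitude_quarters_b(self, rng):
        g = np.abs(rng.normal(size=400))
        w = make_wave(g)
        b = bvalue(w)
        assert bvalue(w.scaled(0.5)) == pytest.approx(b / 4, rel=1e-9)

    def test_scale_to_target(self, rng):
        w = make_wave(np.abs(rng.normal(size=400)) * 20)
        b0 = bvalue(w)
        target = 0.37 * b0
        assert bvalue(scale_to_b(w, target)) == pytest.approx(target, rel=1e-3)

    def test_scaling_preserves_moment_nulls(self):
        n = 2001
        g = rect_lobe(n, 50 * DT, 300 * DT, 25.0) - rect_lobe(
            n, 900 * DT, 300 * DT, 25.0
        )
        w = make_wave(g)
        scaled = scale_to_b(w, bvalue(w) * 0.25)
        assert abs(moment(scaled, 0)) <= 0.5 * abs(moment(w, 0)) + 1e-15

    def test_upscaling_rejected(self):
        w = make_wave(np.ones(100))
        with pytest.raises(ValueError):
            scale_to_b(w, bvalue(w) * 2)


class TestFlowPhase:
    def test_m0_only_waveform_velocity_phase(self):
        n = 2001
        g = rect_lobe(n, 50 * DT, 300 * DT, 25.0) - rect_lobe(
            n, 900 * DT, 300 * DT, 25.0
        )
        w = make_wave(g)  # bipolar: M0 = 0, M1 != 0
        v = 0.12
        assert flow_phase(w, x0=0.03, v=v) == pytest.approx(
            GAMMA * moment(w, 1) * 1e-3 * v, rel=1e-12
        )

    def test_random_waveform_per_sample_oracle(self, rng):
        g = rng.normal(size=300) * 10
        w = make_wave(g, refocus=(150 * DT,))
        x0, v = 0.02, -0.3
        ge = effective_gradient(w) * 1e-3
        t = w.times
        oracle = GAMMA * np.trapezoid(ge * (x0 + v * t), dx=DT)
        assert flow_phase(w, x0, v) == pytest.approx(oracle, rel=1e-9)


def test_waveform_io_roundtrip(tmp_path, rng):
    w = GradientWaveform(
        rng.normal(size=257) * 30,
        DT,
        refocus_times=(100 * DT, 200 * DT),
        rf_windows=((90 * DT, 110 * DT),),
    )
    path = tmp_path / "wave.txt"
    write_waveform(w, path)
    w2 = read_waveform(path)
    assert np.allclose(w2.samples, w.samples, rtol=1e-11)
    assert w2.dt == pytest.approx(w.dt, rel=1e-11)
    assert np.allclose(w2.refocus_times, w.refocus_times)
    assert np.allclose(w2.direction, w.direction)
    assert np.allclose(np.asarray(w2.rf_windows), np.asarray(w.rf_windows))
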