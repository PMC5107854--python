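"""Velocity estimation and Poincaré-section dispersion indices."""

import numpy as np
import pytest

import respstab as rs
from respstab.errors import AnalysisError, InputError

from conftest import make_sine_trace, make_tiled_trace


class TestEstimateVelocity:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / 25.0
        trace = rs.RespTrace(t=t, x=2.0 * t, fs=25.0)
        portrait = rs.estimate_velocity(trace)
        np.testing.assert_allclose(portrait.v[1:-1], 2.0, atol=1e-12)

    def test_constant_is_zero(self):
        t = np.arange(100) / 25.0
        trace = rs.RespTrace(t=t, x=np.full(100, 3.0), fs=25.0)
        portrait = rs.estimate_velocity(trace)
        np.testing.assert_array_equal(portrait.v, 0.0)

    def test_sinusoid_peak_speed(self, sine_trace):
        """max |v| of sin(2*pi*0.25*t) is 2*pi*0.25 within 0.5%."""
        portrait = rs.estimate_velocity(sine_trace)
        expected = 2 * np.pi * 0.25
        assert abs(np.max(np.abs(portrait.v)) - expected) < 0.005 * expected

    def test_smoothing_preserves_length(self, sine_trace):
        portrait = rs.estimate_velocity(sine_trace, smooth_window=7)
        assert len(portrait.x) == sine_trace.n
        assert len(portrait.v) == sine_trace.n

    def test_too_short_rejected(self):
        trace_like = rs.RespTrace(t=np.arange(2) / 25.0,
                                  x=np.array([0.0, 1.0]), fs=25.0)
        with pytest.raises(InputError):
            rs.estimate_velocity(trace_like)


class TestPoincareSection:
    @pytest.mark.parametrize("mode", ["turnaround", "midrange"])
    def test_exactly_periodic_trace_degenerates(self, mode):
        """Sample-commensurate strictly periodic trace: every crossing is
        the same sample of the cycle, so SD_x = SD_v = 0 exactly."""
        trace = make_tiled_trace()
        portrait = rs.estimate_velocity(trace)
        res = rs.poincare_section(portrait, mode=mode)
        assert res.sd_x == 0.0
        assert res.sd_v == 0.0

    def test_one_point_per_cycle(self):
        trace = make_tiled_trace(n_cycles=20)
        portrait = rs.estimate_velocity(trace)
        res = rs.poincare_section(portrait, mode="turnaround")
        assert abs(len(res.points) - 20) <= 1

    @pytest.mark.parametrize("mode", ["turnaround", "midrange"])
    def test_scaling_equivariance(self, mode):
        trace, _ = rs.generate_trace(rs.preset("C", drift=True, seed=4,
                                               duration=400.0))
        k = 2.5
        scaled = trace.copy(x=k * trace.x)
        r1 = rs.poincare_section(rs.estimate_velocity(trace), mode=mode)
        r2 = rs.poincare_section(rs.estimate_velocity(scaled), mode=mode)
        assert r2.sd_x == pytest.approx(k * r1.sd_x, abs=1e-9)
        assert r2.sd_v == pytest.approx(k * r1.sd_v, abs=1e-9)

    @pytest.mark.parametrize("mode", ["turnaround", "midrange"])
    def test_shift_invariance(self, mode):
        trace, _ = rs.generate_trace(rs.preset("B", seed=4, duration=400.0))
        shifted = trace.copy(x=trace.x + 5.0)
        r1 = rs.poincare_section(rs.estimate_velocity(trace), mode=mode)
        r2 = rs.poincare_section(rs.estimate_velocity(shifted), mode=mode)
        assert r2.sd_x == pytest.approx(r1.sd_x, abs=1e-9)
        assert r2.sd_v == pytest.approx(r1.sd_v, abs=1e-9)

    def test_time_reversal_maps_crossing_directions(self):
        """Downward crossings of the reversed trace correspond to upward
        crossings of the original.  The recorded discrete sample sits on
        the far side of the plane in each scan direction, so point sets
        match crossing-for-crossing (count within 1) and the dispersions
        agree closely; for an exactly periodic trace both are zero."""
        tiled = make_tiled_trace()
        rev0 = tiled.copy(x=tiled.x[::-1].copy())
        f0 = rs.poincare_section(rs.estimate_velocity(tiled),
                                 mode="midrange", direction="up")
        b0 = rs.poincare_section(rs.estimate_velocity(rev0),
                                 mode="midrange", direction="down")
        assert f0.sd_x == 0.0
        assert b0.sd_x < 1e-12

        trace = make_sine_trace(freq=0.23, duration=120.0)  # incommensurate
        rev = trace.copy(x=trace.x[::-1].copy())
        fwd = rs.poincare_section(rs.estimate_velocity(trace),
                                  mode="midrange", direction="up")
        bwd = rs.poincare_section(rs.estimate_velocity(rev),
                                  mode="midrange", direction="down")
        assert abs(len(bwd.points) - len(fwd.points)) <= 1
        assert bwd.sd_x == pytest.approx(fwd.sd_x, rel=0.15)

    def test_midrange_amplitude_jitter_shows_in_velocity(self):
        """With the section plane on x, the crossing x is pinned within
        one sample step of the plane while v at mid-rise scales with the
        cycle amplitude: amplitude jitter appears as sd_v, not sd_x."""
        trace, _ = rs.generate_trace(rs.preset("C", seed=3, noise_sd=0.0))
        res = rs.poincare_section(rs.estimate_velocity(trace),
                                  mode="midrange")
        assert res.sd_v > 0.05
        assert res.sd_x < 0.05
        # every recorded x is within one sample's excursion of the plane
        vmax = np.max(np.abs(rs.estimate_velocity(trace).v))
        assert np.max(np.abs(res.points[:, 0] - res.plane_level)) \
            <= vmax / trace.fs

    def test_turnaround_amplitude_jitter_shows_in_x(self):
        """The default end-of-inhale section puts amplitude jitter into
        sd_x, the dispersion the classifier thresholds."""
        regular, _ = rs.generate_trace(rs.preset("A", seed=3))
        irregular, _ = rs.generate_trace(rs.preset("C", seed=3))
        r_reg = rs.poincare_section(rs.estimate_velocity(regular,
                                                         smooth_window=5))
        r_irr = rs.poincare_section(rs.estimate_velocity(irregular,
                                                         smooth_window=5))
        assert r_irr.sd_x > 5 * r_reg.sd_x

    def test_drift_increases_sd_x(self):
        """Paired seeds: adding baseline drift spreads the section
        points along x."""
        plain, _ = rs.generate_trace(rs.preset("B", seed=5))
        drifting, _ = rs.generate_trace(rs.preset("B", drift=True, seed=5))
        r1 = rs.poincare_section(rs.estimate_velocity(plain,
                                                      smooth_window=5))
        r2 = rs.poincare_section(rs.estimate_velocity(drifting,
                                                      smooth_window=5))
        assert r2.sd_x > r1.sd_x

    def test_insufficient_crossings_rejected(self):
        t = np.arange(100) / 25.0
        portrait = rs.estimate_velocity(
            rs.RespTrace(t=t, x=t ** 2, fs=25.0))
        with pytest.raises(AnalysisError, match="Poincaré"):
            rs.poincare_section(portrait, mode="turnaround")

    def test_unknown_mode_rejected(self, sine_trace):
        portrait = rs.estimate_velocity(sine_trace)
        with pytest.raises(InputError):
            rs.poincare_section(portrait, mode="diagonal")
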