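"""Shared fixtures: analytic signals and synthetic archetype traces."""

from __future__ import annotations

import numpy as np
import pytest

import respstab as rs


def make_sine_trace(freq=0.25, duration=60.0, fs=25.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    x = amp * np.sin(2 * np.pi * freq * t + phase)
    return rs.RespTrace(t=t, x=x, fs=fs)


def make_tiled_trace(fs=25.0, period_samples=100, n_cycles=20, amp=1.0):
    """Exactly periodic sampled trace: one cycle tiled bit-identically."""
    phase = np.arange(period_samples) / period_samples
    cycle = amp * np.sin(np.pi * phase) ** 4
    x = np.tile(cycle, n_cycles)
    t = np.arange(len(x)) / fs
    return rs.RespTrace(t=t, x=x, fs=fs)


def make_damped_sine(lam, freq=0.25, duration=80.0, fs=25.0):
    """Exponentially contracting oscillation: LLE = -lam analytically."""
    t = np.arange(int(round(duration * fs))) / fs
    x = np.exp(-lam * t) * np.sin(2 * np.pi * freq * t)
    return rs.RespTrace(t=t, x=x, fs=fs)


def make_envelope_trace(rate, seed=0, n_cyc=40, fs=12.5, jitter=0.3):
    """Breathing whose cycle-amplitude scatter decays at ``rate`` (1/s):
    an initially irregular pattern regularizing toward a stable orbit."""
    rng = np.random.default_rng(seed)
    period = 4.0
    n = int(n_cyc * period * fs)
    t = np.arange(n) / fs
    x = np.empty(n)
    for i in range(n_cyc):
        dev = jitter * (1 + 0.3 * rng.normal())
        amp = 1.0 + dev * np.exp(-rate * i * period)
        k0 = int(np.ceil(i * period * fs - 1e-9))
        k1 = min(n, int(np.ceil((i + 1) * period * fs - 1e-9)))
        x[k0:k1] = amp * np.sin(np.pi * (t[k0:k1] - i * period) / period) ** 4
    return rs.RespTrace(t=t, x=x, fs=fs)


CANONICAL_PRESETS = (("A", False), ("B", False), ("C", True), ("D", True))


@pytest.fixture(scope="session")
def sine_trace():
    return make_sine_trace()


@pytest.fixture(scope="session")
def group_a_trace():
    trace, truth = rs.generate_trace(rs.preset("A", seed=1))
    return trace, truth


@pytest.fixture(scope="session")
def quiet_config():
    return rs.RunConfig(with_lle=False)
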