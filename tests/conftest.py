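import numpy as np
import pytest


def sinusoid_points(half_waves=2, length=300.0, amplitude=20.0, n=1200):
    """Fixed-length planar sinusoid family used across the geometry tests."""
    x = np.linspace(0.0, length, n)
    y = amplitude * np.sin(np.pi * half_waves * x / length)
    return np.column_stack([x, y])


def semicircle_points(radius=1.0, n=2001):
    t = np.linspace(0.0, np.pi, n)
    return np.column_stack([radius * np.sin(t), radius * (1.0 - np.cos(t))])


def s_curve_points(n_half=1001):
    """Two unit-radius semicircles joined at the inflection (an S)."""
    t = np.linspace(0.0, np.pi, n_half)
    a = np.column_stack([np.sin(t), 1.0 - np.cos(t)])
    b = np.column_stack([-np.sin(t), 3.0 - np.cos(t)])
    return np.vstack([a, b[1:]])


def digitized_circle(radius=20, n=4000):
    """8-connected pixel chain approximating a circle."""
    t = np.linspace(0.0, 2.0 * np.pi, n)
    pix = np.round(np.column_stack([radius * np.cos(t), radius * np.sin(t)]))
    keep = np.concatenate([[True], np.any(np.diff(pix, axis=0) != 0, axis=1)])
    return pix[keep]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
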