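"""Unit and property tests for the tortuosity geometry core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinotort.geometry import (
    DegenerateGeometryError,
    InvalidParameterError,
    InvalidPolylineError,
    Polyline2D,
    arc_length,
    chain_code_curvature,
    chord_length,
    grisan_tortuosity,
    hart_tortuosity,
    integrate_tree,
    measure_vessel,
    onkaew_tortuosity,
    partition_constant_sign,
    resample_polyline,
    signed_curvature,
    smooth_polyline,
    trucco_tortuosity,
)

from conftest import (
    digitized_circle,
    s_curve_points,
    semicircle_points,
    sinusoid_points,
)


# ---------------------------------------------------------------------------
# lengths and Hart


@pytest.mark.parametrize(
    "points,expected",
    [
        ([(0, 0), (3, 4)], 5.0),
        ([(0, 0), (1, 1), (2, 0)], 2.0 * np.sqrt(2.0)),
    ],
)
def test_arc_length_hand_examples(points, expected):
    assert arc_length(np.asarray(points, float)) == pytest.approx(expected)


def test_arc_length_semicircle_converges():
    pts = semicircle_points(radius=1.0, n=1000)
    assert arc_length(pts) == pytest.approx(np.pi, rel=1e-4)


@pytest.mark.parametrize(
    "points,expected",
    [
        ([(0, 0), (1, 1), (2, 0)], 2.0),
        ([(0, 0), (3, 4)], 5.0),
    ],
)
def test_chord_length_examples(points, expected):
    assert chord_length(np.asarray(points, float)) == pytest.approx(expected)


def test_polyline_rejects_degenerate_input():
    with pytest.raises(InvalidPolylineError):
        Polyline2D(np.array([[1.0, 2.0]]))
    with pytest.raises(InvalidPolylineError):
        Polyline2D(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))


def test_hart_examples():
    x = np.linspace(0.0, 50.0, 37)
    straight = np.column_stack([x, 2.0 * x + 1.0])
    assert hart_tortuosity(straight) == pytest.approx(0.0, abs=1e-12)
    tri = np.array([(0.0, 0.0), (1.0, 1.0), (2.0, 0.0)])
    assert hart_tortuosity(tri) == pytest.approx(np.sqrt(2.0) - 1.0)
    assert hart_tortuosity(semicircle_points()) == pytest.approx(
        np.pi / 2.0 - 1.0, abs=1e-3
    )


def test_hart_rejects_closed_curve():
    t = np.linspace(0.0, 2.0 * np.pi, 100)
    loop = np.column_stack([np.cos(t), np.sin(t)])
    with pytest.raises(DegenerateGeometryError):
        hart_tortuosity(loop)


def test_hart_similarity_invariance():
    pts = sinusoid_points(3)
    base = hart_tortuosity(pts)
    th = 0.91
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    assert hart_tortuosity(pts @ rot.T + [11.0, -4.0]) == pytest.approx(base, rel=1e-9)
    assert hart_tortuosity(pts * 17.3) == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# derivative curvature


def test_curvature_zero_on_straight_line():
    x = np.linspace(0.0, 100.0, 200)
    prof = signed_curvature(np.column_stack([x, 0.3 * x]))
    assert np.all(np.abs(prof.values) < 1e-9)


def test_curvature_of_unit_circle():
    t = np.linspace(0.0, 2.0 * np.pi, 500)
    pts = np.column_stack([np.cos(t), np.sin(t)])
    prof = signed_curvature(pts, spacing=0.0126, sigma=0.05)
    # interior = clear of the ~3*sigma boundary region of the open curve
    interior = np.abs(prof.values[15:-15])
    assert np.all(np.abs(interior - 1.0) < 0.02)


def test_curvature_of_parabola_vertex():
    x = np.linspace(-0.5, 0.5, 801)
    prof = signed_curvature(np.column_stack([x, x * x]), spacing=0.002, sigma=0.01)
    mid = len(prof.values) // 2
    assert abs(prof.values[mid]) == pytest.approx(2.0, rel=0.02)


def test_curvature_sign_flips_on_reversal():
    pts = sinusoid_points(2)
    f = signed_curvature(pts).values
    b = signed_curvature(pts[::-1]).values
    assert np.allclose(f, -b[::-1], atol=1e-9)


def test_curvature_needs_enough_points():
    with pytest.raises(InvalidPolylineError):
        signed_curvature(np.array([(0.0, 0.0), (1.0, 0.0)]), n_samples=3)


# ---------------------------------------------------------------------------
# constant-sign partitioning


def test_partition_straight_line_single_run():
    x = np.linspace(0.0, 80.0, 300)
    prof = signed_curvature(np.column_stack([x, np.zeros_like(x)]))
    part = partition_constant_sign(prof)
    assert part.n == 1
    assert part.ranges[0] == (0, len(prof.values) - 1)


def test_partition_sine_period_two_runs():
    x = np.linspace(0.0, 2.0 * np.pi, 1500)
    prof = signed_curvature(np.column_stack([x, np.sin(x)]), spacing=0.02, sigma=0.1)
    assert partition_constant_sign(prof).n == 2


def test_partition_arc_single_run():
    phi = np.linspace(0.0, 1.5, 800)
    pts = np.column_stack([100.0 * np.sin(phi), 100.0 * (1.0 - np.cos(phi))])
    assert partition_constant_sign(signed_curvature(pts)).n == 1


def test_partition_covers_polyline_and_conserves_arc():
    pts = sinusoid_points(5)
    prof = signed_curvature(pts)
    part = partition_constant_sign(prof)
    assert part.ranges[0][0] == 0
    assert part.ranges[-1][1] == len(prof.values) - 1
    for (_, stop), (start, _) in zip(part.ranges[:-1], part.ranges[1:]):
        assert start == stop  # shared boundary points
    assert part.arc_lengths.sum() == pytest.approx(prof.polyline.arc_length)
    assert np.all(part.arc_lengths >= part.chord_lengths - 1e-9)


# ---------------------------------------------------------------------------
# Grisan


def test_grisan_zero_for_single_convexity_arc():
    phi = np.linspace(0.0, 1.5, 800)
    pts = np.column_stack([100.0 * np.sin(phi), 100.0 * (1.0 - np.cos(phi))])
    assert grisan_tortuosity(pts) == 0.0


def test_grisan_s_curve_analytic():
    value = grisan_tortuosity(s_curve_points(), spacing=0.01, sigma=0.05)
    assert value == pytest.approx((np.pi - 2.0) / (2.0 * np.pi), abs=1e-2)


def test_grisan_increases_with_inflections():
    vals = [grisan_tortuosity(sinusoid_points(h)) for h in (2, 4, 6)]
    assert vals[0] < vals[1] < vals[2]


def test_grisan_scales_as_inverse_length():
    pts = sinusoid_points(4)
    s = 3.7
    base = grisan_tortuosity(pts)
    scaled = grisan_tortuosity(pts * s, spacing=s, sigma=4.0 * s, zero_tol=1e-3 / s)
    assert base / scaled == pytest.approx(s, rel=1e-3)


# ---------------------------------------------------------------------------
# Trucco


def test_trucco_zero_on_straight_line():
    x = np.linspace(0.0, 60.0, 100)
    assert trucco_tortuosity(np.column_stack([x, np.zeros_like(x)])) == pytest.approx(
        0.0, abs=1e-9
    )


@pytest.mark.parametrize("p,expected", [(1, 100.0), (2, 10.0)])
def test_trucco_quarter_circle(p, expected):
    phi = np.linspace(0.0, np.pi / 2.0, 2000)
    pts = np.column_stack([np.cos(phi), np.sin(phi)])
    # 104 samples -> 100 interior points once the two boundary points per
    # end are excluded; each carries |k| ~ 1 on the unit circle
    value = trucco_tortuosity(pts, p=p, sigma=0.03, n_samples=104)
    assert value == pytest.approx(expected, rel=0.03)


def test_trucco_rejects_bad_exponent():
    pts = sinusoid_points(2, n=50)
    with pytest.raises(InvalidParameterError):
        trucco_tortuosity(pts, p=0)
    with pytest.raises(InvalidParameterError):
        trucco_tortuosity(pts, p=1.5)


# ---------------------------------------------------------------------------
# chain-code curvature and Onkaew


def test_chain_code_zero_on_straight_run():
    pts = np.column_stack([np.arange(20.0), np.zeros(20)])
    prof = chain_code_curvature(pts, k=1)
    assert np.all(prof.values == 0.0)


def test_chain_code_right_angle_corner():
    pts = np.array(
        [(float(x), 0.0) for x in range(11)] + [(10.0, float(y)) for y in range(1, 11)]
    )
    prof = chain_code_curvature(pts, k=1)
    nz = np.flatnonzero(prof.values)
    assert list(nz) == [10]
    assert abs(prof.values[10]) == pytest.approx(np.pi / 2.0)


def test_chain_code_digitized_circle_mean_curvature():
    r = 20
    prof = chain_code_curvature(digitized_circle(radius=r), k=3)
    mean_k = np.abs(prof.values).mean()
    assert abs(mean_k - 1.0 / r) / (1.0 / r) < 0.25
    # full circle has single-convexity turning: one constant-sign run
    assert partition_constant_sign(prof).n == 1


def test_chain_code_rejects_oversized_window():
    pts = np.column_stack([np.arange(10.0), np.zeros(10)])
    with pytest.raises(InvalidParameterError):
        chain_code_curvature(pts, k=6)


def test_onkaew_zero_for_straight_and_single_arc():
    x = np.linspace(0.0, 60.0, 61)
    assert onkaew_tortuosity(np.column_stack([x, np.zeros_like(x)])) == 0.0
    phi = np.linspace(0.0, 1.5, 400)
    arc = np.column_stack([100.0 * np.sin(phi), 100.0 * (1.0 - np.cos(phi))])
    assert onkaew_tortuosity(arc) == 0.0


def _onkaew_oracle(points, k):
    """Independent loop-based chain-code tortuosity: windowed turning angle,
    sign-run count, (n-1)/n * sum|K| / L."""
    pts = np.asarray(points, float)
    angles = []
    for i in range(len(pts) - 1):
        d = pts[i + 1] - pts[i]
        angles.append(np.arctan2(d[1], d[0]))
    turns = []
    for i in range(1, len(angles)):
        t = angles[i] - angles[i - 1]
        while t <= -np.pi:
            t += 2 * np.pi
        while t > np.pi:
            t -= 2 * np.pi
        turns.append(t)
    m = len(pts)
    K = [0.0] * m
    w = 2 * k - 1
    for i in range(m):
        lo = i - k
        hi = i + k - 2
        if lo >= 0 and hi < len(turns):
            K[i] = sum(turns[lo : hi + 1]) / w
    # sign runs with zero-tolerance inheritance and min-run merging (>= 5)
    signs = [0 if abs(v) < 1e-3 else (1 if v > 0 else -1) for v in K]
    runs = []
    cur = None
    for s in signs:
        if s == 0:
            if runs:
                runs[-1][1] += 1
            else:
                runs.append([0, 1])
                cur = 0
            continue
        if cur in (s, 0) and runs:
            if cur == 0:
                runs[-1][0] = s
            runs[-1][1] += 1
            cur = s
        else:
            runs.append([s, 1])
            cur = s
    runs = [r for r in runs]
    merged = True
    while merged and len(runs) > 1:
        merged = False
        for i, (s, ln) in enumerate(runs):
            if ln < 5:
                j = i - 1 if (i > 0 and (i == len(runs) - 1 or runs[i - 1][1] >= runs[i + 1][1])) else i + 1
                runs[j][1] += ln
                del runs[i]
                # coalesce equal-sign neighbours
                i2 = 1
                while i2 < len(runs):
                    if runs[i2][0] == runs[i2 - 1][0]:
                        runs[i2 - 1][1] += runs[i2][1]
                        del runs[i2]
                    else:
                        i2 += 1
                merged = True
                break
    n = len(runs)
    if n == 1:
        return 0.0
    L = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return (n - 1) / n * sum(abs(v) for v in K) / L


def test_onkaew_increases_with_inflections_and_matches_oracle():
    values = []
    for hw in (2, 4, 6):  # 1, 3, 5 inflections at fixed length
        pts = resample_polyline(sinusoid_points(hw), spacing=1.0).points
        v = onkaew_tortuosity(pts, k=5, spacing=None)
        assert v == pytest.approx(_onkaew_oracle(pts, k=5), rel=1e-9)
        values.append(v)
    assert values[0] < values[1] < values[2]


def test_onkaew_scales_as_inverse_length():
    pts = sinusoid_points(4)
    s = 3.7
    assert onkaew_tortuosity(pts) / onkaew_tortuosity(pts * s, spacing=s) == (
        pytest.approx(s, rel=1e-3)
    )


# ---------------------------------------------------------------------------
# tree integration


def test_integrate_tree_examples():
    assert integrate_tree([0.7], [12.0]) == pytest.approx(0.7)
    assert integrate_tree([0.2, 0.6], [5.0, 5.0]) == pytest.approx(0.4)
    assert integrate_tree([0.2, 0.6], [1.0, 3.0]) == pytest.approx(0.5)


def test_integrate_tree_errors():
    from retinotort.geometry import EmptyTreeError

    with pytest.raises(EmptyTreeError):
        integrate_tree([], [])
    with pytest.raises(InvalidParameterError):
        integrate_tree([0.1, 0.2], [1.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0.0, 5.0, allow_nan=False),
            st.floats(0.1, 100.0, allow_nan=False),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_integrate_tree_stays_within_input_range(pairs):
    values = [v for v, _ in pairs]
    lengths = [l for _, l in pairs]
    total = integrate_tree(values, lengths)
    assert min(values) - 1e-12 <= total <= max(values) + 1e-12


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_preserves_straight_line():
    x = np.linspace(0.0, 30.0, 31)
    pts = np.column_stack([x, 1.5 * x])
    out = smooth_polyline(pts, window=5)
    assert np.allclose(out.points, pts, atol=1e-9)


def test_smooth_reduces_staircase_tortuosity():
    steps = [(0.0, 0.0)]
    for i in range(40):  # rasterized diagonal: east, north, east, north ...
        x, y = steps[-1]
        steps.append((x + 1.0, y) if i % 2 == 0 else (x, y + 1.0))
    stair = np.asarray(steps)
    assert hart_tortuosity(smooth_polyline(stair, window=3)) < hart_tortuosity(stair)


def test_smooth_attenuates_zigzag():
    x = np.arange(0.0, 30.0)
    zig = np.column_stack([x, np.where(x.astype(int) % 2 == 0, 1.0, -1.0)])
    out = smooth_polyline(zig, window=3)
    assert np.abs(out.points[1:-1, 1]).max() < 0.5


def test_smooth_rejects_bad_window():
    pts = np.column_stack([np.arange(10.0), np.zeros(10)])
    with pytest.raises(InvalidParameterError):
        smooth_polyline(pts, window=0)


# ---------------------------------------------------------------------------
# cross-metric invariance properties


def test_all_metrics_invariant_under_rigid_motion_and_reversal():
    pts = sinusoid_points(4)
    th = 0.37
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = pts @ rot.T + [13.5, -7.2]
    for f in (hart_tortuosity, grisan_tortuosity, trucco_tortuosity, onkaew_tortuosity):
        base = f(pts)
        assert abs(f(moved) - base) / base < 1e-6
        assert abs(f(pts[::-1]) - base) / base < 1e-6


def test_measure_vessel_returns_all_four_metrics():
    vt = measure_vessel(sinusoid_points(4))
    assert vt.hart > 0 and vt.grisan > 0 and vt.trucco > 0 and vt.onkaew > 0


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_random_walk_polyline_invariants(seed):
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(rng.integers(2, 40), 2))
    steps = steps[np.linalg.norm(steps, axis=1) > 1e-6]
    if len(steps) < 2:
        return
    pts = np.cumsum(steps, axis=0)
    pl = Polyline2D(pts)
    assert pl.arc_length >= pl.chord_length - 1e-12
    if pl.chord_length > 1e-9:
        assert hart_tortuosity(pl) >= 0.0
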