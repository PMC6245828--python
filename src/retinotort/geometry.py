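"""Discrete-geometry core for vessel-centerline tortuosity.

This module implements the four reference tortuosity measures used in
computer-aided retinal image analysis, all defined on an ordered 2-D
centerline (a :class:`Polyline2D`):

* **Hart** -- the arc-to-chord ratio ``L_c / L_x - 1``; dimensionless and
  scale invariant.
* **Grisan** -- partitions the vessel into ``n`` subsegments of constant-sign
  curvature and combines their arc/chord excesses with the subsegment count,
  ``(n - 1) / L_c * sum_i (L_csi / L_xsi - 1)``; behaves as a tortuosity
  density (units 1/pixel).
* **Trucco** -- an L^p aggregate of the pointwise curvature magnitude,
  ``(sum_j |k_s(j)|^p)^(1/p)``.
* **Onkaew** -- ``(n - 1)/n * 1/L_c * sum_i K(p_i, k)`` where ``K`` is a
  chain-code style curvature (windowed turning angle per step) and ``n`` the
  number of constant-sign runs of that curvature.

Per-vessel values are merged into a whole-tree score by arc-length-weighted
averaging (:func:`integrate_tree`), so the total always lies within the range
of the per-vessel values.

Coordinates are ``(x, y)`` with x to the right and y down, 0-based pixel
units; sub-pixel positions are allowed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "Polyline2D",
    "CurvatureProfile",
    "SubsegmentPartition",
    "VesselTortuosity",
    "TreeTortuosity",
    "MetricConfig",
    "InvalidPolylineError",
    "DegenerateGeometryError",
    "InvalidParameterError",
    "EmptyTreeError",
    "arc_length",
    "chord_length",
    "hart_tortuosity",
    "resample_polyline",
    "signed_curvature",
    "partition_constant_sign",
    "grisan_tortuosity",
    "trucco_tortuosity",
    "chain_code_curvature",
    "onkaew_tortuosity",
    "integrate_tree",
    "smooth_polyline",
    "measure_vessel",
    "measure_polylines",
]


class InvalidPolylineError(ValueError):
    """A point sequence cannot form a valid centerline."""


class DegenerateGeometryError(ValueError):
    """A geometric quantity is undefined (e.g. zero chord of a closed curve)."""


class InvalidParameterError(ValueError):
    """A tuning parameter is outside its documented range."""


class EmptyTreeError(ValueError):
    """A tree-level operation received no measurable vessels."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidPolylineError("points must be an (m, 2) array of (x, y)")
    if pts.shape[0] < 2:
        raise InvalidPolylineError("a centerline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise InvalidPolylineError("points must be finite")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(steps == 0.0):
        raise InvalidPolylineError("consecutive points must be distinct")
    return pts


@dataclass(frozen=True)
class Polyline2D:
    """Ordered sub-pixel centerline of one vessel.

    Satisfies ``arc_length >= chord_length`` (triangle inequality), with
    equality only for points collinear in order.
    """

    points: np.ndarray
    id: str = "vessel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", _as_points(self.points))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def arc_length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum()
        )

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def reversed(self) -> "Polyline2D":
        return Polyline2D(self.points[::-1].copy(), id=self.id)


def _coerce(polyline) -> Polyline2D:
    if isinstance(polyline, Polyline2D):
        return polyline
    return Polyline2D(polyline)


@dataclass(frozen=True)
class CurvatureProfile:
    """Per-point signed curvature of a (possibly resampled) centerline.

    ``values`` has one entry per point of ``polyline``; units are 1/pixel for
    the derivative method and radians per step for the chain-code method.
    Boundary points carry the fill value 0 and are excluded from the
    Trucco/Onkaew sums by construction.
    """

    values: np.ndarray
    method: str
    window: float
    polyline: Polyline2D

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.polyline),):
            raise InvalidPolylineError(
                "curvature profile length must match its polyline"
            )
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SubsegmentPartition:
    """Decomposition of a centerline into constant-sign curvature runs.

    ``ranges`` are inclusive ``(start, stop)`` point-index spans; consecutive
    ranges share their boundary point so the subsegment arc lengths sum to the
    total arc length.
    """

    ranges: tuple
    arc_lengths: np.ndarray
    chord_lengths: np.ndarray
    polyline: Polyline2D

    @property
    def n(self) -> int:
        return len(self.ranges)


@dataclass(frozen=True)
class VesselTortuosity:
    """The four reference tortuosity values for one vessel."""

    hart: float
    grisan: float
    trucco: float
    onkaew: float
    p: int = 1


@dataclass(frozen=True)
class TreeTortuosity:
    """Per-vessel metric values plus length-weighted totals for a tree."""

    per_vessel: dict
    totals: dict
    weights: dict
    dropped: tuple = ()


@dataclass(frozen=True)
class MetricConfig:
    """Tuning parameters shared by the four metrics.

    spacing
        arc-length resampling step for curvature estimation, pixels.
    sigma
        Gaussian coordinate-smoothing scale before differentiation, pixels
        of arc length.
    zero_tol
        |curvature| below which a point is treated as sign-neutral during
        partitioning, 1/pixel.
    min_run
        constant-sign runs shorter than this many points are merged into the
        longer neighbour (suppresses noise-driven inflections).
    p
        Trucco exponent, strictly positive integer.
    chain_k
        neighbourhood half-width of the chain-code curvature window, points.
    min_vessel_points
        vessels with fewer input points are excluded from tree totals.
    smooth_window
        moving-average window used when smoothing raw traced centerlines.
    """

    spacing: float = 1.0
    sigma: float = 4.0
    zero_tol: float = 1e-3
    min_run: int = 5
    p: int = 1
    chain_k: int = 5
    min_vessel_points: int = 10
    smooth_window: int = 5
    normalize_by_n: bool = False


# ---------------------------------------------------------------------------
# lengths and the Hart metric


def arc_length(polyline) -> float:
    """Total length along the centerline path, pixels."""
    return _coerce(polyline).arc_length


def chord_length(polyline) -> float:
    """Euclidean distance between the two endpoints, pixels."""
    return _coerce(polyline).chord_length


def hart_tortuosity(polyline) -> float:
    """Arc-to-chord excess ``L_c / L_x - 1``.

    Zero exactly for collinear (in-order) samplings; invariant under rigid
    motion and uniform scaling.  Raises :class:`DegenerateGeometryError` for
    closed curves (zero chord).
    """
    pl = _coerce(polyline)
    lx = pl.chord_length
    if lx <= 1e-12:
        raise DegenerateGeometryError(
            f"vessel {pl.id!r}: zero chord length (closed curve)"
        )
    return pl.arc_length / lx - 1.0


# ---------------------------------------------------------------------------
# resampling, smoothing and derivative curvature


def resample_polyline(polyline, spacing: float = 1.0, n_samples: int | None = None) -> Polyline2D:
    """Resample to uniform arc-length steps by linear interpolation.

    The sample positions are ``linspace(0, L, m)`` so the operation commutes
    with reversing the point order.
    """
    pl = _coerce(polyline)
    pts = pl.points
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    if n_samples is None:
        if spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        n_samples = max(int(round(total / spacing)) + 1, 2)
    if n_samples < 2:
        raise InvalidParameterError("need at least 2 samples")
    t = np.linspace(0.0, total, n_samples)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    out = np.column_stack([x, y])
    # guard against collapsed consecutive samples (can only happen for
    # pathological inputs shorter than floating-point resolution)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(out, axis=0), axis=1) > 0])
    return Polyline2D(out[keep], id=pl.id)


def smooth_polyline(points, window: int = 5, id: str | None = None) -> Polyline2D:
    """Moving-average smoothing of coordinates, endpoints preserved.

    A centered boxcar of ``window`` points low-passes the staircase artifacts
    of pixel-grid tracing; straight uniformly sampled runs pass unchanged.
    """
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    pl = _coerce(points)
    pts = pl.points
    m = len(pl)
    if m < window:
        raise InvalidPolylineError("polyline shorter than the smoothing window")
    # centered boxcar with the half-width shrunk near the ends, so the
    # endpoints are preserved exactly and uniformly sampled linear runs pass
    # through unchanged at every index
    half = (window - 1) // 2
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(pts, axis=0)])
    idx = np.arange(m)
    k = np.minimum(half, np.minimum(idx, m - 1 - idx))
    lo = idx - k
    hi = idx + k
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(out, axis=0), axis=1) > 0]
    )
    keep[-1] = True
    out = out[keep]
    if out.shape[0] >= 2 and np.all(out[-1] == out[-2]):
        out = np.delete(out, -2, axis=0)
    return Polyline2D(out, id=id if id is not None else pl.id)


def signed_curvature(
    polyline,
    spacing: float = 1.0,
    sigma: float = 4.0,
    n_samples: int | None = None,
) -> CurvatureProfile:
    """Signed curvature ``k = (x'y'' - x''y') / (x'^2 + y'^2)^(3/2)``.

    The polyline is resampled to uniform arc-length steps (``spacing`` px, or
    a fixed ``n_samples``), coordinates are smoothed with a Gaussian of scale
    ``sigma`` (arc-length px), and derivatives taken by central differences.
    The first and last two points receive the fill value 0.  The sign flips
    when the traversal direction is reversed; the magnitude does not.
    """
    rp = resample_polyline(polyline, spacing=spacing, n_samples=n_samples)
    m = len(rp)
    if m < 5:
        raise InvalidPolylineError(
            "need at least 5 points after resampling for curvature"
        )
    h = rp.arc_length / (m - 1)
    pts = rp.points
    if sigma > 0:
        sig_samples = sigma / h
        xs = gaussian_filter1d(pts[:, 0], sig_samples, mode="nearest")
        ys = gaussian_filter1d(pts[:, 1], sig_samples, mode="nearest")
    else:
        xs, ys = pts[:, 0], pts[:, 1]
    x1 = np.gradient(xs, h)
    y1 = np.gradient(ys, h)
    x2 = np.gradient(x1, h)
    y2 = np.gradient(y1, h)
    denom = (x1 * x1 + y1 * y1) ** 1.5
    k = np.zeros(m)
    ok = denom > 1e-12
    k[ok] = (x1[ok] * y2[ok] - x2[ok] * y1[ok]) / denom[ok]
    k[:2] = 0.0
    k[-2:] = 0.0
    return CurvatureProfile(values=k, method="derivative", window=sigma, polyline=rp)


# ---------------------------------------------------------------------------
# constant-sign partitioning and the Grisan metric


def _merge_adjacent_same_sign(runs):
    out = [runs[0]]
    for start, stop, sign in runs[1:]:
        pstart, pstop, psign = out[-1]
        if sign == psign:
            out[-1] = (pstart, stop, psign)
        else:
            out.append((start, stop, sign))
    return out


def partition_constant_sign(
    profile: CurvatureProfile,
    min_run: int = 5,
    zero_tol: float = 1e-4,
) -> SubsegmentPartition:
    """Split a curvature profile into maximal constant-sign runs.

    Points with ``|k| < zero_tol`` inherit the sign of the surrounding run; a
    profile that is zero everywhere forms a single subsegment.  Runs shorter
    than ``min_run`` points are merged into the longer neighbour so that
    noise-driven micro-inflections do not inflate the subsegment count.
    """
    k = profile.values
    m = k.shape[0]
    signs = np.where(np.abs(k) < zero_tol, 0, np.sign(k)).astype(int)
    nz = np.flatnonzero(signs)
    if nz.size == 0:
        runs = [(0, m - 1, 0)]
    else:
        filled = signs.copy()
        # zeros inherit the sign of the previous non-zero point; leading
        # zeros take the first run's sign
        idx = np.searchsorted(nz, np.arange(m), side="right") - 1
        idx = np.clip(idx, 0, nz.size - 1)
        filled = signs[nz[idx]]
        change = np.flatnonzero(np.diff(filled)) + 1
        bounds = np.concatenate([[0], change, [m]])
        runs = [
            (int(bounds[i]), int(bounds[i + 1]) - 1, int(filled[bounds[i]]))
            for i in range(len(bounds) - 1)
        ]
        runs = _merge_adjacent_same_sign(runs)
        # iteratively absorb short runs into the longer neighbour
        while len(runs) > 1:
            lengths = [stop - start + 1 for start, stop, _ in runs]
            short = [i for i, ln in enumerate(lengths) if ln < min_run]
            if not short:
                break
            i = min(short, key=lambda j: (lengths[j], j))
            if i == 0:
                j = 1
            elif i == len(runs) - 1:
                j = i - 1
            else:
                j = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
            lo, hi = min(i, j), max(i, j)
            start = runs[lo][0]
            stop = runs[hi][1]
            sign = runs[j][2]
            runs = runs[:lo] + [(start, stop, sign)] + runs[hi + 1 :]
            runs = _merge_adjacent_same_sign(runs)
    # subsegments share boundary points so their arc lengths sum to L_c
    bounds = [0] + [stop for _, stop, _ in runs[:-1]] + [m - 1]
    pts = profile.polyline.points
    ranges = []
    arcs = []
    chords = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        b = max(b, a + 1)
        ranges.append((a, b))
        seg = pts[a : b + 1]
        arcs.append(float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum()))
        chords.append(float(np.linalg.norm(seg[-1] - seg[0])))
    return SubsegmentPartition(
        ranges=tuple(ranges),
        arc_lengths=np.asarray(arcs),
        chord_lengths=np.asarray(chords),
        polyline=profile.polyline,
    )


def grisan_tortuosity(
    polyline,
    spacing: float = 1.0,
    sigma: float = 4.0,
    zero_tol: float = 1e-3,
    min_run: int = 5,
    normalize_by_n: bool = False,
) -> float:
    """Constant-sign subsegment tortuosity density, units 1/pixel.

    ``tau = (n - 1) / L_c * sum_i (L_csi / L_xsi - 1)`` over the ``n``
    constant-sign curvature subsegments; zero whenever ``n == 1``.  With
    ``normalize_by_n`` the historical ``(n - 1) / n`` prefactor variant is
    used instead of the plain ``n - 1``.
    """
    profile = signed_curvature(polyline, spacing=spacing, sigma=sigma)
    part = partition_constant_sign(profile, min_run=min_run, zero_tol=zero_tol)
    n = part.n
    if n == 1:
        return 0.0
    if np.any(part.chord_lengths <= 1e-12):
        raise DegenerateGeometryError("subsegment with zero chord length")
    excess = float(np.sum(part.arc_lengths / part.chord_lengths - 1.0))
    lc = profile.polyline.arc_length
    prefactor = (n - 1) / n if normalize_by_n else (n - 1)
    return prefactor / lc * excess


# ---------------------------------------------------------------------------
# Trucco curvature aggregate


def trucco_tortuosity(
    polyline,
    p: int = 1,
    spacing: float = 1.0,
    sigma: float = 4.0,
    n_samples: int | None = None,
) -> float:
    """L^p aggregate of |curvature| over interior resampled points.

    ``tau = (sum_j |k_s(j)|^p)^(1/p)`` with ``p`` a strictly positive
    integer.  Depends only on the centerline curvature, not on chord lengths.
    """
    if not isinstance(p, (int, np.integer)) or p < 1:
        raise InvalidParameterError("p must be a strictly positive integer")
    profile = signed_curvature(
        polyline, spacing=spacing, sigma=sigma, n_samples=n_samples
    )
    mag = np.abs(profile.values)  # boundary fill zeros contribute nothing
    return float(np.sum(mag**p) ** (1.0 / p))


# ---------------------------------------------------------------------------
# chain-code curvature and the Onkaew metric


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def chain_code_curvature(polyline, k: int = 1, spacing: float | None = None) -> CurvatureProfile:
    """Chain-code style curvature: windowed turning angle per step.

    Each step of the (optionally resampled) polyline is labelled by its
    direction relative to the previous point; on an 8-connected pixel chain
    these directions are exactly the eight Freeman code angles (multiples of
    45 degrees, counter-clockwise from east).  The curvature at an interior
    point is the mean signed turning angle over a window of half-width ``k``
    points, in radians per point; it is zero along straight runs.  Boundary
    points where the window does not fit carry the fill value 0.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidParameterError("k must be a positive integer")
    pl = _coerce(polyline)
    if spacing is not None:
        pl = resample_polyline(pl, spacing=spacing)
    pts = pl.points
    m = pts.shape[0]
    if k > (m - 1) // 2:
        raise InvalidParameterError(
            f"window half-width k={k} too large for a {m}-point polyline"
        )
    d = np.diff(pts, axis=0)
    ang = np.arctan2(d[:, 1], d[:, 0])  # one angle per step
    turn = _wrap_angle(np.diff(ang))  # turn at interior point i -> turn[i-1]
    vals = np.zeros(m)
    w = 2 * k - 1
    if turn.size >= w:
        means = uniform_filter1d(turn, size=w, mode="constant", origin=0)
        # valid centered windows: turn indices k-1 .. len(turn)-k
        lo, hi = k - 1, turn.size - k
        vals[lo + 1 : hi + 2] = means[lo : hi + 1]
    return CurvatureProfile(values=vals, method="chain_code", window=k, polyline=pl)


def onkaew_tortuosity(
    polyline,
    k: int = 5,
    spacing: float | None = 1.0,
    min_run: int = 5,
    zero_tol: float = 1e-4,
) -> float:
    """Chain-code tortuosity density, units 1/pixel.

    ``tau = (n - 1)/n * 1/L_c * sum_i |K(p_i, k)|`` where ``n`` is the number
    of constant-sign runs of the chain-code curvature and the sum runs over
    all points.  Zero when the curvature never changes sign (``n == 1``).
    """
    profile = chain_code_curvature(polyline, k=k, spacing=spacing)
    part = partition_constant_sign(profile, min_run=min_run, zero_tol=zero_tol)
    n = part.n
    if n == 1:
        return 0.0
    lc = profile.polyline.arc_length
    return (n - 1) / n * float(np.sum(np.abs(profile.values))) / lc


# ---------------------------------------------------------------------------
# tree integration


def integrate_tree(values, lengths) -> float:
    """Arc-length-weighted average ``sum L_ci tau_ci / sum L_ci``.

    The N-vessel generalization of the pairwise weighted-additivity rule;
    the result always lies within the closed range of the inputs.
    """
    vals = np.asarray(values, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    if vals.size == 0:
        raise EmptyTreeError("no vessels to integrate")
    if vals.shape != lens.shape:
        raise InvalidParameterError("values and lengths must align")
    if np.any(lens <= 0) or not np.all(np.isfinite(lens)):
        raise InvalidParameterError("arc lengths must be positive and finite")
    return float(np.dot(vals, lens) / lens.sum())


def measure_vessel(polyline, config: MetricConfig | None = None) -> VesselTortuosity:
    """All four tortuosity values for one centerline."""
    cfg = config or MetricConfig()
    pl = _coerce(polyline)
    return VesselTortuosity(
        hart=hart_tortuosity(pl),
        grisan=grisan_tortuosity(
            pl,
            spacing=cfg.spacing,
            sigma=cfg.sigma,
            zero_tol=cfg.zero_tol,
            min_run=cfg.min_run,
            normalize_by_n=cfg.normalize_by_n,
        ),
        trucco=trucco_tortuosity(pl, p=cfg.p, spacing=cfg.spacing, sigma=cfg.sigma),
        onkaew=onkaew_tortuosity(
            pl,
            k=cfg.chain_k,
            spacing=cfg.spacing,
            min_run=cfg.min_run,
            zero_tol=cfg.zero_tol,
        ),
        p=cfg.p,
    )


METRIC_NAMES = ("hart", "grisan", "trucco", "onkaew")


def measure_polylines(polylines, config: MetricConfig | None = None) -> TreeTortuosity:
    """Measure every vessel of a tree and integrate the totals.

    Vessels shorter than ``config.min_vessel_points`` input points are
    excluded from the totals and reported in ``dropped``.
    """
    cfg = config or MetricConfig()
    per_vessel: dict = {}
    weights: dict = {}
    dropped = []
    for pl in polylines:
        pl = _coerce(pl)
        if len(pl) < cfg.min_vessel_points:
            logger.info("dropping short vessel %s (%d points)", pl.id, len(pl))
            dropped.append(pl.id)
            continue
        per_vessel[pl.id] = measure_vessel(pl, cfg)
        weights[pl.id] = pl.arc_length
    if not per_vessel:
        raise EmptyTreeError("no vessels long enough to measure")
    ids = list(per_vessel)
    lens = [weights[i] for i in ids]
    totals = {
        name: integrate_tree([getattr(per_vessel[i], name) for i in ids], lens)
        for name in METRIC_NAMES
    }
    return TreeTortuosity(
        per_vessel=per_vessel,
        totals=totals,
        weights=weights,
        dropped=tuple(dropped),
    )
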