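"""2D whisker shape: arclength S and parabolic curvature coefficient A.

A plucked whisker scanned flat is well approximated over its proximal ~65%
by the parabola ``y = A x**2`` once it is put in standard pose: basepoint at
the origin, the proximal 8% of arclength aligned with the +x axis, concave
up. ``S`` is the polyline arclength of the full trace. The observed (S, A)
pairs admit an upper-bound curve whose value at S = 0 separates curvatures
for which an arclength can be inferred from the bound from those for which
it cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WhiskerTrace2D",
    "Shape2D",
    "UpperBoundCurve",
    "smooth_trace",
    "arclength",
    "standardize_orientation",
    "select_align_fraction",
    "fit_curvature",
    "measure_shape",
    "fit_upper_bound",
    "make_mock_whisker",
    "solve_S_from_bound",
]

#: 2400 dpi flatbed scan: 25.4 mm / 2400 = 10.6 um per pixel
DEFAULT_PIXEL_PITCH_MM = 25.4 / 2400.0
DEFAULT_ALIGN_FRACTION = 0.08
TRUNCATION_FRACTION = 0.65
SMOOTH_WINDOW_PX = 20


@dataclass
class WhiskerTrace2D:
    """Ordered 2D trace of a scanned whisker, base first, in mm."""

    points: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("trace must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("trace needs at least 3 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")

    @classmethod
    def from_pixels(
        cls, pixels: np.ndarray, pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM
    ) -> "WhiskerTrace2D":
        return cls(np.asarray(pixels, float) * pixel_pitch, pixel_pitch)


@dataclass(frozen=True)
class Shape2D:
    """Measured 2D shape: arclength (mm), curvature coefficient (1/mm),
    the align fraction used for standardization, and the parabola-fit MSE."""

    S: float
    A: float
    align_fraction: float = DEFAULT_ALIGN_FRACTION
    mse: float = 0.0

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValueError("S must be positive")
        if not 0.01 <= self.align_fraction <= 0.30:
            raise ValueError("align_fraction must lie in [0.01, 0.30]")


@dataclass(frozen=True)
class UpperBoundCurve:
    """Upper bound of curvature A as a function of arclength S.

    Exponential family ``A_ub(S) = c0 * exp(c1 * S)``; ``c0`` is the value
    of the bound at S = 0 (its intercept on the curvature axis) and must be
    positive, which also makes the bound non-negative for all S.
    """

    c0: float
    c1: float
    window: float = 4.0

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise ValueError("intercept c0 must be positive")

    @property
    def intercept(self) -> float:
        return self.c0

    def evaluate(self, S: float | np.ndarray) -> float | np.ndarray:
        return self.c0 * np.exp(self.c1 * np.asarray(S, float))


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a symmetrically shrinking window.

    Near the ends the half-width shrinks to what fits, so the output has
    the input's length, the endpoints are preserved exactly and a linear
    sequence passes through unchanged (no endpoint bias). Even window
    widths are rounded down to the next odd width to keep the filter
    symmetric.
    """
    n = len(values)
    nominal_half = max((window - 1) // 2, 0)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), nominal_half)
    lo, hi = idx - half, idx + half
    return (csum[hi + 1] - csum[lo]) / (2 * half + 1)


def smooth_trace(trace: WhiskerTrace2D, window: int = SMOOTH_WINDOW_PX) -> WhiskerTrace2D:
    """Smooth the y dimension with a centered moving average (x unchanged)."""
    if len(trace.points) < 3:
        raise ValueError("trace too short to smooth")
    pts = trace.points.copy()
    pts[:, 1] = _moving_average(pts[:, 1], window)
    return WhiskerTrace2D(pts, trace.pixel_pitch)


def arclength(points: np.ndarray) -> float:
    """Polyline arclength: sum of segment lengths between consecutive points."""
    p = np.asarray(points, float)
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def standardize_orientation(
    trace: WhiskerTrace2D, align_fraction: float = DEFAULT_ALIGN_FRACTION
) -> WhiskerTrace2D:
    """Put a trace in standard pose.

    Basepoint at the origin; the proximal ``align_fraction`` of arclength is
    rotated onto the +x axis (its total-least-squares direction, pointed
    away from the base); the trace is reflected if needed so the bulk of the
    whisker is concave up (mean y >= 0).
    """
    pts = trace.points - trace.points[0]
    cum = _cumulative_arclength(pts)
    total = cum[-1]
    n_align = max(int(np.searchsorted(cum, align_fraction * total, side="right")), 2)
    seg = pts[:n_align]
    # principal direction of the proximal segment
    centered = seg - seg.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.linalg.norm(seg[-1] - seg[0]) < 1e-12:
        raise ValueError("degenerate proximal segment; cannot orient trace")
    if float(direction @ (seg[-1] - seg[0])) < 0:
        direction = -direction
    c, s = direction
    rot = np.array([[c, s], [-s, c]])  # maps `direction` onto +x
    out = pts @ rot.T
    if out[:, 1].mean() < 0:
        out[:, 1] = -out[:, 1]
    return WhiskerTrace2D(out, trace.pixel_pitch)


def _parabola_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares A for y = A x^2 (closed form sum(x^2 y)/sum(x^4))."""
    x2 = x * x
    denom = float(np.sum(x2 * x2))
    if denom < 1e-30:
        raise ValueError("degenerate abscissae for parabola fit")
    return float(np.sum(x2 * y) / denom)


def fit_curvature(
    trace: WhiskerTrace2D,
    truncation: float = TRUNCATION_FRACTION,
    return_mse: bool = False,
) -> float | tuple[float, float]:
    """Fit ``y = A x**2`` to the proximal ``truncation`` of a standardized trace.

    Only the proximal ~65% of a whisker stays planar, so the trace is
    truncated to that fraction of its measured arclength before the fit.
    """
    pts = trace.points
    cum = _cumulative_arclength(pts)
    cutoff = truncation * cum[-1]
    keep = pts[cum <= cutoff + 1e-12]
    if len(keep) < 3:
        raise ValueError("fewer than 3 points remain after truncation")
    A = _parabola_coefficient(keep[:, 0], keep[:, 1])
    if not return_mse:
        return A
    mse = float(np.mean((keep[:, 1] - A * keep[:, 0] ** 2) ** 2))
    return A, mse


def select_align_fraction(
    traces: list[WhiskerTrace2D],
    fractions: np.ndarray | None = None,
) -> float:
    """Grid-search the x-axis alignment fraction minimizing mean parabola MSE.

    Candidate fractions span 1%..30% in 1% steps; ties break toward the
    smallest fraction. The production default (8%) was selected this way on
    the original scans and is used when no search is requested.
    """
    if fractions is None:
        fractions = np.arange(0.01, 0.301, 0.01)
    best_frac, best_mse = None, np.inf
    for frac in fractions:
        mses = []
        for trace in traces:
            try:
                std = standardize_orientation(trace, float(frac))
                _, mse = fit_curvature(std, return_mse=True)
            except ValueError:
                continue
            mses.append(mse)
        if not mses:
            continue
        mean_mse = float(np.mean(mses))
        if mean_mse < best_mse - 1e-15:
            best_frac, best_mse = float(frac), mean_mse
    if best_frac is None:
        raise ValueError("no candidate fraction produced a valid fit")
    return best_frac


def measure_shape(
    trace: WhiskerTrace2D,
    align_fraction: float = DEFAULT_ALIGN_FRACTION,
    smooth_window: int = SMOOTH_WINDOW_PX,
) -> Shape2D:
    """Full 2D measurement: smooth, measure S, standardize, fit A."""
    sm = smooth_trace(trace, smooth_window) if smooth_window > 1 else trace
    S = arclength(sm.points)
    std = standardize_orientation(sm, align_fraction)
    A, mse = fit_curvature(std, return_mse=True)
    return Shape2D(S=S, A=max(A, 0.0), align_fraction=align_fraction, mse=mse)


def fit_upper_bound(
    pairs: np.ndarray,
    window: float = 4.0,
    step: float = 1.0,
) -> UpperBoundCurve:
    """Fit the exponential A-vs-S upper bound to windowed maxima.

    A window of ``window`` mm slides over S in ``step`` mm increments; the
    maximum A in each non-empty window, placed at the S where it occurred,
    is the fitting target. Requires at least 4 window maxima. The fit is
    linear least squares on log A.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (S, A)")
    S, A = arr[:, 0], arr[:, 1]
    if np.any(A <= 0):
        raise ValueError("curvature values must be positive to fit the bound")
    locations, maxima = [], []
    start = S.min()
    while start <= S.max() + 1e-9:
        in_win = (S >= start) & (S < start + window)
        if np.any(in_win):
            i = np.argmax(A[in_win])
            locations.append(S[in_win][i])
            maxima.append(A[in_win][i])
        start += step
    if len(maxima) < 4:
        raise ValueError("fewer than 4 window maxima; cannot fit upper bound")
    locations_a = np.asarray(locations)
    log_max = np.log(np.asarray(maxima))
    coef = np.polyfit(locations_a, log_max, 1)
    return UpperBoundCurve(c0=float(np.exp(coef[1])), c1=float(coef[0]), window=window)


def _parabola_arclength(x: float, A: float) -> float:
    """Closed-form arclength of y = A t^2 from t = 0 to t = x."""
    if A == 0.0:
        return x
    u = 2.0 * A * x
    return (x * np.hypot(1.0, u) + np.arcsinh(u) / (2.0 * A)) / 2.0


def make_mock_whisker(S: float, A: float, n_points: int = 200) -> np.ndarray:
    """Idealized whisker on ``y = A x**2`` with total arclength S.

    Base at the origin, base tangent along +x; the x extent solves the
    parabolic arclength integral numerically. Points are uniform in
    arclength so polyline arclength converges to S with dense sampling.
    """
    if not S > 0:
        raise ValueError("S must be positive")
    if A < 0:
        raise ValueError("A must be non-negative")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    if A == 0.0:
        x = np.linspace(0.0, S, n_points)
        return np.column_stack([x, np.zeros_like(x)])
    x_max = brentq(lambda x: _parabola_arclength(x, A) - S, 0.0, S, xtol=1e-12)
    targets = np.linspace(0.0, S, n_points)
    xs = np.array([
        brentq(lambda x: _parabola_arclength(x, A) - t, 0.0, x_max + 1e-12, xtol=1e-12)
        if t > 0 else 0.0
        for t in targets
    ])
    return np.column_stack([xs, A * xs**2])


def read_traces_csv(path, pixel_pitch: float | None = None) -> dict[str, WhiskerTrace2D]:
    """Read per-whisker 2D traces from CSV (whisker_id, point_index, x, y).

    Coordinates are pixels when ``pixel_pitch`` (mm/px) is given, mm
    otherwise.
    """
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, WhiskerTrace2D] = {}
    for wid, grp in df.groupby("whisker_id"):
        pts = grp.sort_values("point_index")[["x", "y"]].to_numpy(float)
        if pixel_pitch is not None:
            out[str(wid)] = WhiskerTrace2D.from_pixels(pts, pixel_pitch)
        else:
            out[str(wid)] = WhiskerTrace2D(pts)
    return out


def write_shape_table(shapes: dict[str, Shape2D], path) -> None:
    """Write measured (S, A) per whisker to CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {"whisker_id": wid, "S": s.S, "A": s.A,
             "align_fraction": s.align_fraction, "mse": s.mse}
            for wid, s in sorted(shapes.items())
        ]
    ).to_csv(path, index=False)


def solve_S_from_bound(
    A: float, bound: UpperBoundCurve, S_max_observed: float
) -> float:
    """Arclength implied by the upper-bound curve for a given curvature.

    For A above the bound's curvature-axis intercept the bound is inverted
    numerically; at or below the intercept S is undefined and the longest
    observed arclength is assigned (the boundary case joins the fallback
    branch).
    """
    if A <= bound.intercept:
        return float(S_max_observed)
    if bound.c1 <= 0:
        raise ValueError("bound is non-increasing; cannot invert above intercept")
    f = lambda S: float(bound.evaluate(S)) - A
    hi = max(S_max_observed, 1.0)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("failed to bracket the bound inversion")
    return float(brentq(f, 0.0, hi, xtol=1e-10))
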