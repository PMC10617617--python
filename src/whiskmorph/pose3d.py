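"""3D emergence-angle fitting for digitized whisker point clouds.

Each whisker's resting orientation is described by three Euler angles:
yaw theta_w (horizontal angle; 0 deg caudal, 90 deg lateral, 180 deg
rostral), pitch phi_w (elevation; +90 deg dorsal) and roll zeta_w (twist
about the whisker's own axis; 0 deg concave down, 90 deg concave forward,
180 deg concave up). The model whisker is a planar parabola of arclength S
and curvature coefficient A, starting at the origin with its proximal
tangent along -y and concavity toward -z, rotated extrinsically about the
global y (roll), x (pitch) and z (yaw) axes in that order.

With right-handed rotation matrices the composite is
``R = Rz(theta) @ Rx(-phi) @ Ry(-zeta)``: the pitch and roll arguments are
negated so that positive phi_w elevates the whisker dorsally and positive
zeta_w rolls its concavity forward, matching the angle semantics above.

Fitting minimizes the mean squared distance between the preprocessed cloud
and the model, both resampled at 0.5 mm and matched by index from the base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry_frame import BasepointSpherical, to_spherical
from .shape2d import _parabola_arclength

__all__ = [
    "WhiskerPointCloud3D",
    "EmergencePose",
    "euler_matrix",
    "preprocess_cloud",
    "synthesize_ideal",
    "fit_pose",
    "simulate_measurement_error",
]

RESAMPLE_STEP_MM = 0.5
SMOOTH_WINDOW_PTS = 5
MIN_S_FOR_ZETA_MM = 8.0
#: dimensionless sagitta proxy below which roll is unidentifiable
ZETA_PLANARITY_FLOOR = 0.05


class PoseFitError(RuntimeError):
    """Raised when the pose optimization fails to converge."""


@dataclass
class WhiskerPointCloud3D:
    """Digitized whisker: basepoint plus shaft points, head frame, mm."""

    basepoint: np.ndarray
    shaft_points: np.ndarray

    def __post_init__(self) -> None:
        self.basepoint = np.asarray(self.basepoint, float)
        self.shaft_points = np.asarray(self.shaft_points, float)
        if self.shaft_points.ndim != 2 or self.shaft_points.shape[1] != 3:
            raise ValueError("shaft_points must be (n, 3)")
        if len(self.shaft_points) < 4:
            raise ValueError("need at least 4 shaft points")
        if np.any(
            np.linalg.norm(self.shaft_points - self.basepoint, axis=1) > 100.0
        ):
            raise ValueError("shaft points must lie within 100 mm of the basepoint")


@dataclass
class EmergencePose:
    """Fitted emergence parameters. ``zeta_w`` is NaN when unidentifiable
    (whisker shorter than 8 mm or nearly straight)."""

    theta_w: float
    phi_w: float
    zeta_w: float
    S: float
    A: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.theta_w = float(self.theta_w) % 360.0
        if not -90.0 <= self.phi_w <= 90.0:
            raise ValueError("phi_w must lie in [-90, 90]")
        if not np.isnan(self.zeta_w):
            self.zeta_w = _wrap180(float(self.zeta_w))
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def _wrap180(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_matrix(theta_w: float, phi_w: float, zeta_w: float) -> np.ndarray:
    """Extrinsic y (roll), x (pitch), z (yaw) rotation for emergence angles.

    Signs follow the emergence-angle conventions (positive pitch dorsal,
    positive roll concave-forward): R = Rz(theta) @ Rx(-phi) @ Ry(-zeta).
    """
    return _rot_z(theta_w) @ _rot_x(-phi_w) @ _rot_y(-zeta_w)


def _parabola_points_by_arclength(S: float, A: float, s_values: np.ndarray) -> np.ndarray:
    """(x, y) points on y = A x^2 at prescribed arclengths from the base.

    The arclength-to-x map is inverted by interpolation on a dense grid of
    the closed-form integral, which is fast and accurate to ~(S/grid)^2.
    """
    if A == 0.0:
        return np.column_stack([s_values, np.zeros_like(s_values)])
    grid_x = np.linspace(0.0, S, 512)
    u = 2.0 * A * grid_x
    grid_s = (grid_x * np.hypot(1.0, u) + np.arcsinh(u) / (2.0 * A)) / 2.0
    xs = np.interp(s_values, grid_s, grid_x)
    return np.column_stack([xs, A * xs**2])


def synthesize_ideal(
    S: float,
    A: float,
    zeta_w: float,
    phi_w: float,
    theta_w: float,
    step: float = RESAMPLE_STEP_MM,
) -> np.ndarray:
    """Generate the idealized 3D whisker polyline for given parameters.

    A planar parabola of arclength S and curvature coefficient A starts at
    the origin with proximal tangent along -y and concavity toward -z, then
    is rotated extrinsically by roll (y), pitch (x) and yaw (z).
    Points are spaced ``step`` mm in arclength (the tip is always included).
    """
    if not S > 0:
        raise ValueError("S must be positive")
    if A < 0:
        raise ValueError("A must be non-negative")
    n_seg = max(int(np.floor(S / step + 1e-9)), 1)
    s_values = np.arange(n_seg + 1) * step
    if s_values[-1] < S - 1e-9:
        s_values = np.append(s_values, S)
    flat = _parabola_points_by_arclength(S, A, s_values)
    # embed: 2D (u, v) -> 3D (0, -u, -v): tangent -y, concave -z
    pts3 = np.column_stack([np.zeros(len(flat)), -flat[:, 0], -flat[:, 1]])
    return pts3 @ euler_matrix(theta_w, phi_w, zeta_w).T


def _smooth_columns(points: np.ndarray, window: int) -> np.ndarray:
    """Column-wise symmetric shrinking moving average (see shape2d)."""
    n = len(points)
    nominal_half = max((window - 1) // 2, 0)
    csum = np.vstack([np.zeros((1, points.shape[1])), np.cumsum(points, axis=0)])
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), nominal_half)
    return (csum[idx + half + 1] - csum[idx - half]) / (2 * half + 1)[:, None]


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n_seg = max(int(np.floor(total / step + 1e-9)), 1)
    s_values = np.arange(n_seg + 1) * step
    if s_values[-1] < total - 1e-9:
        s_values = np.append(s_values, total)
    return np.column_stack(
        [np.interp(s_values, cum, points[:, j]) for j in range(points.shape[1])]
    )


def preprocess_cloud(
    cloud: WhiskerPointCloud3D,
    step: float = RESAMPLE_STEP_MM,
    smooth_window: int = SMOOTH_WINDOW_PTS,
) -> np.ndarray:
    """Sort, smooth, resample and re-base a whisker point cloud.

    Points are sorted by distance from the basepoint, each coordinate is
    smoothed with a centered moving average (window of five points,
    shrinking at the ends), the polyline is resampled at 0.5 mm arc steps
    and translated so its base sits at the origin.
    """
    pts = cloud.shaft_points
    order = np.argsort(np.linalg.norm(pts - cloud.basepoint, axis=1), kind="stable")
    pts = pts[order]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if seg.sum() < 1.0:
        raise ValueError("whisker shorter than 1 mm after sorting")
    sm = _smooth_columns(pts, smooth_window)
    res = _resample_polyline(sm, step)
    return res - res[0]


def _index_matched_cost(cloud_pts: np.ndarray, model_pts: np.ndarray) -> float:
    """Mean squared distance with index matching from the base.

    Both polylines are sampled at the same arc step; indices beyond the
    shorter polyline are matched against its final point so that arclength
    mismatch is penalized rather than truncated away.
    """
    n_c, n_m = len(cloud_pts), len(model_pts)
    n = max(n_c, n_m)
    if n_c < n:
        cloud_pts = np.vstack([cloud_pts, np.repeat(cloud_pts[-1:], n - n_c, axis=0)])
    if n_m < n:
        model_pts = np.vstack([model_pts, np.repeat(model_pts[-1:], n - n_m, axis=0)])
    d = cloud_pts - model_pts
    return float(np.mean(np.sum(d * d, axis=1)))


def _initial_direction_angles(pts: np.ndarray, n_proximal: int) -> tuple[float, float]:
    """Yaw/pitch implied by the proximal segment direction."""
    k = min(max(n_proximal, 1), len(pts) - 1)
    t = pts[k] - pts[0]
    norm = np.linalg.norm(t)
    if norm < 1e-12:
        return 90.0, 0.0
    t = t / norm
    theta = float(np.degrees(np.arctan2(t[0], -t[1]))) % 360.0
    phi = float(np.degrees(np.arcsin(np.clip(t[2], -1.0, 1.0))))
    return theta, phi


def fit_pose(
    cloud: WhiskerPointCloud3D,
    step: float = RESAMPLE_STEP_MM,
    preprocess: bool = True,
) -> EmergencePose:
    """Fit (theta_w, phi_w, zeta_w, S, A) to a whisker point cloud.

    Bounded local optimization (Powell) from 8 systematic starts: the four
    roll quadrants crossed with two yaw/pitch initializations taken from
    short and long proximal segment directions — the roll objective is
    multimodal, the yaw/pitch one is not. ``zeta_w`` is reported as NaN for
    whiskers shorter than 8 mm or flatter than the planarity floor
    (A*S < 0.05), where roll is not identifiable.
    """
    pts = preprocess_cloud(cloud, step) if preprocess else cloud.shaft_points
    S0 = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    theta_a, phi_a = _initial_direction_angles(pts, 2)
    theta_b, phi_b = _initial_direction_angles(pts, max(len(pts) // 3, 2))
    # curvature initializer from the sagitta: distance of the cloud from
    # its base-tip chord, h ~ A (S/2)^2 for a parabola
    chord = pts[-1] - pts[0]
    chord_len = np.linalg.norm(chord)
    if chord_len > 1e-9:
        perp = pts - np.outer((pts @ chord) / chord_len**2, chord)
        sagitta = float(np.linalg.norm(perp - perp[0], axis=1).max())
        A0 = float(np.clip(sagitta / max((S0 / 2.0) ** 2, 1e-9), 1e-3, 0.3))
    else:
        A0 = 0.01

    def objective(params: np.ndarray) -> float:
        theta, phi, zeta, S, A = params
        # Powell's line search may probe marginally outside its bounds
        model = synthesize_ideal(max(S, step), max(A, 0.0), zeta, phi, theta, step)
        # identical smoothing + chordal resampling as the cloud, so the
        # objective is exactly zero at the true parameters of a noiseless
        # synthesized cloud
        model = _resample_polyline(_smooth_columns(model, SMOOTH_WINDOW_PTS), step)
        return _index_matched_cost(pts, model)

    starts = [(theta_a, phi_a)]
    if abs(theta_b - theta_a) > 1.0 or abs(phi_b - phi_a) > 1.0:
        starts.append((theta_b, phi_b))

    def _bounds(theta0: float, phi0: float, zeta0: float) -> list[tuple[float, float]]:
        return [
            (theta0 - 60.0, theta0 + 60.0),
            (max(phi0 - 60.0, -89.9), min(phi0 + 60.0, 89.9)),
            (zeta0 - 140.0, zeta0 + 140.0),
            (max(0.5 * S0, step), 1.5 * S0),
            (0.0, 0.5),
        ]

    # coarse pass over all systematic starts, then full refinement of the
    # best candidates (the objective is multimodal in the roll angle)
    candidates: list[tuple[float, object, list, float]] = []
    exact = False
    for theta0, phi0 in starts:
        for zeta0 in (-135.0, -45.0, 45.0, 135.0):
            x0 = np.array([theta0, phi0, zeta0, S0, A0])
            bounds = _bounds(theta0, phi0, zeta0)
            res = minimize(
                objective, x0, method="Powell", bounds=bounds,
                options={"xtol": 1e-2, "ftol": 1e-8, "maxiter": 4},
            )
            candidates.append((res.fun, res, bounds, zeta0))
            if res.fun < 1e-10:
                exact = True
                break
        if exact:
            break

    def _refine(res, bounds):
        for _ in range(3):  # restarts reset Powell's direction set
            prev = res.fun
            res = minimize(
                objective, res.x, method="Powell", bounds=bounds,
                options={"xtol": 1e-9, "ftol": 1e-14, "maxiter": 2000},
            )
            if res.fun < 1e-12 or prev - res.fun < 1e-12:
                break
        return res

    candidates.sort(key=lambda c: c[0])
    best = _refine(candidates[0][1], candidates[0][2])
    if best.fun > 1e-10:
        # polish the best candidate from a different roll quadrant too:
        # a coarse ranking can prefer the wrong roll basin
        for fun, res, bounds, zeta0 in candidates[1:]:
            if zeta0 != candidates[0][3]:
                other = _refine(res, bounds)
                if other.fun < best.fun:
                    best = other
                break
    if best is None or not np.isfinite(best.fun):
        raise PoseFitError("pose optimization did not converge from any start")
    theta, phi, zeta, S, A = best.x
    if S < MIN_S_FOR_ZETA_MM or A * S < ZETA_PLANARITY_FLOOR:
        zeta = np.nan
    return EmergencePose(
        theta_w=theta, phi_w=float(np.clip(phi, -90.0, 90.0)), zeta_w=zeta,
        S=float(S), A=float(A), residual=float(best.fun),
    )


def _angle_deviation(a: float, b: float) -> float:
    """Short-way absolute angular difference in degrees."""
    if np.isnan(a) or np.isnan(b):
        return np.nan
    return abs(_wrap180(a - b))


def simulate_measurement_error(
    pose: EmergencePose,
    basepoint: np.ndarray,
    n_trials: int = 30,
    amplitude: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Digitization-noise simulation for one whisker.

    The whisker is synthesized at ``basepoint`` from ``pose``; each trial
    perturbs every point (including the basepoint) independently and
    uniformly by +/-``amplitude`` mm per axis, re-derives the spherical
    basepoint coordinates and re-fits the pose. Returns per-parameter
    deviation arrays and their maxima.
    """
    rng = np.random.default_rng(seed)
    basepoint = np.asarray(basepoint, float)
    true_sph = to_spherical(basepoint)
    shaft = basepoint + synthesize_ideal(
        pose.S, pose.A, 0.0 if np.isnan(pose.zeta_w) else pose.zeta_w,
        pose.phi_w, pose.theta_w,
    )
    params = ("r_bp", "theta_bp", "phi_bp", "theta_w", "phi_w", "zeta_w")
    devs: dict[str, list[float]] = {p: [] for p in params}
    for _ in range(n_trials):
        noise = rng.uniform(-amplitude, amplitude, size=shaft.shape)
        noisy = shaft + noise
        noisy_bp = noisy[0]
        sph = to_spherical(noisy_bp)
        refit = fit_pose(WhiskerPointCloud3D(noisy_bp, noisy))
        devs["r_bp"].append(abs(sph.r_bp - true_sph.r_bp))
        devs["theta_bp"].append(abs(sph.theta_bp - true_sph.theta_bp))
        devs["phi_bp"].append(abs(sph.phi_bp - true_sph.phi_bp))
        devs["theta_w"].append(_angle_deviation(refit.theta_w, pose.theta_w))
        devs["phi_w"].append(_angle_deviation(refit.phi_w, pose.phi_w))
        devs["zeta_w"].append(_angle_deviation(refit.zeta_w, pose.zeta_w))
    arrays = {p: np.asarray(v, float) for p, v in devs.items()}
    maxima = {
        p: (float(np.nanmax(v)) if np.any(np.isfinite(v)) else np.nan)
        for p, v in arrays.items()
    }
    return {"deviations": arrays, "max": maxima, "amplitude": amplitude, "seed": seed}
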