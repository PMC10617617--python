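"""Average-array generation, species comparison and landmark registration.

Evaluating a species' coefficient set over its row/column layout produces
the average 3D whisker array: per-whisker spherical basepoint coordinates
(theta_bp from column, phi_bp from row, r_bp from the two angles), 2D shape
(S, A from theta_bp) and emergence angles (theta_w, phi_w, zeta_w), with
each whisker rendered as an idealized parabolic polyline placed at its
basepoint. Facial landmarks ride along from a template. Cross-species
comparison reports rostro-caudal and bilateral scaling factors and the
size-normalized angular overlay of features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .geometry_frame import BasepointSpherical, from_spherical, mirror_left
from .models import CoefficientSet, evaluate
from .pose3d import synthesize_ideal

__all__ = [
    "WhiskerArray3D",
    "FacialLandmarkSet",
    "ScalingReport",
    "generate_basepoints",
    "generate_array",
    "basepoint_area_density",
    "compare_species",
    "register_landmarks",
]

ROW_LETTERS = "ABCDE"


@dataclass
class GeneratedWhisker:
    row: int
    col: int
    side: str
    basepoint: np.ndarray
    polyline: np.ndarray
    S: float
    A: float
    theta_w: float
    phi_w: float
    zeta_w: float
    zeta_low_confidence: bool = False

    @property
    def name(self) -> str:
        return f"{ROW_LETTERS[self.row - 1]}{self.col}"


@dataclass
class FacialLandmarkSet:
    """Named facial/skull landmark coordinates in the head frame (mm)."""

    landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.landmarks = {k: np.asarray(v, float) for k, v in self.landmarks.items()}
        for name in ("bregma", "lambda"):
            if name in self.landmarks and abs(self.landmarks[name][0]) >= 1.0:
                raise ValueError(f"{name} must lie within 1 mm of the midline")

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"landmark": k, "x_mm": v[0], "y_mm": v[1], "z_mm": v[2]}
            for k, v in sorted(self.landmarks.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class WhiskerArray3D:
    """Generated average array: mirrored right/left whiskers + landmarks."""

    species: str
    whiskers: list[GeneratedWhisker]
    landmarks: FacialLandmarkSet | None = None

    def side(self, side: str) -> list[GeneratedWhisker]:
        return [w for w in self.whiskers if w.side == side]

    def basepoint_table(self) -> pd.DataFrame:
        rows = []
        for w in self.whiskers:
            rows.append(
                {
                    "row": w.row, "col": w.col, "side": w.side, "name": w.name,
                    "x_mm": w.basepoint[0], "y_mm": w.basepoint[1],
                    "z_mm": w.basepoint[2], "S": w.S, "A": w.A,
                    "theta_w": w.theta_w, "phi_w": w.phi_w, "zeta_w": w.zeta_w,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for w in self.whiskers:
            for i, p in enumerate(w.polyline):
                rows.append(
                    {
                        "whisker": w.name, "side": w.side, "point_index": i,
                        "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_obj(self, path: str | Path) -> None:
        """Simple polyline OBJ export (one `l` element per whisker)."""
        lines: list[str] = []
        offset = 1
        for w in self.whiskers:
            for p in w.polyline:
                lines.append(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
            idx = " ".join(str(offset + i) for i in range(len(w.polyline)))
            lines.append(f"l {idx}")
            offset += len(w.polyline)
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ScalingReport:
    """Cross-species scaling summary.

    Rostro-caudal ratios compare |y| distances of matched features from the
    basepoint-centroid origin, bilateral ratios compare |x| distances;
    ``rc_slope_origin`` / ``bilateral_slope_origin`` are through-origin
    regression slopes, and the affine fields an ordinary linear fit.
    Angular coordinates (theta, phi per feature) give the size-normalized
    overlay.
    """

    rostro_caudal_ratios: dict[str, float]
    bilateral_ratios: dict[str, float]
    rc_slope_origin: float
    rc_affine: tuple[float, float]
    bilateral_slope_origin: float
    bilateral_affine: tuple[float, float]
    angular_overlay_a: dict[str, tuple[float, float]]
    angular_overlay_b: dict[str, tuple[float, float]]
    base_diameter_slope: float | None = None

    def to_dict(self) -> dict:
        return {
            "rostro_caudal_ratios": self.rostro_caudal_ratios,
            "bilateral_ratios": self.bilateral_ratios,
            "rc_slope_origin": self.rc_slope_origin,
            "rc_affine": list(self.rc_affine),
            "bilateral_slope_origin": self.bilateral_slope_origin,
            "bilateral_affine": list(self.bilateral_affine),
            "angular_overlay_a": {k: list(v) for k, v in self.angular_overlay_a.items()},
            "angular_overlay_b": {k: list(v) for k, v in self.angular_overlay_b.items()},
            "base_diameter_slope": self.base_diameter_slope,
        }


def generate_basepoints(coeffs: CoefficientSet) -> pd.DataFrame:
    """Evaluate the basepoint equations over the species' array layout.

    theta_bp comes from the column equation, phi_bp from the row equation
    and r_bp from the angle-based equation (the form that generalizes
    across species with different layouts); Cartesian coordinates follow,
    with the left side mirrored across the y-z plane.
    """
    rows = []
    for row, col in coeffs.identities():
        theta = float(evaluate(coeffs.equation("theta_bp_from_col"), {"col": col}))
        phi = float(evaluate(coeffs.equation("phi_bp_from_row"), {"row": row}))
        r = float(
            evaluate(coeffs.equation("r_bp_from_angles"), {"theta_bp": theta, "phi_bp": phi})
        )
        xyz = from_spherical(BasepointSpherical(r, theta, phi))
        for side in ("right", "left"):
            p = xyz if side == "right" else mirror_left(xyz)
            rows.append(
                {
                    "row": row, "col": col, "side": side,
                    "r_bp": r, "theta_bp": theta, "phi_bp": phi,
                    "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                }
            )
    return pd.DataFrame(rows)


def generate_array(
    coeffs: CoefficientSet,
    landmarks: FacialLandmarkSet | None = None,
    step: float = 0.5,
) -> WhiskerArray3D:
    """Generate the full 3D average whisker array for a species.

    Per whisker: S from the exponential arclength model, A from the linear
    curvature model, theta_w from the reduced horizontal-angle model,
    phi_w from the elevation model and zeta_w from the reduced twist model;
    identities the reduced twist model excludes (A row, rostral-most
    column) fall back to the full model and are flagged low-confidence.
    Left whiskers are exact mirrors of right whiskers.
    """
    bp = generate_basepoints(coeffs)
    whiskers: list[GeneratedWhisker] = []
    for _, r in bp[bp["side"] == "right"].iterrows():
        row, col = int(r["row"]), int(r["col"])
        theta_bp, phi_bp = float(r["theta_bp"]), float(r["phi_bp"])
        preds = {"theta_bp": theta_bp, "phi_bp": phi_bp}
        S = float(evaluate(coeffs.equation("s_from_theta_bp"), preds))
        A = max(float(evaluate(coeffs.equation("a_from_theta_bp"), preds)), 0.0)
        theta_w = float(evaluate(coeffs.equation("theta_w_reduced"), preds))
        phi_w = float(evaluate(coeffs.equation("phi_w_from_phi_bp"), preds))
        low_conf = coeffs.zeta_is_low_confidence(row, col)
        zeta_eq = "zeta_w_full" if low_conf else "zeta_w_reduced"
        zeta_w = float(evaluate(coeffs.equation(zeta_eq), preds))
        base = np.array([r["x_mm"], r["y_mm"], r["z_mm"]])
        poly = base + synthesize_ideal(S, A, zeta_w, phi_w, theta_w, step)
        whiskers.append(
            GeneratedWhisker(row, col, "right", base, poly, S, A,
                             theta_w, phi_w, zeta_w, low_conf)
        )
        whiskers.append(
            GeneratedWhisker(row, col, "left", mirror_left(base), mirror_left(poly),
                             S, A, theta_w, phi_w, zeta_w, low_conf)
        )
    return WhiskerArray3D(species=coeffs.species, whiskers=whiskers, landmarks=landmarks)


def basepoint_area_density(basepoints: np.ndarray) -> tuple[float, float]:
    """Area (mm^2) and density (whiskers/mm^2) of basepoints in the y-z plane.

    Basepoints of one side are projected onto the y-z (sagittal) plane and
    the area is that of their convex hull — a deliberate, documented choice
    since density values depend on the area definition.
    """
    pts = np.asarray(basepoints, float)
    if pts.shape[1] == 3:
        pts = pts[:, 1:]
    hull = ConvexHull(pts)
    area = float(hull.volume)  # 2D ConvexHull: `volume` is the area
    return area, len(pts) / area


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(x * y) / np.sum(x * x))


def compare_species(
    landmarks_a: FacialLandmarkSet,
    landmarks_b: FacialLandmarkSet,
    base_diameters: pd.DataFrame | None = None,
) -> ScalingReport:
    """Scaling comparison of two species' facial-feature layouts.

    For every feature present in both sets, |y| (rostro-caudal) and |x|
    (bilateral) distances from the basepoint-centroid origin are compared
    as ratios (b relative to a), with both a through-origin slope and an
    ordinary affine fit across features, plus the scale-free angular
    overlay (theta, phi of each feature). An optional paired base-diameter
    table (columns ``diam_a``, ``diam_b``) yields a through-origin slope.
    """
    common = sorted(set(landmarks_a.landmarks) & set(landmarks_b.landmarks))
    if not common:
        raise ValueError("no common landmarks to compare")
    rc_a, rc_b, bi_a, bi_b = [], [], [], []
    rc_ratios, bi_ratios = {}, {}
    overlay_a, overlay_b = {}, {}
    for name in common:
        pa, pb = landmarks_a.landmarks[name], landmarks_b.landmarks[name]
        rc_a.append(abs(pa[1]))
        rc_b.append(abs(pb[1]))
        if abs(pa[1]) > 1e-9:
            rc_ratios[name] = abs(pb[1]) / abs(pa[1])
        if abs(pa[0]) > 1e-9:
            bi_a.append(abs(pa[0]))
            bi_b.append(abs(pb[0]))
            bi_ratios[name] = abs(pb[0]) / abs(pa[0])
        for p, overlay in ((pa, overlay_a), (pb, overlay_b)):
            r = np.linalg.norm(p)
            overlay[name] = (
                float(np.degrees(np.arctan2(p[1], p[0]))),
                float(np.degrees(np.arcsin(np.clip(p[2] / r, -1, 1)))),
            )
    rc_a_arr, rc_b_arr = np.asarray(rc_a), np.asarray(rc_b)
    bi_a_arr, bi_b_arr = np.asarray(bi_a), np.asarray(bi_b)
    rc_affine = np.polyfit(rc_a_arr, rc_b_arr, 1)
    bi_affine = np.polyfit(bi_a_arr, bi_b_arr, 1)
    diam_slope = None
    if base_diameters is not None:
        diam_slope = _through_origin_slope(
            base_diameters["diam_a"].to_numpy(float),
            base_diameters["diam_b"].to_numpy(float),
        )
    return ScalingReport(
        rostro_caudal_ratios=rc_ratios,
        bilateral_ratios=bi_ratios,
        rc_slope_origin=_through_origin_slope(rc_a_arr, rc_b_arr),
        rc_affine=(float(rc_affine[0]), float(rc_affine[1])),
        bilateral_slope_origin=_through_origin_slope(bi_a_arr, bi_b_arr),
        bilateral_affine=(float(bi_affine[0]), float(bi_affine[1])),
        angular_overlay_a=overlay_a,
        angular_overlay_b=overlay_b,
        base_diameter_slope=diam_slope,
    )


def register_landmarks(
    source_points: np.ndarray, target_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid registration of corresponding point sets (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``R @ source + t ~= target``. No scaling: the transform found for the
    correspondence subset (e.g. bregma, lambda, incisor corners) can then
    be applied to every other digitized feature. Requires at least three
    non-collinear correspondences.
    """
    src = np.asarray(source_points, float)
    tgt = np.asarray(target_points, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 correspondences")
    src_c, tgt_c = src.mean(axis=0), tgt.mean(axis=0)
    a, b = src - src_c, tgt - tgt_c
    if np.linalg.matrix_rank(a, tol=1e-9 * max(np.abs(a).max(), 1e-300)) < 2:
        raise ValueError("correspondences are collinear; rotation is ambiguous")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tgt_c - rot @ src_c
    resid = (src @ rot.T + trans) - tgt
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rot, trans, rmsd
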