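"""Head-centered coordinate frame construction for whisker-array digitizations.

A digitization session yields labelled 3D points in an arbitrary digitizer
frame. This module builds the standard head-centered frame used by all
downstream analyses:

* origin — the mean of all whisker basepoints matched across left and right
  sides (a whisker identity contributes only if present bilaterally);
* z axis — the dorsal-pointing normal of the "average whisker row plane",
  the mean of total-least-squares planes fitted to each of the five rows;
* x axis — the line connecting the left and right array centroids, projected
  into that plane, pointing toward the right array;
* y axis — z x x, pointing rostrally.

Basepoints are then expressed in spherical coordinates (r_bp, theta_bp,
phi_bp): radius from the origin, horizontal angle (rostral positive) and
elevation (dorsal positive), in mm and degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WhiskerIdentity",
    "RawDigitization",
    "HeadFrame",
    "BasepointSpherical",
    "Plane",
    "compute_origin",
    "fit_plane",
    "average_row_plane",
    "build_head_frame",
    "mirror_left",
    "to_spherical",
    "from_spherical",
    "standardize_digitization",
    "read_digitization_csv",
    "write_standardized_csv",
]

#: controlled vocabulary for the structure_label column of input CSVs
STRUCTURE_LABELS = frozenset(
    {
        "whisker_basepoint",
        "whisker_shaft",
        "eye_medial",
        "eye_lateral",
        "nostril",
        "mouth",
        "incisor",
        "pinna",
        "bregma",
        "lambda",
        "meatus",
        "lateral_canal",
    }
)

ROW_LETTERS = "ABCDE"


class DegenerateGeometryError(ValueError):
    """Raised when a digitization cannot support frame construction."""


@dataclass(frozen=True, order=True)
class WhiskerIdentity:
    """Row/column/side identity of a whisker.

    Rows run 1 (A, dorsal) to 5 (E, ventral); columns run 1 (the caudal
    "Greek arc") to 7 (rostral).
    """

    row: int
    col: int
    side: str = "right"

    def __post_init__(self) -> None:
        if not 1 <= self.row <= 5:
            raise ValueError(f"row must be in [1, 5], got {self.row}")
        if not 1 <= self.col <= 7:
            raise ValueError(f"col must be in [1, 7], got {self.col}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def name(self) -> str:
        """Conventional name, e.g. ``C2`` for row 3, column 2."""
        return f"{ROW_LETTERS[self.row - 1]}{self.col}"

    def mirrored(self) -> "WhiskerIdentity":
        other = "left" if self.side == "right" else "right"
        return WhiskerIdentity(self.row, self.col, other)


@dataclass
class RawDigitization:
    """Labelled 3D point set for one animal, in the digitizer frame.

    ``points`` is a DataFrame with columns: structure_label, row, col, side,
    point_index, x_mm, y_mm, z_mm.  Whisker structures carry row/col/side;
    facial and skull landmarks leave row/col as NA.
    """

    animal_id: str
    points: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "structure_label",
            "row",
            "col",
            "side",
            "point_index",
            "x_mm",
            "y_mm",
            "z_mm",
        }
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"digitization missing columns: {sorted(missing)}")
        coords = self.points[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("digitized coordinates must be finite")
        bad = set(self.points["structure_label"]) - STRUCTURE_LABELS
        if bad:
            raise ValueError(f"unknown structure labels: {sorted(bad)}")

    def basepoints(self, side: str | None = None) -> dict[WhiskerIdentity, np.ndarray]:
        """Map each labelled whisker identity to its basepoint coordinate."""
        sel = self.points[self.points["structure_label"] == "whisker_basepoint"]
        if side is not None:
            sel = sel[sel["side"] == side]
        out: dict[WhiskerIdentity, np.ndarray] = {}
        for _, r in sel.iterrows():
            ident = WhiskerIdentity(int(r["row"]), int(r["col"]), str(r["side"]))
            out[ident] = np.array([r["x_mm"], r["y_mm"], r["z_mm"]], float)
        return out

    def shaft_points(self, ident: WhiskerIdentity) -> np.ndarray:
        """Ordered (n, 3) array of shaft points for one whisker."""
        sel = self.points[
            (self.points["structure_label"] == "whisker_shaft")
            & (self.points["row"] == ident.row)
            & (self.points["col"] == ident.col)
            & (self.points["side"] == ident.side)
        ].sort_values("point_index")
        return sel[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def landmarks(self) -> dict[str, np.ndarray]:
        """Mean coordinate per non-whisker structure, keyed by label[/side]."""
        sel = self.points[
            ~self.points["structure_label"].isin(["whisker_basepoint", "whisker_shaft"])
        ]
        out: dict[str, np.ndarray] = {}
        for (label, side), grp in sel.groupby(["structure_label", "side"], dropna=False):
            key = label if (pd.isna(side) or side == "") else f"{label}_{side}"
            out[key] = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float).mean(axis=0)
        return out


@dataclass(frozen=True)
class Plane:
    """Plane in Hesse normal form: ``normal . p = offset`` with unit normal."""

    normal: np.ndarray
    offset: float

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset


@dataclass
class HeadFrame:
    """Head-centered frame: origin plus row-wise orthonormal axes.

    ``axes`` rows are the x (lateral, toward the right array), y (rostral)
    and z (dorsal) unit vectors expressed in the digitizer frame, so
    ``axes @ (p - origin)`` maps a digitizer point into head coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be 3x3")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed (det = +1)")

    def to_head(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        out = (p - self.origin) @ self.axes.T
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_digitizer(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        out = p @ self.axes + self.origin
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_json(self) -> str:
        return json.dumps(
            {"origin": self.origin.tolist(), "axes": self.axes.tolist()}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "HeadFrame":
        d = json.loads(text)
        return cls(np.array(d["origin"], float), np.array(d["axes"], float))


@dataclass(frozen=True)
class BasepointSpherical:
    """Spherical basepoint coordinate: radius (mm), horizontal angle and
    elevation (degrees). theta_bp > 0 rostral of the x-z plane; phi_bp > 0
    dorsal of the x-y plane."""

    r_bp: float
    theta_bp: float
    phi_bp: float

    def __post_init__(self) -> None:
        if not self.r_bp > 0:
            raise ValueError("r_bp must be positive")


def compute_origin(
    basepoints_left: Mapping[WhiskerIdentity, np.ndarray],
    basepoints_right: Mapping[WhiskerIdentity, np.ndarray],
) -> np.ndarray:
    """Mean of all whisker basepoints matched across the two sides.

    A whisker identity contributes only if it was digitized on both sides;
    unmatched identities are omitted.  Raises ``DegenerateGeometryError``
    when no identity is matched.
    """
    left_keys = {(k.row, k.col) for k in basepoints_left}
    right_keys = {(k.row, k.col) for k in basepoints_right}
    matched = left_keys & right_keys
    if not matched:
        raise DegenerateGeometryError(
            "no whisker identity present on both sides; cannot define origin"
        )
    pts = []
    for row, col in sorted(matched):
        pts.append(basepoints_left[WhiskerIdentity(row, col, "left")])
        pts.append(basepoints_right[WhiskerIdentity(row, col, "right")])
    return np.mean(np.asarray(pts, float), axis=0)


def fit_plane(points: np.ndarray, reference_up: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through >= 3 points (SVD of centered cloud).

    The normal is the singular vector of the smallest singular value —
    isotropic digitizer noise justifies total over ordinary least squares.
    If ``reference_up`` is given the normal sign is flipped to have a
    positive dot product with it.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 three-dimensional points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear clouds have two (near-)zero singular values
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise DegenerateGeometryError("points are collinear; plane is not defined")
    normal = vt[2]
    if reference_up is not None and float(normal @ np.asarray(reference_up, float)) < 0:
        normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


def average_row_plane(row_planes: Iterable[Plane], centroids: Iterable[np.ndarray]) -> Plane:
    """Mean of the per-row planes: average the sign-aligned unit normals,
    renormalize, and pass the plane through the mean row centroid.

    Normals must already be sign-consistent (dorsal-positive). Fewer than
    five rows is tolerated (the mean of what exists is used).
    """
    planes = list(row_planes)
    cents = [np.asarray(c, float) for c in centroids]
    if not planes:
        raise ValueError("no planes to average")
    normals = np.array([p.normal for p in planes], float)
    # align all normals with the first to guard against stray sign flips
    signs = np.sign(normals @ normals[0])
    signs[signs == 0] = 1.0
    mean_normal = (normals * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean_normal)
    if norm < 1e-12:
        raise DegenerateGeometryError("row-plane normals cancel; no average plane")
    mean_normal = mean_normal / norm
    mean_centroid = np.mean(cents, axis=0)
    return Plane(normal=mean_normal, offset=float(mean_normal @ mean_centroid))


def _row_planes(
    digitization: RawDigitization,
) -> tuple[list[Plane], list[np.ndarray]]:
    """Per-row total-least-squares planes, rows pooled across both sides."""
    bps = digitization.basepoints()
    planes: list[Plane] = []
    centroids: list[np.ndarray] = []
    # provisional dorsal direction: from the E-row centroid toward the A-row
    # centroid, used only to sign the normals consistently
    by_row: dict[int, list[np.ndarray]] = {}
    for ident, p in bps.items():
        by_row.setdefault(ident.row, []).append(p)
    rows_present = sorted(by_row)
    if len(rows_present) < 2:
        raise DegenerateGeometryError("need at least two whisker rows")
    up = np.mean(by_row[rows_present[0]], axis=0) - np.mean(
        by_row[rows_present[-1]], axis=0
    )
    for row in rows_present:
        pts = np.asarray(by_row[row], float)
        if len(pts) < 3:
            continue
        try:
            planes.append(fit_plane(pts, reference_up=up))
        except DegenerateGeometryError:
            continue
        centroids.append(pts.mean(axis=0))
    if not planes:
        raise DegenerateGeometryError("no whisker row had 3+ non-collinear basepoints")
    return planes, centroids


def build_head_frame(digitization: RawDigitization) -> HeadFrame:
    """Construct the head-centered frame from a raw digitization.

    Requires matched basepoint identities on both sides. The x axis (line
    between left/right array centroids) is projected into the average row
    plane to keep the frame orthonormal; an x line within 5 degrees of the
    plane normal is rejected as a degenerate digitization.
    """
    left = digitization.basepoints("left")
    right = digitization.basepoints("right")
    origin = compute_origin(left, right)
    planes, centroids = _row_planes(digitization)
    avg_plane = average_row_plane(planes, centroids)
    z = avg_plane.normal
    centroid_right = np.mean(list(right.values()), axis=0)
    centroid_left = np.mean(list(left.values()), axis=0)
    x_line = centroid_right - centroid_left
    x_norm = np.linalg.norm(x_line)
    if x_norm < 1e-12:
        raise DegenerateGeometryError("left and right array centroids coincide")
    x_line = x_line / x_norm
    if abs(float(x_line @ z)) > np.cos(np.radians(5.0)):
        raise DegenerateGeometryError(
            "centroid line within 5 degrees of the row-plane normal"
        )
    x = x_line - (x_line @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return HeadFrame(origin=origin, axes=np.array([x, y, z]))


def mirror_left(points: np.ndarray) -> np.ndarray:
    """Mirror head-frame points across the y-z plane (x -> -x).

    Applied to left-side whiskers before any pose fitting so that all
    equations are expressed for the right array. An involution.
    """
    p = np.asarray(points, float).copy()
    if p.ndim == 1:
        p[0] = -p[0]
    else:
        p[..., 0] = -p[..., 0]
    return p


def to_spherical(xyz: np.ndarray, frame: HeadFrame | None = None) -> BasepointSpherical:
    """Convert a head-frame point to (r_bp, theta_bp, phi_bp).

    theta_bp is the angle from the +x axis within the horizontal plane,
    rostral (+y) positive; phi_bp is the elevation above the horizontal
    plane, dorsal (+z) positive. If ``frame`` is given, ``xyz`` is first
    mapped from the digitizer frame into head coordinates.
    """
    p = np.asarray(xyz, float)
    if frame is not None:
        p = frame.to_head(p)
    r = float(np.linalg.norm(p))
    if r < 1e-12:
        raise ValueError("zero radius: point coincides with the origin")
    theta = float(np.degrees(np.arctan2(p[1], p[0])))
    phi = float(np.degrees(np.arcsin(np.clip(p[2] / r, -1.0, 1.0))))
    return BasepointSpherical(r_bp=r, theta_bp=theta, phi_bp=phi)


def from_spherical(sph: BasepointSpherical) -> np.ndarray:
    """Inverse of :func:`to_spherical` (head-frame Cartesian coordinates)."""
    th = np.radians(sph.theta_bp)
    ph = np.radians(sph.phi_bp)
    return sph.r_bp * np.array(
        [np.cos(ph) * np.cos(th), np.cos(ph) * np.sin(th), np.sin(ph)]
    )


def standardize_digitization(
    digitization: RawDigitization,
) -> tuple[RawDigitization, HeadFrame]:
    """Map every digitized point into the head frame.

    Returns a new digitization whose coordinates are head-centered (left
    whiskers are NOT yet mirrored; see :func:`mirror_left`) plus the frame.
    """
    frame = build_head_frame(digitization)
    pts = digitization.points.copy()
    xyz = frame.to_head(pts[["x_mm", "y_mm", "z_mm"]].to_numpy(float))
    pts[["x_mm", "y_mm", "z_mm"]] = xyz
    return RawDigitization(digitization.animal_id, pts), frame


def read_digitization_csv(path: str | Path) -> list[RawDigitization]:
    """Read one-row-per-point CSV into per-animal digitizations."""
    df = pd.read_csv(path)
    if "animal_id" not in df.columns:
        raise ValueError("CSV must contain an animal_id column")
    return [
        RawDigitization(str(animal), grp.drop(columns=["animal_id"]).reset_index(drop=True))
        for animal, grp in df.groupby("animal_id", sort=True)
    ]


def write_standardized_csv(
    digitizations: Iterable[tuple[RawDigitization, HeadFrame]],
    csv_path: str | Path,
    frame_json_path: str | Path | None = None,
) -> None:
    """Write standardized coordinates plus per-animal frame metadata."""
    frames: dict[str, dict] = {}
    chunks = []
    for dig, frame in digitizations:
        part = dig.points.copy()
        part.insert(0, "animal_id", dig.animal_id)
        chunks.append(part)
        frames[dig.animal_id] = {
            "origin": frame.origin.tolist(),
            "axes": frame.axes.tolist(),
        }
    pd.concat(chunks, ignore_index=True).to_csv(csv_path, index=False)
    if frame_json_path is not None:
        Path(frame_json_path).write_text(json.dumps(frames, indent=2))
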