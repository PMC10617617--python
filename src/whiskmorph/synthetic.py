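"""Synthetic multi-animal digitization datasets with known ground truth.

The generator emulates the study design the analysis assumes: eight
animals, ~30 whiskers per mystacial pad arranged in a row/column lattice,
an exponential arclength gradient across the pad, parabolic whisker shapes
and linear emergence-angle gradients. Each animal gets a multiplicative
head-size factor (applied to r_bp and S); each whisker's true parameters
are the coefficient-set equations plus independent Gaussian residuals, with
a small fraction of gross outliers to exercise the outlier filter.
Digitization renders every whisker as a 3D polyline (4-60 points), perturbs
every point uniformly by +/-0.5 mm per axis (the digitizer's resolution),
places facial landmarks from a template and emits each animal's array in a
random rigid pose so the frame-construction step is exercised.

The facial-landmark templates are synthetic fixtures: plausible rodent
head layouts, with the rat template scaled from the mouse one (2.03x
rostro-caudally and dorso-ventrally; bilaterally by x -> 1.49 x + 1.45).
They are not digitized animal data.

All randomness flows through one seeded generator; ``GroundTruth.manifest``
records the seed and every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generator import FacialLandmarkSet
from .geometry_frame import BasepointSpherical, from_spherical, mirror_left
from .models import CoefficientSet, evaluate
from .pose3d import _resample_polyline, synthesize_ideal
from .shape2d import DEFAULT_PIXEL_PITCH_MM, WhiskerTrace2D, _cumulative_arclength

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "digitize",
    "render_scan",
    "mouse_landmark_template",
    "rat_landmark_template",
    "base_diameter_pairs",
    "DEFAULT_RESIDUAL_SDS",
]

#: Per-parameter residual standard deviations (degrees / mm; S is a log-sd).
#: Chosen to reproduce the qualitative fit-quality ordering of real arrays:
#: elevation angle tightest, twist angle loosest, radius noisier than the
#: basepoint angles, curvature scatter large relative to its range.
DEFAULT_RESIDUAL_SDS = {
    "theta_bp": 4.0,
    "phi_bp": 4.0,
    "r_bp": 0.45,
    "S_log": 0.12,
    "A": 0.004,
    "theta_w": 8.0,
    "phi_w": 3.5,
    "zeta_w": 12.0,
}

DEFAULT_SCALE_SD = 0.06
DEFAULT_OUTLIER_FRACTION = 0.04
#: gross outliers are displaced by this many residual SDs (>= 3 group SDs)
OUTLIER_SHIFT_SDS = 6.0


# synthetic mouse facial-landmark template (head frame, mm); bilateral
# features are given for the right side and mirrored automatically
_MOUSE_TEMPLATE_RIGHT = {
    "eye_medial": (4.0, 4.5, 3.5),
    "eye_lateral": (5.5, 3.0, 3.5),
    "nostril": (1.5, 11.0, -1.0),
    "mouth": (3.0, 8.0, -4.0),
    "incisor": (1.0, 10.5, -4.5),
    "pinna": (7.0, -8.0, 5.0),
    "meatus": (6.5, -7.0, 1.0),
    "lateral_canal": (5.5, -9.0, 2.0),
}
_MOUSE_TEMPLATE_MIDLINE = {
    "bregma": (0.0, -6.0, 8.0),
    "lambda": (0.0, -10.0, 7.5),
}

RC_SCALE = 2.03          # rostro-caudal (and dorso-ventral) rat/mouse factor
BILATERAL_SLOPE = 1.49   # bilateral scaling: x_rat = 1.49 x_mouse + 1.45
BILATERAL_INTERCEPT = 1.45
BASE_DIAMETER_RATIO = 2.35


def mouse_landmark_template() -> FacialLandmarkSet:
    """Bilateral synthetic mouse landmark layout (left = mirrored right)."""
    lm: dict[str, np.ndarray] = {}
    for name, p in _MOUSE_TEMPLATE_RIGHT.items():
        lm[f"{name}_right"] = np.array(p, float)
        lm[f"{name}_left"] = mirror_left(np.array(p, float))
    for name, p in _MOUSE_TEMPLATE_MIDLINE.items():
        lm[name] = np.array(p, float)
    return FacialLandmarkSet(lm)


def rat_landmark_template() -> FacialLandmarkSet:
    """Rat layout scaled from the mouse template.

    y and z scale by 2.03 about the basepoint-centroid origin; bilateral
    offsets follow |x| -> 1.49 |x| + 1.45 (midline features stay midline).
    """
    mouse = mouse_landmark_template()
    lm: dict[str, np.ndarray] = {}
    for name, p in mouse.landmarks.items():
        x = 0.0 if abs(p[0]) < 1e-12 else np.sign(p[0]) * (
            BILATERAL_SLOPE * abs(p[0]) + BILATERAL_INTERCEPT
        )
        lm[name] = np.array([x, RC_SCALE * p[1], RC_SCALE * p[2]])
    return FacialLandmarkSet(lm)


def base_diameter_pairs() -> pd.DataFrame:
    """Paired synthetic base diameters (mm) for matched whisker identities.

    Mouse values are plausible macrovibrissa base diameters; rat values are
    the mouse values scaled by the cross-species diameter ratio.
    """
    mouse = {
        "A2": 0.040, "B2": 0.048, "C1": 0.056, "C2": 0.050,
        "C3": 0.042, "C4": 0.035, "D2": 0.046, "E2": 0.044,
    }
    return pd.DataFrame(
        {
            "whisker": list(mouse),
            "diam_a": list(mouse.values()),
            "diam_b": [BASE_DIAMETER_RATIO * v for v in mouse.values()],
        }
    )


@dataclass
class GroundTruth:
    """True per-whisker parameters for a synthetic multi-animal dataset."""

    coeffs: CoefficientSet
    table: pd.DataFrame
    scale_factors: dict[str, float]
    seed: int
    manifest: dict = field(default_factory=dict)

    def observation_table(self) -> pd.DataFrame:
        """Ground-truth values in the observation-table schema."""
        cols = [
            "animal_id", "row", "col", "side",
            "r_bp", "theta_bp", "phi_bp",
            "theta_w", "phi_w", "zeta_w", "S", "A",
        ]
        return self.table[cols].copy()


def make_ground_truth(
    coeffs: CoefficientSet,
    n_animals: int = 8,
    scale_sd: float = DEFAULT_SCALE_SD,
    residual_sds: dict[str, float] | None = None,
    outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
    seed: int = 0,
) -> GroundTruth:
    """Draw a multi-animal ground-truth parameter table.

    Per animal a lognormal(0, ``scale_sd``) head-size factor multiplies
    r_bp and S. Per whisker, every parameter is its generating-equation
    value plus an independent Gaussian residual; a fraction of values is
    displaced by several group SDs to emulate gross digitization errors.
    Same seed, same table, bit for bit.
    """
    sds = dict(DEFAULT_RESIDUAL_SDS)
    if residual_sds:
        sds.update(residual_sds)
    if any(v < 0 for v in sds.values()) or scale_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    scale_factors: dict[str, float] = {}
    for i in range(n_animals):
        animal = f"animal_{i + 1:02d}"
        scale = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd > 0 else 1.0
        scale_factors[animal] = scale
        for side in ("right", "left"):
            for row, col in coeffs.identities():
                theta_bp = float(
                    evaluate(coeffs.equation("theta_bp_from_col"), {"col": col})
                ) + rng.normal(0.0, sds["theta_bp"])
                phi_bp = float(
                    evaluate(coeffs.equation("phi_bp_from_row"), {"row": row})
                ) + rng.normal(0.0, sds["phi_bp"])
                preds = {"theta_bp": theta_bp, "phi_bp": phi_bp}
                r_bp = scale * float(
                    evaluate(coeffs.equation("r_bp_from_angles"), preds)
                ) + rng.normal(0.0, sds["r_bp"])
                S = scale * float(
                    evaluate(coeffs.equation("s_from_theta_bp"), preds)
                ) * float(np.exp(rng.normal(0.0, sds["S_log"])))
                A = max(
                    float(evaluate(coeffs.equation("a_from_theta_bp"), preds))
                    + rng.normal(0.0, sds["A"]),
                    1e-4,
                )
                theta_w = float(
                    evaluate(coeffs.equation("theta_w_reduced"), preds)
                ) + rng.normal(0.0, sds["theta_w"])
                phi_w = float(
                    np.clip(
                        float(evaluate(coeffs.equation("phi_w_from_phi_bp"), preds))
                        + rng.normal(0.0, sds["phi_w"]),
                        -89.0, 89.0,
                    )
                )
                zeta_w = float(
                    evaluate(coeffs.equation("zeta_w_reduced"), preds)
                ) + rng.normal(0.0, sds["zeta_w"])
                rows.append(
                    {
                        "animal_id": animal, "row": row, "col": col, "side": side,
                        "r_bp": r_bp, "theta_bp": theta_bp, "phi_bp": phi_bp,
                        "theta_w": theta_w, "phi_w": phi_w, "zeta_w": zeta_w,
                        "S": S, "A": A,
                    }
                )
    table = pd.DataFrame(rows)
    # gross outliers: displace a random subset of each response well beyond
    # the residual scatter so the 2-SD group filter has something to remove
    if outlier_fraction > 0:
        shift = {
            "theta_bp": OUTLIER_SHIFT_SDS * sds["theta_bp"],
            "phi_bp": OUTLIER_SHIFT_SDS * sds["phi_bp"],
            "r_bp": OUTLIER_SHIFT_SDS * sds["r_bp"],
            "theta_w": OUTLIER_SHIFT_SDS * sds["theta_w"],
            "phi_w": OUTLIER_SHIFT_SDS * sds["phi_w"],
            "zeta_w": OUTLIER_SHIFT_SDS * sds["zeta_w"],
            "S": None,  # multiplicative
            "A": OUTLIER_SHIFT_SDS * sds["A"],
        }
        for response, amount in shift.items():
            mask = rng.random(len(table)) < outlier_fraction
            signs = rng.choice([-1.0, 1.0], size=int(mask.sum()))
            if response == "S":
                table.loc[mask, "S"] *= np.exp(
                    signs * OUTLIER_SHIFT_SDS * sds["S_log"]
                )
            else:
                table.loc[mask, response] += signs * amount
        table["A"] = table["A"].clip(lower=1e-4)
    manifest = {
        "seed": seed,
        "n_animals": n_animals,
        "scale_sd": scale_sd,
        "residual_sds": sds,
        "outlier_fraction": outlier_fraction,
        "species": coeffs.species,
    }
    return GroundTruth(coeffs, table, scale_factors, seed, manifest)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR of a Gaussian matrix) + translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50.0, 50.0, size=3)
    return q, t


def digitize(
    truth: GroundTruth,
    point_spacing: float = 0.75,
    noise_amplitude: float = 0.5,
    seed: int = 0,
):
    """Render ground truth as per-animal raw digitizations.

    Every whisker becomes a 3D polyline with 4-60 points at roughly
    ``point_spacing`` mm; every point (and every landmark) is perturbed
    independently and uniformly by +/-``noise_amplitude`` mm per axis, and
    each animal's full point set is emitted in a random rigid pose.
    """
    from .geometry_frame import RawDigitization

    rng = np.random.default_rng(seed)
    template = (
        rat_landmark_template()
        if truth.coeffs.species == "rat"
        else mouse_landmark_template()
    )
    digs = []
    for animal, sub in truth.table.groupby("animal_id", sort=True):
        scale = truth.scale_factors[animal]
        rot, trans = _random_rigid(rng)
        records = []

        def emit(label, row, col, side, pts):
            pts = np.atleast_2d(pts)
            noisy = pts + rng.uniform(-noise_amplitude, noise_amplitude, pts.shape)
            posed = noisy @ rot.T + trans
            for k, p in enumerate(posed):
                records.append(
                    {
                        "structure_label": label, "row": row, "col": col,
                        "side": side, "point_index": k,
                        "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                    }
                )

        for _, w in sub.iterrows():
            base = from_spherical(
                BasepointSpherical(w["r_bp"], w["theta_bp"], w["phi_bp"])
            )
            shaft = synthesize_ideal(
                w["S"], w["A"], w["zeta_w"], w["phi_w"], w["theta_w"],
                step=point_spacing,
            )
            n_pts = len(shaft)
            if n_pts > 60:
                keep = np.unique(np.linspace(0, n_pts - 1, 60).round().astype(int))
                shaft = shaft[keep]
            elif n_pts < 4:
                shaft = _resample_polyline(shaft, float(w["S"]) / 3.001)
            shaft = base + shaft
            if w["side"] == "left":
                base, shaft = mirror_left(base), mirror_left(shaft)
            emit("whisker_basepoint", int(w["row"]), int(w["col"]), w["side"], base)
            emit("whisker_shaft", int(w["row"]), int(w["col"]), w["side"], shaft)
        for name, p in template.landmarks.items():
            side = None
            label = name
            for suffix in ("_left", "_right"):
                if name.endswith(suffix):
                    side, label = suffix[1:], name[: -len(suffix)]
            emit(label, np.nan, np.nan, side, scale * p)
        digs.append(RawDigitization(str(animal), pd.DataFrame(records)))
    return digs


def render_scan(
    true_whisker_2d: np.ndarray,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM,
    seed: int | None = None,
    max_tip_trim_px: float = 2.0,
) -> WhiskerTrace2D:
    """Emulate a flatbed scan of a flattened whisker.

    The planar shape is quantized to the scanner's pixel grid and each end
    is shortened by a uniform 0-``max_tip_trim_px`` pixels, emulating the
    endpoint-detection uncertainty of semi-automated tracing (about two
    pixels per endpoint). ``pixel_pitch = 0`` disables quantization.
    """
    rng = np.random.default_rng(seed)
    pts = np.asarray(true_whisker_2d, float)
    if pixel_pitch > 0:
        # traces come out of image processing at roughly pixel spacing
        pts2 = np.column_stack([pts, np.zeros(len(pts))])
        pts = _resample_polyline(pts2, pixel_pitch)[:, :2]
    if max_tip_trim_px > 0 and pixel_pitch > 0:
        cum = _cumulative_arclength(pts)
        trim0 = rng.uniform(0.0, max_tip_trim_px) * pixel_pitch
        trim1 = rng.uniform(0.0, max_tip_trim_px) * pixel_pitch
        keep = (cum >= trim0) & (cum <= cum[-1] - trim1)
        if keep.sum() >= 3:
            pts = pts[keep]
    if pixel_pitch > 0:
        pts = np.round(pts / pixel_pitch) * pixel_pitch
        dup = np.concatenate([[False], np.all(np.diff(pts, axis=0) == 0.0, axis=1)])
        pts = pts[~dup]
    return WhiskerTrace2D(pts, pixel_pitch if pixel_pitch > 0 else DEFAULT_PIXEL_PITCH_MM)
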