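"""End-to-end fitting workflow: raw digitizations -> consensus equations.

Chains the frame construction (geometry_frame), per-whisker pose fitting
(pose3d) and the statistical stage (models): grouped outlier removal,
per-animal forward selection and cross-animal consensus. 2D scan traces,
when provided, contribute the arclength/curvature branch with its optional
log transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry_frame import (
    HeadFrame,
    RawDigitization,
    WhiskerIdentity,
    mirror_left,
    standardize_digitization,
    to_spherical,
)
from .models import (
    CoefficientSet,
    ModelEquation,
    consensus_model,
    forward_select,
    remove_outliers,
)
from .pose3d import PoseFitError, WhiskerPointCloud3D, fit_pose

__all__ = ["extract_observations", "fit_consensus_models", "fit_pipeline", "FitResult"]

#: responses fitted on the basepoint angles, with their candidate predictors
RESPONSE_CANDIDATES: dict[str, tuple[str, ...]] = {
    "theta_bp": ("col",),
    "phi_bp": ("row",),
    "r_bp": ("theta_bp", "phi_bp"),
    "theta_w": ("theta_bp", "phi_bp"),
    "phi_w": ("theta_bp", "phi_bp"),
    "zeta_w": ("theta_bp", "phi_bp"),
    "S": ("theta_bp", "phi_bp"),
    "A": ("theta_bp", "phi_bp"),
}
LOG_RESPONSES = ("S", "A")
MIN_S_FOR_ZETA = 8.0


@dataclass
class FitResult:
    observations: pd.DataFrame
    equations: dict[str, ModelEquation]
    per_animal: dict[str, list]
    outlier_reports: list[dict]
    frames: dict[str, HeadFrame] = field(default_factory=dict)


def extract_observations(
    digitizations: list[RawDigitization],
) -> tuple[pd.DataFrame, dict[str, HeadFrame]]:
    """Per-whisker observation table from raw digitizations.

    Each animal is standardized into its head frame; left-side whiskers are
    mirrored across the y-z plane so every pose is expressed in right-array
    convention. Basepoints give (r_bp, theta_bp, phi_bp); the 3D pose fit
    gives (theta_w, phi_w, zeta_w, S, A).
    """
    rows = []
    frames: dict[str, HeadFrame] = {}
    for dig in digitizations:
        std, frame = standardize_digitization(dig)
        frames[std.animal_id] = frame
        for ident, bp in std.basepoints().items():
            shaft = std.shaft_points(ident)
            if ident.side == "left":
                bp, shaft = mirror_left(bp), mirror_left(shaft)
            sph = to_spherical(bp)
            rec = {
                "animal_id": std.animal_id,
                "row": ident.row, "col": ident.col, "side": ident.side,
                "r_bp": sph.r_bp, "theta_bp": sph.theta_bp, "phi_bp": sph.phi_bp,
                "theta_w": np.nan, "phi_w": np.nan, "zeta_w": np.nan,
                "S": np.nan, "A": np.nan, "residual": np.nan, "flags": "",
            }
            if len(shaft) >= 4:
                try:
                    pose = fit_pose(WhiskerPointCloud3D(bp, shaft))
                except (PoseFitError, ValueError):
                    rec["flags"] = "pose_fit_failed"
                else:
                    rec.update(
                        theta_w=pose.theta_w, phi_w=pose.phi_w,
                        zeta_w=pose.zeta_w, S=pose.S, A=pose.A,
                        residual=pose.residual,
                    )
            else:
                rec["flags"] = "too_few_shaft_points"
            rows.append(rec)
    return pd.DataFrame(rows), frames


def fit_consensus_models(
    observations: pd.DataFrame,
    min_support: int = 6,
    outlier_k: float = 2.0,
    exclude_zeta_identities: bool = True,
) -> tuple[dict[str, ModelEquation], dict[str, list], list[dict]]:
    """Outlier filtering, per-animal selection and consensus for all responses.

    Twist angles are only modelled for whiskers of 8 mm or more, and with
    ``exclude_zeta_identities`` the A row and each row's rostral-most
    column are dropped from the twist fit (the documented reduced preset).
    """
    table = observations.copy()
    reports = []
    for response in RESPONSE_CANDIDATES:
        if response in table.columns:
            table, rep = remove_outliers(table, response, k=outlier_k)
            reports.append(rep)
    equations: dict[str, ModelEquation] = {}
    per_animal_all: dict[str, list] = {}
    animals = sorted(table["animal_id"].unique())
    max_col = table.groupby("row")["col"].max()
    for response, candidates in RESPONSE_CANDIDATES.items():
        if response not in table.columns:
            continue
        sub = table
        if response == "zeta_w":
            sub = sub[sub["S"].isna() | (sub["S"] >= MIN_S_FOR_ZETA)]
            if exclude_zeta_identities:
                rostral_most = sub["col"] == sub["row"].map(max_col)
                sub = sub[(sub["row"] != 1) & ~rostral_most]
        allow_log = response in LOG_RESPONSES
        per_animal = []
        for animal in animals:
            data = sub[sub["animal_id"] == animal]
            try:
                per_animal.append(
                    forward_select(data, response, candidates, allow_log=allow_log)
                )
            except ValueError:
                continue
        if not per_animal:
            continue
        per_animal_all[response] = per_animal
        equations[response] = consensus_model(
            per_animal, sub, response, min_support=min_support
        )
    return equations, per_animal_all, reports


def fit_pipeline(
    digitizations: list[RawDigitization],
    min_support: int = 6,
    outlier_k: float = 2.0,
) -> FitResult:
    """Raw digitizations in, consensus equation set out."""
    observations, frames = extract_observations(digitizations)
    equations, per_animal, reports = fit_consensus_models(
        observations, min_support=min_support, outlier_k=outlier_k
    )
    return FitResult(
        observations=observations,
        equations=equations,
        per_animal=per_animal,
        outlier_reports=reports,
        frames=frames,
    )
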