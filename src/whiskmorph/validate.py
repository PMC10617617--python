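"""Self-check computations: worked-example quantities and quick invariants.

The worked-example values are recomputed from the packaged coefficient sets
and closed forms at run time (nothing is hard-coded outside the coefficient
files), so they double as an integrity check on the installed package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import load_coefficient_set

__all__ = ["compute_targets", "quick_checks"]


def compute_targets(seed: int = 0) -> dict[str, dict]:
    """Recompute the package's reference quantities.

    t2 — the curvature-vs-arclength upper-bound function of the mouse
    coefficient set evaluated at zero arclength (its intercept on the
    curvature axis, in 1/mm).
    """
    mouse = load_coefficient_set("mouse")
    ub0 = float(mouse.upper_bound.evaluate(0.0))
    return {"t2": {"value": ub0, "n": 1}}


def quick_checks(seed: int = 0) -> dict[str, bool]:
    """Fast structural invariants of the geometry and generator layers."""
    from .generator import generate_array, register_landmarks
    from .geometry_frame import from_spherical, to_spherical

    rng = np.random.default_rng(seed)
    results: dict[str, bool] = {}

    pts = rng.normal(scale=10.0, size=(200, 3))
    results["spherical_round_trip"] = all(
        np.allclose(from_spherical(to_spherical(p)), p, atol=1e-9) for p in pts
    )

    src = rng.normal(size=(6, 3))
    ang = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(ang), np.sin(ang)
    rot_true = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    tgt = src @ rot_true.T + np.array([1.0, -2.0, 3.0])
    _, _, rmsd = register_landmarks(src, tgt)
    results["registration_exact"] = bool(rmsd < 1e-9)

    arr = generate_array(load_coefficient_set("mouse"))
    right = pd.DataFrame(
        [
            {"row": w.row, "col": w.col, "S": w.S, "phi_w": w.phi_w}
            for w in arr.side("right")
        ]
    )
    results["phi_w_constant_within_row"] = bool(
        (right.groupby("row")["phi_w"].nunique() == 1).all()
    )
    results["s_decreases_rostrally"] = all(
        g.sort_values("col")["S"].is_monotonic_decreasing
        for _, g in right.groupby("row")
    )
    return results
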