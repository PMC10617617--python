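import numpy as np
import pandas as pd
import pytest

from whiskmorph import load_coefficient_set, make_ground_truth


@pytest.fixture(scope="session")
def mouse_coeffs():
    return load_coefficient_set("mouse")


@pytest.fixture(scope="session")
def rat_coeffs():
    return load_coefficient_set("rat")


@pytest.fixture(scope="session")
def default_truth(mouse_coeffs):
    """The default 8-animal synthetic dataset (seeded)."""
    return make_ground_truth(mouse_coeffs, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def make_lattice_digitization(animal_id="m1", jitter=0.0, rng=None, with_shafts=False):
    """Synthetic basepoint lattice already in standard head pose.

    Rows at constant z, columns at constant y, bilateral symmetry, zero
    centroid: the head frame recovered from it is the identity.
    """
    records = []
    shaft_dir = np.array([0.8, 0.5, 0.33166247903554])  # unit-ish
    for row in range(1, 6):
        for col in range(1, 8):
            y = float(col - 4)
            z = float(3 - row)
            x = 5.0 + 0.1 * row + 0.05 * col
            for side, sx in (("right", x), ("left", -x)):
                p = np.array([sx, y, z])
                if jitter and rng is not None:
                    p = p + rng.normal(0, jitter, 3)
                records.append(
                    {
                        "structure_label": "whisker_basepoint",
                        "row": row, "col": col, "side": side, "point_index": 0,
                        "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                    }
                )
                if with_shafts:
                    sign = 1.0 if side == "right" else -1.0
                    for k in range(1, 7):
                        q = p + k * 1.2 * shaft_dir * np.array([sign, 1, 1])
                        records.append(
                            {
                                "structure_label": "whisker_shaft",
                                "row": row, "col": col, "side": side,
                                "point_index": k - 1,
                                "x_mm": q[0], "y_mm": q[1], "z_mm": q[2],
                            }
                        )
    from whiskmorph.geometry_frame import RawDigitization

    return RawDigitization(animal_id, pd.DataFrame(records))
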