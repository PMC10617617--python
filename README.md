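# whiskmorph

Parametric 3D morphology of rodent vibrissal (whisker) arrays.

Mice and rats explore the world with ~30 macrovibrissae per cheek, arranged
in a lattice of rows (A–E, dorsal to ventral) and columns (1 = the caudal
"Greek arc", up to 7 rostrally). To simulate the tactile signals this
system acquires — or to design stimuli for neurophysiology — one needs a
quantitative model of where each whisker is and how it is shaped and
oriented. `whiskmorph` implements such a model as a two-way toolkit:

* a **fitting pipeline** that takes raw 3D digitizations of whisker
  basepoints, whisker shafts and facial landmarks (plus 2D flatbed scans of
  plucked whiskers) and derives the model's regression equations; and
* a **generator** that evaluates a stored coefficient set to synthesize a
  complete average 3D whisker array with facial landmarks, and compares
  arrays across species.

## The model

All lengths are in mm, angles in degrees, curvature in 1/mm. The
head-centered frame has its origin at the mean of all bilaterally matched
whisker basepoints; the horizontal plane is the *average whisker row plane*
(mean of least-squares planes through each row's basepoints); +x points
through the right array's centroid, +y rostral, +z dorsal. Left arrays are
mirrored across the y–z plane so every equation is a right-array equation.

Each whisker is described by eight parameters:

| parameter | meaning |
|---|---|
| r_bp, θ_bp, φ_bp | spherical basepoint coordinates (radius, horizontal angle — rostral positive, elevation — dorsal positive) |
| S | arclength of the whisker (sum of trace segment lengths) |
| A | intrinsic curvature coefficient of the parabola y = A·x² fitted to the proximal 65 % |
| θ_w, φ_w, ζ_w | resting emergence angles: yaw (0° caudal, 180° rostral), pitch (+90° dorsal) and twist about the whisker's own axis (0° concave down, 90° concave forward) |

The model equations are low-order regressions: θ_bp is linear in column and
φ_bp in row; r_bp is linear in (θ_bp, φ_bp); S decays exponentially with
θ_bp (S ≈ 11.7 mm at the rostro-caudal center, θ_bp = 0); A grows linearly
with θ_bp with an upper bound A_ub(S) whose value at S = 0 is
0.012 mm⁻¹; θ_w is linear in θ_bp, φ_w in φ_bp, and ζ_w in both. Fitting
uses per-animal forward selection (terms enter at p ≤ 0.05, order escalates
to quadratic only when AIC improves by > 2) followed by a cross-animal
consensus (a term needs support from at least 6 animals).

The packaged mouse and rat coefficient sets
(`src/whiskmorph/data/*_synthetic.json`) are synthetic reconstructions
anchored to the published summary values of the source study (whose raw
data are deposited at https://doi.org/10.5281/zenodo.7992354); see
`docs/methods.md` for exactly which values anchor which coefficients.

## Worked example

Generate the average mouse array, then compare mouse and rat facial
layouts:

```bash
$ whiskmorph generate --species mouse --out out/
generated 60 whiskers -> out

$ whiskmorph compare --out out/
rostro-caudal slope 2.030; bilateral fit y=1.49x+1.45; diameter slope 2.35
```

The first command writes `mouse_array.csv` (polyline points for 30 right +
30 mirrored left whiskers), an OBJ export and a landmark JSON. The second
prints the cross-species scaling factors recomputed from the landmark
layouts and the paired base-diameter table: rostro-caudal distances between
rat facial features are 2.03× the mouse's, bilateral distances follow
y = 1.49·x + 1.45, and rat whisker base diameters are 2.35× thicker.

From Python, the same fitting machinery runs end to end on synthetic data
with known ground truth:

```python
from whiskmorph import load_coefficient_set, make_ground_truth, digitize
from whiskmorph.pipeline import fit_pipeline

coeffs = load_coefficient_set("mouse")
truth = make_ground_truth(coeffs, n_animals=3, seed=31)      # 8 is the study design
digs = digitize(truth, noise_amplitude=0.5, seed=32)          # ±0.5 mm digitizer noise
result = fit_pipeline(digs, min_support=3)
print({k: round(v, 3) for k, v in result.equations["theta_bp"].terms.items()})
# {'1': -67.202, 'col': 19.027}   (generating values: -66.817, 19.0)
```

`simulate` and `fit` expose the same loop on the command line; `validate`
recomputes the package's reference quantities and quick invariants.

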