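# fodeform

Prediction of foot-orthosis plantar-surface deformation during walking from
contour marker-cluster orientations, with a neural-network surrogate trained
per orthosis, rigid/non-rigid motion separation, and nonparametric
statistical comparison of orthosis conditions.

## The scientific problem

A foot orthosis (FO) deforms under the plantar load of every step, and that
deformation — how much the surface is pressed down, where, and when in the
stance phase — is exactly what distinguishes one orthosis design from
another in use. But the plantar surface is hidden inside the shoe: no
optical motion-capture system can see it during walking.

What *can* be tracked are small three-marker clusters ("triads") glued
around the FO contour, which protrude from the shoe. Because each triad
rides on the deforming surface, its orientation encodes the local
deformation state. `fodeform` exploits this: in a dedicated **training
session** the FO is held outside the shoe, its surface is covered with
markers, and an instrumented stick applies point loads across all ten
plantar regions, so that triad orientations and surface-point positions are
recorded simultaneously. A neural-network **surrogate** learns the mapping
from the 15 orientation features (Cardan angles of five triads relative to
the Back triad) to the 165 surface coordinates (55 virtual plantar points).
In subsequent **walking sessions** only the triads are visible; the
surrogate reconstructs the hidden surface frame by frame.

From the reconstructed surface the package:

* removes the whole-FO rigid motion per frame (optimal rototranslation via
  polar decomposition), leaving the non-rigid deformation;
* extracts the vertical depression/reformation of each point, normalized to
  101 samples of the stance phase, giving a 55 × 101 deformation field per
  subject and condition;
* compares two orthosis conditions across subjects with a nonparametric
  statistical-parametric-mapping (SPM) paired test: a t-statistic per cell
  and a family-wise threshold from the exhaustive sign-flip permutation
  distribution of the field-wide maximum |t|, with connected
  supra-threshold clusters on the surface-grid × time lattice.

Because a real bench-and-gait data set cannot ship with the code, the
package includes a synthetic deformable-orthosis simulator (Gaussian-kernel
point-load deformation with surface-following triads, stick-loading and
walking protocols, configurable stiffness and marker noise) on which the
entire method is exercised and validated end to end against known ground
truth. See [docs/methods.md](docs/methods.md) for the model, every
parameter, and what the generator does and does not emulate.

## Worked example

Train a surrogate on a simulated training session of a compliant orthosis,
then reconstruct its deformation field during simulated walking where the
surface markers are hidden:

```python
import numpy as np
from fodeform import (
    FINAL_CONFIG, build_dataset, make_fo_model, predict_surface,
    rmse, simulate_training_session, simulate_walking_session, train,
)
from fodeform.pipeline import ground_truth_field, walking_deformation

# A compliant ("sport") orthosis: stiffness 5 N/mm, Gaussian kernel sigma 25 mm.
fo = make_fo_model(stiffness_k=5.0, kernel_sigma=25.0, seed=0)

# Training session: stick loads over all ten regions, 0.1 mm marker noise.
scene = simulate_training_session(fo, n_loads_per_region=8, seed=1)
dataset = build_dataset(scene, seed=2, filter_cutoff=8.0)

# Train the selected architecture on the 85% learning split, score the rest.
model = train(*dataset.learning, FINAL_CONFIG)
x_test, y_test = dataset.test
per_marker, summary = rmse(y_test, predict_surface(model, x_test))
print(f"held-out RMSE: {summary['mean']:.3f} +/- {summary['sd']:.3f} mm "
      f"over {len(x_test)} frames")

# Walking: only the contour triads are observed; predict the hidden surface,
# remove the rigid motion, normalize each stance to 101 samples.
walk = simulate_walking_session(fo, n_steps=10, peak_force=30.0, seed=3)
field, cycles, stances = walking_deformation(walk, model, filter_cutoff=8.0)
truth = ground_truth_field(walk, stances)
corr = np.corrcoef(field.values.ravel(), truth.values.ravel())[0, 1]
print(f"peak depression: {field.values.min():.2f} mm "
      f"(truth {truth.values.min():.2f} mm), field correlation {corr:.3f}")
```

Output:

```
held-out RMSE: 0.216 +/- 0.052 mm over 651 frames
peak depression: -4.63 mm (truth -4.53 mm), field correlation 0.989
```

The full two-condition study — sport (5 N/mm) vs. regular (12 N/mm)
orthosis, eight subjects wearing both, SPM comparison of the deformation
fields — is one call (or `fodeform run --seed 1 --out results/run` from the
shell):

```python
from fodeform.pipeline import PipelineConfig, run_pipeline
art = run_pipeline(PipelineConfig(seed=1), outdir="results/run")
print(art["spm"].threshold, art["spm"].clusters[0].extent)
```

A command-line interface mirrors the stages: `fodeform simulate`,
`build-dataset`, `train`, `validate`, `walk`, `compare`, and `run`; see
`fodeform --help`.

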