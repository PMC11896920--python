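# gutmotion

Quantification and characterisation of **small intestinal motility in 3D
cine-MRI** using centerline-aware motion estimation.

Conventional 2D cine-MRI motility tools measure only the local magnitude of
intestinal motion; they cannot tell coordinated peristalsis apart from
uncoordinated mixing, because that distinction requires correlating motion at
multiple known positions along the gut. `gutmotion` works in 3D: given a 4D
cine acquisition (one volume per second) and the centerline of a
small-intestinal segment, it estimates the local velocity of luminal content
*along* the segment and aggregates it into interpretable motility metrics.

The pipeline, per segment:

1. **Bidirectional deformable registration** of consecutive frames inside a
   40 mm tube around the centerline. Two sinusoidal coordinate networks
   (SIRENs) are optimised jointly — one maps frame *t* coordinates towards
   frame *t+1*, the other back — under a composite objective: normalised
   cross-correlation (NCC) of the linked intensities, a symmetric Jacobian
   determinant penalty, and a cycle-consistency penalty, trained with a
   one-cycle learning-rate schedule (1500 iterations at full scale). The
   backend is implemented in pure NumPy with hand-written backpropagation
   and is pluggable: an analytic oracle backend serves ground-truth fields
   for validation.
2. **Common-mode suppression.** At each centerline point the mean
   displacement over a large disc (⌀ 30 mm, orthogonal to the local tangent)
   is subtracted from the mean over a small disc (⌀ 0.5 mm). Motion shared
   with the surroundings — breathing, cardiac, adjacent loops — cancels;
   motion confined to the lumen survives. Any spatially uniform field is
   rejected exactly.
3. **Centerline propagation.** Every frame is also registered directly to
   the frame in which the centerline was defined; the sampled displacements
   are smoothed with an 8 mm moving average along the centerline and a 3 s
   moving average across time, then added to the reference points.
4. **Velocity projection.** The suppressed displacement at each propagated
   centerline point is projected onto the local unit tangent and divided by
   the frame interval: a signed local velocity *v(s, t)* in mm/s (positive =
   towards the end of the centerline).
5. **Metrics and classification.** Two global metrics summarise the
   space–time velocity map:

   - **mean velocity** ⟨v⟩ — net peristaltic transport (opposing motions
     cancel);
   - **mean absolute velocity** ⟨|v|⟩ — motility magnitude irrespective of
     direction.

   Two serial 1-D linear classifiers turn these into labels: a threshold on
   ⟨|v|⟩ detects motility; two cut points on ⟨v⟩ assign motile segments a
   direction (backward / bidirectional / forward). Thresholds are fitted by
   exhaustive accuracy-maximising search under five-fold cross-validation
   grouped by subject, and evaluated with ROC AUC, accuracy and Cohen's
   kappa.

Because clinical cine-MRI scans are not distributable, the package ships a
first-class **phantom module**: synthetic 4D volumes of a bright, textured,
fluid-filled tube with prescribed Poiseuille-like luminal flow, optional
wall contraction waves, breathing-like common-mode drift and additive noise
— with the exact frame-to-frame displacement of every world point available
as an oracle for every downstream stage.

## Worked example

Generate a compact peristaltic phantom (constant +2 mm/s peak luminal flow)
and analyse it with the ground-truth oracle backend:

```bash
gutmotion phantom --kind motile_forward --seed 1 --compact --output-dir demo/phantom
gutmotion analyze --volume demo/phantom/phantom.nii \
                  --centerline demo/phantom/centerline.csv \
                  --backend oracle --phantom-json demo/phantom/phantom_config.json \
                  --output-dir demo/analysis
```

which prints

```
INFO gutmotion: mean velocity 1.749 mm/s, mean absolute velocity 1.749 mm/s
```

and writes `demo/analysis/metrics.json` / `velocity_map.csv`. The prescribed
peak flow is 2 mm/s; the method reports 1.749 mm/s. The ~12.5% shortfall is
intrinsic and expected: the 30 mm outer suppression disc still contains the
moving lumen, which for a parabolic flow profile of radius R subtracts
`v·R²/(2·15²)` ≈ 0.125 v from the centerline estimate. Mean velocity equals
mean absolute velocity here because the flow never changes sign; a
`bidirectional` phantom instead yields ⟨v⟩ ≈ 0 with large ⟨|v|⟩, and a
`non_motile` (breathing-drift only) phantom yields ⟨|v|⟩ ≈ 0 because the
drift is rejected as common mode.

To use the trained registration instead of the oracle, drop
`--backend oracle`/`--phantom-json` (add `--full-profile` for the
1500-iteration schedule). `gutmotion classify` runs subject-grouped
cross-validated classification on a segment table CSV, and
`gutmotion evaluate` computes accuracy/kappa/contingency between label
columns.

## Library use

```python
import gutmotion as gm
from gutmotion.phantom import preset_phantoms, generate_phantom
from gutmotion.registration import OracleBackend

frames, centerline, truth = generate_phantom(preset_phantoms("bidirectional", seed=0, compact=True))
vmap = gm.compute_velocity_map(frames, centerline, OracleBackend(truth))
metrics = gm.aggregate_metrics(vmap)
print(metrics.mean_velocity, metrics.mean_absolute_velocity)
```

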