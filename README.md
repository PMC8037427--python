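# thermofoot

Registration of thermal-infrared and visible images of feet, with
multi-rater reference segmentations and overlap-based evaluation.

Remote monitoring of the diabetic foot pairs a visible RGB camera with a
low-cost thermal camera on a rigid mount: abnormal plantar temperature
patterns are an early sign of ulcer formation, and detecting them needs
the two sensors' images aligned pixel-for-pixel.  The cameras differ in
resolution (1280×720 visible vs 384×288 thermal), field of view and
mounting position, so the visible frame must be mapped into the thermal
frame by an estimated spatial transform.  `thermofoot` implements and
benchmarks four estimators for that transform:

| Method | Model | Data used |
|---|---|---|
| **GOT** (geometric optical translation) | fixed angular-resolution scaling + translation `T(x) = x + t` | checkerboard keypoints |
| **Homography** | full projective `T(x) = Hx`, 8 d.o.f., RANSAC + normalized DLT | checkerboard keypoints |
| **ICP** | rigid `T(x) = R(x−c) + t + c` on contour keypoints, closed-form SVD fits | segmentation masks |
| **Affine-ASGD** | affine `T(x) = A(x−c) + t + c`, 6 d.o.f., adaptive stochastic gradient descent | segmentation masks |

Registration quality is scored against reference segmentations fused from
several imperfect raters by the STAPLE EM algorithm (which jointly
estimates each rater's sensitivity p_j and specificity q_j), using the
Dice coefficient, Jaccard index, signed volume similarity, and
false-negative / false-positive fractions.  A distance-robustness
experiment freezes each method's transform at the 800 mm focal plane and
re-scores it at 760–850 mm.

Real clinical images of this kind are not redistributable, so the package
ships a fully synthetic two-camera rig (`thermofoot.synthgen`): foot-shaped
binary masks on a metric world plane, pinhole-style projections with known
ground-truth transforms at every distance, dual-spectrum checkerboard
calibration targets, Bernoulli raters with known performance, and
timestamped frame streams for software synchronization.  Every generator is
a pure function of an explicit seed.

## Worked example

```python
from thermofoot import PipelineConfig, run_pipeline

table = run_pipeline(PipelineConfig(seed=1, output_dir="run1"))
dice = table[table.metric == "dice"].pivot(
    index="distance_mm", columns="method", values="value")
print(dice.round(4))
```

```
method       Affine-ASGD     GOT  Homography     ICP
distance_mm
760.0             0.9767  0.9768      0.9743  0.9744
780.0             0.9850  0.9877      0.9853  0.9847
800.0             0.9902  0.9879      0.9901  0.9862
820.0             0.9833  0.9804      0.9825  0.9795
835.0             0.9764  0.9738      0.9760  0.9757
850.0             0.9714  0.9674      0.9717  0.9680
```

Each cell is the Dice overlap between the registered visible-mask and the
thermal reference mask at one working distance, using the transform each
method estimated at the 800 mm focal plane.  All methods peak at the focal
plane and degrade toward the edges of the ±50 mm band while staying above
0.95; the affine and homography models, which can absorb the small
inter-sensor scale difference, edge out the fixed-scale GOT and rigid ICP
at the focal plane.  `run1/` receives the full 120-row table
(`robustness.csv`), the estimated transforms as JSON, and a frame-sync
report.

The same pipeline is scriptable from the shell:

```bash
thermofoot run-all --seed 1 --out run1
thermofoot generate --out scenes --seed 0          # synthetic scene pairs
thermofoot staple r1.png r2.png --out-prefix fused # rater fusion
thermofoot register --method icp --visible-mask vis.png \
    --thermal-mask ir.png --out transform.json
```

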