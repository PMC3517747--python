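# kneekin

3D tibiofemoral and patellofemoral knee kinematics from segmented MRI
geometry.

Knee instability — in particular deficiency of the posterior cruciate
ligament (PCL) — alters how the femur, tibia and patella move relative to
each other, and those altered motion patterns are a suspected driver of
osteoarthritis. Quantifying them in vivo requires measuring 3D joint
kinematics from static MR acquisitions of the knee in several flexion
positions, with and without isometric flexor-muscle loading. `kneekin`
implements that measurement pipeline for anyone working with segmented
knee geometry (label volumes or surface meshes): biomechanics researchers,
medical-image analysts, and anyone who needs a tested, reproducible
implementation of these joint parameters.

## What it computes

Starting from per-structure segmentations (femur, tibia, patella, plus the
tibial-plateau, posterior-condylar and trochlear articular surfaces), per
acquisition:

* **Tibial frame** — origin at the area-centroid of the tibial plateau;
  axes from the plateau's principal directions (`x_t` medio-lateral, `y_t`
  anterior, `z_t` proximal).
* **Epicondylar axis** — least-squares cylinder fitted to both posterior
  condylar surfaces, minimising Σ(dᵢ − r)² over axis direction, anchor and
  radius; medial/lateral reference points are the condylar centroids
  projected onto the axis, the femoral centre their midpoint.
* **Tibiofemoral kinematics** — reference-point AP positions in the tibial
  frame and the epicondylar rotation (angle of the projected
  medial→lateral axis to `x_t`, internal rotation positive), differenced
  across flexion positions (0°, 30°, 90°) and muscle states.
* **Patellofemoral parameters** in a patella-based coordinate system
  (PBCS; origin at the patellar volume centroid C, `Py` longitudinal,
  `Px` medio-lateral, `Pz` anterior): patellar height = dist(IPP, tibial
  ML axis); patellofemoral angle = ∠(`Py`, femoral long axis); patellar
  tilt = ∠(trochlear facet line Pmin1→Pmin2, `Px`), medial opening
  positive; patellar shift = (C − Pmax)·`x_t`, lateral positive, with
  Pmax the trochlear sulcus floor.

A synthetic knee generator (`kneekin.synthetic_knee`) builds parametric
femur/tibia/patella scenes with exactly known ground truth and samples
cohorts calibrated to published healthy and PCL-deficient per-condition
means and standard deviations (healthy n = 20, PCL-deficient n = 12),
so the entire chain is testable without patient data. A statistics layer
mirrors the study-style summary tables and paired/unpaired t comparisons.
See `docs/methods.md` for conventions, algorithms and limitations.

## Worked example

Measure the default PCL-deficient knee phantom at 30° and 90° flexion and
a calibrated 12-subject cohort:

```python
import kneekin as kk
from kneekin.pipeline import measure_cohort
from kneekin.synthetic_knee import MotionModel

shape = kk.KneeShapeParams()
motion = MotionModel.pcl_deficient_default()
for flexion in (30, 90):
    scene = kk.generate_knee(shape, motion, flexion, "relaxed")
    rec = kk.measure_record(scene)
    print(f"{flexion:>2} deg: medial AP {rec.medial_ap:+.1f} mm, "
          f"lateral AP {rec.lateral_ap:+.1f} mm, rotation {rec.rotation:+.1f} deg, "
          f"tilt {rec.tilt:.1f} deg, shift {rec.shift:.1f} mm")

cohort = kk.sample_cohort(kk.CohortSpec(group="pcl_deficient", n=12, seed=1))
records = measure_cohort(cohort, conditions=[(90, "relaxed")])
print(f"cohort mean tilt  {records['tilt'].mean():.1f} deg")
print(f"cohort mean shift {records['shift'].mean():.1f} mm")
```

prints

```
30 deg: medial AP -2.0 mm, lateral AP -2.0 mm, rotation +0.0 deg, tilt 9.7 deg, shift 2.4 mm
90 deg: medial AP +4.0 mm, lateral AP -0.0 mm, rotation -4.0 deg, tilt 13.1 deg, shift 6.7 mm
cohort mean tilt  14.2 deg
cohort mean shift 5.7 mm
```

Reading the single-knee lines: from 30° to 90° the medial condyle
translates 6 mm *anteriorly* (−2.0 → +4.0 mm) while the lateral condyle
stays nearly put — the paradoxical anterior translation characteristic of
PCL deficiency — and the epicondylar axis rotates 4° externally. The tilt
and shift values are the imposed per-condition calibration means,
recovered exactly by the measurement chain on mesh input. The cohort lines
show 12 subjects drawn around that calibration (means 13.1° / 6.7 mm) and
measured end-to-end; the cohort means land within sampling error of the
calibration.

## Command line

```sh
kneekin simulate --group both --n-healthy 20 --n-pcl 12 --seed 1 --out data/
kneekin measure  --dataset data/ --out measured/
kneekin stats    --records measured/records.csv --out stats/
kneekin report   --stats-dir stats/
```

`simulate` writes per-subject/condition mesh scenes (ASCII PLY; NIfTI
label volumes with `--voxel-spacing`), a ground-truth table and a seeded
manifest; `measure` runs the full pipeline over a dataset directory;
`stats` writes the summary table (CSV + aligned text) and the group
comparison table; `report` prints them.

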