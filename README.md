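# kneemorph

Landmark-coordinate geometry for lower-limb alignment angles on full-leg AP
radiographs — including the trochlear-groove bisector angle — together with
multi-rater agreement statistics (extended Bland–Altman / limits of agreement
with the mean, absolute-agreement ICC, repeatability coefficient) and a
synthetic-cohort generator for end-to-end validation without image data.

## What it computes

From digitized named landmark coordinates, per annotation:

| angle | definition |
|---|---|
| `hka_deviation` | hip–knee–ankle angle as a signed deviation from 180° (varus negative) |
| `mldfa` | lateral angle, femoral mechanical axis vs distal femoral joint line |
| `mmpta` | medial angle, tibial mechanical axis vs tibial plateau line |
| `tga` | angle at the trochlear groove apex between the medial and lateral facet tangents |
| `ba` | medial angle between the proximal groove bisector and the femoral joint line (perpendicular = 90°; < 90° = medial lean) |

From a complete crossed subjects × observers × occasions table of one angle:
ANOVA variance components, two-way random-effects absolute-agreement ICC
(single and average forms, F-based 95% CI), LOAM halfwidth, extended
Bland–Altman plot data, and (single observer, repeated occasions) the
repeatability coefficient.

All angles are invariant under translation, rotation, uniform scaling, and
mirror + side flip of the landmarks; tangent points may be digitized directly
or derived from facet contour samples via a supporting-line search.

## CLI

```bash
# synthetic fixture (landmarks.csv, angles.csv, truth.csv, config echo)
kneemorph simulate --out fixtures/demo --seed 1 --n-subjects 59

# measure all five angles from a landmarks CSV
kneemorph measure --landmarks fixtures/demo/landmarks.csv --out angles.csv

# agreement report (JSON) + extended Bland–Altman plot data (CSV)
kneemorph agree --angles angles.csv --angle ba --out reports/

# all of the above: inter-rater arm (m=3, r=1) + intra-rater arm (m=1, r=3)
kneemorph pipeline --out runs/demo --seed 1
```

Options may also be given in a YAML config (`--config run.yaml`); explicit
flags win. All randomness flows from the single `--seed`; identical seeds
give byte-identical outputs.

### File schemas

* **Landmarks CSV** — one row per point: `subject_id, side, observer_id,
  occasion, landmark, point_index, x, y`. Landmark names come from a closed
  vocabulary (`hip_center, femoral_notch_center, trochlear_apex,
  trochlear_tangent_medial, trochlear_tangent_lateral, condyle_medial,
  condyle_lateral, tibial_spines_center, ankle_center, plateau_medial,
  plateau_lateral`); contour samples use `trochlear_contour_medial` /
  `trochlear_contour_lateral` with a `point_index`. Parsing is strict.
* **Angles CSV** — wide, one row per subject × observer × occasion with the
  five angle columns.
* **Agreement report** — JSON with full-precision values plus a `printed`
  block rounded to 0.1° (ICC to 3 decimals).

## Library sketch

```python
from kneemorph import (AngleSet, PopulationConfig, ObserverConfig,
                       build_subject_geometry, measure_all,
                       simulate_angle_table, agreement_report)

ann = build_subject_geometry(AngleSet(0.0, 87.6, 88.0, 30.0, 89.4))
assert abs(measure_all(ann).ba - 89.4) < 1e-9

table = simulate_angle_table(PopulationConfig(), ObserverConfig(seed=1), "ba")
report = agreement_report(table)
print(report.to_json())
```
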