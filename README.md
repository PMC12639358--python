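# trapdiel

Camera-trap diel activity analysis for wildlife ecologists: who is active
when, how strongly species select parts of the diel cycle, and whether human
disturbance — here, tourist presence in a protected area — shifts those
patterns.

The package implements the full analysis pipeline of a tropical camera-trap
tourism study at desk scale:

* **Temporal independence** — greedy per-(site, species) filtering with a
  1-hour rule.
* **Solar time bands & electivity** — Sunrise/Day/Sunset/Night bands from
  monthly mean sun times, and Jacobs' index
  `D = (r − p)/(r + p − 2rp)` per band with a bootstrap (10,000
  replicates by default).
* **Circular KDE** — von Mises kernel density of activity on the 24-h
  circle with the plug-in bandwidth rule of the overlap literature.
* **Activity overlap** — `Δ̂₁` (grid) below 75 detections, `Δ̂₄` (points)
  otherwise; `Δ = ∫ min(f̂, ĝ)` on [0, 1]; smoothed-bootstrap 95% CIs;
  Watson's two-sample `U²` test; percentile classification of overlaps
  (low ≤ P50 < moderate ≤ P75 < high) within the comparison set.
* **Watson's `U²`** — one-sample uniformity and two-sample homogeneity
  tests with finite-sample-corrected asymptotic p-values.
* **Species accumulation** — randomised (1000×) accumulation curves over
  camera-trap-days with confidence bands.
* **Checklist summaries** — richness arithmetic over a packaged 60-species
  mammal checklist (Karen Mogensen Wildlife Refuge, Nicoya Peninsula,
  Costa Rica).
* **Synthetic surveys** — a generator with von Mises mixture activity
  profiles, Poisson detection rates, tourist-day phase shifts/rate
  multipliers, and analytic ground-truth overlap, so every stage can be
  validated against known truth.

The central objects follow the model/results idiom: build a
`TourismStudy` (or `OverlapModel`) from data, call `.fit()`, and read the
estimates, intervals, tests and `summary()` from the returned report.

## Worked example

Simulate a study-shaped survey (6 cameras × 102 days, 52 tourist days, no
injected tourism effect) and run the full comparison:

```python
import trapdiel as td

survey = td.generate_survey(design=td.SurveyDesign(seed=42))
study = td.TourismStudy.from_survey(survey)
report = study.fit(seed=42, bootstrap_reps=2000)
print(report.summary())
```

```
Tourism impact on diel activity
==================================
independent detections: 489 (of 495 raw)
tourist days: 52 present / 50 absent

unit                           n+   n-  est    Delta  95% CI              U2       p  class
-------------------------------------------------------------------------------------------
agouti                         38   43  Dhat1  0.864  [0.68, 0.94]     0.135   0.140  low
coati                          46   37  Dhat1  0.943  [0.76, 0.94]     0.035   0.889  high
deer                           18   24  Dhat1  0.931  [0.71, 0.97]     0.045   0.779  low
peccary                       111  102  Dhat4  0.932  [0.83, 0.96]     0.058   0.621  moderate
whole community               249  240  Dhat4  0.936  [0.87, 0.96]     0.078   0.427  high
diurnal species               214  207  Dhat4  0.920  [0.85, 0.96]     0.116   0.204  low
nocturnal species              34   30  Dhat1  0.906  [0.71, 0.94]     0.073   0.477  low
omnivores and carnivores       74   62  Dhat1  0.931  [0.77, 0.96]     0.039   0.841  low
herbivores                    175  178  Dhat4  0.931  [0.85, 0.96]     0.128   0.159  moderate
```

Each row compares one analysis unit's activity density on tourist days
(`n+` detections) against tourist-free days (`n-`): `Delta` is the overlap
coefficient (1 = identical patterns) with its smoothed-bootstrap CI, `U2`
and `p` are Watson's two-sample test, and `class` ranks the overlap against
the other comparisons' percentiles. Here — by construction, since no effect
was injected — every overlap is high (≥ 0.86) and no test is significant:
the pipeline correctly reports no tourism impact. The electivity of a
diurnal species looks like:

```python
ind = td.filter_independent(survey.records, 60)
coati = td.DielSample("coati", [r for r in ind if r.species == "coati"])
print(td.bootstrap_selectivity(coati, survey.solar, reps=2000, seed=1).summary())
```

```
Jacobs electivity: coati (n=83 independent detections)
  Sunrise  r=0.012 p=0.083 D=-0.763 boot mean -0.778 [-1.000, -0.416]
  Day      r=0.916 p=0.422 D=+0.874 boot mean +0.874 [+0.780, +0.965]
  Sunset   r=0.048 p=0.083 D=-0.285 boot mean -0.329 [-0.763, +0.080]
  Night    r=0.024 p=0.411 D=-0.932 boot mean -0.932 [-1.000, -0.832]
```

i.e. strong selection for daylight (D = +0.87) and avoidance of night
(−0.93), as a diurnal profile should produce.

The same steps are exposed on the command line:

```bash
trapdiel simulate --seed 42 --out-dir sim/
trapdiel tourism-report --detections sim/detections.csv --solar sim/solar.csv \
    --calendar sim/calendar.csv --traits sim/traits.csv --out-dir report/
trapdiel checklist-summary
```

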