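# leafletmotion

Quantitative analysis of aortic valve leaflet motion from a single
parasternal long axis (PLAX) echocardiographic view.

Grading aortic stenosis (AS) severity usually requires Doppler
hemodynamics, yet the restricted excursion of the aortic leaflets is
visible — and currently judged only qualitatively — in the very first
PLAX clip of every study. `leafletmotion` turns five manually annotated
landmarks on the anterior (right coronary) leaflet (base/hinge `B`,
midpoint `M`, tip `T`, aortic wall at the sinotubular junction `A`,
opposing hinge `OB`), in one open and one closed frame, into eight
per-patient motion metrics, and carries those metrics through group
statistics, reliability analysis, and supervised severity classification.

With base-anchored vectors `v_x = x − B` (in mm, after per-axis pixel
calibration) and the global vector `v_G = (v_M + v_T)/2`:

* linear displacement `ld_x = ‖v_x(sys) − v_x(dia)‖₂` at `M`, `T`, and
  `G` (mm);
* angular displacement `ad_x = |θ_x(sys) − θ_x(dia)|` at `M` and `T`,
  where `θ_x = ∠(v_x, v_A)` from the clamped normalized dot product, with
  `ad_global = (ad_mid + ad_tip)/2` (degrees; an optional `B→OB`-based
  whole-heart rotation correction is available);
* linearity: the diastolic internal angle at apex `M` between `M→B` and
  `M→T` (180° = straight, calcified leaflet);
* flexibility: `|internal angle(sys) − internal angle(dia)|`.

The cohort stage applies Kruskal–Wallis omnibus tests, Games–Howell
post-hoc pairs with Holm–Bonferroni adjustment, Pearson correlation with
aortic valve area, ICC(2,1) reliability on a 10% re-measurement sample,
and a Monte-Carlo power routine. The modelling stage trains elastic-net
logistic regression, k-NN and random-forest classifiers (collinearity
filter at |r| > 0.9, stratified 80:20 split, 5-fold CV tuning) for two
tasks: significant AS (moderate-or-worse) as a binary outcome, and the
three-class severity grade with septal/posterior wall thickness added.

Because the underlying echocardiograms are not publicly deposited, the
package includes a first-class synthetic cohort generator whose
class-conditional marginals are moment-matched to the published per-class
mean ± SD (lognormal on positive support, truncated normals for bounded
quantities, single-latent-factor Gaussian copula within class), plus a
landmark-level simulator with exact analytic ground truth and simulated
rater replicates. See `docs/methods.md` for the model, parameters and
limitations.

## Worked example

```python
import leafletmotion as lm

config = lm.SimulationConfig(seed=1)
cohort = lm.cohort_to_frame(lm.simulate_feature_cohort(config))

table = lm.descriptive_table(cohort)
print(table[["characteristic", "control", "moderate", "severe", "p_value"]]
      .iloc[[3, 6, 8]].to_string(index=False))

r, p = lm.pearson_correlation(cohort["ld_global"], cohort["ava"])
print(f"corr(ld_global, AVA): r = {r:.2f}")

fitted, report = lm.run_task(cohort, "binary_significant_AS",
                             "elastic_net_logistic", seed=1)
print(f"binary significant-AS: AUC = {report.auc:.3f}, "
      f"accuracy = {report.accuracy:.3f}")
print("top features:", ", ".join(lm.feature_importance(fitted).feature.head(3)))
```

prints

```
                      characteristic       control      moderate      severe      p_value
  Linear displacement, averaged (mm)   8.70 ± 2.32   3.55 ± 2.21 1.85 ± 1.35 1.013065e-28
Angular displacement, averaged (deg) 46.37 ± 11.81 20.46 ± 16.48 8.71 ± 8.01 1.408929e-26
                   Flexibility (deg) 52.43 ± 14.62   8.52 ± 9.60 3.06 ± 3.06 6.181421e-30
corr(ld_global, AVA): r = 0.87
binary significant-AS: AUC = 0.970, accuracy = 0.925
top features: flexibility, ld_mid, ad_global
```

Global leaflet motion collapses from ~9 mm and ~46° in controls to
~2 mm and ~9° in severe AS (omnibus p ≪ 0.001 per row), correlates
strongly with valve area, and the eight motion metrics alone separate
significant AS from controls on the held-out 20% with AUC 0.97.

The same flow is available from the shell:

```sh
leafletmotion simulate --seed 1 --landmark-mode --outdir run/data
leafletmotion extract run/data/annotations.csv --out run/metrics.csv --correct-rotation
leafletmotion stats run/data/patient_records.csv --metrics run/metrics.csv --outdir run/stats
leafletmotion classify run/data/patient_records.csv --task binary --model enet --outdir run/models
leafletmotion run --seed 1 --outdir run/full     # all stages + manifest
```

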