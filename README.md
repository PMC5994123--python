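# densethresh

Threshold-adjusted mammographic percent density and its evaluation as a
breast-cancer risk factor in matched case-control cohorts.

Volumetric breast-density software estimates, at every pixel of a raw
digital mammogram, the height *h* (mm) of radiodense fibroglandular tissue
— a "density map".  The conventional volumetric percent density uses all
of this tissue; this package implements the *thresholded* family of
measures, which discard tissue of height ≤ *t* mm before summarizing:

* **VPD(t)** = 100 · Σ{h : h > t, in breast} · a / (T · A_breast) — dense
  volume above the threshold as a percentage of breast volume (pixel area
  *a*, compressed-breast thickness *T*);
* **APD(t)** = 100 · #{pixels : h > t} / #{breast pixels} — dense *area*
  above the threshold as a percentage of breast area.

VPD(0) is the ordinary un-thresholded volumetric percent density.  The
scientific question is whether some t in 0–25 mm predicts breast-cancer
risk better than t = 0, for whom this package provides:

* **conditional logistic regression** for 1:m matched case-control sets
  (likelihood ℓ(β) = Σ_s [x_case·β − log Σ_{j∈s} exp(x_j·β)], Newton–Raphson,
  Wald CIs, standardized odds ratios per SD of the predictor);
* **model selection** via AIC = 2k − 2ℓ̂ threshold sweeps and the five
  standard modelling schemes M1–M5 (VPD0; VPD(t_v); APD(t_a);
  VPD0+VPD(t_v); VPD0+APD(t_a));
* the **matched concordance index** mC — within each matched set, the
  fraction of controls whose risk score falls below the case's (ties
  half-credited), averaged over sets — with set-resampling bootstrap
  comparison of two scores;
* **screen-detected vs interval cancer** interaction analysis, a
  varying-threshold sensitivity analysis, Spearman correlations between
  measures, and likelihood-ratio (G²) chi-square tests for demographic
  tables;
* a **synthetic-data generator** (correlated log-normal height maps and
  exactly matched cohorts labelled by the conditional-logistic model) so
  the entire pipeline is testable without clinical data, which cannot be
  redistributed.

## Worked example

```python
import numpy as np
from densethresh.synthetic_cohort import simulate_subjects, build_matched_sets, RiskParams
from densethresh.evaluation import threshold_sweep_analysis, compare_model_schemes

subjects = simulate_subjects(4700, study=1, seed=42)
cohort, sets = build_matched_sets(
    subjects, RiskParams(predictor="apd_6", beta=np.log(1.34)), m=3, seed=43
)
sweep = threshold_sweep_analysis(cohort)
print(f"best measure: {sweep.best_kind} at {sweep.best_threshold:g} mm "
      f"(AIC {sweep.best_aic:.2f})")
comp = compare_model_schemes(cohort, t_v=5, t_a=6, bootstrap_B=1000, seed=44)
```

This simulates 4,700 women with density measures, forms 1,091 exactly
matched 1:3 sets, labels one member of each set as the case with softmax
probability driven by her measured APD at 6 mm (log-OR ln 1.34 per SD),
and asks the threshold sweep to find the signal blind.  Output:

```
best measure: apd at 6 mm (AIC 2959.20)
M1: AIC 2976.73 (dAIC +0.00), mC 0.575 (0.554-0.598); vpd_0 OR 1.27 (1.19-1.36)
M2: AIC 2975.62 (dAIC -1.11), mC 0.579 (0.557-0.603); vpd_5 OR 1.28 (1.19-1.36)
M3: AIC 2959.20 (dAIC -17.53), mC 0.589 (0.568-0.612); apd_6 OR 1.33 (1.24-1.42)
M4: AIC 2977.56 (dAIC +0.84), mC 0.580 (0.558-0.603); vpd_0 OR 0.94 (0.53-1.65), vpd_5 OR 1.36 (0.78-2.39)
M5: AIC 2956.37 (dAIC -20.36), mC 0.592 (0.571-0.614); vpd_0 OR 0.79 (0.64-0.98), apd_6 OR 1.66 (1.34-2.05)
```

The sweep recovers the generating threshold (areal, 6 mm), the M3
standardized OR 1.33 recovers the generating 1.34, the single-predictor
areal model dominates the baseline by AIC, and mC rises from 0.575 to
0.589.  Each OR is the change in odds per SD of the predictor, with a 95%
Wald CI; mC intervals are percentile set-bootstrap.

A command-line pipeline wraps the same steps:

```sh
densethresh simulate --n 2000 --study 2 --seed 5 --out run/
densethresh sweep    --cohort run/cohort.csv --out run/ --plot
densethresh compare  --cohort run/cohort.csv --out run/
densethresh interaction --cohort run/cohort.csv --out run/interaction.json
densethresh table    --counts counts.csv --out run/g2.json
```

## Layout

| module | contents |
| --- | --- |
| `densethresh.density_maps` | `DensityMap`, VPD/APD/threshold masks, TIFF/PGM+JSON raster I/O |
| `densethresh.synthetic_cohort` | map/measure simulation, subjects, matched-set construction, cohort CSV I/O |
| `densethresh.matched_logit` | conditional-logit likelihood, Newton fitting, AIC, LR tests, standardized ORs, interactions |
| `densethresh.concordance` | matched concordance index, set-bootstrap comparison |
| `densethresh.evaluation` | threshold sweeps, schemes M1–M5, screen/interval analysis, varying thresholds, correlations |
| `densethresh.cohort_tables` | demographic tables, G² tests |
| `densethresh.cli` | `densethresh` command-line pipeline |

See `docs/methods.md` for the statistical model, the synthetic-data
design and its limitations, and all numerical conventions.
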