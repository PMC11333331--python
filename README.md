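# herbniche

Habitat-suitability modelling and phytochemical quality zoning for
medicinal plants, built around the workflow used to map *Lonicera
japonica* Flos (honeysuckle flower, a major herb of traditional Chinese
medicine): where can the species grow, how will that change under future
climates, and where does the environment favour accumulation of its
marker compounds?

It is aimed at ecologists and pharmacognosists who want the full chain —
species distribution model, suitability zoning, range-centroid migration,
HPLC fingerprint similarity, and environment→metabolite regression — as
one tested, scriptable Python package rather than a patchwork of GUI
tools.

## What it computes

**Presence-background maximum entropy (MaxEnt).** Given presence points
and gridded covariates x, the model estimates the Gibbs distribution over
background cells

    q(x) = exp(λ·f(x)) / Z,

maximising the L1-penalised average presence log-likelihood
`(1/m) Σ log q(xᵢ) − Σⱼ βⱼ|λⱼ|`, with linear, quadratic, product and
hinge features f scaled to [0, 1]. Suitability is reported on the
logistic scale `p = e^H q / (1 + e^H q)` where H is the entropy of q.
Fitting is by full-gradient proximal (FISTA) convex optimisation;
assessment includes ROC/AUC, percent contributions, permutation
importance, jackknife training gains and marginal response curves.

**Zoning and range shift.** Continuous suitability is graded into
no/low/medium/high classes (fixed edges 0.2/0.4/0.6 or optimal
Fisher–Jenks natural breaks), class areas are summed with
latitude-corrected cell areas on a spherical Earth (R = 6371.0 km), and
the area-weighted centroid of the suitable range (p ≥ threshold) is
tracked across climate scenarios with haversine distances.

**Fingerprints and quality.** HPLC traces are reduced to peak tables,
retention times are corrected piecewise-linearly against a reference
sample, peaks present in every sample form the common-peak matrix, and
samples are scored with the congruence (cosine) coefficient
`a·b/(‖a‖‖b‖)`. Site-level compound contents (mg/g) are regressed on
ecological factors by stepwise OLS (AIC/BIC), predicted over the grid,
min–max normalised within the suitable region, averaged, and Jenks-graded
into the quality zoning map.

**Synthetic truth.** `herbniche.synthetic` generates correlated Gaussian
random fields, presences from a known logistic suitability law,
chromatograms with planted peaks, and contents with known environmental
coefficients — every stage of the pipeline is testable against ground
truth without any downloads.

## Worked example

```python
import numpy as np
from herbniche import synthetic, bootstrap_ensemble, jackknife, classify, range_centroid

stack, occ, truth = synthetic.default_scene(seed=1, nrows=60, ncols=60)
suit, aucs, models = bootstrap_ensemble(occ, stack, reps=5, seed=1)
print("mean test AUC:", round(float(np.mean(aucs)), 3))

jk = jackknife(occ, stack, seed=1)
print("top single-variable driver:", jk.top_driver())

cm = classify(suit)          # grade edges 0.2 / 0.4 / 0.6
print("high-suitability area km2:", round(cm.areas_km2[3]))
c = range_centroid(suit, threshold=0.04)
print("range centroid:", round(c.lon, 3), round(c.lat, 3))
```

prints

```
mean test AUC: 0.865
top single-variable driver: bio6
high-suitability area km2: 2177
range centroid: 101.692 26.582
```

The scene's suitability law is dominated by bio6 (minimum temperature of
the coldest month), and the model recovers it: the held-out AUC of 0.865
is close to the 0.89 ceiling set by the generating law itself, the
jackknife ranks bio6 first, and the graded map and area-weighted range
centroid are ready for scenario comparison with
`herbniche.migration_table`.

The same stages are available from the shell:

```sh
herbniche synth --out scene --seed 1
herbniche sdm --rasters scene/rasters --occurrences scene/occurrences.csv --out sdm
herbniche zone --suitability sdm/suitability.asc --out zone
herbniche fingerprint --chromatograms scene/chromatograms --out fp
```

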