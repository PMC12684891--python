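# plastrisk

Quantitative risk assessment of **acute mortality from macroplastic ingestion**
in seabirds, marine mammals and sea turtles.

Necropsy studies record, for each stranded or bycaught animal, how much plastic
of each material category (hard, soft, fishing debris, rubber, foam, cloth,
other) was in its gastrointestinal tract and whether plastic ingestion killed
it. `plastrisk` turns such per-individual records into dose–mortality
thresholds: *how much ingested plastic gives an animal a 50% (or 90%) chance of
dying from it?*

## The model

The core is a right-censored **Weibull accelerated-failure-time (AFT)
regression** in which the event axis is the gastrointestinal plastic load *p*
(pieces ≥ 5 mm, volume in cm³ per cm body length, or — for fishing debris —
length in cm per cm body length) rather than time:

```
P(death by load p | x) = 1 − exp( −( p · e^(−xβ) )^(1/σ) )
```

Animals killed by plastic (cause codes KD/PD) are failures observed at their
load; animals that died of anything else (KND) are right-censored at their load
— their lethal threshold is only known to exceed what they carried;
indeterminate deaths (IND) are excluded. Covariates *x* (individual body
length, species mean length) rescale the lethal-load axis. Inverting the
fitted cumulative incidence gives the lethal-load thresholds

```
p_q = e^(xβ) · (−ln(1 − q))^σ        (LD50 at q = 0.5, LD90 at q = 0.9)
```

with 95% confidence intervals from a case-resampling percentile bootstrap
(1,000 refits by default). Around the model sit the supporting stages of the
analysis: CSV ingest with detection-limit harmonization and body-size
imputation, screening statistics (frequency of occurrence, χ²/Fisher
association tests, Bray–Curtis PERMANOVA across taxa, Kruskal–Wallis + Dunn
rank tests), a data-sufficiency gate (≥ 5 deaths per taxon–material
combination and KD loads significantly above KND loads), AIC model selection,
and per-species absolute threshold scaling. A fully specified synthetic-data
generator draws datasets from the exact generative law the model assumes, so
every stage is testable end to end without any external data.

## Worked example

```python
import numpy as np
from plastrisk import (Taxon, LoadMetric, AFTModelSpec, generate_dataset,
                       derive_load_observations, fit_aft, bootstrap_fits,
                       threshold_with_ci)
from plastrisk.simulate import SimulationConfig

ds = generate_dataset(SimulationConfig(n=1000, seed=3))          # synthetic necropsies
spec = AFTModelSpec(Taxon.SEA_TURTLE, None, LoadMetric.VOLUME_PER_LENGTH)
obs = derive_load_observations(ds, spec)                         # (load, event, x)
fit = fit_aft(obs, spec=spec)
boots = bootstrap_fits(obs, spec=spec, n_boot=200, seed=4)
for q in (0.5, 0.9):
    est = threshold_with_ci(fit, boots, q)
    print(f"{int(q*100)}% lethal load: {est.point:.2f} "
          f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}) cm^3/cm")
```

Output:

```
50% lethal load: 5.73 (95% CI 5.28-6.30) cm^3/cm
90% lethal load: 12.09 (95% CI 10.75-13.52) cm^3/cm
```

The generator's truth here is β₀ = 2.0, σ = 0.6, so the true 50% threshold is
e² · (ln 2)^0.6 ≈ 5.93 cm³ of plastic per cm of body length — inside the
reported interval. The same estimator is exposed scikit-learn style as
`plastrisk.WeibullAFT` (`fit(X, y)` with `y = [load, event]` columns,
`predict_mortality`, `predict_threshold`, fitted attributes `intercept_`,
`coef_`, `sigma_`).

The full pipeline (ingest → screening → gate → fit → thresholds → report) runs
from one YAML/JSON config:

```bash
plastrisk simulate --config sim.yaml --out necropsies.csv
plastrisk screen --input necropsies.csv --taxon sea_turtle
plastrisk fit --config pipeline.yaml --out results/
```

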