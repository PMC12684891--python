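# Methods

## Model

The package estimates the probability that an animal dies acutely from the
macroplastic in its gastrointestinal (GI) tract, as a function of the load it
carries. The load axis plays the role time plays in survival analysis. With
load *p* ≥ 0, covariate vector *x* and parameters β (intercept plus covariate
coefficients) and σ > 0, the cumulative incidence of death is

    F(p | x) = 1 − exp(−(p · e^(−xβ))^(1/σ)),

the standard Weibull accelerated-failure-time (AFT) form with shape k = 1/σ
and load scale e^(xβ). Larger xβ means a larger lethal load. The likelihood
is the usual right-censored one: an animal whose death was attributed to
plastic (cause codes KD or PD) contributes the density f(p); an animal that
died of something else (KND) contributes the survival S(p) = 1 − F(p),
because its lethal threshold is only known to exceed the load it carried.
Indeterminate deaths (IND) are excluded. A censored animal with zero load
contributes log S(0) = 0 exactly: retaining such animals is harmless and the
implementation asserts it.

Cause-of-death coding follows the necropsy convention: KND "known not
debris", KD "known debris", PD "probable debris", IND "indeterminate". KD and
PD are pooled as events.

One modelling rule is worth stating explicitly because raw necropsy tables do
not force it: an animal killed by category A appears in a model of category
B ≠ A as *censored at its category-B load* — its B load demonstrably did not
kill it. The observation-derivation step applies this rule and logs the
resulting event/censored counts per model.

### Load metrics

Three metrics are supported, selected per model:

- `PIECE_COUNT` — number of pieces ≥ 5 mm (treated as a continuous load; the
  likelihood is continuous and counts of the relevant magnitude make the
  discretization immaterial);
- `VOLUME_PER_LENGTH` — total volume (cm³) divided by body length (cm), a
  proxy for volume relative to GI-tract size;
- `LENGTH_PER_LENGTH` — total fishing-debris length (cm) per cm body length,
  meaningful for line/rope/net only.

Body length means curved carapace length for turtles, individual length for
mammals, and species mean length for seabirds (stored in both length fields
for birds). Records missing a volume (or body length) are excluded from
volume-metric models rather than imputed, so the effective N legitimately
differs between the piece and volume models of the same combination.

### Estimation

`WeibullAFT` maximizes the likelihood over (β, log σ) with L-BFGS-B and an
analytic gradient; optimizing log σ keeps σ positive. Initialisation:
β₀ = log(mean event load), other coefficients 0, σ = 1; up to three
deterministically jittered restarts run before a fit is declared
non-converged (gradient-norm criterion). Standard errors come from the
inverse observed information (central-difference Hessian of the negative
log-likelihood at the optimum); covariate p-values are two-sided Wald tests.
`fix_sigma=1` gives the censored-exponential submodel, whose closed-form MLE
exp(β̂₀) = Σpᵢ / #events anchors the unit tests. An independent survival
package (lifelines) reproduces coefficients, σ, log-likelihood and standard
errors in the test suite; it is a cross-check, never the implementation.

Model selection per taxon–category–metric combination: candidate models are
the intercept-only fit plus each configured covariate (individual length,
species mean length) and their pair. The lowest-AIC converged fit wins, with
AIC = 2k − 2ℓ and k = len(β) + 1 (σ is always counted, including when held
fixed — a deliberate simplification so the reported AIC has one definition).
A covariate model is eligible only when every added covariate has finite SE
and Wald p < 0.05; ties break toward fewer parameters.

### Thresholds and uncertainty

Inverting F at probability q gives p_q = e^(xβ) · (−ln(1−q))^σ, the load at
which mortality probability reaches q (LD50/LD90 analogues at q = 0.5, 0.9).
The identity p₉₀/p₅₀ = (ln 10 / ln 2)^σ holds exactly and is asserted to
1e-10. Confidence intervals are percentile intervals (2.5/97.5) over
case-resampling bootstrap refits — individuals resampled with replacement at
the original sample size, 1,000 resamples by default; resamples with zero
events or non-converged refits are dropped and counted, with a warning above
20% loss. The percentile method was chosen over BCa for transparency and
because the bootstrap distribution of log-thresholds is close to symmetric in
the regimes exercised here; it is configurable in principle via the recorded
bootstrap fits.

For multivariate models a threshold needs a covariate profile. The package
evaluates headline thresholds at the *event-weighted mean covariate vector*
of the fitted data, records the profile in every output, and accepts any
explicit profile — single published thresholds from multivariate fits are
only reproducible given the profile used, so it is never left implicit.

Absolute per-animal thresholds scale a per-length threshold by a body length;
the product is rounded half-up to two decimals for reporting (cm³, or cm for
fishing debris). Scaling is exactly linear before rounding.

## Ingest filters

- **Detection-limit harmonization.** Loads are standardized to pieces ≥ 5 mm.
  Records whose source reported no detection limit pass through unchanged
  (all macroplastics assumed captured); records whose limit already meets
  5 mm cannot contain smaller pieces. Only when a source's limit is below the
  cutoff are per-piece sizes consulted: sub-threshold pieces are dropped and
  category volume is scaled by the retained piece fraction. If that removes
  every attributed piece of a debris death, the cause is recoded IND rather
  than keeping an event with no supporting load. The filter is idempotent.
- **Body-size imputation.** A missing body length is filled from the species
  reference mean for the record's age class; a missing age class is assigned
  from the species' length ranges. Ranges are checked in ascending order of
  mean length with inclusive bounds, so a length on a shared boundary goes to
  the younger class (an arbitrary but documented tie-break). Lookups that
  miss return the record unchanged with a warning.
- **Piece-volume estimation.** A deterministic cascade: measured volume if
  present; else a configurable geometric formula (box, ellipsoid, cylinder)
  from linear dimensions; else a configured per-category mean piece volume.
  Every estimate carries a provenance tag. The cascade is a configurable
  stand-in for source-specific volume protocols, which vary.

## Screening statistics and the sufficiency gate

Frequency of occurrence is the percent of a taxon's individuals carrying at
least one piece of a category (plus TOTAL, any category); mortality given
ingestion is the percent of a category's ingesters whose death was attributed
to it (KD and PD separately). Association between category and
ingestion/mortality uses Pearson's χ² unless any expected cell falls below 5,
in which case Fisher's exact test is used — the cutoff is configurable
because published analyses typically state only "depending on sample size".
Fisher's exact is implemented for 2×2 tables; larger sparse tables fall back
to χ² with a warning (no exact network algorithm is shipped).

Differences in load across cause-of-death groups (KND, IND, KD∪PD) use
Kruskal–Wallis with tie correction and Dunn's pairwise z-tests on rank means,
Holm-adjusted by default (none/Bonferroni configurable). When every load is
identical the statistic is undefined and the package returns H = 0, p = 1 by
logged convention.

A taxon–category combination is *data-sufficient* for modelling when (1) at
least five individuals died from that category, (2) KD loads are
significantly above KND loads (Dunn adjusted p < 0.05, KD rank mean higher),
and (3) medians order KND ≤ IND ≤ KD (non-strict; trivially satisfied when no
IND records exist). The gate is evaluated on piece counts; verdicts carry the
failure reasons. The median version of the "IND in between" requirement is
one defensible operationalization of an informally stated criterion.

PERMANOVA on Bray–Curtis dissimilarities of per-category composition tests
whether plastic communities differ across taxa. The pseudo-F uses
among/within sums of squared dissimilarities; p = (1 + #{F* ≥ F}) / (1 + B)
under seeded label permutation, with an exhaustive-enumeration mode for tiny
inputs. Raw (untransformed) quantities are used by default. scikit-bio's
PERMANOVA is the independent cross-check in the tests.

## Synthetic data generator

The generator draws datasets from the exact law the model assumes, so
recovery failures indict the implementation, not the data. Per animal i:
covariates (species mean length per synthetic species from a lognormal law;
individual length as species mean × lognormal noise, or identical to it for
seabirds), lethal load Tᵢ = e^(xᵢβ) · Eᵢ^σ with Eᵢ ~ Exp(1), observation
load Cᵢ from a configurable censoring law with a zero-inflation share for
animals that ingested nothing. If Tᵢ ≤ Cᵢ the record is a debris death *at
load Tᵢ* — exactly the quantity the likelihood's density term assumes, a
point the generator documents prominently because observation models are
rarely stated — otherwise a KND record censored at Cᵢ. A configured fraction
of deaths is labelled PD rather than KD (the two are pooled downstream) and a
fraction of all records is relabelled IND.

Scalar loads are decomposed into per-category records via a Dirichlet split
around the configured category mix (trace shares dropped so individuals carry
realistic category subsets); piece counts derive from volumes via per-category
mean piece volumes, rounded to an integer with a floor of one piece for
events. Defaults, chosen once as the study conditions: intercept-only truth
β₀ = 2.0, σ = 0.6; lognormal censoring (log-mean 1.0, log-sd 1.5); 50%
zero-load individuals (roughly half of necropsied individuals carry no
plastic); PD fraction 0.2 of debris deaths; IND fraction 0.05; sea-turtle
taxon with a hard/soft/fishing-debris/rubber mix of 0.4/0.3/0.2/0.1 and mean
piece volume 0.22 cm³. Under these conditions roughly one in six animals dies
of plastic, the sufficiency gate passes at realistic sample sizes, and
event loads in the continuous volume metric round-trip exactly through the
CSV dialect (recovery and coverage studies therefore run on the volume
metric; integer rounding would add a discretization the piece metric's real
data also carries, but it is not what those studies are calibrating).

What the generator does *not* emulate: study-level heterogeneity in detection
limits and necropsy protocols (one optional limit per dataset), clustering of
individuals within source studies, covariate effects on ingestion propensity,
and any exposure/encounter process. Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own assumptions,
not robustness to the messiness of compiled field data.

Reproducibility: one seeded generator stream per dataset plus per-animal
sub-streams keyed by (seed, index), so the same seed yields byte-identical
CSVs.

## Pipeline and reporting

`run_pipeline` executes ingest (CSV or synthetic) → detection-limit filter →
optional body-size imputation → rate tables → sufficiency gate → candidate
fits and AIC selection → bootstrap → thresholds and curves → per-species
absolute thresholds, from one config, deterministically given the seed.
Every filter logs counts in/out and every fit logs its event/censored split.
Gate-skipped combinations never reach the threshold table. Exit codes (CLI):
0 success, 2 no sufficient combination, 1 crash. Mortality curves are
reported on a grid up to the 99% threshold with pointwise 2.5/97.5 bootstrap
envelopes, clipped to bracket the point curve.

## Problem sizes and numerical choices

Simulation studies shipped with the package use: parameter/threshold recovery
with 100 replicates at n = 2,000 (agreement judged within 3 Monte-Carlo
standard errors); bootstrap-CI coverage with 100 replicates at n = 1,000 and
200 resamples per replicate; PERMANOVA type-I error with 500 null replicates
of 2 × 12 individuals at 199 permutations. These sizes give Monte-Carlo
error comfortably below the effects being checked while keeping the whole
suite at a couple of minutes on one CPU.

Numerical details: likelihood and gradient are fully vectorized with
overflow-guarded evaluation (non-finite trial points return a large penalty);
zero-load censored observations short-circuit to an exact zero contribution;
the grid oracle in the tests brackets the optimizer on 200×200 (β₀, log σ)
grids; percentile CIs use linear interpolation (so bootstrap values 1..100
yield (3.475, 97.525)); CSV writing uses %.17g and reading uses round-trip
float parsing so writer∘reader is the identity.

## Known limitations

- Necropsy compilations over-represent dead and stranded animals; thresholds
  estimated from them describe mortality risk conditional on the sampled
  population, not wild-population rates. Nothing in the package corrects for
  that sampling.
- No frailty/cluster adjustment for source study; bootstrap resampling is
  unstratified.
- Chronic and sublethal effects (e.g. food dilution) and entanglement are out
  of scope; thresholds cover acute GI-tract mortality from ingestion only.
- Fisher's exact test is limited to 2×2 tables.
- The published headline thresholds can only be reproduced from the original
  per-individual necropsy compilation, which is not redistributable with the
  package; the corresponding end-to-end check runs whenever that file is
  supplied (see `tests/test_acceptance.py`) and the rest of the suite
  exercises the identical code path on synthetic data.
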