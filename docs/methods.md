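# Methods

## Problem setting

Metabolome-wide association studies relate hundreds of LC-MS metabolite
features to a panel of clinical traits and outcomes. Each analysis produces
three quantities per (metabolite, outcome) pair — an effect estimate, its
direction, and a P value — and the analytical challenge is as much visual as
statistical: a display must let the reader compare one metabolite across all
outcomes (row-wise) and all metabolites within one outcome (column-wise) at
once. The rain plot does this by encoding the beta coefficient as a
diverging color fill and the significance as the size of a circular mark,
over a metabolites x outcomes grid; Manhattan plots, paired heatmaps, and
bar-and-scatter plots are provided as the conventional comparators, each
carrying a strict subset of those information channels.

## Preprocessing

Raw intensities are processed per metabolite in a fixed order:

1. **Imputation.** Missing intensities are replaced by 0.25 × the minimum
   observed intensity of that metabolite, a standard minimum-fraction rule
   for features that fall below the LC-MS detection limit. The rule is
   applied per metabolite across all samples; observed values are never
   altered. An all-missing column, or a minimum observed value ≤ 0, is an
   error.
2. **Natural-log transform.** Raw intensities are right-skewed over orders
   of magnitude; the log makes multiplicative instrument effects additive.
3. **Standardization.** Each log column is z-scored to mean 0, SD 1 so that
   betas are per 1-SD of log abundance and comparable across metabolites.
   The sample (n−1) denominator is the default; a population (n) denominator
   is available via `sd_denominator="n"`.

The composition is scale-equivariant: multiplying a raw column by any c > 0
leaves the output unchanged (the log turns scaling into a shift, the z-score
removes it), and within-metabolite sample ranks are preserved, with imputed
entries strictly below every observed one. Metabolites exceeding a
missingness threshold are *counted* in the preprocessing report (threshold
0.10) but not excluded — imputation, not exclusion, is the default policy.
An opt-in `max_missing_frac` filter exists for sensitivity analyses.
Standardization happens once on the full matrix, before any per-model sample
exclusion; models fitted on complete-case subsets therefore share one
exposure scale.

## Regression

Metabolites are modeled as exposures. For continuous outcomes, ordinary
least squares on [1, x, covariates] with the classical homoskedastic SE and
a two-sided t-test on n − k degrees of freedom. For binary outcomes,
logistic regression fitted by iteratively reweighted least squares:
convergence when the maximum absolute coefficient change falls below 1e-8,
capped at 100 iterations; SE from the inverse observed information; Wald P.
Both solvers live in this package (they are the quantity under test, and the
suite checks them against closed-form normal equations, an independent
Newton–Raphson maximizer, and statsmodels). IRLS weights are floored at
1e-10 to survive extreme fitted probabilities.

A non-converged logistic fit — complete separation being the common cause —
is returned with `converged=False` and NaN beta/SE/P. The grid remains
complete (one record per pair); plot builders silently omit such cells, and
ordering by P treats them as sorting last.

Design choices where convention had to be picked:

- **Covariates.** The age model adjusts for sex, the sex model for age,
  every other model for age + sex. Fully configurable per `ModelSpec`.
- **Complete cases per model,** not globally: samples missing one outcome
  still contribute to every other model, maximizing n per model.
- **Classical SEs,** not robust: the conventional default in cohort
  epidemiology; robust variants are out of scope.
- **Incident outcomes** (incident diabetes, incident hard CVD) are fitted as
  logistic regressions on the event indicator. Time-to-event models are
  deliberately not implemented; the `ModelSpec.family` field leaves room.

The packaged default panel has eight models in a fixed clinical display
order — age, female sex, body mass index, metabolic syndrome, prevalent
diabetes, incident diabetes, Framingham risk score, incident hard
cardiovascular disease — carried by `display_index`, never by file column
order, so the ordering survives serialization.

## Orderings

- **P value:** ascending summary P, where the summary is the row minimum
  across outcomes by default (the natural reading when eight P values exist
  per metabolite), or a single anchor outcome's P on request. Sorts are
  stable; ties keep input order.
- **m/z:** ascending mass-to-charge value, stable on ties.
- **Clustering:** agglomerative hierarchical clustering of the
  per-metabolite beta vectors (not P values — the point of the clustered
  ordering is to group metabolites by effect *profile*). Defaults: Euclidean
  distance, average linkage; both configurable. Leaf order is produced by a
  deterministic traversal that always visits the smaller cluster index
  first, so identical input yields identical figures. Note the caveat: this
  tie rule keys on input position, so permuting input rows can flip
  left/right order within merges even though the clustering itself (the
  nested groups) is permutation-invariant.
- **Top-k selection** keeps the k = 50 metabolites with smallest summary P
  (same summary rule), returned in ascending-P order; k ≥ n returns all.

## Visual encodings

All encoding rules live on renderer-independent model objects so they are
testable without rasterization.

- **Rain plot.** Fill = beta clipped to symmetric limits (±max|beta| over
  the displayed grid by default, configurable); a diverging
  blue–white–red map puts beta = 0 at the midpoint. Radius = r_min +
  (r_max − r_min) · min(−log10 P, cap)/cap with the cap defaulting to the
  Bonferroni threshold −log10(α/m) — droplets saturate at study-wide
  significance. Radius-proportional scaling is the default;
  area-proportional (`size_mode="area"`) and stepped significance tiers
  (`sig_bins`) are available because perception of the two differs and the
  choice is a matter of taste, not correctness. −log10(P) itself is capped
  at 300 to absorb floating-point underflow.
- **Manhattan.** x = actual m/z value (rank mode available), y = −log10(P),
  point color = sign(beta); facets share y limits so outcomes are
  comparable. The threshold line is Bonferroni α/m by default (raw α
  available). No magnitude channel exists in this display — that is its
  documented limitation, and a model-introspection test pins it.
- **Paired heatmaps.** Betas on symmetric diverging limits and −log10(P) on
  sequential [0, cap] limits, identical row/column orders enforced by
  construction.
- **Bar-and-scatter.** One outcome: signed beta bars, −log10(P) dots on the
  same metabolite axis.

Rendering uses matplotlib (SVG/PNG/PDF). Output is deterministic: SVG ids
are salted with a fixed string and date metadata is stripped. Each rain
droplet is a matplotlib `Circle` patch tagged with a `droplet-<row>-<col>`
gid; matplotlib serializes circles as SVG `<path>` elements, so the
machine-checkable contract is "one uniquely-identified circle mark per
cell", counted via those ids.

## Synthetic studies

The generator emulates the shape of a population-cohort lipidomics dataset:
log-normal raw intensities (log-mean U(10, 16), log-SD U(0.3, 0.8), so raw
values span ~2e4–9e6), m/z uniform on the 225–650 acquisition range, age
66 ± 9 years, 54% women, and realistic base prevalences for the binary
outcomes (metabolic syndrome 0.30, prevalent diabetes 0.10, incident
diabetes 0.07, incident hard CVD 0.09). Effects are planted on the
population-standardized log scale: continuous outcomes add β·z to the
linear predictor; binary outcomes pass it through a logistic link. The
desk-scale fixture is 500 metabolites × 300 samples (the cohort's ~1500
samples scaled down for test speed) with 16% of metabolites assigned >10%
missingness.

Every draw descends from one seed through named `SeedSequence` children —
one stream per metabolite and per phenotype block — so output is
byte-reproducible and independent of generation order.

What the generator does **not** emulate: intensity-dependent (left-censored)
missingness is available as an option (`missing_mode="left"`) but the
default is completely-at-random, which real LC-MS dropout is not; there is
no correlation structure between metabolites, no batch effects, and no
retention-time information. A green parameter-recovery test therefore
establishes that the estimator is correct under the stated model, not that
the pipeline is robust to informative missingness or co-regulated lipids.

One calibration subtlety: effects are planted against the population z-score
while the fitted exposure is the *sample* z-score, so the estimand differs
from the planted value by the factor s_z (sample SD of the latent z),
which is 1 ± O(n^{-1/2}). At the n = 1000 used for coverage checks this
inflates CI non-coverage by well under a percentage point and the empirical
coverage band [92%, 98%] absorbs it.

## Numerical notes

- Linear fits use `scipy.linalg.lstsq`; rank is checked explicitly and
  rank-deficient designs are an error, not a silent pseudo-inverse fit.
- A perfect (zero-residual) linear fit would give SE = 0 and P = 0; both are
  reported as the smallest positive double so records stay within their
  domain invariants.
- P values are floored at the smallest positive double for the same reason;
  −log10(P) is capped at 300.
- Grid CSVs print floats at 17 significant digits and are parsed with
  round-trip float precision, so write→read is bit-identical.
- The association grid is complete by construction: constructors reject
  missing or duplicated (metabolite, outcome) pairs outright.

## Known limitations

- No survival models for incident outcomes; no interaction terms; no mixed
  models; no robust or clustered SEs.
- No batch correction or alternative imputation (kNN, MICE) — the
  preprocessing is exactly the three-step rule above.
- Clustering leaf order is deterministic but input-order-sensitive at merge
  tie-breaks (see Orderings).
- Figures are static SVG/PNG/PDF; no interactive output.
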