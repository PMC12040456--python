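# Methods

## The experiment the generator emulates

The synthetic-data module emulates a one-factor-at-a-time (OFAT)
cultivation screening: five freshwater genera (*Chlorella*,
*Botryococcus*, *Chlamydomonas*, *Tetraselmis*, *Closterium*), five
environmental factors each at four levels — CO₂ 5/7/9/11 %, pH 5/7/9/11,
temperature 10/20/30/40 °C, light intensity 2000/2500/3000/3500 lux,
light colour white/red/green/blue — and nine responses: biomass (g l⁻¹),
lipid, protein, fibre, ash, moisture and nitrogen-free extract (% of dry
weight), Na and K (mg / 100 g). Each treatment series varies one factor
across its levels while the others are held at a baseline; each condition
is run in triplicate, giving 20 conditions × 3 replicates × 5 genera =
300 rows.

The baselines (CO₂ 9 %, pH 7, 30 °C, 3000 lux, white light) are the
joint optimum the screening is expected to find. Holding values in such
studies are usually unreported, so taking the optimum as the holding
point is an assumption of this generator, not a property of OFAT designs
in general; it makes the all-baseline condition the best observed
combination under the default surfaces.

### Response surfaces

Each (genus, response) surface is additive:

```
y(condition) = base + Σ_f e_f(level_f) + ε,   ε ~ N(0, σ²), clipped to bounds
```

Numeric factors use a quadratic peak: `e(x) = A (1 − ((x − x*)/w)²)` with
`x*` the planted optimum level and `w` the distance to the farthest level,
so the contribution runs from `A` at the optimum to 0 at the far end.
Light colour uses additive per-level offsets. The per-response amplitude
weights fix the planted dominance ordering — CO₂ dominates biomass,
lipid, ash, Na and K; pH dominates protein, fibre, moisture and NFE —
and the colour optimum is red for protein and lipid, white otherwise.
Per-genus base and peak levels follow the magnitudes typical of these
genera (e.g. biomass peaks 1.5–1.95 g l⁻¹, protein up to ~50 %). Noise is
additive Gaussian, truncated by clipping at the physical bounds (biomass
0.2–2.1 g l⁻¹, percentages 0–100, minerals 0–50); clipping is
deterministic and simple but biases means inward at extreme settings,
which matters only when a surface value sits within ~2σ of a bound.

What the generator does **not** emulate: growth kinetics over time,
inter-response biochemical coupling (NFE is not constrained to
100 − protein − fibre − ash − fat), replicate-level batch effects, and
factor interactions (the surface is additive by construction). Passing
recovery tests therefore show the analysis chain is sound under additive,
independent-noise conditions — not that it is robust to interaction
structure or correlated errors in real cultures.

## MANOVA stage

For a grouping factor with g levels, the total SSCP matrix of the nine
responses about the grand mean is decomposed into hypothesis H
(df_h = g − 1) and error E (df_e = n − g). The four statistics are
functions of the eigenvalues λᵢ of E⁻¹H, computed from the symmetric
generalized eigenproblem H v = λ E v (Cholesky-checked; a singular E is
reported as an error, never silently regularized):

- Wilks Λ = Π 1/(1+λᵢ), Rao's F approximation;
- Pillai V = Σ λᵢ/(1+λᵢ) and Hotelling–Lawley T = Σ λᵢ, the classical
  trace F approximations (statsmodels applies the McKeon refinement to
  T's denominator df, so its F differs by ~1 % on small samples; values
  agree to machine precision);
- Roy θ = λ₁ with the upper-bound F, so Roy's p is an upper bound on
  significance.

All four reduce exactly to the univariate ANOVA F when p = 1. The
screening analysis uses the treatment-series label as the grouping
variable, per genus and pooled, since a single joint factorial model is
not identifiable from an OFAT layout.

## Model selection

Features are the four numeric factors plus four colour indicators (full
one-hot, no dropped level: tree ensembles are indifferent to the
collinearity and importance pooling needs every level). Metadata (genus,
series label, replicate) is excluded. Standardization is fit on training
data only; the split unit is the row (grouping replicates into the same
side is a possible refinement — row-level splitting lets replicates of
one condition appear on both sides, an optimistic bias acknowledged
here).

The composite score `W = X/(1+X)` with `X = ((R²t + R²v)/(MSE + RMSE +
MAE)) · (1−d)/(1+d)`, `d = |R²t − R²v|`, is a pure function of its five
inputs. Edge policy: any non-positive accuracy–concordance product maps
to 0 (such models are never selectable, and this keeps the score in
[0, 1) without a singularity at X = −1); zero error with positive skill
maps to 1; zero error without skill is an error. Error metrics are
computed on the validation partition, so the error term measures
generalization. In cross-validation one score is computed from the
fold-mean metrics (not the mean of fold scores), matching the convention
of reporting one metric set per model. Note the evaluator enforces
RMSE = √MSE, but the score itself does not assume it, because published
metric tables are often rounded independently.

Grid search enumerates (family, grid point, reduction branch) in roster
order, scores each by CV on the training 70 %, breaks ties toward the
earlier candidate, and reports the winner refit on the 70 % against the
held-out 30 %. Default grids are single points per family (forest:
100 trees, depth 10, min split 5, min leaf 5 — selection-stage defaults);
wider ranges (e.g. 50–300 trees, depth 10–50) are config options. The
PCA branch supports both a fixed component count and a cumulative
explained-variance threshold (smallest k reaching it).

## Importance and optimization

Importance is mean decrease in impurity: the ensemble's per-feature
impurity-reduction totals are summed within each source factor (pooling
the colour indicators first, then normalizing, so colour is comparable
to numeric factors) and normalized to sum to 1. A constant target yields
an all-zero profile flagged `no_signal` rather than a fabricated uniform
ranking.

The importance refit always uses the unreduced encoded features
(component-space importances cannot be attributed to factors) and
overrides the split controls to `min_samples_leaf=1,
min_samples_split=2`. This matters in a triplicate OFAT layout: a
factor's sharpest contrast lives in just `replicates` rows, and a leaf
floor above that makes the contrast unsplittable, silently transferring
impurity credit to factors whose contrasts span more rows (notably the
colour indicators). Prediction-tuned leaf sizes are kept for the
selection stage, where they belong.

Optimum location groups observations by the full factor combination and
returns the highest-mean combination, with ties broken toward the
design-order lexicographically smallest one (by level index); only
observed combinations compete, which in an OFAT layout means the 16
distinct conditions.

## Problem sizes and determinism

Default study size is the full 300-row table; recovery simulations use a
single genus (60 rows) over 50 generator seeds with a 3:1 dominant-factor
amplitude ratio and noise at ~3 % of the response range, the regime in
which dominant-factor recovery is expected to be near-certain. All
randomness is seeded explicitly (generation, splitting, CV, model
fitting); there are no wall-clock defaults, and identical configurations
produce byte-identical report bundles for deterministic roster families.

## Known limitations

- Additive surfaces cannot represent factor interactions, and OFAT data
  could not identify them anyway; reported optima are conditional on the
  holding values.
- Clipping at bounds biases condition means toward the interior when the
  noiseless value is near a bound.
- Roy's p-value is anti-conservative by construction (upper-bound F).
- Impurity-based importance is biased toward high-cardinality features
  in general; within this fixed design all numeric factors have four
  levels, so the comparison is fair across them, but comparisons against
  the pooled colour factor inherit the usual caveats.
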