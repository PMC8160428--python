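# Methods

This note documents the models, algorithms, numerical choices and
limitations of `germfilter`, in the spirit of the model-documentation pages
of packages like statsmodels or msprime. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Germination indices

A germination trial is one replicate dish of `n` sown seeds checked daily
for `D` days (default 60); `G_i` seeds germinate on day `i` (1-based: day 1
is the first check after sowing, which also keeps the rate index below
well-defined).

- **GP** (germination percentage): final germinated fraction. Replicates
  are pooled as a ratio of sums (Σ G_fin / Σ n), which is the exact ML
  estimate under binomial sampling; a per-replicate mean is available as a
  config switch (`gp_pooling="mean"`).
- **GR** (germination rate): `GR = (1/n) Σ_i G_i / i`, the Maguire-type
  speed index. Its printed range [0, 1] is attained only by this
  per-day-weighted reading (all seeds on day 1 ⇒ GR = 1); a literal
  `ΣG_i/(n·i)` with a single i would be ill-defined. Replicates are
  averaged after computing the index per dish (each dish is the
  experimental unit for timing); pooled computation on summed daily counts
  is a config switch (`gr_pooling="pooled"`).
- **R_5/25** and **R_wc**: normalized differences of two GPs,
  `(a − b)/(a + b)` in [−1, 1], undefined when both are 0. The storage
  contrast is evaluated at the same (alternating) incubation regime for
  both storage histories.
- **Temperature niche** over the R = 5 constant temperatures:
  `O_j = g_j / g_max` (occupation), `P_j = O_j / Σ O_j` (niche
  proportion, sums to 1), `BTN = (1/R) Σ O_j ∈ [1/R, 1]` (breadth). All
  three are undefined when no germination occurred at any constant
  temperature. O, P and BTN are scale-free in the five GPs.

Undefined indices are carried as explicit missing values with a reason code
(`no_germination` or `missing_condition`) and are never imputed as 0;
downstream stages drop them per analysis and report how many they dropped.

## Community metrics

- **RA and R_f**: relative abundance per treatment pools counts over the
  five replicate blocks (ratio of summed counts); `R_f` contrasts the top
  dose with the control only. A per-block variant (compute R_f within each
  block, average where defined) is available (`rf_pooling="per_block"`).
- **CWM**: `Σ trait_i · RA_i` with weights renormalized over the species
  whose trait is defined, which keeps the CWM a convex combination of
  trait values (bounded by the min/max contributing trait — a tighter,
  always-true bound than any nominal index range). The abundance share of
  included species before renormalization is reported as *coverage*, so a
  CWM resting on a thin slice of the community is visible.
- The community-level variable set comprises 22 CWMs: GP at the five
  constant temperatures, GR at 5/10/20/25 °C, BTN, O and P at the five
  temperatures, R_5/25 and R_wc. (GR at 15 °C is excluded from the
  community variable list; the per-species table still contains it.)

## Functional diversity

FRic, FEve and FDiv follow Villéger, Mason & Mouillot (2008) for
all-quantitative traits. The trait space uses seven variables (GP at the
five constant temperatures, R_5/25, R_wc), z-score standardized; species
missing any of the seven are dropped and recorded. All communities share
one space and one dimensionality m — richness volumes are only comparable
on common axes. By default m = min(7, S_min − 1), where S_min is the
smallest number of retained species in any community (floor 2), because a
convex hull in m dimensions requires more than m affinely independent
points; when m < 7 the coordinates are the first m principal coordinates of
the Euclidean distance matrix (exact for Euclidean input, so the reduction
is an orthogonal projection). Communities still under-determined get an
*undefined* FRic/FDiv rather than a silently degenerate zero volume.

- **FRic**: convex-hull volume (Qhull).
- **FEve**: minimum spanning tree on Euclidean distances; branch l joining
  i, j gets `EW_l = d(i,j)/(w_i + w_j)`; with `PEW_l = EW_l/ΣEW`,
  `FEve = (Σ min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1))`.
- **FDiv**: G is the *unweighted* centroid of the hull vertices (the
  original definition); with dG_i the species distances to G, d̄ their
  unweighted mean, Δd = Σ w_i (dG_i − d̄), Δ|d| = Σ w_i |dG_i − d̄|:
  `FDiv = (Δd + d̄)/(Δ|d| + d̄)`.

The test suite checks all three against independent oracles: a Delaunay
simplex-decomposition volume, an O(S²) Prim MST, and the FDiv definition
with hull vertices detected by linear programming.

## Beta regression

The fertilization response lives in [−1, 1]; a beta-distributed response
must lie strictly inside (0, 1). Boundary cases (±1, i.e. species present
in only one of the contrasted treatments) are removed — within a
configurable tolerance `boundary_epsilon` (default 1e−9, exact boundaries
only) — and the remainder mapped `y → (y + 1)/2`. The model is the
mean–precision beta regression of Ferrari & Cribari-Neto (2004):
`y ~ Beta(μφ, (1−μ)φ)`, `logit(μ) = β₀ + β₁x`, with constant precision φ
estimated on the log scale. Fitting is BFGS with analytic gradients from
logit-OLS starting values, followed by damped-Newton polishing until the
gradient norm is ≈ 0 (the polish step matters: quasi-Newton optimizers can
stall with a small nonzero gradient). Standard errors come from the inverse
observed information (central differences of the analytic gradient); the
slope test is Wald (two-sided normal); pseudo-R² is the squared Pearson
correlation of logit(y) with the fitted linear predictor. Fits with fewer
than 10 usable cases, or a constant predictor, are refused with a
diagnostic; in the all-predictors sweep such failures are isolated per
predictor. Predictors enter untransformed (only the response is rescaled);
no multiple-testing correction is applied across the per-predictor fits by
default.

## Linear mixed model and LRT

Community responses are modelled as Gaussian with fixed treatment factors
and a single block random intercept. (The CWMs and FD indices are
continuous; an identity-link Gaussian mixed model is the appropriate member
of the GLMM family here.) For a fixed variance ratio λ = σ²_b/σ²_e the
marginal covariance is block-diagonal with `V_k = I + λJ`, so
`V_k⁻¹ = I − λ/(1 + λn_k) J` and `|V_k| = 1 + λn_k` are closed-form; the
GLS estimate of β and the profiled log-likelihood then reduce the full ML
fit to a bounded 1-D search over log λ ∈ [−15, 15], with the λ = 0 (OLS)
boundary checked explicitly. ML (not REML) is used everywhere so
likelihood-ratio χ² tests between nested fixed-effect structures are
valid. Per-temperature responses (GP, GR, O, P families) are melted to long
format and tested for temperature, fertilization (each against the additive
model) and their interaction (against the additive model); scalar responses
(BTN, R_5/25, R_wc, FRic, FEve, FDiv) are tested for fertilization against
the intercept-only model. In the 5-temperature × 4-dose design this gives
the familiar 4/3/12 degrees of freedom.

The χ² reference for the ML likelihood ratio is asymptotic. The calibration
experiment in the test suite therefore uses 20 blocks × 4 doses (n = 80):
at the field design's own size (5 blocks, n = 20) the ML LRT is expected to
be liberal, as for any ML LRT at small n, and findings at that size should
lean on the Tukey comparisons and effect directions rather than the
χ² p-value alone.

Tukey HSD uses the pooled within-group variance (or a model-based variance
with its df), the studentized-range quantile at the configured α, the
Tukey–Kramer SE for unbalanced groups, and Piepho-style insert-and-absorb
compact letter display.

## PCA

Correlation-matrix PCA: columns standardized (ddof = 1), components from
the SVD of the standardized matrix; variance shares are the normalized
squared singular values and sum to 1 over the returned min(n, p)
components. Sign convention: the largest-magnitude loading of each
component is positive, making output deterministic across BLAS builds.
Quadrats with any undefined CWM are dropped with a logged warning, never
imputed.

## Synthetic-data generator

The generator emulates the study designs with known truth:

- **Thermal response**: Gaussian,
  `p(T) = p_max · exp(−(T − t_opt)²/(2 t_sd²))` — the simplest unimodal
  germination–temperature model, chosen because the true BTN is available
  in closed form (p_max cancels in O_j). The alternating regime shifts the
  15 °C logit by `alt_effect`; wet-cold storage adds `coldstrat_effect` on
  the logit scale; probabilities are clamped to (1e−9, 1 − 1e−9).
- **Trait distributions** (per species): t_opt ~ U(5, 25) °C;
  t_sd ~ LogNormal(log 6, 0.4) °C; p_max ~ Beta(4, 2);
  alt_effect ~ N(0.5, 0.7); coldstrat_effect ~ N(0.3, 0.7);
  timing_hazard ~ U(0.03, 0.5) per day; base log-abundance ~ N(0, 1) (a
  log-normal abundance spectrum, the standard shape for species-abundance
  distributions).
- **Trials**: germinating seeds ~ Binomial(50, p) per dish; each
  germinating seed's day ~ Geometric(timing_hazard), right-censored at the
  trial duration (censored seeds are recorded as not germinated) — a
  one-parameter memoryless timing model. The condition grid is the six
  incubation regimes after dry-warm storage plus the alternating regime
  after wet-cold storage (the storage contrast is what the wet-cold
  response consumes; a separate 20/5 °C response curve is not modelled).
- **Quadrats**: expected relative abundance of species i in block b at dose
  d is softmax of `base_i + slope_i · d/d_max + ε_{i,b}`, with
  ε_{i,b} ~ N(0, block_sd = 0.3) shared across doses within a block (the
  block random effect) and counts Multinomial with a Poisson(400) total —
  so RA denominators vary realistically. The fertilization slope is
  `slope_i = Σ_t γ_t · z(trait_t) + N(0, noise_sd = 0.3)` over the
  configured trait couplings. `slope_i` is expressed as the log-abundance
  change over the *full dose range* (the dose enters scaled by its
  maximum): with couplings of order 1–2 per trait SD this yields strong but
  non-degenerate compositional shifts, whereas a per-(g N m⁻² yr⁻¹)
  reading would put shifts of e⁴⁰–e⁸⁰ at the top dose and collapse every
  community to a single species.
- **Determinism**: all randomness flows from one root seed through named
  substreams (one per stage), so adding a stage never perturbs another
  stage's draws; identical configs give bit-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: spatial structure within quadrats, seed banks and
between-year dynamics, interspecific interactions beyond the shared
multinomial total, non-Gaussian thermal responses (e.g. plateaus or
bimodality), dormancy classes beyond a single storage contrast, and
observation error in the vegetation counts.

One interaction worth knowing when interpreting recovery experiments:
because the alternating-temperature effect is a logit shift, its imprint on
the realized R_5/25 saturates for species that already germinate well at
15 °C. Under couplings that simultaneously favour broad-niche (high-GP)
species, the community-mean R_5/25 contrast between top dose and control is
therefore a noisy readout of the alt-effect coupling — its direction is
not guaranteed in every simulated pool even with noiseless abundances.

## Problem sizes used in the tests

The suite validates the index algebra on ~1000 randomized trial sets
against naive recomputation (exact for counts, 1e−12 for floats); the FD
indices on 100+ random instances (S ≤ 12, m ≤ 3; FRic within 1%,
FEve/FDiv within 1e−9); beta-regression optima against independent
Nelder–Mead restarts (within 1e−6 log-likelihood) plus Wald-interval
coverage over 200 simulations at n = 500; LRT type-I error over 1000 null
simulations; and end-to-end directional recovery over 100 seeded runs of
the default 63-species, 5-block design. These sizes keep the whole suite in
a few minutes on one CPU while leaving the Monte-Carlo margins (±0.02 on a
0.05 rate, ±0.03 on 0.95 coverage) comfortably wider than binomial noise.
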