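# Methods

## The estimation problem

The package estimates area-level associations between built-environment
walkability and the prevalence of guideline-level physical activity, and maps
the residual geographic variation, from individual survey responses
aggregated to small areas. Because individual covariate effects and
area-level contextual effects cannot be fit in one desk-scale model, a
two-stage strategy is used: individual-level logistic adjustment produces
per-area expected counts, which become offsets of an area-level Bayesian
ecological regression.

## Outcomes

Weekly activity items record sessions ("times") and minutes separately for
walking, moderate and vigorous activity. MVPA minutes are
`walk + moderate + 2 × vigorous` (the double weighting reflects intensity).
Inclusive thresholds define three binary outcomes: sufficient walking
(≥150 walking minutes and ≥5 walking sessions), sufficient MVPA (≥150 MVPA
minutes and ≥5 total sessions) and high MVPA (≥300 and ≥5). Sufficient
walking therefore implies sufficient MVPA, and high MVPA implies sufficient
MVPA; both implications are enforced property-style in the tests. The
session rule binds on reported times per week — the only session information
the instrument carries; a per-session 10-minute minimum is treated as
embedded in the walking item wording and is not separately enforceable for
moderate/vigorous items.

## Walkability index

Abridged three-variable index: residential dwelling density (dwellings per
hectare of residential land), intersection density (3+-way intersections per
km² of total land), and land-use mix entropy over five classes,
`H = −Σ p_i ln p_i / ln 5` with `p_i` the class share of summed class area —
proportions cancel spatial-unit size, so H is unit-free in [0, 1].
Normalisation uses all five *defined* classes; a switch
(`n_classes=None`) normalises by classes present instead. Each variable is
decile-scored 1–10 (near-equal bins; ties broken by stable area order —
deterministic, since the data source does not dictate a rule), summed to a
3–30 total and cut at the sample quartiles; boundary ties go to the lower
quartile. Degenerate densities: zero dwellings on zero residential land give
density 0; dwellings on zero land are an error.

## Stage 1: individual model

Reference-cell dummy coding of 13 covariates (50 levels, 37 non-reference
dummies + intercept), complete cases only. The logistic fit is IRLS maximum
likelihood (statsmodels GLM under the hood) with in-package rank and
separation guards (|β| > 15 raises), Wald 95% CIs exponentiated to odds
ratios, and the tie-corrected Mann–Whitney AUC. Adjusted expected counts are
within-area sums of fitted probabilities; by the score equation they sum to
the total observed events (asserted to 1e-8). Areas without respondents are
excluded from the spatial stage and their graph edges dropped.

## Stage 2: BYM model

`O_j ~ Poisson(e_j θ_j)`, `log θ_j = α + x_j'β + s_j + u_j`. The ICAR prior
on `s` has log-kernel `−(τ_s/2) Σ_{i~j} (s_i − s_j)²` on the queen
contiguity graph; `u_j ~ N(0, 1/τ_u)`; `τ_s, τ_u ~ Gamma(0.5, 0.0005)`
(shape–rate on the precision scale); `α` flat; `β ~ N(0, 100²)` (vague).
ICAR impropriety is handled by recentring `s` to sum zero every sweep with
the subtracted mean absorbed into `α`; the heterogeneity field is centred
the same way (its mean is unidentified against the flat-prior intercept), so
its precision update uses (n−1)/2 degrees of freedom. Islands (areas with no
neighbours) have `s_j` pinned at 0. Recentring is global rather than
per-component: per-component constants cannot all be absorbed into one
intercept without changing the linear predictor; the lattices used here are
connected, where the two coincide.

### Sampler

Per sweep: (1) `s` updated by adaptive random-walk Metropolis in
graph-colour blocks (sites within a colour class are mutually non-adjacent,
hence conditionally independent — a greedy colouring gives 4 classes on
queen grids); (2) `u` updated as one vector (sites independent given the
rest); (3) three likelihood-preserving reallocation moves for the weakly
identified s/u split — a Jacobian-corrected partial transfer
`(s, u) → (s + γ(u−ū), u − γ(u−ū))`, an involutive mode swap that exchanges
the two fields and their precisions, and scalar transfers along the 12
lowest-frequency Laplacian eigenvectors (fixed, state-independent
directions; unit Jacobian) that shuttle smooth structure between the fields;
(4) scalar Metropolis for `α` and each `β_r` (binary dummy columns use an
indexed shortcut); (5) conjugate Gibbs for `τ_s`
(shape + rank/2, rank = n_active − components) and `τ_u` (shape + (n−1)/2).
Step sizes adapt toward 44% acceptance in windows of 50 sweeps during
burn-in only and are frozen afterwards to preserve detailed balance;
post-adaptation acceptance outside [0.1, 0.6] warns.

Chains start over-dispersed: chain-specific scalings (0.5×, 1.5×, …) of the
centred log-SMR residuals for `s`, alternating precisions {0.1, 10}, and
offset intercepts. Starting `s` at zero is a known trap: the first conjugate
`τ_s` draw would be ~Gamma(0.5 + rank/2, 0.0005), i.e. a precision around
10⁵ that freezes the field permanently.

Defaults are 2 chains × 40,000 iterations, thin 10, 50% burn-in. The
acceptance studies run shorter schedules (6,000–12,000 iterations, thin 4–6,
≥1,200 retained draws per fit), chosen as desk-scale problem sizes; longer
schedules are one config field away.

### Diagnostics and model choice

Gelman–Rubin PSRF from ≥2 chains (classic between/within form,
cross-checked against arviz's rank-normalised variant on clean chains). DIC
with the plug-in deviance at the posterior means of the per-area log rates
(`pD = D̄ − D̂`, `DIC = D̄ + pD`), verified against a quadrature oracle on
the conjugate single-rate model. Ladder support bands: ΔDIC ≤ 2 deserves
consideration, 3–7 less support, > 7 none.

### Variance partition and maps

The spatial fraction ρ uses the *marginal* variation of the random effects —
per-draw empirical across-area variances of `s` and `u` — summarised as the
posterior median of per-draw ρ (default) or as a ratio of median variances
(flag), because the ICAR τ_s is a conditional precision and not
interpretable as a marginal variance. Excess PRs are per-area posterior
medians of `exp(s_j + u_j)`; spatial-variance reduction between nested
models is `100·(1 − median σ²_s(b)/median σ²_s(a))`. Choropleths export as
GeoJSON with deterministic quantile class breaks.

## Synthetic-data generator

The generator is the package's test bed and emulates the statistical
structure of the motivating cohort study, not its geography:

* **Lattice** — square grid (default 16×16 = 256 areas ≈ the ~255 analysed
  areas), queen contiguity, lognormal land areas (median 7.6 km²).
* **Environment** — three positive fields sharing a smooth latent factor
  (graph-Laplacian-filtered Gaussian noise, smoothness set by
  `spatial_range`; the default 1.5 gives Moran's I ≈ 0.55 for log dwelling
  density), with magnitudes spanning metropolitan ranges (dwelling densities
  ~0.1–200/ha, intersection densities ~0.1–700/km², entropies mostly below
  0.2) and five land-use class areas that sum exactly to the land area; plus
  a spatially smooth disadvantage quintile.
* **Cohort** — multinomial allocation with lognormal weights
  (`allocation_sigma = 1` reproduces a heavily skewed respondents-per-area
  distribution, max/median ≈ 13, as in the emulated study); 13 covariates
  drawn independently from the published sample margins (the source gives
  margins, not a joint distribution).
* **Outcomes** — log link on probability, so ground-truth effects are
  prevalence ratios, the scale stage 2 estimates:
  `p_i = exp(log p₀ + x_iβ + s_j + u_j)` clipped to (0, 0.99), with `s` an
  exact centred ICAR draw (eigen-decomposition of τ_s(D−W)) and `u` iid
  normal; a warning fires if > 1% of pre-clipping probabilities exceed 1.
  The two outcomes not under the spatial model are filled from fixed
  conditionals that match the target margins (31.7/69.4/56.1%) while
  preserving the logical implications. Activity items are then synthesised
  *consistently with the flags*, so re-deriving outcomes from items
  reproduces them exactly.

What the generator does **not** emulate: real geography and spatial weights
heterogeneity, correlated covariates, item nonresponse, within-area
clustering of covariates, and measurement error in self-reported activity.
Passing recovery tests therefore demonstrate the estimator chain, not the
epidemiology of any real region.

## Packaged studies and their design

* **Recovery** (`studies.recovery_study`): 16×16 lattice, 10,000 persons,
  true high-vs-low walkability PR 1.20, truth precisions τ_s = τ_u = 10;
  M3 fit per replicate; 20 replicates. The study is a *calibration
  experiment*, so it isolates the parameter under test: uniform respondent
  allocation and mild environment clustering (`spatial_range = 0.3`). Under
  heavy allocation skew and strong clustering the walkability quartiles
  confound with the ICAR field and the replicate dispersion of any estimator
  roughly doubles — the general spatial-confounding problem of ecological
  regression, worth remembering when interpreting real-data CrIs. Even in
  the clean design, the posterior-median band check (1.10–1.31) retains a
  per-replicate failure probability of roughly a quarter from the
  irreducible heterogeneity-field contrast, so its 15-of-20 pass mark is
  inherently fragile; coverage of the truth by the 95% CrI is the robust
  clause (19–20 of 20 observed).
* **Spatial fraction** (`spatial_fraction_study`): direct area-level counts
  under pure-ICAR vs pure-iid truth (τ = 4, e_j = 40, 12×12); median ρ ≈
  0.94–0.98 vs ≈ 0.002. At intermediate signal-to-noise the s/u attribution
  is weakly identified under vague Gamma priors (a known BYM property); the
  reallocation moves make the chains agree on the posterior rather than on
  their starting mode.
* **Attenuation** (`attenuation_study`): strong walkability gradient
  (PRs 1.10/1.25/1.50) on a clustered environment; adding the true covariate
  (M1 → M3 analogue) cuts median spatial variance by > 30% in ~8–9 of 10
  replicates and shrinks the excess-PR range.
* **Weighting** (`weighting_study`): a population is simulated, respondents
  drawn with a uniform Bernoulli response, and post-stratification weights
  (area × sex × age band, terminal ≥85 band pooled) benchmark the sample
  back; weighted and unweighted area PRs correlate at r ≈ 0.96–0.97 for both
  offset modes. Empty sampled strata are excluded (and logged), never
  collapsed.

## Numerical and degenerate-input conventions

Entropy of an all-zero class vector is an error; 0·ln 0 := 0. Deciles
require ≥ 10 areas, quartiles ≥ 4. Offsets must be positive; an area with
events but zero expectation is an error. DIC needs ≥ 2 retained draws.
`compare_pr` returns NaN when either PR vector is constant, and exactly 1
for identical inputs. All generator and sampler randomness flows from
explicit seeds through `numpy.random.SeedSequence` substreams; same seed ⇒
byte-identical pipeline artifacts.

## Known limitations

* The s/u variance split (hence ρ) is prior-sensitive where the data carry
  little smoothness information; report ρ with its CrI, not as a point fact.
* Poisson stage-2 likelihood on binomial-generated counts is conservative
  (overstates dispersion) at high prevalence.
* Stage-1 offsets are treated as fixed in stage 2; their estimation noise is
  ignored, as in the two-stage strategy generally.
* The CAR family is ICAR-only (no Leroux/proper CAR), and there is no joint
  individual+area multilevel model.
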