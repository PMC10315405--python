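# Methods

## Model

`rpclust` fits a joint global/local latent class model to an n × p matrix
of categorical consumption levels y_ij ∈ {1..d} with a known subgroup
label s_i ∈ {1..S} per person.  Three latent layers generate the data:

1. a global class z_i ~ Categorical(π), π of length K0;
2. a local class c_i ~ Categorical(λ^(s_i)), λ^(s) of length Ks —
   **one local class per person**, not per item;
3. per-item allocation indicators G_ij ~ Bernoulli(ν_{s_i,j}), with
   G_ij = 1 meaning item j follows the global pattern
   θ0[z_i, j, ·] and G_ij = 0 the local pattern θ1[s_i, c_i, j, ·].

Conditional on G_i the person's likelihood factorizes into a sum over
global classes for the globally allocated items times a single sum over
local classes for the locally allocated items.  An alternative reading of
the model puts the local-class sum inside the per-item product, implying
item-wise independent local classes; this package implements the
one-class-per-person form, and its enumeration oracle (exhaustive sums
over (h, l) pairs) tests exactly that form.

Priors are fully conjugate: symmetric Dirichlet(1/K0_max) on π and
Dirichlet(1/Ks_max) on each λ^(s) (the sparse overfitted-mixture regime),
flat Dirichlet(1) on every pattern row, Beta(1, 1) on every ν entry.  The
Gibbs sweep updates, in fixed order: z, c, G, π, λ, θ0, θ1, ν — all exact
full conditionals (categorical draws via Gumbel-max on log-space weights;
Dirichlet draws via gamma normalization, floored at 1e-300 so sparse
concentrations cannot produce exact zeros).

ν is indexed by (subgroup, item).  The indicator itself is per person and
item; ν pools persons within a subgroup, which is what the allocation
heatmap reports.

### Overfitted mixture and "nonempty" patterns

K0_max = Ks_max = 30 is the default configuration; the desk-scale studies
in the tests and the acceptance script use 15–20, which is still 5–10×
the true pattern counts they plant.  A component is "nonempty" when its
posterior-median occupancy (fraction of the relevant population assigned
to it) is at least 5% — both numbers are configuration values.

### Initialization: multi-start with mode selection

The joint posterior is multimodal in a structural way: besides the
crystallized state (sharp pattern rows, indicators matching the true
source of each item) there are metastable traps —

- **all-global mimicry**: enough global components specialize to each
  subgroup's local patterns, indicators drift global;
- **all-local blends**: local components absorb everything, rows converge
  to ν-weighted blends of global and local truth;
- **blended half-states** in which neither process sharpens.

A single Gibbs chain essentially never crosses between these states, and
measured conditional log-likelihoods separate them decisively (on the
mixed-truth benchmark: crystallized ≈ −4 800 versus blends ≈ −17 000
nats).  `run_mcmc` therefore defaults to a short multi-start phase:

- pattern rows are **person-seeded** (each component's rows start at a
  sharpened copy of a randomly drawn person's observed responses, in the
  spirit of k-means++), which makes the first indicator updates
  informative;
- `n_starts` = 8 candidate chains warm up for 600 sweeps, alternating
  indicator starts G ≡ 1 (global) and G ≡ 0 (local);
- global-start candidates hold ν at 0.5 for the first 300 sweeps so
  neither process starves before rows crystallize; local-start candidates
  run free (holding ν there would hand the global process the time to
  mimic the subgroup patterns);
- the candidate with the best mean conditional log-likelihood over the
  last warmup third continues; a local-start winner must beat the best
  global start by 0.75 sd of that window — ties go to the global start,
  the more parsimonious population-level explanation.

`init_indicators="global"` with `theta_init="prior"` reproduces a plain
single-chain sampler from prior draws.  All of this is seeded and
bit-reproducible.

### Degenerate reductions

`nu_fixed=1.0` pins every indicator global and the sweep is literally a
standard latent class model on (π, θ0); `nu_fixed=0.0` with S = 1 is a
plain LCM on (λ, θ1).  The test suite checks both reductions against an
independently written LCM Gibbs sampler (different draw mechanisms, loop
structure) at n = 800 and 4 000 sweeps: posterior means agree within 0.02
sup-norm after total-variation component matching.

## Posterior summarization

Label switching is handled per draw: every draw's components are aligned
to the final draw by greedy total-variation matching of the pattern rows,
occupancy is computed on the aligned draws, components below the
occupancy threshold are pruned, survivors are ordered by descending mean
occupancy, and θ means, weights, memberships and modal patterns are
computed on the aligned survivors.  Greedy matching (rather than optimal
assignment or ECR) is sufficient here because retained components are few
and well separated; a permuted-fixture test guards it.  When almost every
item localizes, the global family legitimately ends up with no component
above threshold; the summary then reports zero global patterns rather
than failing (an error is raised only if every family is empty).

The modal pattern of a profile is the arg-max level of each averaged row;
ties break toward the lower level and are flagged.  The allocation
heatmap reports, per (item, subgroup), both the posterior mean fraction
of persons whose indicator was global and the posterior mean of ν; the
two agree up to Monte-Carlo error and both are emitted.

Survey-weighted descriptives are Horvitz–Thompson weighted means and
proportions per stratum with person-level bootstrap standard errors; the
output metadata names the method.  Design-based (stratum/PSU
Taylor-linearized) variance estimation is intentionally not implemented.

## Preprocessing conventions

- **Recall averaging**: unweighted mean over a person's available recall
  days (1 or 2); persons with no complete recall are excluded with a
  logged reason.
- **Tertile categorization**: cutpoints are the 1/3 and 2/3 quantiles of
  the strictly positive amounts pooled over the whole analytic population,
  under the inverse-empirical-CDF (type-1) quantile convention; levels map
  by half-open intervals 0 → 1, (0, t1] → 2, (t1, t2] → 3, (t2, ∞) → 4,
  so ties at a cutpoint go to the lower level.  Columns with fewer than
  three distinct positive values are degenerate: positive amounts collapse
  to level 2.  A weighted-quantile option exists; the default is
  unweighted.
- **Eligibility**: filters apply in the fixed order sex → age →
  race/ethnicity → income ratio → pregnancy → diet completeness, each
  person tallied under the first criterion that removes them.  Age 20–80
  with 80 inclusive (survey top-code); income-to-poverty ratio ≤ 1.30.
- **Risk flags** (boundary behavior deliberate): obesity BMI ≥ 30
  (inclusive); high cholesterol total > 200 strict, or LDL > 150, or
  medication; hypertension SBP > 140 mm Hg or DBP > 90 or medication;
  diabetes fasting glucose > 126 or medication; smoking by current-use
  item.  A flag with a true disjunct is 1 even if other inputs are
  missing; all-known-false is 0; otherwise missing (the person stays in
  the analysis, out of that flag's summaries).

## Synthetic data

`TruthSpec` holds the full generative truth (sizes, π, λ, θ0, θ1, ν,
seed); `generate_dataset` draws (h, l, G, y) and returns the latent truth
for recovery testing, bit-reproducible given the seed.  G = 1 denotes
"global" throughout the package.  Zero inflation is implemented by mixing
extra mass into level 1 of the affected rows — the model treats "none" as
just category 1, so no hurdle process is needed.

Presets encode study regimes rather than fitted values (the real study's
generative parameters are unknowable); sizes mirror the NHANES 2011–2018
low-income female analytic sample (2 917 persons: 526/386/999/805/201
across five race/ethnicity subgroups, 28 items, 4 levels):

- `paper_scale` — that geometry with 3 weakly separated global patterns
  (modal mass 0.35), a dominant local pattern per subgroup, ν = 0.10 and
  zero-inflated episodic items;
- `all_local` — the strong-localization regime (ν = 0.10 ≤ 0.12
  everywhere) with two well-separated local patterns per subgroup.  Two
  features are essential for the regime to be identifiable, and both
  mirror structure real data carry: within-subgroup heterogeneity (with a
  single product-form local pattern per subgroup, one global pattern can
  copy one subgroup's row per item and the allocation becomes
  observationally indifferent there) and subgroup-varying zero inflation
  and modal mass (no-consumption mass shared identically across subgroups
  is itself a global behavior, and the model would correctly allocate it
  globally);
- `mixed_recovery` — the recovery benchmark: 2 subgroups × 500 persons,
  2 global + 1-per-subgroup local patterns, ν = 0.5, modal mass 0.98.
  The separation is set from an information-floor analysis: each pattern
  row receives ~250 observations, and the best possible estimate (row
  frequencies computed from the true latent assignments, with the same
  prior smoothing) errs by ≈ 0.035 sup-norm (≤ 0.045 across 20 seeds), so
  a 0.05 recovery tolerance tests the sampler, not the noise realization.
  At lower separation (0.85) the floor itself is ≈ 0.10–0.12 and no
  correct implementation could pass;
- `all_global`, `single_group_local` — the degenerate-reduction fixtures;
- `tiny` — a 150-person smoke fixture.

What the generator does **not** emulate: item-level consumption amounts
(simulation starts at categorized food-group levels), recall-day
nonresponse, survey design clustering, and correlated item selection
(G_ij are independent given ν).  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real-data misspecification.

## Problem sizes and runtimes

The bundled studies are sized for a desk machine: n = 800–1 500, p = 28,
K_max = 10–20, 2 000–4 000 sweeps with half burn-in and thinning 5
(seconds to ~2 minutes each; the full test suite runs in a few minutes).
The `paper_scale` preset configuration (n ≈ 2 900, 30 + 30 components,
10 000 sweeps) runs in tens of minutes through the same interfaces.

## Known limitations

- ν is weakly identified in regimes where global and local processes
  explain the data equally well (e.g. data generated entirely from shared
  global patterns: local components can duplicate them at no likelihood
  cost).  The sampler's allocation then reflects the parsimony tie-break,
  and the posterior mean of ν settles high but not at 1 (≈ 0.9 on
  all-global data).
- Mode selection compares a finite set of warm starts; data whose best
  explanation is a mixture of allocation regimes per item block could in
  principle require starts not in the set.
- Greedy relabeling assumes the retained components are separated by
  total variation; heavily overlapping patterns would need ECR-style
  relabeling.
- Bootstrap standard errors for weighted descriptives ignore the survey's
  stratum/PSU structure.
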