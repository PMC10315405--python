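# rpclust

Robust profile clustering of categorical dietary-consumption data: a
Bayesian joint global/local latent class model fit by Gibbs sampling,
together with the dietary preprocessing that produces its input, posterior
summarization, and a synthetic-data generator with known truth.

## Who this is for

Nutritional epidemiologists deriving dietary patterns from categorical
consumption data (e.g. 24-hour recalls summarized to food-group
equivalents) in populations with predefined subgroups — race/ethnicity
strata, study sites, cultural groups — where a single latent class model
would let the largest subgroup dominate the derived patterns and dismiss
smaller subgroups' behaviors as noise.

## The model

Person *i* in subgroup *s\_i* reports consumption levels
*y\_i = (y\_i1, …, y\_ip)* with *y\_ij ∈ {1, …, d}* (level 1 = no
consumption, then tertiles of positive consumption).  The model couples:

- a **global** latent class process: class *z\_i = h* with weights
  *π = (π₁, …, π\_K₀)* and item distributions *θ₀\_{j·|h}*, shared by the
  whole population;
- a **local** process per subgroup: class *c\_i = l* with subgroup weights
  *λ^{(s)}* and item distributions *θ₁\_{j·|l,s}*;
- per-person-per-item binary **allocation indicators**
  *G\_ij ~ Bernoulli(ν\_{s,j})*: item *j* is drawn from the global pattern
  when *G\_ij = 1* and from the subgroup's local pattern when *G\_ij = 0*.

Conditional on the indicators the subject likelihood is

```
f(y_i | s_i, G_i) = [ Σ_h π_h Π_{j:G_ij=1} θ0_{j,y_ij|h} ]
                  × [ Σ_l λ^(s_i)_l Π_{j:G_ij=0} θ1_{j,y_ij|l,s_i} ]
```

All priors are conjugate (Dirichlet on weights and pattern rows, Beta on
ν), so the sampler uses exact full-conditional Gibbs sweeps.  The mixture
is deliberately **overfitted** (30 global and 30 local components by
default) with sparse Dirichlet(1/K) weights, so redundant components empty
out and the occupied count estimates the number of patterns.  ν measures
how strongly an item's consumption is explained at the population level:
low ν across all items means diet is organized by subgroup, not by shared
population-wide profiles.

## Worked example

```python
import rpclust as rp

# synthetic study: 5 subgroups, 28 food items, strong localization
spec = rp.nhanes_like_spec("all_local", size_factor=0.5, seed=17)
data, truth = rp.generate_dataset(spec)

config = rp.MCMCConfig(n_iter=2000, k0_max=15, ks_max=15, seed=27)
samples = rp.run_mcmc(data, config)
summary = rp.prune_and_relabel(samples, occupancy_threshold=0.05)

print("nonempty global patterns:", summary.n_global_nonempty)
print("nonempty local patterns:", summary.n_local_nonempty)
print("max P(item follows global pattern): %.2f" % summary.heatmap_G.max())
```

prints

```
nonempty global patterns: 1
nonempty local patterns: [2, 2, 2, 2, 2]
max P(item follows global pattern): 0.21
```

Read: the overfitted fit kept one (weak) global profile, found the two
local dietary patterns planted in each of the five subgroups, and every
item had at most a 21% probability of following the global process — the
diet structure lives almost entirely at the subgroup level, which is what
this generator preset encodes.  `summary.modal_local_frame()` tabulates
each local pattern's modal consumption level per food with its posterior
probability; `rpclust.plots` renders the modal-pattern grid, the
item-by-subgroup allocation heatmap and the local pattern distributions.

The same stages run from the shell:

```sh
rpclust simulate --preset all_local --size-factor 0.5 --seed 17 --out data.csv
rpclust fit --data data.csv --k0 15 --ks 15 --iters 2000 --seed 27 --out draws/
rpclust summarize --draws draws/ --outdir summary/ --figures
rpclust run --config pipeline.yaml --outdir run/   # all stages + manifest
```

Preprocessing utilities (`average_recalls`, `fit_categorization`,
`categorize`, `apply_eligibility`, `derive_risk_flags`,
`weighted_descriptives`) turn raw recall tables into the categorical
matrix and the descriptive summaries; see `docs/methods.md` for their
conventions.

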