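# pollinet

Structure, null models and extinction scenarios for plant–floral-visitor
networks in invaded plant communities.

## The problem

Coastal plant communities are increasingly invaded by alien plant species.
Whether aliens disrupt or quietly integrate into the native
plant–pollinator web is an empirical question that is usually answered by
assembling, for each study site, a bipartite interaction matrix `A` (rows =
plant species, columns = floral-visitor species, cells = observed visit
counts) and asking three things:

1. **Structure** — how nested, specialized, modular and robust is each
   network, and is that structure distinguishable from a degree-based random
   expectation?
2. **Species roles** — do alien plants occupy different positions than
   natives (degree, strength, contribution to nestedness), and are their
   flowers phenotypically distinct (trait similarity)?
3. **Consequences of loss** — if the alien plants went extinct, would network
   structure change more than if an equal number of natives were lost?

`pollinet` implements that whole workflow for the study system that motivated
it — nine coastal sand-dune communities on a gradient of alien flower
abundance (11–99%), dominated by a super-generalist honey bee — together
with a synthetic-community generator that reproduces the system's
statistical structure, so every stage can be exercised and tested without
field data.

## Metrics implemented

* **NODF nestedness** (0–100): mean paired overlap between species with
  strictly decreasing marginal totals, on the binarized matrix.
* **H2′ network specialization** (0–1): the two-dimensional Shannon entropy
  of interaction proportions, standardized between the minimum and maximum
  entropies achievable under the observed marginal totals,
  `H2' = (H2max − H2) / (H2max − H2min)`.
* **Barber bipartite modularity Q** with a simulated-annealing partition
  search (and an exhaustive oracle for small networks):
  `Q = (1/m) Σ_ij (A_ij − k_i d_j / m) δ(g_i, g_j)`.
* **Robustness R** (0–1): area under the secondary-extinction curve as one
  guild is removed in random order.
* **CE null model**: cell presence probability `p_ij = (k_i/c + d_j/r)/2`,
  with Monte-Carlo z-scores and one-sided p-values for NODF (1000
  replicates) and modularity (100 replicates).
* **Species-level roles**: normalized degree, species strength (sum of
  partner dependencies; plant strengths sum exactly to the number of
  visitor species), and a per-species nestedness-contribution z-score.
* **Floral traits**: Gower mixed-trait distances, a per-species similarity
  index `s_i = 1 − mean_j d_Gower(i, j)`, native/alien group summaries, and
  chromatic (X, Y) coordinates in the trichromatic bee colour hexagon.
* **Extinction scenarios**: aliens-removed, natives-removed and random
  removal (matched removal counts), with bias-corrected Hedges' g effect
  sizes and percent change against the intact network.
* **Sampling completeness**: interaction accumulation curves and the Chao1
  asymptotic interaction-richness estimator.

## Worked example

```python
from pollinet import (GeneratorConfig, generate_site, compute_network_metrics,
                      significance_test, group_similarity_summary)

community, traits = generate_site(GeneratorConfig(seed=1), 0)
print(len(community.plants), len(community.visitors),
      community.total_visits, len(community.alien_plants()))
# 12 30 2060 6   -> 12 plants (6 alien) x 30 visitors, 2060 visits

m = compute_network_metrics(community.counts, n_orders=200, seed=0)
print(f"NODF={m.nodf:.2f} H2'={m.h2prime:.3f} Q={m.modularity_q:.3f} "
      f"R={m.robustness:.3f}")
# NODF=78.25 H2'=0.044 Q=0.055 R=0.913

ens = significance_test(community.counts, "nodf", 1000, seed=0)
print(f"null mean={ens.null_mean:.2f} z={ens.z:.2f} p={ens.p_value:.4f}")
# null mean=72.81 z=2.26 p=0.0060

sim = group_similarity_summary(traits,
                               {p.species_id: p.origin for p in community.plants})
print(f"similarity mean={sim.mean:.3f} native={sim.native_mean:.3f} "
      f"alien={sim.alien_mean:.3f}")
# similarity mean=0.760 native=0.776 alien=0.744
```

The site is significantly nested relative to the CE null (z = 2.26,
p = 0.006), weakly specialized and non-modular, and alien flowers are
phenotypically indistinguishable from natives (group similarity means within
0.04) — the abundance-driven, honey-bee-dominated regime the generator
emulates by default.

The same stages are available from the shell:

```sh
pollinet simulate --seed 1 --n-sites 9 --out study/
pollinet metrics study/site00 --out metrics.json
pollinet run --seed 1 --n-sites 9 --out report/
```

`pollinet run` writes per-site artifacts (metrics, null summaries,
species-level tables, scenario outputs, completeness) plus consolidated
study tables (`site_summary.csv`, `network_metrics.csv`,
`scenario_effects.csv`), each embedding the configuration and seed.

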