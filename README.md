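# traitscape

Trait-based multifunctionality assessment and species selection for
ecological restoration landscapes.

Restoration projects that run for decades produce heterogeneous
landscapes: each site carries a different mix of planted and naturally
regenerated species, and so delivers a different set of ecosystem
functions. `traitscape` gives restoration ecologists a quantitative
pipeline to (1) measure how much of a landscape's functional potential
is currently restored, (2) attribute that to planted vs. naturally
regenerated species, (3) find which species to add — and how many
individuals — to push more sites over their functional thresholds, and
(4) design species compositions for new sites from scratch.

## The model

Each target ecosystem function is proxied by an abundance-weighted
trait statistic of the plant community. With relative abundances
`p_i = a_i / Σ a` and trait values `t_i`:

- community-weighted mean: `CWM = Σ p_i t_i` (for a binary trait, the
  proportion of individuals bearing it);
- community-weighted variance: `CWV = Σ p_i (t_i − CWM)²`.

A function counts as **restored** at a site when its statistic reaches
the threshold — by default the mean of the statistic over reference
sites of remnant natural vegetation. With `F_i` the number of restored
functions at site `i` (0 … `F_max`), landscape multifunctionality over
`N` sites is

```
LM = Σ_i F_i / (N · F_max) × 100   [%]
```

a threshold statistic: a deficit in one function cannot be compensated
by a surplus in another.

Species additions are searched by constrained Monte-Carlo community
assembly: candidate compositions draw a richness uniformly from the
range observed in reference sites (default 10–26), pick species
sequentially with probability proportional to their average observed
relative abundances, never combine species pairs that co-occur
significantly less than expected under a hypergeometric null
(`P(j) = C(N₁,j)·C(N−N₁,N₂−j)/C(N,N₂)`), and allocate the individual
budget by a multinomial draw. Candidates are evaluated on the union
community (resident abundances can never decline); the best candidate
that strictly improves the site's restored-function count — with
priority functions ranked first on flagged sites — becomes that site's
winner.

## Worked example

The package ships a seeded synthetic study system that emulates a
long-term quarry restoration: a 172-species pool (26 planted, 90
naturally regenerated, 56 found only in reference vegetation) with six
traits, 59 restoration sites (8 fire-prone border sites prioritizing
fire resilience) and 19 reference shrubland sites.

```python
import numpy as np
from traitscape import (assess, filter_by_provenance, negative_pairs,
                        run_enrichment, dose_response_frame)
from traitscape.synthetic_fixtures import FixtureSpec, generate_fixture

fx = generate_fixture(FixtureSpec(seed=1))
profiles, summary = assess(fx.restoration, fx.pool,
                           fx.function_specs, fx.thresholds)
print(f"current LM = {summary.lm:.1f}%")

planted = filter_by_provenance(fx.restoration, fx.pool, {"planted"})
_, planted_only = assess(planted, fx.pool, fx.function_specs, fx.thresholds)
print(f"planted-only LM = {planted_only.lm:.1f}%")

plans = run_enrichment(
    fx.restoration, fx.reference, fx.pool, fx.function_specs,
    levels=[0.1, 1.2], n_sim=200, thresholds=fx.thresholds,
    priority_functions=["fire_resilience"], seed=7)
print(dose_response_frame(plans, ["fire_resilience"]).round(1))
```

prints (abridged):

```
current LM = 33.9%
planted-only LM = 26.0%
   level  lm_baseline  lm_post  n_winners  mean_new_species  total_new_species  coverage_fire_resilience
0    0.1         33.9     50.8         49               5.3                 20                      42.4
1    1.2         33.9     81.4         59              10.3                 35                      81.4
```

Reading: the landscape currently restores 33.9% of its maximum
function-by-site potential, dropping to 26.0% if naturally regenerated
species are ignored — natural regeneration carries real functional
weight. Adding 10% more individuals per site (optimally composed)
lifts LM to ~51%; adding 120% lifts it to ~81%, introduces 35 species
new to the landscape, and restores fire resilience in most sites.
(Passing the negative co-occurrence exclusion set via `exclusions=`
constrains the search further; the CLI `enrich` subcommand does this
automatically.)

The same pipeline is scriptable from the shell:

```sh
traitscape fixtures --seed 1 --out fx/
traitscape thresholds --config fx/config.yaml --out out/
traitscape assess     --config fx/config.yaml --out out/
traitscape cooccur    --config fx/config.yaml --out out/
traitscape enrich     --config fx/config.yaml --out out/ --levels 0.1:2.0:0.1 --nsim 5000 --seed 1
traitscape denovo     --config fx/config.yaml --out out/ --nsim 20000 --seed 1
```

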