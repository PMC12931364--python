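# Methods

## Model and assumptions

`traitscape` treats each target ecosystem function as an
abundance-weighted trait statistic of a plant community. For a site
with absolute abundances `a_i` (individual counts) and trait values
`t_i`, relative abundances are `p_i = a_i / Σ a`, and a function is
quantified as either

- `CWM = Σ p_i t_i` — the community-weighted mean; for a binary trait
  (0/1) this is the proportion of individuals carrying the trait — or
- `CWV = Σ p_i (t_i − CWM)²` — the community-weighted variance.

CWV is the population (not sample-corrected) weighted variance: it is
defined directly as the abundance-weighted squared deviation from the
CWM, so no `n/(n−1)` correction applies. Both statistics depend only on
relative abundances, so they are invariant to rescaling a site's total
count.

A function is **restored** at a site when its statistic meets the
threshold in the configured direction. Comparison is inclusive —
reaching the threshold exactly counts as restored (`≥` for
`at_or_above`, `≤` for `at_or_below`). Thresholds default to the
unweighted arithmetic mean of the per-site statistic over the reference
sites; explicit per-function thresholds override derivation. Using the
reference mean assumes remnant natural vegetation exhibits adequate
function levels; stricter quantile-based benchmarks can be expressed
through explicit thresholds.

Landscape multifunctionality over `N` sites with `F_i` restored
functions each (out of `F_max`) is `LM = Σ F_i / (N·F_max) · 100`, in
percent. It is a threshold ("count") statistic: functions are not
traded off against each other. Sites whose abundance drops to zero
under provenance filtering stay in the landscape with `F_i = 0` — the
denominator `N` never shrinks, so a planted-only assessment is
comparable to the full one.

## Provenance attribution

Every species carries a provenance label: `planted`, `regenerated`
(established spontaneously), or `reference_only` (recorded only in
reference vegetation). Filtering a community matrix to a label subset
is pure column selection — retained abundances are untouched — and the
relative abundances are recomputed from the remaining columns.
Recomputing LM on the planted-only matrix isolates the contribution of
natural regeneration by difference. Observed-community assessment uses
all recorded species; the per-species exclusion list (for non-native
planted taxa that practitioners no longer use) applies only to the
simulation candidate pool.

## Negative co-occurrence screening

For two species occupying `N₁` and `N₂` of `N` sites placed uniformly
at random, the shared-site count is hypergeometric,
`P(j) = C(N₁,j)·C(N−N₁,N₂−j)/C(N,N₂)` (evaluated via
`scipy.stats.hypergeom`, which works in log space). A pair is
*negative* when the inclusive lower tail `P(J ≤ j_obs)` is below `α`
(default 0.05). Pairs with expected overlap `N₁N₂/N < 1` are untested
by default (the expected-count filter), since the test carries almost
no information there; the filter and the site set used (default:
restoration and reference sites pooled, giving the most occupancy
information) are configurable. Negative pairs are excluded from all
simulated compositions, preventing recommendations that combine species
which do not naturally coexist. Positive associations are not acted on.

## Constrained community simulation

A candidate composition is drawn as follows:

1. target richness ~ uniform on the configured bounds (default 10–26,
   the richness range of the reference sites);
2. species are selected sequentially without replacement with
   probability proportional to their sampling weight; selecting a
   species removes its negative partners from the remaining weight mass
   (distributionally identical to rejecting conflicting candidates and
   redrawing, but with no unbounded rejection loop). If the mass runs
   out below the minimum richness the draw restarts; after 100 failed
   restarts an error names the bottleneck;
3. the individual budget is allocated over the selected species by one
   multinomial draw with probabilities proportional to their weights.

Sampling weights are empirical: for each species, the zero-inclusive
mean of its within-site relative abundance is computed separately over
restoration and reference sites, and the two means are averaged with
equal weight — the two data sources are treated symmetrically. Species
observed nowhere (e.g., reference-pool species recommended for future
use) receive a floor of 0.1 × the smallest nonzero weight so they
remain drawable; a floor of zero makes them strictly undrawable.

The simulator does not attempt exact uniform sampling over the space of
exclusion-respecting compositions (an independent-set sampling
problem); it is a generate-and-test framework, and the sequential
scheme slightly favors high-weight species in conflicted
neighbourhoods. All draws come from a `numpy` PCG64 generator; batch
and level streams are spawned from one master `SeedSequence`, so every
result is reproducible from a single integer seed.

## Enrichment of ongoing sites

At addition level `L` (fraction of the site's current individuals), the
budget is `round-half-up(L · total)`, floored at one individual.
Candidates are drawn per site and per level (default 5000 per
site-level; the batches are independent because winners are chosen per
site). Each candidate is evaluated on the union community — baseline
plus additions; absolute abundances can only grow. Candidates are
ranked by a lexicographic key: restored flags of the site's priority
functions first (in configured order, only on priority-flagged sites),
then the total restored-function count. The winner is the best
candidate whose key strictly exceeds the baseline key; equal-key
candidates are not adopted (no churn without benefit), and ties are
broken by fewer species new to the site, then by draw order. The drawn
composition is the *addition* set: residents are not forced into it,
and its richness bound applies to the addition, not to the union
community (union richness is reported but unconstrained).

Reported per level: LM before/after, per-function coverage, mean new
species per site among sites with winners, and the count of added
species that were previously absent from the whole restoration
landscape.

## De-novo screening

From-scratch candidates use the same weights and exclusions, with a
nominal fixed budget of 1000 individuals (CWM/CWV are scale-invariant,
so the budget only sets multinomial granularity). Each community is
evaluated standalone; the screen tabulates the full restored-subset
spectrum, the maximum-`F` compositions, and the *super-communities*
restoring all `F_max` functions, with a provenance breakdown
(all-planted vs. containing at least one non-planted species).

## Synthetic study system

The fixture generator emulates a decades-long Mediterranean quarry
restoration: 172 species (26 planted / 90 regenerated / 56
reference-only), six traits — three binary (animal seed dispersal,
prevalence 0.50; resprouting, 0.35; insect pollination, 0.55) and three
continuous, log-normal because they are positive and right-skewed
(flowering duration, median 3.5 months, log-sd 0.35; leaf mass per
area, 0.09 mg mm⁻², 0.30; height, 150 cm, 0.60) — 59 restoration sites
(8 priority "border" sites) and 19 reference sites, with 80–200
individuals per site.

Reference sites draw from the regenerated + reference-only pool with
weight `exp(0.6 · z)` on a standardized function-positive trait score
`z`, making derived thresholds demanding but attainable. Restoration
sites mix planted species (drawn uniformly — practitioners' historical
choices were not function-optimized) with regenerated species (drawn
with the same bias at 0.6 — regeneration disperses in from the natural
surroundings), with 50% of individuals in planted species at ~30% of
site richness. These defaults put baseline LM in a moderate 30–60%
band with the planted-only LM below it, reproducing the qualitative
structure of a landscape where natural regeneration sustains much of
current multifunctionality.

Optional embedded designs give tests ground truth: a composition
verified by direct evaluation to restore all functions (found by a
biased search at generation time; generation fails loudly if none
exists), or an unrestorable function (one trait zeroed across the pool
with an explicit positive threshold, verified airtight via the CWM/CWV
upper bounds).

What the synthetic system does **not** emulate: spatial structure and
dispersal limitation, trait covariance and trade-off geometry (traits
are drawn independently, so real pools may have emptier corners of
trait space), temporal dynamics, carrying capacity, and measurement
error in trait data. Passing tests therefore demonstrate the
correctness and internal consistency of the computations — not that a
particular real landscape will respond as simulated.

## Numerical choices and degenerate inputs

- CWV is clipped at zero against floating-point round-off for
  near-constant traits; `min(t) ≤ CWM ≤ max(t)` and
  `CWV ≤ (max−min)²/4` are property-tested.
- Zero-abundance sites produce NaN composition values and all-false
  restored flags.
- Combination tables sort by count descending, then subset size, then
  label — byte-stable output for regression testing.
- All tail probabilities are inclusive, so `p_lt + p_gt ≥ 1` (they
  share the mass at the observed overlap).
- Species with missing values on any active trait are dropped at read
  time with a logged warning, not imputed.

## Problem sizes in the shipped analyses

The test suite and `scripts/acceptance.py` run the full pipeline on the
default 172-species, 59+19-site system with 1000 candidates per
site-level at three addition levels (10%, 120%, 200%) and a 10,000-draw
de-novo screen — sizes chosen to make the complete analysis
reproducible on a laptop in well under a minute while keeping
Monte-Carlo noise in the reported percentages to a few points. The
library defaults (5000 candidates per site-level across a 10–200%
sweep; 20,000-draw screens) match what a production analysis of a real
landscape would use.
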