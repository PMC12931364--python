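"""Optimizing the addition of individuals to ongoing restoration sites.

For each restoration site and each addition level (a fraction of the
site's current individual count), candidate additions are simulated as
random constrained compositions; each candidate is evaluated on the
union community (baseline + additions — absolute abundances can never
decline), and the best candidate that strictly improves the site's
restored-function key is adopted as the winner. Sites flagged as
priority (e.g., fire-prone border sites) rank candidates
lexicographically: priority functions first, in order, then total
restored-function count. Sweeping addition levels yields a
dose–response of landscape multifunctionality against planting effort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_simulator import (
    SamplingWeights,
    SimulatedCommunity,
    draw_community,
)
from .data_model import CommunityMatrix, FunctionSpec, TraitTable, ValidationError
from .functional_composition import ThresholdSet
from .multifunctionality import (
    FunctionProfile,
    LandscapeSummary,
    landscape_multifunctionality,
    landscape_profiles,
)


@dataclass(frozen=True)
class SiteOutcome:
    """Result of the search at one site and one addition level."""

    site_id: str
    baseline: FunctionProfile
    post: FunctionProfile
    winner: SimulatedCommunity | None
    added: dict[str, int] = field(default_factory=dict)
    n_new_species: int = 0
    new_to_landscape: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EnrichmentPlan:
    """Winners and landscape summaries for one addition level."""

    level: float
    outcomes: list[SiteOutcome]
    baseline_summary: LandscapeSummary
    post_summary: LandscapeSummary

    @property
    def n_winners(self) -> int:
        return sum(1 for o in self.outcomes if o.winner is not None)

    def mean_new_species(self) -> float:
        """Average new species per site, over sites that received a winner."""
        news = [o.n_new_species for o in self.outcomes if o.winner is not None]
        return float(np.mean(news)) if news else 0.0

    def total_new_species(self) -> int:
        """Distinct added species not previously present anywhere in the
        restoration landscape."""
        new: set[str] = set()
        for o in self.outcomes:
            new |= o.new_to_landscape
        return len(new)


def addition_budget(total: int, level: float) -> int:
    """Individuals to add: round-half-up(level × total), at least 1."""
    if level <= 0:
        raise ValidationError("addition level must be positive")
    if total <= 0:
        raise ValidationError("site total must be positive")
    return max(1, int(math.floor(level * total + 0.5)))


def apply_addition(
    baseline: pd.Series, sim: SimulatedCommunity
) -> tuple[pd.Series, int]:
    """Union community after adding a simulated composition to a site.

    Returns the post-addition abundance vector (indexed by the union of
    species) and the count of species new to the site. No resident
    abundance ever decreases.
    """
    additions = sim.as_series()
    post = baseline.add(additions, fill_value=0.0)
    resident = set(baseline.index[baseline > 0])
    n_new = sum(
        1 for s, c in additions.items() if c > 0 and s not in resident
    )
    return post, n_new


def _profile_key(
    restored: dict[str, bool], priority_functions: list[str]
) -> tuple:
    """Lexicographic ranking key: priority-function flags in order, then F."""
    flags = tuple(int(restored.get(fn, False)) for fn in priority_functions)
    return flags + (sum(restored.values()),)


def select_winner(
    baseline_profile: FunctionProfile,
    candidate_keys: list[tuple],
    candidate_new_counts: list[int],
    priority_functions: list[str],
) -> int | None:
    """Index of the best strictly-improving candidate, or None.

    Ties on the ranking key are broken by fewer new species introduced,
    then by candidate index (seed order).
    """
    base_key = _profile_key(baseline_profile.restored, priority_functions)
    best: int | None = None
    for i, key in enumerate(candidate_keys):
        if key <= base_key:
            continue
        if best is None:
            best = i
            continue
        bk = candidate_keys[best]
        if key > bk or (
            key == bk and candidate_new_counts[i] < candidate_new_counts[best]
        ):
            best = i
    return best


def _evaluate_candidates_post(
    baseline_vec: np.ndarray,
    additions: np.ndarray,
    traits: dict[str, np.ndarray],
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vectorized post-addition evaluation over a candidate batch.

    ``additions`` is (n_candidates × n_pool); returns the boolean
    restored matrix (n_candidates × n_functions, in spec order) and the
    per-function value arrays.
    """
    post = baseline_vec[None, :] + additions
    totals = post.sum(axis=1)
    P = post / totals[:, None]
    restored = np.zeros((post.shape[0], len(specs)), dtype=bool)
    values: dict[str, np.ndarray] = {}
    for k, spec in enumerate(specs):
        t = traits[spec.trait]
        mean = P @ t
        if spec.statistic == "weighted_mean":
            v = mean
        else:
            v = np.maximum(P @ (t ** 2) - mean ** 2, 0.0)
        values[spec.name] = v
        thr = thresholds.values[spec.name]
        if thresholds.directions[spec.name] == "at_or_above":
            restored[:, k] = v >= thr
        else:
            restored[:, k] = v <= thr
    return restored, values


def enrich_level(
    restoration: CommunityMatrix,
    tt: TraitTable,
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
    weights: SamplingWeights,
    *,
    level: float,
    n_sim: int,
    exclusions: frozenset[frozenset[str]] = frozenset(),
    richness_bounds: tuple[int, int] = (10, 26),
    priority_functions: list[str] | None = None,
    rng: np.random.Generator,
) -> EnrichmentPlan:
    """Run the per-site winner search at a single addition level."""
    priority_functions = priority_functions or []
    unknown = [f for f in priority_functions
               if f not in {s.name for s in specs}]
    if unknown:
        raise ValidationError(f"unknown priority functions: {unknown}")

    base_profiles = landscape_profiles(restoration, tt, specs, thresholds)
    base_by_site = {p.site_id: p for p in base_profiles}
    base_summary = landscape_multifunctionality(base_profiles, f_max=len(specs))

    pool = list(weights.species)
    pool_pos = {s: i for i, s in enumerate(pool)}
    traits = {
        spec.trait: tt.traits.loc[pool, spec.trait].to_numpy()
        for spec in specs
    }
    landscape_resident = set(
        restoration.species[(restoration.abundances.sum(axis=0) > 0)]
    )

    outcomes: list[SiteOutcome] = []
    post_profiles: list[FunctionProfile] = []
    for site in restoration.sites:
        site = str(site)
        baseline_row = restoration.abundances.loc[site]
        base_profile = base_by_site[site]
        total = int(round(baseline_row.sum()))
        prio = (priority_functions
                if bool(restoration.priority.loc[site]) else [])
        if total <= 0 or n_sim == 0:
            outcomes.append(SiteOutcome(site, base_profile, base_profile, None))
            post_profiles.append(base_profile)
            continue
        budget = addition_budget(total, level)
        batch = [
            draw_community(
                weights, rng, richness_bounds=richness_bounds,
                budget=budget, exclusions=exclusions, sim_id=i,
            )
            for i in range(n_sim)
        ]
        additions = np.zeros((n_sim, len(pool)))
        for r, sim in enumerate(batch):
            for sp, c in zip(sim.species, sim.counts):
                additions[r, pool_pos[sp]] = c
        baseline_vec = baseline_row.reindex(pool, fill_value=0.0).to_numpy()
        restored, values = _evaluate_candidates_post(
            baseline_vec, additions, traits, specs, thresholds,
        )
        spec_names = [s.name for s in specs]
        resident = set(baseline_row.index[baseline_row > 0])
        keys = []
        new_counts = []
        for r in range(n_sim):
            rd = dict(zip(spec_names, restored[r]))
            keys.append(_profile_key(rd, prio))
            new_counts.append(
                sum(1 for sp, c in zip(batch[r].species, batch[r].counts)
                    if c > 0 and sp not in resident)
            )
        best = select_winner(base_profile, keys, new_counts, prio)
        if best is None:
            outcomes.append(SiteOutcome(site, base_profile, base_profile, None))
            post_profiles.append(base_profile)
            continue
        win = batch[best]
        added = {sp: int(c) for sp, c in zip(win.species, win.counts) if c > 0}
        post_profile = FunctionProfile(
            site_id=site,
            values={name: float(values[name][best]) for name in spec_names},
            restored={name: bool(restored[best][k])
                      for k, name in enumerate(spec_names)},
        )
        new_to_landscape = frozenset(
            sp for sp in added if sp not in landscape_resident
        )
        outcomes.append(SiteOutcome(
            site, base_profile, post_profile, win,
            added=added, n_new_species=new_counts[best],
            new_to_landscape=new_to_landscape,
        ))
        post_profiles.append(post_profile)

    post_summary = landscape_multifunctionality(post_profiles, f_max=len(specs))
    return EnrichmentPlan(
        level=level, outcomes=outcomes,
        baseline_summary=base_summary, post_summary=post_summary,
    )


def run_enrichment(
    restoration: CommunityMatrix,
    reference: CommunityMatrix,
    tt: TraitTable,
    specs: list[FunctionSpec],
    *,
    levels: list[float],
    n_sim: int = 5000,
    thresholds: ThresholdSet | None = None,
    weights: SamplingWeights | None = None,
    exclusions: frozenset[frozenset[str]] = frozenset(),
    richness_bounds: tuple[int, int] = (10, 26),
    priority_functions: list[str] | None = None,
    seed: int = 0,
) -> list[EnrichmentPlan]:
    """Sweep addition levels; one independent winner search per level.

    Candidate batches are drawn independently per site and per level
    from streams derived deterministically from ``seed``.
    """
    from .functional_composition import derive_thresholds
    from .community_simulator import sampling_weights as make_weights

    if thresholds is None:
        thresholds = derive_thresholds(reference, tt, specs)
    if weights is None:
        weights = make_weights(
            restoration, reference, pool=list(tt.candidate_pool())
        )
    plans = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(levels))
    for level, stream in zip(levels, streams):
        rng = np.random.Generator(np.random.PCG64(stream))
        plans.append(enrich_level(
            restoration, tt, specs, thresholds, weights,
            level=level, n_sim=n_sim, exclusions=exclusions,
            richness_bounds=richness_bounds,
            priority_functions=priority_functions, rng=rng,
        ))
    return plans


def dose_response_frame(
    plans: list[EnrichmentPlan],
    priority_functions: list[str] | None = None,
) -> pd.DataFrame:
    """Level-by-level summary table of the enrichment sweep."""
    priority_functions = priority_functions or []
    rows = []
    for plan in plans:
        row = {
            "level": plan.level,
            "lm_baseline": plan.baseline_summary.lm,
            "lm_post": plan.post_summary.lm,
            "n_winners": plan.n_winners,
            "mean_new_species": plan.mean_new_species(),
            "total_new_species": plan.total_new_species(),
        }
        for fn in priority_functions:
            row[f"coverage_{fn}"] = plan.post_summary.coverage.get(fn, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def winners_frame(plan: EnrichmentPlan) -> pd.DataFrame:
    """Long-format (site, species, added count) table for one level."""
    rows = [
        {"site_id": o.site_id, "species": sp, "added": c}
        for o in plan.outcomes if o.winner is not None
        for sp, c in sorted(o.added.items())
    ]
    return pd.DataFrame(rows, columns=["site_id", "species", "added"])
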