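"""Screening from-scratch species compositions for future restoration sites.

Candidate communities are simulated directly from the regional pool
(same empirical-abundance weighting and negative-co-occurrence
exclusions as the enrichment search) and evaluated standalone: each
community's own relative abundances feed the CWM/CWV statistics. The
screen reports the full restored-function combination spectrum, the
compositions achieving the maximum restored-function count, and the
"super-communities" that restore every target function simultaneously —
the compositions one would plant when designing a new site from the
ground up.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_simulator import (
    SamplingWeights,
    SimulatedCommunity,
    evaluate_batch,
    simulate_batch,
)
from .data_model import FunctionSpec, TraitTable
from .functional_composition import ThresholdSet


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a de-novo community screen."""

    communities: list[SimulatedCommunity]
    restored_sets: list[frozenset[str]]
    f_counts: np.ndarray
    f_max: int

    @property
    def n_sim(self) -> int:
        return len(self.communities)

    @property
    def max_f(self) -> int:
        return int(self.f_counts.max()) if len(self.f_counts) else 0

    def super_communities(self) -> list[SimulatedCommunity]:
        """Compositions restoring all target functions."""
        return [
            c for c, f in zip(self.communities, self.f_counts)
            if f == self.f_max
        ]

    def best_communities(self) -> list[SimulatedCommunity]:
        """Compositions at the maximum restored-function count observed."""
        top = self.max_f
        return [
            c for c, f in zip(self.communities, self.f_counts) if f == top
        ]

    def spectrum(self) -> dict[frozenset[str], int]:
        """Exact restored-subset counts; sums to n_sim."""
        return dict(Counter(self.restored_sets))

    def spectrum_frame(self) -> pd.DataFrame:
        rows = [
            {"functions": "+".join(sorted(s)) if s else "(none)",
             "n_functions": len(s), "n_communities": c}
            for s, c in self.spectrum().items()
        ]
        rows.sort(key=lambda r: (-r["n_communities"], r["n_functions"],
                                 r["functions"]))
        return pd.DataFrame(
            rows, columns=["functions", "n_functions", "n_communities"]
        )

    def marginal_counts(self) -> dict[str, int]:
        functions = sorted({f for s in self.restored_sets for f in s})
        return {
            fn: sum(1 for s in self.restored_sets if fn in s)
            for fn in functions
        }


def screen_communities(
    tt: TraitTable,
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
    weights: SamplingWeights,
    *,
    n_sim: int = 20000,
    richness_bounds: tuple[int, int] = (10, 26),
    exclusions: frozenset[frozenset[str]] = frozenset(),
    budget: int = 1000,
    rng: np.random.Generator,
) -> ScreenResult:
    """Simulate and evaluate ``n_sim`` standalone candidate communities.

    The nominal ``budget`` fixes absolute community size; CWM/CWV depend
    only on relative abundances, so it affects multinomial granularity,
    not the statistics' scale.
    """
    batch = simulate_batch(
        n_sim, weights, rng,
        richness_bounds=richness_bounds, budget=budget,
        exclusions=exclusions,
    )
    if not batch:
        return ScreenResult(
            communities=[], restored_sets=[],
            f_counts=np.zeros(0, dtype=int), f_max=len(specs),
        )
    values = evaluate_batch(batch, tt, specs)
    restored_sets: list[frozenset[str]] = []
    for _, row in values.iterrows():
        restored_sets.append(frozenset(
            spec.name for spec in specs
            if thresholds.meets(spec.name, float(row[spec.name]))
        ))
    f_counts = np.array([len(s) for s in restored_sets], dtype=int)
    return ScreenResult(
        communities=batch, restored_sets=restored_sets,
        f_counts=f_counts, f_max=len(specs),
    )


def provenance_breakdown(
    result: ScreenResult, tt: TraitTable
) -> dict[str, int]:
    """Partition super-communities by whether they use only planted species.

    Returns counts of all-planted vs. contains-non-planted
    super-communities, plus the distinct species they span overall and
    the distinct non-planted species among them.
    """
    supers = result.super_communities()
    planted = set(tt.species_with({"planted"}))
    all_planted = 0
    contains_non_planted = 0
    species_used: set[str] = set()
    non_planted_used: set[str] = set()
    for sim in supers:
        present = {s for s, c in zip(sim.species, sim.counts) if c > 0}
        species_used |= present
        outside = present - planted
        if outside:
            contains_non_planted += 1
            non_planted_used |= outside
        else:
            all_planted += 1
    return {
        "n_super": len(supers),
        "all_planted": all_planted,
        "contains_non_planted": contains_non_planted,
        "distinct_species": len(species_used),
        "distinct_non_planted_species": len(non_planted_used),
    }


def super_communities_frame(
    result: ScreenResult, tt: TraitTable
) -> pd.DataFrame:
    """Long-format (sim_id, species, count, provenance) super-community table."""
    rows = []
    for sim in result.super_communities():
        for sp, c in zip(sim.species, sim.counts):
            if c > 0:
                rows.append({
                    "sim_id": sim.sim_id, "species": sp, "count": int(c),
                    "provenance": str(tt.provenance.loc[sp]),
                })
    return pd.DataFrame(rows, columns=["sim_id", "species", "count",
                                       "provenance"])
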