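"""Seeded synthetic species pools and landscapes with known structure.

The generator emulates the structure of a long-term quarry-restoration
study system: a regional pool of ~170 limestone-adapted species carrying
six traits (three binary — animal seed dispersal, resprouting ability,
insect pollination — and three continuous — flowering duration, leaf
mass per area, plant height), split by provenance into planted,
naturally-regenerated and reference-only species (default 26/90/56);
a landscape of 59 restoration sites (8 of them fire-prone border sites
with a priority function) and 19 reference shrubland sites.

Reference sites draw species with a configurable bias toward
function-positive trait values, so that thresholds derived from them
are demanding but attainable; restoration sites mix planted and
regenerated species with a configurable individual share. Optional
embedded designs give tests known ground truth: a composition verified
to restore every function, or a function no composition can restore.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community_simulator import (
    SamplingWeights,
    SimulatedCommunity,
    draw_community,
)
from .data_model import (
    CommunityMatrix,
    FunctionSpec,
    TraitTable,
    ValidationError,
)
from .functional_composition import ThresholdSet, derive_thresholds
from .multifunctionality import site_function_profile

#: trait → Bernoulli prevalence in the pool
DEFAULT_BINARY_TRAITS = {
    "zoochory": 0.50,
    "resprouter": 0.35,
    "entomophily": 0.55,
}

#: trait → (median, log-sd); positive right-skewed traits are log-normal
DEFAULT_CONTINUOUS_TRAITS = {
    "flowering_months": (3.5, 0.35),   # months
    "lma": (0.09, 0.30),               # mg mm^-2
    "height": (150.0, 0.60),           # cm
}

DEFAULT_UNITS = {
    "zoochory": "", "resprouter": "", "entomophily": "",
    "flowering_months": "months", "lma": "mg mm^-2", "height": "cm",
}


def default_function_specs() -> list[FunctionSpec]:
    """The six target functions: five CWMs plus height CWV (structure)."""
    return [
        FunctionSpec("seed_dispersal", "zoochory", "weighted_mean"),
        FunctionSpec("fire_resilience", "resprouter", "weighted_mean"),
        FunctionSpec("pollination", "entomophily", "weighted_mean"),
        FunctionSpec("flowering_duration", "flowering_months", "weighted_mean"),
        FunctionSpec("drought_resistance", "lma", "weighted_mean"),
        FunctionSpec("vegetation_structure", "height", "weighted_variance"),
    ]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study system."""

    n_planted: int = 26
    n_regenerated: int = 90
    n_reference_only: int = 56
    binary_traits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_TRAITS))
    continuous_traits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS_TRAITS))
    n_restoration_sites: int = 59
    n_reference_sites: int = 19
    n_priority_sites: int = 8
    site_total_range: tuple[int, int] = (80, 200)
    restoration_richness: tuple[int, int] = (8, 20)
    reference_richness: tuple[int, int] = (10, 26)
    planted_share: float = 0.5
    reference_bias: float = 0.6
    regenerated_bias: float = 0.6
    reference_includes_planted: bool = False
    failing_function_trait: str | None = None
    embed_super_community: bool = False
    seed: int = 0

    @property
    def n_species(self) -> int:
        return self.n_planted + self.n_regenerated + self.n_reference_only


@dataclass(frozen=True)
class Fixture:
    """A generated study system plus its function configuration."""

    spec: FixtureSpec
    pool: TraitTable
    restoration: CommunityMatrix
    reference: CommunityMatrix
    function_specs: list[FunctionSpec]
    thresholds: ThresholdSet
    embedded_super: SimulatedCommunity | None = None


def generate_pool(spec: FixtureSpec) -> TraitTable:
    """Seeded species pool with trait values and provenance labels."""
    if min(spec.n_planted, spec.n_regenerated, spec.n_reference_only) < 0:
        raise ValidationError("provenance split counts must be nonnegative")
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([spec.seed, 0])))
    n = spec.n_species
    width = max(3, len(str(n)))
    species = [f"sp{i:0{width}d}" for i in range(1, n + 1)]
    cols = {}
    kinds = {}
    for trait, prev in spec.binary_traits.items():
        cols[trait] = rng.binomial(1, prev, size=n).astype(float)
        kinds[trait] = "binary"
    for trait, (median, sigma) in spec.continuous_traits.items():
        cols[trait] = np.exp(rng.normal(np.log(median), sigma, size=n))
        kinds[trait] = "continuous"
    if spec.failing_function_trait is not None:
        t = spec.failing_function_trait
        if t not in cols:
            raise ValidationError(f"failing-function trait {t!r} not in layout")
        cols[t] = np.zeros(n)
    traits = pd.DataFrame(cols, index=pd.Index(species, name="species_id"))
    provenance = pd.Series(
        ["planted"] * spec.n_planted
        + ["regenerated"] * spec.n_regenerated
        + ["reference_only"] * spec.n_reference_only,
        index=traits.index, name="provenance",
    )
    units = {t: DEFAULT_UNITS.get(t, "") for t in kinds}
    return TraitTable(traits=traits, trait_kind=kinds, units=units,
                      provenance=provenance)


def _trait_score(pool: TraitTable) -> np.ndarray:
    """Standardized function-positive score per species (for reference bias)."""
    parts = []
    for trait, kind in pool.trait_kind.items():
        v = pool.traits[trait].to_numpy(dtype=float)
        if kind == "continuous":
            v = np.log(np.maximum(v, 1e-12))
        sd = v.std()
        parts.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    score = np.mean(parts, axis=0)
    sd = score.std()
    return (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)


def _fill_site(
    rng: np.random.Generator,
    candidates: np.ndarray,
    weights: np.ndarray,
    richness: int,
    total: int,
) -> dict[str, int]:
    k = min(richness, len(candidates))
    if k < 1 or total < 1:
        raise ValidationError("cannot fill a site with no species/individuals")
    p = weights / weights.sum()
    chosen = rng.choice(len(candidates), size=k, replace=False, p=p)
    # uneven within-site abundances: log-normal relative dominance
    dom = np.exp(rng.normal(0.0, 1.0, size=k))
    counts = rng.multinomial(total - k, dom / dom.sum()) + 1  # every species ≥1
    return {str(candidates[i]): int(c) for i, c in zip(chosen, counts)}


def generate_landscape(
    spec: FixtureSpec, pool: TraitTable
) -> tuple[CommunityMatrix, CommunityMatrix]:
    """Seeded restoration and reference community matrices."""
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([spec.seed, 1])))
    score = pd.Series(_trait_score(pool), index=pool.species)

    ref_labels = {"regenerated", "reference_only"}
    if spec.reference_includes_planted:
        ref_labels.add("planted")
    ref_candidates = np.array(pool.species_with(ref_labels))
    ref_w = np.exp(spec.reference_bias * score.loc[ref_candidates].to_numpy())

    planted = np.array(pool.species_with({"planted"}))
    regen = np.array(pool.species_with({"regenerated"}))
    # regenerated species disperse in from natural surroundings, so their
    # establishment is biased toward the same function-positive trait values
    # that characterize reference vegetation
    regen_w = (np.exp(spec.regenerated_bias * score.loc[regen].to_numpy())
               if len(regen) else np.ones(0))

    lo_t, hi_t = spec.site_total_range
    rows_ref = {}
    for i in range(spec.n_reference_sites):
        richness = int(rng.integers(*spec.reference_richness, endpoint=True))
        total = int(rng.integers(lo_t, hi_t, endpoint=True))
        rows_ref[f"ref{i + 1:02d}"] = _fill_site(
            rng, ref_candidates, ref_w, richness, total)

    rows_res = {}
    for i in range(spec.n_restoration_sites):
        richness = int(rng.integers(*spec.restoration_richness, endpoint=True))
        total = int(rng.integers(lo_t, hi_t, endpoint=True))
        k_p = max(1, round(richness * 0.3)) if len(planted) else 0
        k_r = max(1, richness - k_p) if len(regen) else 0
        t_p = max(k_p, round(total * spec.planted_share)) if k_p else 0
        t_r = max(k_r, total - t_p) if k_r else 0
        site: dict[str, int] = {}
        if k_p:
            site.update(_fill_site(
                rng, planted, np.ones(len(planted)), k_p, t_p))
        if k_r:
            site.update(_fill_site(rng, regen, regen_w, k_r, t_r))
        rows_res[f"res{i + 1:02d}"] = site

    all_species = list(pool.species)

    def to_matrix(rows: dict, role: str, n_priority: int = 0) -> CommunityMatrix:
        ab = pd.DataFrame(rows).T.reindex(columns=all_species).fillna(0.0)
        ab.index.name = "site_id"
        roles = pd.Series(role, index=ab.index, name="role")
        priority = pd.Series(False, index=ab.index, name="priority")
        if n_priority:
            priority.iloc[:n_priority] = True
        return CommunityMatrix(abundances=ab, roles=roles, priority=priority)

    restoration = to_matrix(rows_res, "restoration", spec.n_priority_sites)
    reference = to_matrix(rows_ref, "reference")
    return restoration, reference


def _verify_failing_design(
    spec: FixtureSpec, pool: TraitTable, specs: list[FunctionSpec]
) -> None:
    trait = spec.failing_function_trait
    affected = [s for s in specs if s.trait == trait]
    if not affected:
        raise ValidationError(
            f"no function uses the failing trait {trait!r}")
    for s in affected:
        if s.threshold is None:
            raise ValidationError(
                f"failing function {s.name!r} needs an explicit threshold")
        max_val = float(pool.traits[trait].max())
        # CWM ≤ max trait value and CWV ≤ (max span)²/4; both are 0 here
        if max_val >= s.threshold:
            raise ValidationError(
                f"failing-function design not airtight: max {trait} value "
                f"{max_val} can reach threshold {s.threshold}")


def _find_super_community(
    pool: TraitTable,
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
    rng: np.random.Generator,
    *,
    n_tries: int = 5000,
    richness_bounds: tuple[int, int] = (10, 26),
) -> SimulatedCommunity:
    # bias the search toward function-positive species; the found
    # composition is still verified by direct evaluation below
    weights = SamplingWeights(
        species=tuple(pool.species),
        weights=np.exp(1.5 * _trait_score(pool)),
    )
    for i in range(n_tries):
        sim = draw_community(
            weights, rng, richness_bounds=richness_bounds,
            budget=1000, sim_id=i,
        )
        profile = site_function_profile(
            f"candidate{i}", sim.counts, list(sim.species),
            pool, specs, thresholds,
        )
        if profile.f_count == len(specs):
            return sim
    raise ValidationError(
        f"no all-function composition found in {n_tries} tries; "
        "the pool/threshold configuration may make one infeasible")


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Full study system: pool, landscape, function config, thresholds.

    Embedded designs are verified by direct evaluation at generation
    time; generation fails loudly if a design does not hold.
    """
    pool = generate_pool(spec)
    restoration, reference = generate_landscape(spec, pool)
    specs = default_function_specs()
    if spec.failing_function_trait is not None:
        # a positive explicit threshold no all-zero trait can ever reach
        specs = [
            replace(s, threshold=0.5) if s.trait == spec.failing_function_trait
            else s
            for s in specs
        ]
        _verify_failing_design(spec, pool, specs)
    thresholds = derive_thresholds(reference, pool, specs)
    embedded = None
    if spec.embed_super_community:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([spec.seed, 2])))
        embedded = _find_super_community(pool, specs, thresholds, rng)
        profile = site_function_profile(
            "embedded", embedded.counts, list(embedded.species),
            pool, specs, thresholds,
        )
        if profile.f_count != len(specs):
            raise ValidationError("embedded super-community failed verification")
    return Fixture(
        spec=spec, pool=pool, restoration=restoration, reference=reference,
        function_specs=specs, thresholds=thresholds, embedded_super=embedded,
    )
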