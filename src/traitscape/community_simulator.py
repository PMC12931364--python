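"""Constrained random community assembly from a regional species pool.

Candidate plantings are generated as random species compositions:
richness drawn uniformly from a configured range (default 10–26, the
range observed in reference shrubland sites), species drawn sequentially
without replacement with probability proportional to empirical sampling
weights, and individuals allocated to the selected species by a single
multinomial draw. Two ecological-realism constraints apply:

* sampling weights are the average relative abundances observed in
  reference and restoration sites, so naturally rare species are not
  recommended at high abundance;
* species pairs that co-occur significantly less than expected by
  chance are never combined — selecting a species removes its negative
  partners from the remaining candidate mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CommunityMatrix, TraitTable, ValidationError


@dataclass(frozen=True)
class SamplingWeights:
    """Normalized per-species draw probabilities over the candidate pool."""

    species: tuple[str, ...]
    weights: np.ndarray  # aligned with species, sums to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("negative sampling weight")
        if len(self.species) != len(w):
            raise ValidationError("species/weight length mismatch")
        if w.sum() <= 0:
            raise ValidationError("all sampling weights are zero")
        object.__setattr__(self, "weights", w / w.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.species), name="weight")


@dataclass(frozen=True)
class SimulatedCommunity:
    """One candidate composition: selected species and allocated counts."""

    species: tuple[str, ...]
    counts: np.ndarray
    sim_id: int = 0

    @property
    def richness(self) -> int:
        return len(self.species)

    @property
    def budget(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.species), name="count")


def mean_relative_abundance(cm: CommunityMatrix) -> pd.Series:
    """Zero-inclusive mean of within-site relative abundances per species."""
    ab = cm.abundances
    totals = ab.sum(axis=1)
    rel = ab.div(totals, axis=0)
    rel = rel.loc[totals > 0]  # flagged zero sites carry no information
    return rel.mean(axis=0)


def sampling_weights(
    restoration: CommunityMatrix | None,
    reference: CommunityMatrix | None,
    *,
    pool: list[str] | pd.Index | None = None,
    floor: float | None = None,
) -> SamplingWeights:
    """Empirical sampling weights from restoration and reference matrices.

    Each matrix contributes the zero-inclusive mean within-site relative
    abundance of every species; the two sources are averaged with equal
    weight. Species absent from both matrices (e.g., reference-pool
    species not yet established anywhere) receive a small positive floor
    (default: 0.1 × the smallest nonzero weight) so they stay drawable.
    """
    if restoration is None and reference is None:
        raise ValidationError("need at least one community matrix")
    parts = []
    for cm in (restoration, reference):
        if cm is not None and len(cm.sites) > 0:
            parts.append(mean_relative_abundance(cm))
    if not parts:
        raise ValidationError("both matrices are empty")
    combined = pd.concat(parts, axis=1).fillna(0.0).mean(axis=1)
    if pool is not None:
        combined = combined.reindex(list(pool), fill_value=0.0)
    w = combined.to_numpy(dtype=float)
    if floor is None:
        nonzero = w[w > 0]
        floor = 0.1 * nonzero.min() if len(nonzero) else 1.0
    if floor > 0:
        w = np.where(w > 0, w, floor)
    return SamplingWeights(species=tuple(combined.index), weights=w)


def _conflict_matrix(
    species: tuple[str, ...], exclusions: frozenset[frozenset[str]]
) -> np.ndarray:
    n = len(species)
    conflict = np.zeros((n, n), dtype=bool)
    if exclusions:
        index = {s: i for i, s in enumerate(species)}
        for pair in exclusions:
            a, b = tuple(pair)
            if a in index and b in index:
                conflict[index[a], index[b]] = True
                conflict[index[b], index[a]] = True
    return conflict


def draw_community(
    weights: SamplingWeights,
    rng: np.random.Generator,
    *,
    richness_bounds: tuple[int, int] = (10, 26),
    budget: int = 1000,
    exclusions: frozenset[frozenset[str]] = frozenset(),
    residents: tuple[str, ...] = (),
    max_restarts: int = 100,
    sim_id: int = 0,
) -> SimulatedCommunity:
    """Draw one exclusion-respecting composition and allocate individuals.

    Selecting a species zeroes out the remaining weight of its negative
    co-occurrence partners (equivalent to rejecting conflicting
    candidates and redrawing). If the available weight mass runs out
    before the minimum richness is reached, the draw restarts; after
    ``max_restarts`` failures an error names the bottleneck.
    """
    lo, hi = richness_bounds
    if not (1 <= lo <= hi):
        raise ValidationError(f"invalid richness bounds {richness_bounds}")
    if budget < 1:
        raise ValidationError("budget must be at least 1 individual")
    species = weights.species
    base_w = weights.weights
    conflict = _conflict_matrix(species, exclusions)
    index = {s: i for i, s in enumerate(species)}
    seed_idx = []
    for s in residents:
        if s not in index:
            raise ValidationError(f"resident species {s!r} not in pool")
        seed_idx.append(index[s])

    for _ in range(max_restarts):
        target = int(rng.integers(lo, hi + 1))
        target = max(target, len(seed_idx))
        w = base_w.copy()
        selected: list[int] = []
        ok = True
        for i in seed_idx:
            if w[i] <= 0:
                ok = False
                break
            selected.append(i)
            w[i] = 0.0
            w[conflict[i]] = 0.0
        if not ok:
            raise ValidationError(
                "mandatory residents conflict with the exclusion set or "
                "carry zero weight"
            )
        while len(selected) < target:
            mass = w.sum()
            if mass <= 0:
                break
            # inverse-CDF draw; cheaper than rng.choice re-normalization
            u = rng.random() * mass
            i = int(np.searchsorted(np.cumsum(w), u, side="right"))
            i = min(i, len(w) - 1)
            selected.append(i)
            w[i] = 0.0
            w[conflict[i]] = 0.0
        if len(selected) >= lo:
            sel = np.array(selected)
            probs = base_w[sel] / base_w[sel].sum()
            counts = rng.multinomial(budget, probs)
            return SimulatedCommunity(
                species=tuple(species[i] for i in sel),
                counts=counts.astype(np.int64),
                sim_id=sim_id,
            )
    raise ValidationError(
        f"could not assemble {lo} species after {max_restarts} restarts; "
        "the exclusion set or zero weights make the richness bound infeasible"
    )


def simulate_batch(
    n_sim: int,
    weights: SamplingWeights,
    rng: np.random.Generator,
    **draw_kwargs,
) -> list[SimulatedCommunity]:
    """n_sim independent draws from one seeded stream (reproducible)."""
    if n_sim < 0:
        raise ValidationError("n_sim must be nonnegative")
    return [
        draw_community(weights, rng, sim_id=i, **draw_kwargs)
        for i in range(n_sim)
    ]


def batch_frame(batch: list[SimulatedCommunity]) -> pd.DataFrame:
    """Long-format (sim_id, species, count) table for a batch."""
    rows = [
        {"sim_id": sim.sim_id, "species": sp, "count": int(c)}
        for sim in batch
        for sp, c in zip(sim.species, sim.counts)
    ]
    return pd.DataFrame(rows, columns=["sim_id", "species", "count"])


def evaluate_batch(
    batch: list[SimulatedCommunity],
    tt: TraitTable,
    specs,
) -> pd.DataFrame:
    """Composition values for each simulated community (own abundances).

    Returns a DataFrame indexed by sim_id with one column per function;
    vectorized across the batch.
    """
    pool = list(tt.species)
    pos = {s: i for i, s in enumerate(pool)}
    A = np.zeros((len(batch), len(pool)))
    for r, sim in enumerate(batch):
        for sp, c in zip(sim.species, sim.counts):
            A[r, pos[sp]] = c
    totals = A.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("simulated community with zero individuals")
    P = A / totals[:, None]
    out = {}
    for spec in specs:
        t = tt.traits[spec.trait].to_numpy()
        mean = P @ t
        if spec.statistic == "weighted_mean":
            out[spec.name] = mean
        else:
            out[spec.name] = np.maximum(P @ (t ** 2) - mean ** 2, 0.0)
    return pd.DataFrame(out, index=[sim.sim_id for sim in batch])
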