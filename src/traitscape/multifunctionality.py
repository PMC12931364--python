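"""Threshold multifunctionality: per-site profiles and the landscape statistic.

Each site's multifunctionality is the count Fᵢ of target functions whose
composition statistic meets its threshold — a threshold approach, so a
shortfall in one function cannot be compensated by a surplus in another.
Landscape multifunctionality aggregates over N sites:

    LM = Σᵢ Fᵢ / (N · Fmax) · 100

i.e., the percentage of the maximum achievable restored-function count
(all sites restoring all Fmax functions). The module also tabulates the
exact combination of restored functions per site (the counts behind an
upset plot).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CommunityMatrix, FunctionSpec, TraitTable, ValidationError
from .functional_composition import ThresholdSet, site_composition


@dataclass(frozen=True)
class FunctionProfile:
    """Restored-function flags for one site."""

    site_id: str
    values: dict[str, float]
    restored: dict[str, bool]

    @property
    def f_count(self) -> int:
        return sum(self.restored.values())

    @property
    def restored_set(self) -> frozenset[str]:
        return frozenset(k for k, v in self.restored.items() if v)


@dataclass(frozen=True)
class LandscapeSummary:
    n_sites: int
    f_max: int
    lm: float
    coverage: dict[str, float]          # % of sites restoring each function
    combination_counts: dict[frozenset[str], int]

    def coverage_mean(self) -> float:
        return float(np.mean(list(self.coverage.values())))


def site_function_profile(
    site_id: str,
    abundances: np.ndarray,
    species: list[str] | pd.Index,
    tt: TraitTable,
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
) -> FunctionProfile:
    """Profile a single site given its abundance vector over ``species``."""
    missing = [s.name for s in specs if s.name not in thresholds.values]
    if missing:
        raise ValidationError(f"missing thresholds for functions: {missing}")
    a = np.asarray(abundances, dtype=float)
    values: dict[str, float] = {}
    restored: dict[str, bool] = {}
    if a.sum() <= 0:
        for spec in specs:
            values[spec.name] = float("nan")
            restored[spec.name] = False
        return FunctionProfile(site_id, values, restored)
    from .functional_composition import composition_value

    t_lookup = tt.traits.loc[list(species)]
    for spec in specs:
        v = composition_value(a, t_lookup[spec.trait].to_numpy(), spec.statistic)
        values[spec.name] = v
        restored[spec.name] = thresholds.meets(spec.name, v)
    return FunctionProfile(site_id, values, restored)


def landscape_profiles(
    cm: CommunityMatrix,
    tt: TraitTable,
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
) -> list[FunctionProfile]:
    """Profiles for every site in a matrix (vectorized composition pass)."""
    missing = [s.name for s in specs if s.name not in thresholds.values]
    if missing:
        raise ValidationError(f"missing thresholds for functions: {missing}")
    comp = site_composition(cm, tt, specs)
    profiles = []
    for site in cm.sites:
        row = comp.loc[site]
        if row.isna().all():
            values = {s.name: float("nan") for s in specs}
            restored = {s.name: False for s in specs}
        else:
            values = {s.name: float(row[s.name]) for s in specs}
            restored = {
                s.name: thresholds.meets(s.name, values[s.name]) for s in specs
            }
        profiles.append(FunctionProfile(str(site), values, restored))
    return profiles


def landscape_multifunctionality(
    profiles: list[FunctionProfile], f_max: int
) -> LandscapeSummary:
    """Aggregate site profiles into the landscape statistic and tabulations."""
    if f_max <= 0:
        raise ValidationError("f_max must be positive")
    n = len(profiles)
    if n < 1:
        raise ValidationError("need at least one site profile")
    f_counts = [p.f_count for p in profiles]
    if max(f_counts) > f_max:
        raise ValidationError("a site restores more functions than f_max")
    lm = sum(f_counts) / (n * f_max) * 100.0
    functions = sorted({name for p in profiles for name in p.restored})
    coverage = {
        fn: 100.0 * sum(p.restored.get(fn, False) for p in profiles) / n
        for fn in functions
    }
    combos = Counter(p.restored_set for p in profiles)
    return LandscapeSummary(
        n_sites=n, f_max=f_max, lm=float(lm),
        coverage=coverage, combination_counts=dict(combos),
    )


def combination_counts(profiles: list[FunctionProfile]) -> pd.DataFrame:
    """Exact-subset counts (upset-ready long format), plus marginals.

    Rows are sorted by count descending, ties by subset size then
    lexicographic subset label, so output is deterministic.
    """
    combos = Counter(p.restored_set for p in profiles)
    rows = [
        {"functions": "+".join(sorted(subset)) if subset else "(none)",
         "n_functions": len(subset), "n_sites": count}
        for subset, count in combos.items()
    ]
    rows.sort(key=lambda r: (-r["n_sites"], r["n_functions"], r["functions"]))
    return pd.DataFrame(rows, columns=["functions", "n_functions", "n_sites"])


def marginal_counts(profiles: list[FunctionProfile]) -> dict[str, int]:
    """Number of sites restoring each function (upset marginals)."""
    functions = sorted({name for p in profiles for name in p.restored})
    return {
        fn: sum(p.restored.get(fn, False) for p in profiles) for fn in functions
    }


def assess(
    cm: CommunityMatrix,
    tt: TraitTable,
    specs: list[FunctionSpec],
    thresholds: ThresholdSet,
) -> tuple[list[FunctionProfile], LandscapeSummary]:
    """Convenience: profiles plus landscape summary for one matrix."""
    profiles = landscape_profiles(cm, tt, specs, thresholds)
    return profiles, landscape_multifunctionality(profiles, f_max=len(specs))
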