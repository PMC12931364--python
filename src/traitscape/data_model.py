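"""Core domain types and CSV I/O for trait tables and community matrices.

A restoration landscape is described by two tables:

* a species × trait table with per-trait kind metadata (binary or
  continuous) and a provenance label per species — whether it was
  planted, established through natural regeneration, or has so far been
  recorded only in reference vegetation;
* one or more site × species abundance matrices (absolute counts of
  individuals) with per-site role (restoration vs. reference) and an
  optional priority flag marking sites where one ecosystem function is
  to be prioritized (e.g., fire-prone border sites).

All readers validate on load; downstream modules can then assume clean
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROVENANCE_LABELS = frozenset({"planted", "regenerated", "reference_only"})
TRAIT_KINDS = frozenset({"binary", "continuous"})
STATISTICS = frozenset({"weighted_mean", "weighted_variance"})
DIRECTIONS = frozenset({"at_or_above", "at_or_below"})


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class FunctionSpec:
    """Maps one ecosystem function to a trait, a statistic and a threshold rule.

    Parameters
    ----------
    name
        Function name (e.g., ``"seed_dispersal"``).
    trait
        Trait column the statistic is computed from.
    statistic
        ``"weighted_mean"`` (CWM) or ``"weighted_variance"`` (CWV).
    direction
        ``"at_or_above"`` — function restored when the statistic reaches
        or exceeds the threshold — or ``"at_or_below"`` for the reverse.
    threshold
        Explicit threshold; ``None`` means derive it from reference sites.
    """

    name: str
    trait: str
    statistic: str = "weighted_mean"
    direction: str = "at_or_above"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TraitTable:
    """Species pool: trait values, trait kinds, and provenance labels.

    Attributes
    ----------
    traits
        DataFrame indexed by species id, one column per trait.
    trait_kind
        Mapping trait → ``"binary"`` / ``"continuous"``.
    units
        Mapping trait → free-text unit (may be empty).
    provenance
        Series indexed by species id with values in
        ``{"planted", "regenerated", "reference_only"}``.
    excluded
        Boolean Series; species excluded from the simulation candidate
        pool (e.g., non-native planted species). Exclusion does not
        affect observed-community assessment.
    n_dropped
        Count of species dropped at read time for missing active traits.
    """

    traits: pd.DataFrame
    trait_kind: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)
    provenance: pd.Series = None  # type: ignore[assignment]
    excluded: pd.Series = None  # type: ignore[assignment]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.provenance is None:
            object.__setattr__(
                self,
                "provenance",
                pd.Series("planted", index=self.traits.index, name="provenance"),
            )
        if self.excluded is None:
            object.__setattr__(
                self,
                "excluded",
                pd.Series(False, index=self.traits.index, name="excluded"),
            )
        self.validate()

    @property
    def species(self) -> pd.Index:
        return self.traits.index

    def validate(self) -> None:
        idx = self.traits.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        bad = set(self.provenance.unique()) - PROVENANCE_LABELS
        if bad:
            raise ValidationError(f"unknown provenance labels: {sorted(bad)}")
        for trait, kind in self.trait_kind.items():
            if kind not in TRAIT_KINDS:
                raise ValidationError(f"trait {trait!r}: unknown kind {kind!r}")
            if trait not in self.traits.columns:
                raise ValidationError(f"trait {trait!r} missing from table")
            col = self.traits[trait]
            if kind == "binary":
                ok = col.dropna().isin([0, 1])
                if not ok.all():
                    bad_sp = col.dropna()[~ok].index.tolist()
                    raise ValidationError(
                        f"binary trait {trait!r} has non-0/1 values for {bad_sp}"
                    )

    def provenance_counts(self) -> dict[str, int]:
        counts = self.provenance.value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in sorted(PROVENANCE_LABELS)}

    def species_with(self, provenance: set[str] | frozenset[str]) -> pd.Index:
        bad = set(provenance) - PROVENANCE_LABELS
        if bad:
            raise ValidationError(f"unknown provenance labels: {sorted(bad)}")
        return self.traits.index[self.provenance.isin(provenance)]

    def candidate_pool(self) -> pd.Index:
        """Species eligible for simulation (exclusion list applied)."""
        return self.traits.index[~self.excluded.astype(bool)]


@dataclass(frozen=True)
class CommunityMatrix:
    """Site × species absolute abundances with site metadata.

    ``zero_flagged`` records sites whose total abundance dropped to zero
    through provenance filtering; such sites stay in the landscape and
    contribute zero restored functions.
    """

    abundances: pd.DataFrame
    roles: pd.Series
    priority: pd.Series = None  # type: ignore[assignment]
    zero_flagged: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.priority is None:
            object.__setattr__(
                self,
                "priority",
                pd.Series(False, index=self.abundances.index, name="priority"),
            )
        self.validate()

    @property
    def sites(self) -> pd.Index:
        return self.abundances.index

    @property
    def species(self) -> pd.Index:
        return self.abundances.columns

    def validate(self) -> None:
        ab = self.abundances
        if ab.index.has_duplicates:
            raise ValidationError("duplicate site ids")
        if (ab.values < 0).any():
            r, c = np.argwhere(ab.values < 0)[0]
            raise ValidationError(
                f"negative abundance at site {ab.index[r]!r}, "
                f"species {ab.columns[c]!r}"
            )
        totals = ab.sum(axis=1)
        zero = set(totals.index[totals == 0]) - set(self.zero_flagged)
        if zero:
            raise ValidationError(f"sites with zero total abundance: {sorted(zero)}")
        bad_roles = set(self.roles.unique()) - {"restoration", "reference"}
        if bad_roles:
            raise ValidationError(f"unknown site roles: {sorted(bad_roles)}")
        if not self.roles.index.equals(ab.index):
            raise ValidationError("role metadata does not cover the site index")

    def subset_roles(self, role: str) -> "CommunityMatrix":
        keep = self.roles.index[self.roles == role]
        return CommunityMatrix(
            abundances=self.abundances.loc[keep],
            roles=self.roles.loc[keep],
            priority=self.priority.loc[keep],
            zero_flagged=frozenset(s for s in self.zero_flagged if s in set(keep)),
        )

    def total_individuals(self) -> float:
        return float(self.abundances.values.sum())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_trait_table(
    path,
    trait_kind: dict[str, str],
    *,
    units: dict[str, str] | None = None,
    species_col: str = "species_id",
    provenance_col: str = "provenance",
    excluded_col: str = "excluded",
    active_traits: list[str] | None = None,
) -> TraitTable:
    """Read a species × trait CSV into a validated :class:`TraitTable`.

    Rows missing any *active* trait value are dropped with a warning and
    counted in ``TraitTable.n_dropped``; species must be imputed or
    completed upstream if they are to stay in the pool.
    """
    df = pd.read_csv(path)
    if species_col not in df.columns:
        raise ValidationError(f"missing species id column {species_col!r}")
    if df[species_col].duplicated().any():
        dups = df[species_col][df[species_col].duplicated()].tolist()
        raise ValidationError(f"duplicate species ids: {dups}")
    df = df.set_index(species_col)
    active = list(active_traits) if active_traits is not None else list(trait_kind)
    missing_cols = [t for t in active if t not in df.columns]
    if missing_cols:
        raise ValidationError(f"trait columns missing from CSV: {missing_cols}")
    incomplete = df[active].isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        logger.warning(
            "dropping %d species with missing active-trait values: %s",
            n_dropped,
            df.index[incomplete].tolist(),
        )
        df = df.loc[~incomplete]
    if provenance_col in df.columns:
        provenance = df[provenance_col].astype(str).rename("provenance")
    else:
        provenance = pd.Series("planted", index=df.index, name="provenance")
    if excluded_col in df.columns:
        excluded = df[excluded_col].astype(bool).rename("excluded")
    else:
        excluded = pd.Series(False, index=df.index, name="excluded")
    traits = df[[t for t in trait_kind if t in df.columns]].astype(float)
    return TraitTable(
        traits=traits,
        trait_kind=dict(trait_kind),
        units=dict(units or {}),
        provenance=provenance,
        excluded=excluded,
        n_dropped=n_dropped,
    )


def write_trait_table(tt: TraitTable, path) -> None:
    out = tt.traits.copy()
    out["provenance"] = tt.provenance
    out["excluded"] = tt.excluded.astype(int)
    out.index.name = "species_id"
    out.to_csv(path)


def read_community_matrix(path, meta_path) -> CommunityMatrix:
    """Read a site × species count CSV plus a site-metadata CSV.

    The metadata CSV needs columns ``site_id``, ``role`` and optionally
    ``priority`` (0/1).
    """
    ab = pd.read_csv(path, index_col=0)
    ab.index = ab.index.astype(str)
    ab = ab.astype(float)
    meta = pd.read_csv(meta_path, dtype={"site_id": str}).set_index("site_id")
    missing = set(ab.index) - set(meta.index)
    if missing:
        raise ValidationError(f"sites without metadata: {sorted(missing)}")
    meta = meta.loc[ab.index]
    priority = (
        meta["priority"].astype(bool)
        if "priority" in meta.columns
        else pd.Series(False, index=ab.index)
    )
    return CommunityMatrix(
        abundances=ab,
        roles=meta["role"].astype(str).rename("role"),
        priority=priority.rename("priority"),
    )


def write_community_matrix(cm: CommunityMatrix, path, meta_path) -> None:
    out = cm.abundances.copy()
    out.index.name = "site_id"
    out.to_csv(path)
    meta = pd.DataFrame(
        {"role": cm.roles, "priority": cm.priority.astype(int)},
        index=cm.abundances.index,
    )
    meta.index.name = "site_id"
    meta.to_csv(meta_path)


# ---------------------------------------------------------------------------
# Provenance filtering
# ---------------------------------------------------------------------------

def filter_by_provenance(
    cm: CommunityMatrix, tt: TraitTable, keep: set[str] | frozenset[str]
) -> CommunityMatrix:
    """Restrict a community matrix to species of the given provenance labels.

    Used to quantify how much of current multifunctionality is owed to a
    species group — e.g., keep only planted species to remove the
    contribution of natural regeneration. Abundances of retained species
    are untouched (pure column selection). Sites whose total drops to
    zero are retained and flagged; they count zero restored functions
    rather than shrinking the landscape.
    """
    keep = frozenset(keep)
    if not keep:
        raise ValidationError("empty provenance keep-set")
    bad = keep - PROVENANCE_LABELS
    if bad:
        raise ValidationError(f"unknown provenance labels: {sorted(bad)}")
    kept_species = [s for s in cm.species if s in set(tt.species_with(keep))]
    ab = cm.abundances[kept_species]
    totals = ab.sum(axis=1)
    flagged = frozenset(cm.zero_flagged) | frozenset(totals.index[totals == 0])
    return replace(cm, abundances=ab, zero_flagged=flagged)


def validate_inputs(cm: CommunityMatrix, tt: TraitTable) -> list[str]:
    """Cross-table check: species in the matrix but absent from the pool."""
    return [s for s in cm.species if s not in set(tt.species)]
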