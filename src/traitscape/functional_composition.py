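"""Abundance-weighted trait statistics (CWM, CWV) and restoration thresholds.

The community-weighted mean of a trait, CWM = Σ pᵢ tᵢ with pᵢ the
relative abundance of species i, is the standard proxy for the
functional composition of a community; for a binary trait it equals the
proportion of individuals bearing the trait. The community-weighted
variance, CWV = Σ pᵢ (tᵢ − CWM)², measures trait spread (used here for
plant height as a structural-complexity proxy).

A function is considered restored at a site when its CWM (or CWV)
reaches the threshold — by default the arithmetic mean of the statistic
over reference sites, the operational target level of remnant natural
vegetation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CommunityMatrix, FunctionSpec, TraitTable, ValidationError


@dataclass(frozen=True)
class ThresholdSet:
    """Per-function restoration thresholds with comparison directions."""

    values: dict[str, float]
    directions: dict[str, str]
    n_reference_sites: int = 0

    def __post_init__(self) -> None:
        if set(self.values) != set(self.directions):
            raise ValidationError("threshold values and directions must cover "
                                  "the same functions")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValidationError(f"non-finite threshold for {name!r}")

    def meets(self, name: str, value: float) -> bool:
        """Inclusive comparison: 'reached or exceeded' counts as restored."""
        thr = self.values[name]
        if self.directions[name] == "at_or_above":
            return bool(value >= thr)
        return bool(value <= thr)

    def to_frame(self, specs: list[FunctionSpec] | None = None) -> pd.DataFrame:
        rows = []
        by_name = {s.name: s for s in (specs or [])}
        for name, thr in self.values.items():
            spec = by_name.get(name)
            rows.append({
                "function": name,
                "trait": spec.trait if spec else "",
                "statistic": spec.statistic if spec else "",
                "threshold": thr,
                "direction": self.directions[name],
                "n_reference_sites": self.n_reference_sites,
            })
        return pd.DataFrame(rows)


def relative_abundances(abundances: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative count vector to relative abundances pᵢ."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValidationError("negative abundance")
    total = a.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    return a / total


def cwm(p: np.ndarray, t: np.ndarray) -> float:
    """Community-weighted mean Σ pᵢ tᵢ."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {t.shape}")
    return float(p @ t)


def cwv(p: np.ndarray, t: np.ndarray) -> float:
    """Community-weighted variance Σ pᵢ (tᵢ − CWM)²."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {t.shape}")
    m = p @ t
    # clip: roundoff can produce tiny negatives for near-constant traits
    return float(max((p @ (t - m) ** 2), 0.0))


def composition_value(
    abundances: np.ndarray, traits: np.ndarray, statistic: str
) -> float:
    p = relative_abundances(abundances)
    if statistic == "weighted_mean":
        return cwm(p, traits)
    if statistic == "weighted_variance":
        return cwv(p, traits)
    raise ValidationError(f"unknown statistic {statistic!r}")


def site_composition(
    cm: CommunityMatrix, tt: TraitTable, specs: list[FunctionSpec]
) -> pd.DataFrame:
    """Per-site composition values, one column per function.

    Vectorized over sites: CWM columns come from P @ t and CWV from
    E[t²] − CWM² under the per-site relative-abundance weights.
    Zero-abundance (flagged) sites get NaN.
    """
    _warn_variance_on_binary(tt, specs)
    ab = cm.abundances
    missing = [s for s in ab.columns if s not in set(tt.species)]
    if missing:
        raise ValidationError(f"species without trait data: {missing}")
    totals = ab.sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        P = ab.to_numpy() / totals[:, None]
    out = {}
    for spec in specs:
        t = tt.traits.loc[ab.columns, spec.trait].to_numpy()
        mean = P @ t
        if spec.statistic == "weighted_mean":
            out[spec.name] = mean
        else:
            val = P @ (t ** 2) - mean ** 2
            out[spec.name] = np.maximum(val, 0.0)
    df = pd.DataFrame(out, index=ab.index)
    df.loc[totals == 0] = np.nan
    return df


def derive_thresholds(
    reference: CommunityMatrix, tt: TraitTable, specs: list[FunctionSpec]
) -> ThresholdSet:
    """Reference-derived thresholds: unweighted mean over reference sites.

    Explicit thresholds in a :class:`FunctionSpec` override derivation
    for that function.
    """
    if len(reference.sites) < 1:
        raise ValidationError("need at least one reference site")
    comp = site_composition(reference, tt, specs)
    values, directions = {}, {}
    for spec in specs:
        if spec.threshold is not None:
            values[spec.name] = float(spec.threshold)
        else:
            values[spec.name] = float(comp[spec.name].mean())
        directions[spec.name] = spec.direction
    return ThresholdSet(
        values=values, directions=directions,
        n_reference_sites=int(len(reference.sites)),
    )


def _warn_variance_on_binary(tt: TraitTable, specs: list[FunctionSpec]) -> None:
    for spec in specs:
        if (spec.statistic == "weighted_variance"
                and tt.trait_kind.get(spec.trait) == "binary"):
            warnings.warn(
                f"function {spec.name!r}: weighted_variance on binary trait "
                f"{spec.trait!r} is unusual",
                stacklevel=3,
            )
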