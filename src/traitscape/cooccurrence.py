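"""Probabilistic pairwise species co-occurrence under a hypergeometric null.

For two species occupying N1 and N2 of N sites uniformly at random, the
number of shared sites j is hypergeometric:

    P(j) = C(N1, j) · C(N − N1, N2 − j) / C(N, N2)

A pair co-occurs significantly less than expected by chance when the
inclusive lower tail P(J ≤ j_obs) falls below α. Such negative pairs are
excluded from simulated plantings, preventing recommendations that
combine species which do not naturally coexist. Pairs expected to share
fewer than one site (N1·N2/N < 1) carry almost no information and are by
default not tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_model import CommunityMatrix, ValidationError


@dataclass(frozen=True)
class PairResult:
    species_a: str
    species_b: str
    n_sites: int
    n1: int
    n2: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    tested: bool
    negative: bool

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.species_a, self.species_b})


def _check_occupancy(n: int, n1: int, n2: int) -> None:
    if n < 1:
        raise ValidationError("need at least one site")
    if not (0 <= n1 <= n and 0 <= n2 <= n):
        raise ValidationError(
            f"occupancies ({n1}, {n2}) must lie in [0, {n}]"
        )


def feasible_range(n: int, n1: int, n2: int) -> tuple[int, int]:
    return max(0, n1 + n2 - n), min(n1, n2)


def pair_probability(n: int, n1: int, n2: int, j: int) -> float:
    """P(exactly j shared sites); 0 outside the feasible range."""
    _check_occupancy(n, n1, n2)
    lo, hi = feasible_range(n, n1, n2)
    if not (lo <= j <= hi):
        return 0.0
    # hypergeom(M=n, n=n1, N=n2): draws n2 sites, counts hits among n1
    return float(hypergeom.pmf(j, n, n1, n2))


def pair_pvalues(n: int, n1: int, n2: int, j_obs: int) -> tuple[float, float]:
    """Inclusive tail probabilities (P(J ≤ j_obs), P(J ≥ j_obs))."""
    _check_occupancy(n, n1, n2)
    lo, hi = feasible_range(n, n1, n2)
    if not (lo <= j_obs <= hi):
        raise ValidationError(
            f"observed overlap {j_obs} outside feasible range [{lo}, {hi}]"
        )
    dist = hypergeom(n, n1, n2)
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    return min(p_lt, 1.0), min(p_gt, 1.0)


def analyze_pairs(
    cm: CommunityMatrix,
    *,
    alpha: float = 0.05,
    expected_filter: bool = True,
    min_expected: float = 1.0,
) -> list[PairResult]:
    """Test every species pair of a matrix for negative co-occurrence.

    The matrix is reduced to presence/absence (abundance > 0). With
    ``expected_filter`` on, pairs whose expected shared-site count is
    below ``min_expected`` are reported untested and never flagged.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    pres = (cm.abundances.to_numpy() > 0)
    n = pres.shape[0]
    occupancy = pres.sum(axis=0)
    species = list(cm.species)
    results = []
    for i, k in combinations(range(len(species)), 2):
        n1, n2 = int(occupancy[i]), int(occupancy[k])
        j_obs = int(np.sum(pres[:, i] & pres[:, k]))
        expected = n1 * n2 / n
        tested = (not expected_filter) or (expected >= min_expected)
        if tested:
            p_lt, p_gt = pair_pvalues(n, n1, n2, j_obs)
            negative = p_lt < alpha
        else:
            p_lt, p_gt = float("nan"), float("nan")
            negative = False
        a, b = sorted((species[i], species[k]))
        results.append(PairResult(
            species_a=a, species_b=b, n_sites=n, n1=n1, n2=n2, j_obs=j_obs,
            expected=expected, p_lt=p_lt, p_gt=p_gt,
            tested=tested, negative=negative,
        ))
    return results


def negative_pairs(
    cm: CommunityMatrix,
    *,
    alpha: float = 0.05,
    expected_filter: bool = True,
    min_expected: float = 1.0,
) -> frozenset[frozenset[str]]:
    """Exclusion set: unordered pairs co-occurring less than chance at α."""
    results = analyze_pairs(
        cm, alpha=alpha, expected_filter=expected_filter,
        min_expected=min_expected,
    )
    return frozenset(r.pair for r in results if r.negative)


def pair_results_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = [
        {"species_a": r.species_a, "species_b": r.species_b,
         "n1": r.n1, "n2": r.n2, "j_obs": r.j_obs,
         "expected": r.expected, "p_lt": r.p_lt, "p_gt": r.p_gt,
         "tested": r.tested, "excluded": r.negative}
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(
        ["species_a", "species_b"], ignore_index=True
    )
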