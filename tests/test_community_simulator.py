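from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from traitscape import (
    CommunityMatrix,
    SamplingWeights,
    ValidationError,
    draw_community,
    sampling_weights,
    simulate_batch,
)


def rng_for(seed):
    return np.random.Generator(np.random.PCG64(seed))


def matrix_from(rows, species, role="restoration"):
    ab = pd.DataFrame(rows, columns=species, dtype=float)
    ab.index = pd.Index([f"s{i}" for i in range(len(ab))], name="site_id")
    return CommunityMatrix(
        abundances=ab, roles=pd.Series(role, index=ab.index, name="role"))


class TestSamplingWeights:
    def test_constant_relative_abundance_preserved(self):
        rest = matrix_from([[2, 8], [4, 16]], ["a", "b"])
        ref = matrix_from([[1, 4], [10, 40]], ["a", "b"], role="reference")
        w = sampling_weights(rest, ref).as_series()
        assert w["a"] == pytest.approx(0.2)
        assert w["b"] == pytest.approx(0.8)

    def test_half_half_average_of_the_two_sources(self):
        # per-set mean relative abundances 0.5/0.3/0.2 and 0.1/0.3/0.6
        rest = matrix_from([[5, 3, 2]], ["a", "b", "c"])
        ref = matrix_from([[1, 3, 6]], ["a", "b", "c"], role="reference")
        w = sampling_weights(rest, ref).as_series()
        np.testing.assert_allclose(w[["a", "b", "c"]], [0.3, 0.3, 0.4])

    def test_absent_species_with_zero_floor_never_drawn(self):
        rest = matrix_from([[5, 5]], ["a", "b"])
        w = sampling_weights(rest, None, pool=["a", "b", "ghost"], floor=0.0)
        sim = draw_community(w, rng_for(0), richness_bounds=(2, 2), budget=50)
        assert "ghost" not in sim.species

    def test_default_floor_keeps_unobserved_species_drawable(self):
        rest = matrix_from([[5, 5]], ["a", "b"])
        w = sampling_weights(rest, None, pool=["a", "b", "novel"])
        s = w.as_series()
        assert s["novel"] > 0
        assert s["novel"] == pytest.approx(0.1 * s[["a", "b"]].min(),
                                           rel=1e-9)

    def test_empty_sources_rejected(self):
        with pytest.raises(ValidationError):
            sampling_weights(None, None)


def uniform_weights(n):
    return SamplingWeights(
        species=tuple(f"sp{i}" for i in range(n)), weights=np.ones(n))


class TestDrawCommunity:
    def test_full_pool_selection_and_budget(self):
        sim = draw_community(uniform_weights(10), rng_for(1),
                             richness_bounds=(10, 10), budget=100)
        assert sim.richness == 10
        assert sim.budget == 100
        assert (sim.counts >= 0).all()

    def test_richness_within_bounds(self):
        for seed in range(20):
            sim = draw_community(uniform_weights(30), rng_for(seed),
                                 richness_bounds=(5, 12), budget=40)
            assert 5 <= sim.richness <= 12

    def test_same_seed_reproduces_draw(self):
        a = draw_community(uniform_weights(20), rng_for(9),
                           richness_bounds=(4, 9), budget=77)
        b = draw_community(uniform_weights(20), rng_for(9),
                           richness_bounds=(4, 9), budget=77)
        assert a.species == b.species
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_excluded_pairs_never_cooccur(self):
        exclusions = frozenset({
            frozenset({"sp0", "sp1"}), frozenset({"sp2", "sp5"})})
        for seed in range(50):
            sim = draw_community(
                uniform_weights(8), rng_for(seed), richness_bounds=(3, 6),
                budget=30, exclusions=exclusions)
            present = set(sim.species)
            for pair in exclusions:
                assert not pair <= present

    def test_pariah_species_effectively_never_selected(self):
        """A species excluding the whole pool can't reach min richness."""
        exclusions = frozenset(
            frozenset({"sp0", f"sp{i}"}) for i in range(1, 10))
        for seed in range(100):
            sim = draw_community(
                uniform_weights(10), rng_for(seed), richness_bounds=(3, 5),
                budget=20, exclusions=exclusions)
            assert "sp0" not in sim.species

    def test_residents_preseeded(self):
        sim = draw_community(
            uniform_weights(10), rng_for(3), richness_bounds=(4, 6),
            budget=30, residents=("sp7", "sp8"))
        assert {"sp7", "sp8"} <= set(sim.species)

    def test_infeasible_richness_raises(self):
        # 4-species pool fully mutually exclusive beyond sp0
        exclusions = frozenset(
            frozenset(p) for p in combinations(["sp0", "sp1", "sp2", "sp3"], 2))
        with pytest.raises(ValidationError, match="richness"):
            draw_community(uniform_weights(4), rng_for(0),
                           richness_bounds=(2, 3), budget=10,
                           exclusions=exclusions)


class TestBatches:
    def test_singleton_batch(self):
        batch = simulate_batch(1, uniform_weights(12), rng_for(4),
                               richness_bounds=(3, 6), budget=20)
        assert len(batch) == 1

    def test_batch_reproducible_elementwise(self):
        kwargs = dict(richness_bounds=(3, 8), budget=60)
        a = simulate_batch(200, uniform_weights(15), rng_for(6), **kwargs)
        b = simulate_batch(200, uniform_weights(15), rng_for(6), **kwargs)
        for x, y in zip(a, b):
            assert x.species == y.species
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_counts_always_sum_to_budget(self):
        batch = simulate_batch(100, uniform_weights(12), rng_for(8),
                               richness_bounds=(2, 10), budget=37)
        assert all(sim.budget == 37 for sim in batch)

    def test_uniform_weights_give_uniform_inclusion(self):
        """With equal weights, inclusion frequencies match MC error bars."""
        n, k, n_sim = 6, 3, 4000
        batch = simulate_batch(n_sim, uniform_weights(n), rng_for(10),
                               richness_bounds=(k, k), budget=10)
        freq = np.zeros(n)
        for sim in batch:
            for sp in sim.species:
                freq[int(sp[2:])] += 1
        freq /= n_sim
        p = k / n
        sigma = np.sqrt(p * (1 - p) / n_sim)
        assert np.all(np.abs(freq - p) < 4 * sigma)

    def test_weighted_inclusion_matches_enumeration_oracle(self):
        """Sequential-sampling inclusion probabilities on a 4-species pool.

        The oracle enumerates all ordered draws of k=2 of 4 species
        without replacement and accumulates exact path probabilities.
        """
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        k = 2
        incl = np.zeros(4)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                p_path = weights[i] * weights[j] / (1 - weights[i])
                incl[i] += p_path
                incl[j] += p_path
        sw = SamplingWeights(species=("sp0", "sp1", "sp2", "sp3"),
                             weights=weights)
        n_sim = 20000
        batch = simulate_batch(n_sim, sw, rng_for(12),
                               richness_bounds=(k, k), budget=5)
        freq = np.zeros(4)
        for sim in batch:
            for sp in sim.species:
                freq[int(sp[2:])] += 1
        freq /= n_sim
        sigma = np.sqrt(incl * (1 - incl) / n_sim)
        assert np.all(np.abs(freq - incl) < 4 * sigma)
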