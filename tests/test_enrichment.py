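import numpy as np
import pandas as pd
import pytest

from traitscape import (
    CommunityMatrix,
    FunctionProfile,
    FunctionSpec,
    SamplingWeights,
    SimulatedCommunity,
    ThresholdSet,
    TraitTable,
    ValidationError,
    addition_budget,
    apply_addition,
    dose_response_frame,
    run_enrichment,
    select_winner,
)


@pytest.mark.parametrize("total,level,expected", [
    (100, 0.10, 10),
    (5, 0.10, 1),       # 0.5 rounds half-up, floor of one individual
    (237, 1.20, 284),   # 284.4 rounds down
    (10, 0.25, 3),      # 2.5 rounds half-up
])
def test_addition_budget_rounding(total, level, expected):
    assert addition_budget(total, level) == expected


def test_addition_budget_rejects_nonpositive_level():
    with pytest.raises(ValidationError):
        addition_budget(100, 0.0)


class TestApplyAddition:
    def test_empty_addition_is_identity(self):
        base = pd.Series({"a": 10.0, "b": 0.0})
        sim = SimulatedCommunity(species=("a",), counts=np.array([0]))
        post, n_new = apply_addition(base, sim)
        assert post["a"] == 10.0 and n_new == 0

    def test_new_species_enter_with_added_count(self):
        base = pd.Series({"a": 10.0, "b": 0.0})
        sim = SimulatedCommunity(species=("b",), counts=np.array([5]))
        post, n_new = apply_addition(base, sim)
        assert post["a"] == 10.0 and post["b"] == 5.0
        assert n_new == 1

    def test_residents_never_decline_and_total_adds_budget(self):
        rng = np.random.default_rng(3)
        base = pd.Series(rng.integers(0, 20, size=8).astype(float),
                         index=[f"sp{i}" for i in range(8)])
        counts = rng.multinomial(50, np.ones(5) / 5)
        sim = SimulatedCommunity(
            species=tuple(f"sp{i}" for i in range(3, 8)), counts=counts)
        post, _ = apply_addition(base, sim)
        assert (post.reindex(base.index) >= base).all()
        assert post.sum() == base.sum() + 50


class TestSelectWinner:
    def base(self, restored):
        return FunctionProfile("s", {k: 0.0 for k in restored}, restored)

    def test_no_improving_candidate_returns_none(self):
        base = self.base({"A": True, "B": False})
        assert select_winner(base, [(1,), (1,)], [0, 0], []) is None

    def test_priority_function_outranks_total_count(self):
        # A restores the priority function only; B restores 4 others
        base = self.base({"FR": False, "w": False, "x": False,
                          "y": False, "z": False})
        keys = [(1, 1), (0, 4)]
        assert select_winner(base, keys, [0, 0], ["FR"]) == 0

    def test_tie_broken_by_fewer_new_species_then_index(self):
        base = self.base({"A": False})
        keys = [(1, 4), (1, 4), (0, 6)]
        assert select_winner(base, keys, [3, 2, 0], ["A"]) == 1
        assert select_winner(base, keys, [2, 2, 0], ["A"]) == 0

    def test_equal_key_not_adopted(self):
        base = self.base({"A": True, "B": False})
        # same key as baseline: (1, restored count 1)
        assert select_winner(base, [(1, 1)], [0], ["A"]) is None


def rescuer_system():
    """Tiny landscape where one designed species fixes every deficit.

    Two binary functions; each site fails exactly one of them; the
    rescuer species carries both traits, so a rescuer-dominated addition
    pushes both CWMs over the 0.5 thresholds.
    """
    traits = pd.DataFrame(
        {"t1": [1.0, 0.0, 1.0], "t2": [0.0, 1.0, 1.0]},
        index=pd.Index(["only1", "only2", "rescuer"], name="species_id"),
    )
    tt = TraitTable(
        traits=traits,
        trait_kind={"t1": "binary", "t2": "binary"},
        provenance=pd.Series(["planted", "planted", "reference_only"],
                             index=traits.index),
    )
    specs = [FunctionSpec("f1", "t1", threshold=0.5),
             FunctionSpec("f2", "t2", threshold=0.5)]
    ab = pd.DataFrame(
        {"only1": [20.0, 0.0], "only2": [0.0, 20.0], "rescuer": [0.0, 0.0]},
        index=pd.Index(["s1", "s2"], name="site_id"))
    restoration = CommunityMatrix(
        abundances=ab,
        roles=pd.Series("restoration", index=ab.index, name="role"))
    ref_ab = pd.DataFrame(
        {"only1": [1.0], "only2": [1.0], "rescuer": [2.0]},
        index=pd.Index(["r1"], name="site_id"))
    reference = CommunityMatrix(
        abundances=ref_ab,
        roles=pd.Series("reference", index=ref_ab.index, name="role"))
    return tt, specs, restoration, reference


def test_nsim_zero_leaves_landscape_unchanged():
    tt, specs, restoration, reference = rescuer_system()
    plans = run_enrichment(restoration, reference, tt, specs,
                           levels=[0.5], n_sim=0, richness_bounds=(1, 2),
                           seed=0)
    plan = plans[0]
    assert plan.n_winners == 0
    assert plan.post_summary.lm == plan.baseline_summary.lm


def test_rescuer_species_lifts_lm_to_100():
    tt, specs, restoration, reference = rescuer_system()
    plans = run_enrichment(restoration, reference, tt, specs,
                           levels=[2.0], n_sim=200, richness_bounds=(1, 2),
                           seed=1)
    plan = plans[0]
    assert plan.baseline_summary.lm == pytest.approx(50.0)
    assert plan.post_summary.lm == pytest.approx(100.0)
    # the rescuer is new to both sites
    for outcome in plan.outcomes:
        assert outcome.winner is not None
        assert "rescuer" in outcome.added


def test_enrichment_invariants_on_fixture(study_fixture):
    """Winners only ever add individuals and never lower the key."""
    fx = study_fixture
    plans = run_enrichment(
        fx.restoration, fx.reference, fx.pool, fx.function_specs,
        levels=[0.3], n_sim=60, thresholds=fx.thresholds,
        priority_functions=["fire_resilience"], seed=3)
    plan = plans[0]
    assert plan.post_summary.lm >= plan.baseline_summary.lm
    for outcome in plan.outcomes:
        assert outcome.post.f_count >= outcome.baseline.f_count
        if outcome.winner is None:
            assert outcome.post == outcome.baseline
        else:
            base_row = fx.restoration.abundances.loc[outcome.site_id]
            budget = addition_budget(int(base_row.sum()), 0.3)
            assert sum(outcome.added.values()) == budget
        if bool(fx.restoration.priority.loc[outcome.site_id]):
            assert (outcome.post.restored["fire_resilience"]
                    >= outcome.baseline.restored["fire_resilience"])


def test_same_seed_reproduces_dose_response(study_fixture):
    fx = study_fixture
    kwargs = dict(levels=[0.2, 0.6], n_sim=40, thresholds=fx.thresholds,
                  priority_functions=["fire_resilience"], seed=21)
    a = run_enrichment(fx.restoration, fx.reference, fx.pool,
                       fx.function_specs, **kwargs)
    b = run_enrichment(fx.restoration, fx.reference, fx.pool,
                       fx.function_specs, **kwargs)
    pd.testing.assert_frame_equal(
        dose_response_frame(a, ["fire_resilience"]),
        dose_response_frame(b, ["fire_resilience"]))


def test_unknown_priority_function_rejected(study_fixture):
    fx = study_fixture
    with pytest.raises(ValidationError, match="priority"):
        run_enrichment(fx.restoration, fx.reference, fx.pool,
                       fx.function_specs, levels=[0.1], n_sim=1,
                       thresholds=fx.thresholds,
                       priority_functions=["not_a_function"], seed=0)
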