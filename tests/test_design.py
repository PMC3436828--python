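"""Knockout filtering, strategy search and MOMA flux prediction."""

import itertools

import numpy as np
import pytest

from fluxmodes import (
    apply_knockouts,
    brute_force_ems,
    enumerate_ems,
    fba,
    knockout_search,
    moma_predict,
    production_counts,
    random_network,
    wildtype_reference,
)


def test_apply_knockouts_removes_modes_using_knocked_reactions(diamond):
    ems = enumerate_ems(diamond.model)
    rids = diamond.model.reaction_ids
    kept = apply_knockouts(ems, ["R2"], rids)
    assert len(kept) == 1
    assert kept[0].support == frozenset({0, 2, 3})
    assert apply_knockouts(ems, [], rids) == ems
    with pytest.raises(KeyError, match="unknown reaction"):
        apply_knockouts(ems, ["R99"], rids)


def test_apply_knockouts_composes_over_unions(branched):
    ems = branched.expected_modes
    rids = branched.model.reaction_ids
    for a, b in itertools.combinations(["R2", "R4", "R7"], 2):
        joint = apply_knockouts(ems, [a, b], rids)
        sequential = apply_knockouts(apply_knockouts(ems, [a], rids), [b], rids)
        assert joint == sequential


def test_production_counts(branched):
    ems = branched.expected_modes
    rids = branched.model.reaction_ids
    total, producing, viable = production_counts(ems, "R7", "R6", rids)
    assert total == 5
    assert producing == 1          # only the skip pathway uses R7
    assert viable == 5             # every mode reaches the sink reaction
    # counts are monotone under subsetting
    sub = ems[:2]
    t2, p2, v2 = production_counts(sub, "R7", "R6", rids)
    assert t2 <= total and p2 <= producing and v2 <= viable


def test_knockout_search_removes_competing_pathway(diamond):
    ems = enumerate_ems(diamond.model)
    rids = diamond.model.reaction_ids
    strategy = knockout_search(ems, target_id="R3", biomass_id="R4",
                               reaction_ids=rids, candidate_ids=["R2", "R3"],
                               max_ko=1)
    assert strategy.knocked_reactions == frozenset({"R2"})
    assert strategy.surviving_ems == 1
    assert strategy.producing_ems == 1
    assert strategy.biomass_viable_ems == 1


def test_knockout_search_requires_a_viable_producing_mode(diamond):
    ems = enumerate_ems(diamond.model)
    rids = diamond.model.reaction_ids
    producing_free = apply_knockouts(ems, ["R3"], rids)
    with pytest.raises(ValueError, match="no biomass-viable producing"):
        knockout_search(producing_free, target_id="R3", biomass_id="R4",
                        reaction_ids=rids, candidate_ids=["R2"], max_ko=1)


def test_knockout_search_never_kills_biomass(branched):
    ems = branched.expected_modes
    rids = branched.model.reaction_ids
    strategy = knockout_search(ems, target_id="R7", biomass_id="R6",
                               reaction_ids=rids,
                               candidate_ids=[r for r in rids
                                              if r not in ("R1", "R6", "R7")],
                               max_ko=4)
    assert strategy.biomass_viable_ems >= 1
    # the optimum keeps only the producing skip pathway
    assert strategy.producing_ems == 1
    assert strategy.surviving_ems == 1


@pytest.mark.parametrize("seed", range(6))
def test_greedy_matches_exhaustive_on_small_networks(seed):
    model = random_network(4, 9, rev_fraction=0.0, seed=300 + seed)
    ems = brute_force_ems(model)
    rids = model.reaction_ids
    # pick target and biomass inside one mode's support so a biomass-viable
    # producing mode is guaranteed to exist
    ref = max(ems, key=len)
    support = sorted(ref.support)
    target, biomass = rids[support[-1]], rids[support[0]]
    candidates = [r for r in rids if r not in (target, biomass)]
    exhaustive = knockout_search(ems, target, biomass, rids, candidates,
                                 max_ko=2, exhaustive_budget=10**6)
    greedy = knockout_search(ems, target, biomass, rids, candidates,
                             max_ko=2, exhaustive_budget=0)
    assert greedy.score <= exhaustive.score
    if greedy.knocked_reactions == exhaustive.knocked_reactions:
        assert greedy.score == exhaustive.score


def test_moma_with_no_knockout_returns_wildtype(diamond):
    wt = np.array([2.0, 1.0, 1.0, 2.0])
    v, rate = moma_predict(diamond.model, wt, [], target_id="R3")
    np.testing.assert_allclose(v, wt, atol=1e-8)
    assert rate == pytest.approx(1.0)


def test_moma_knockout_matches_closed_form(diamond):
    """Knocking R2 restricts flux to v = (t, 0, t, t); minimising
    (t-2)^2 + (t-1)^2 + (t-2)^2 gives t = 5/3."""
    wt = np.array([2.0, 1.0, 1.0, 2.0])
    v, rate = moma_predict(diamond.model, wt, ["R2"], target_id="R3")
    np.testing.assert_allclose(v, [5 / 3, 0.0, 5 / 3, 5 / 3], atol=1e-6)
    assert rate == pytest.approx(5 / 3, abs=1e-6)


def test_moma_zero_distance_iff_wildtype_feasible(diamond):
    wt = np.array([1.0, 0.0, 1.0, 1.0])   # already avoids R2
    v, _ = moma_predict(diamond.model, wt, ["R2"])
    assert float(np.sum((v - wt) ** 2)) == pytest.approx(0.0, abs=1e-12)


def test_moma_respects_bounds(diamond):
    model = diamond.model.with_bounds(
        [[0, 1.0], [0, 10], [0, 10], [0, 10]])
    wt = np.array([2.0, 1.0, 1.0, 2.0])   # outside the R1 bound
    v, _ = moma_predict(model, wt, [])
    assert v[0] <= 1.0 + 1e-6
    S_int = model.S[model.internal]
    assert np.abs(S_int @ v).max() < 1e-6


def test_moma_blocked_biomass_gives_zero_flux(diamond):
    wt = np.array([2.0, 1.0, 1.0, 2.0])
    v, rate = moma_predict(diamond.model, wt, ["R2", "R3"], target_id="R4")
    assert rate == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(v, 0.0, atol=1e-8)


def test_fba_wildtype_reference_maximises_biomass(diamond):
    model = diamond.model.with_bounds([[0, 10], [0, 10], [0, 10], [0, 20]])
    wt = wildtype_reference(model, "R4")
    assert wt[model.reaction_index("R4")] == pytest.approx(10.0)
    v = fba(model, "R4", maximize=False)
    assert v[model.reaction_index("R4")] == pytest.approx(0.0, abs=1e-9)
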