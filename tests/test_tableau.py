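"""Canonical-basis tableau: initialisation, pair combination, minimality."""

import numpy as np
import pytest

from fluxmodes import (
    ElementaryMode,
    brute_force_ems,
    combine_rows,
    enumerate_ems,
    extract_modes,
    init_tableau,
    is_minimal,
    pair_combinations,
    process_metabolite,
    random_network,
    toy_network,
    verify_elementary,
)
from fluxmodes.tableau import TableauRow


def test_init_tableau_is_transposed_stoichiometry_plus_identity(diamond):
    tab = init_tableau(diamond.model)
    assert len(tab.rows) == diamond.model.n_reactions
    S_int = diamond.model.S[diamond.model.internal]
    for j, row in enumerate(tab.rows):
        np.testing.assert_array_equal(row.met, S_int[:, j])
        expected_rxn = np.zeros(4)
        expected_rxn[j] = 1
        np.testing.assert_array_equal(row.rxn, expected_rxn)
        assert not row.reversible


def test_init_tableau_marks_fully_reversible_rows(rev_cycle):
    tab = init_tableau(rev_cycle.model)
    assert all(row.reversible for row in tab.rows)


def test_pair_combinations_orientation_rules(diamond):
    # metabolite A: producer R1 (+1), consumers R2, R3 (-1); all irreversible
    tab = init_tableau(diamond.model)
    pairs = pair_combinations(tab, 0)
    assert {(j, k) for j, k, *_ in pairs} == {(0, 1), (0, 2)}
    assert all(sj == 1 and sk == 1 for *_, sj, sk in pairs)


def test_same_sign_irreversible_rows_cannot_pair():
    met = np.array([[2.0], [3.0]])
    rows = [TableauRow(met[i], np.eye(2)[i], False) for i in range(2)]
    tab_like = init_tableau(toy_network("chain").model)
    tab_like.rows = rows
    tab_like.S_int = np.array([[2.0, 3.0]])
    assert pair_combinations(tab_like, 0) == []
    # making one row reversible allows the flipped orientation
    rows[0].reversible = True
    pairs = pair_combinations(tab_like, 0)
    assert pairs == [(0, 1, -1, 1)]


def test_combine_rows_weighted_cancellation():
    row_j = TableauRow(np.array([2.0]), np.array([1.0, 0.0]), True)
    row_k = TableauRow(np.array([3.0]), np.array([0.0, 1.0]), False)
    out = combine_rows(row_j, row_k, 0, (-1, 1))
    assert out.met[0] == 0.0
    # 3*(-row_j) + 2*row_k, normalized to max |coeff| 1
    np.testing.assert_allclose(out.rxn, [-1.0, 2 / 3])
    assert not out.reversible


def test_combine_rows_rejects_opposed_reversible_reaction():
    # both parents carry reversible reaction index 2 in opposite directions
    row_j = TableauRow(np.array([1.0]), np.array([1.0, 0.0, 1.0]), False)
    row_k = TableauRow(np.array([-1.0]), np.array([0.0, 1.0, -1.0]), False)
    assert combine_rows(row_j, row_k, 0, (1, 1)) is None


def test_combine_rows_requires_annulled_column():
    row_j = TableauRow(np.array([1.0]), np.array([1.0, 0.0]), False)
    row_k = TableauRow(np.array([1.0]), np.array([0.0, 1.0]), False)
    with pytest.raises(ValueError, match="orientation"):
        combine_rows(row_j, row_k, 0, (1, 1))


def test_rank_based_minimality(diamond):
    model = diamond.model
    S_int = model.S[model.internal]
    # (R1, R2) after processing A: rank [1, -1] = 1 = 2 - 1 -> minimal
    cand = TableauRow(np.zeros(2), np.array([1.0, 1.0, 0.0, 0.0]), False)
    assert is_minimal(cand, S_int, [0])
    # sum of both elementary modes is not minimal once A and B are processed
    both = TableauRow(np.zeros(2), np.array([2.0, 1.0, 1.0, 2.0]), False)
    assert not is_minimal(both, S_int, [0, 1])
    # singleton support with zero processed coefficients: rank 0 = 1 - 1
    lone = TableauRow(np.zeros(2), np.array([0.0, 0.0, 0.0, 1.0]), False)
    assert is_minimal(lone, S_int, [])


@pytest.mark.parametrize("seed", range(6))
def test_candidate_sum_of_two_modes_fails_rank_test(seed):
    model = random_network(4, 8, rev_fraction=0.0, seed=seed)
    ems = brute_force_ems(model)
    if len(ems) < 2:
        pytest.skip("network with fewer than two modes")
    e1, e2 = ems[0], ems[1]
    combo = TableauRow(np.zeros(model.n_internal),
                       e1.coeffs + e2.coeffs, False)
    S_int = model.S[model.internal]
    assert not is_minimal(combo, S_int, list(range(model.n_internal)))


def test_process_metabolite_keeps_zero_rows_and_appends_survivors(diamond):
    tab = init_tableau(diamond.model)
    process_metabolite(tab, 0)   # eliminate A
    assert tab.processed == [0]
    supports = {frozenset(np.flatnonzero(r.rxn).tolist()) for r in tab.rows}
    assert supports == {frozenset({3}), frozenset({0, 1}), frozenset({0, 2})}
    with pytest.raises(ValueError, match="already processed"):
        process_metabolite(tab, 0)


def test_filter_only_removes_candidates(diamond):
    captured = {}

    def spy(batch):
        captured["n"] = len(batch)
        return batch[:1]

    tab = init_tableau(diamond.model)
    process_metabolite(tab, 0, filter_fn=spy)
    assert captured["n"] == 2
    assert len(tab.rows) == 2  # R4 row + one survivor


def test_extract_requires_all_metabolites_processed(diamond):
    tab = init_tableau(diamond.model)
    with pytest.raises(RuntimeError, match="unprocessed"):
        extract_modes(tab)


@pytest.mark.parametrize("name,count", [
    ("chain", 1), ("diamond", 2), ("rev_cycle", 1), ("branched", 5),
])
def test_enumeration_counts_on_toys(name, count):
    fx = toy_network(name)
    ems = enumerate_ems(fx.model)
    assert len(ems) == count
    assert set(ems) == set(fx.expected_modes)


def test_reversible_cycle_mode_is_reported_once_and_oriented(rev_cycle):
    (mode,) = enumerate_ems(rev_cycle.model)
    assert mode.reversible
    np.testing.assert_allclose(mode.coeffs, [1.0, 1.0])


@pytest.mark.parametrize("seed", range(15))
@pytest.mark.parametrize("rev", [0.0, 0.4])
def test_enumeration_matches_brute_force_oracle(seed, rev):
    model = random_network(4, 9, rev_fraction=rev, seed=seed)
    assert set(enumerate_ems(model)) == set(brute_force_ems(model))


@pytest.mark.parametrize("seed", range(4))
def test_enumeration_is_order_independent(seed):
    model = random_network(4, 9, rev_fraction=0.3, seed=50 + seed)
    reference = set(enumerate_ems(model))
    rng = np.random.default_rng(seed)
    for _ in range(3):
        order = rng.permutation(model.n_internal).tolist()
        assert set(enumerate_ems(model, order=order)) == reference
    assert set(enumerate_ems(model, order="fewest")) == reference


@pytest.mark.parametrize("seed", range(4))
def test_every_enumerated_mode_is_verified_elementary(seed):
    model = random_network(5, 10, rev_fraction=0.3, seed=200 + seed)
    ems = enumerate_ems(model)
    assert len(set(ems)) == len(ems)
    assert all(verify_elementary(m, model) for m in ems)
    irrev = ~model.reversible
    S_int = model.S[model.internal]
    for mode in ems:
        assert np.abs(S_int @ mode.coeffs).max() <= 1e-6
        assert (mode.coeffs[irrev] >= -1e-9).all()


def test_exact_rational_mode_agrees_with_float(branched):
    exact = enumerate_ems(branched.model, exact=True)
    assert set(exact) == set(enumerate_ems(branched.model))
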