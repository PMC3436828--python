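"""Canonical-basis tableau algorithm for elementary flux modes.

The tableau starts as ``T = [S_int^T | I_n]``: one row per reaction, holding
the reaction's internal-metabolite column (the "metabolite part") next to a
unit vector over reactions (the "reaction part").  Internal metabolites are
eliminated one at a time: every pair of rows with opposite-sign entries in the
current metabolite column is combined into a new row that balances that
metabolite, reversible rows may be flipped to achieve opposite signs, and each
candidate must pass the rank-based minimality test

    rank(S[processed metabolites, support(candidate)]) == |support| - 1

before it is kept.  When every internal metabolite has been processed the
metabolite parts are zero and the reaction parts are exactly the elementary
modes.

A hook (``filter_fn``) is applied to each metabolite's batch of new candidate
rows after deduplication; the identity hook yields complete enumeration, and
the random subsampling hook in :mod:`fluxmodes.sampling` yields EM samples.

Arithmetic is floating point with a 1e-9 zero tolerance by default; an exact
rational mode (``exact=True``) is available for small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .model import MetabolicModel, internal_stoichiometry
from .modes import ZERO_TOL, ElementaryMode, dedupe_modes, matrix_rank

FilterFn = Callable[[list["TableauRow"]], list["TableauRow"]]

#: Residual metabolite-part magnitude tolerated at extraction.
RESIDUAL_TOL = 1e-6


@dataclass
class TableauRow:
    """One candidate mode: residual metabolite part + reaction coefficients.

    ``met`` keeps full width over internal metabolites; entries of processed
    metabolites are exactly zero.  ``reversible`` is true iff every reaction
    in the support is reversible, so the row may be used in either direction.
    """

    met: np.ndarray
    rxn: np.ndarray
    reversible: bool


@dataclass
class Tableau:
    rows: list[TableauRow]
    processed: list[int]            # internal metabolite indices, in order
    S_int: np.ndarray               # float internal stoichiometry (rank tests)
    model: MetabolicModel
    exact: bool = False

    @property
    def n_internal(self) -> int:
        return self.S_int.shape[0]

    def unprocessed(self) -> list[int]:
        done = set(self.processed)
        return [i for i in range(self.n_internal) if i not in done]


def _to_exact(x: float) -> Fraction:
    return Fraction(x).limit_denominator(10**6)


def _is_zero(x, exact: bool) -> bool:
    return x == 0 if exact else abs(x) <= ZERO_TOL


def _normalize_row(row: TableauRow, exact: bool) -> TableauRow:
    scale = max(abs(x) for x in row.rxn) if exact else np.abs(row.rxn).max()
    if _is_zero(scale, exact):
        raise ValueError("tableau row with zero reaction part")
    met = row.met / scale
    rxn = row.rxn / scale
    if not exact:
        met[np.abs(met) <= ZERO_TOL] = 0.0
        rxn[np.abs(rxn) <= ZERO_TOL] = 0.0
    if row.reversible:
        # canonical orientation: first nonzero reaction coefficient positive
        for x in rxn:
            if not _is_zero(x, exact):
                if x < 0:
                    met, rxn = -met, -rxn
                break
    return TableauRow(met, rxn, row.reversible)


def _row_key(row: TableauRow, exact: bool) -> tuple:
    if exact:
        return tuple((i, x) for i, x in enumerate(row.rxn) if x != 0)
    nz = np.flatnonzero(row.rxn)
    return tuple((int(i), round(float(row.rxn[i]), 9)) for i in nz)


def init_tableau(model: MetabolicModel, exact: bool = False) -> Tableau:
    """Build the initial tableau ``[S_int^T | I_n]``."""
    S_int = internal_stoichiometry(model)
    m_int, n = S_int.shape
    rows = []
    for j in range(n):
        if exact:
            met = np.array([_to_exact(x) for x in S_int[:, j]], dtype=object)
            rxn = np.array([Fraction(int(i == j)) for i in range(n)],
                           dtype=object)
        else:
            met = S_int[:, j].astype(float).copy()
            rxn = np.zeros(n)
            rxn[j] = 1.0
        rows.append(TableauRow(met, rxn, bool(model.reversible[j])))
    return Tableau(rows=rows, processed=[], S_int=S_int.astype(float),
                   model=model, exact=exact)


def pair_combinations(tableau: Tableau,
                      col: int) -> list[tuple[int, int, int, int]]:
    """Oriented row pairs ``(j, k, sigma_j, sigma_k)`` whose combination can
    annul metabolite ``col``.

    Orientations make the two column entries opposite in sign; a row may only
    be negated (sigma = -1) if it is reversible.  For a reversible-reversible
    pair with same-sign entries the two valid orientations give mode and
    anti-mode, so a single canonical one is returned.
    """
    exact = tableau.exact
    rows = tableau.rows
    active = [j for j, r in enumerate(rows) if not _is_zero(r.met[col], exact)]
    pairs = []
    for a_pos, j in enumerate(active):
        for k in active[a_pos + 1:]:
            opposite = (rows[j].met[col] > 0) != (rows[k].met[col] > 0)
            if opposite:
                pairs.append((j, k, 1, 1))
            elif rows[j].reversible:
                pairs.append((j, k, -1, 1))
            elif rows[k].reversible:
                pairs.append((j, k, 1, -1))
    return pairs


def combine_rows(row_j: TableauRow, row_k: TableauRow, col: int,
                 orientation: tuple[int, int],
                 exact: bool = False) -> TableauRow | None:
    """Combine two oriented rows so the ``col`` entry cancels.

    Returns ``None`` when the oriented parents carry a shared reversible
    reaction in opposite directions — such a candidate would use a reversible
    reaction both ways at once and is discarded without the rank test.
    """
    sj, sk = orientation
    a = sj * row_j.met[col]
    b = sk * row_k.met[col]
    if _is_zero(a, exact) or _is_zero(b, exact) or (a > 0) == (b > 0):
        raise ValueError("orientation does not annul the column entry")
    rxn_j = sj * row_j.rxn
    rxn_k = sk * row_k.rxn
    # opposite-direction use of a shared reaction (necessarily reversible)
    if exact:
        clash = any(x * y < 0 for x, y in zip(rxn_j, rxn_k))
    else:
        clash = bool(np.any((rxn_j > ZERO_TOL) & (rxn_k < -ZERO_TOL))
                     or np.any((rxn_j < -ZERO_TOL) & (rxn_k > ZERO_TOL)))
    if clash:
        return None
    wj, wk = abs(b), abs(a)
    met = wj * (sj * row_j.met) + wk * (sk * row_k.met)
    rxn = wj * rxn_j + wk * rxn_k
    met[col] = Fraction(0) if exact else 0.0
    return _normalize_row(
        TableauRow(met, rxn, row_j.reversible and row_k.reversible), exact
    )


def is_minimal(candidate: TableauRow, S_int: np.ndarray,
               processed: Sequence[int], exact: bool = False) -> bool:
    """Rank test: the candidate's support is minimal iff the stoichiometric
    submatrix (processed metabolites x support) has rank |support| - 1."""
    if exact:
        support = [i for i, x in enumerate(candidate.rxn) if x != 0]
    else:
        support = np.flatnonzero(np.abs(candidate.rxn) > ZERO_TOL).tolist()
    if not support:
        raise ValueError("candidate with empty support")
    sub = S_int[np.ix_(sorted(processed), support)]
    if exact:
        import sympy

        rank = sympy.Matrix(sub).rank()
    else:
        rank = matrix_rank(sub)
    return rank == len(support) - 1


def process_metabolite(tableau: Tableau, col: int,
                       filter_fn: FilterFn | None = None) -> Tableau:
    """Eliminate one internal metabolite in place.

    Rows with a zero entry at ``col`` are kept; all minimal oriented pair
    combinations are collected, deduplicated, passed through ``filter_fn``
    and appended.  ``col`` is then marked processed.
    """
    if col in tableau.processed:
        raise ValueError(f"metabolite column {col} already processed")
    exact = tableau.exact
    processed_with_col = tableau.processed + [col]

    new_rows: list[TableauRow] = []
    seen: set[tuple] = set()
    for j, k, sj, sk in pair_combinations(tableau, col):
        cand = combine_rows(tableau.rows[j], tableau.rows[k], col,
                            (sj, sk), exact)
        if cand is None:
            continue
        key = _row_key(cand, exact)
        if key in seen:
            continue
        if is_minimal(cand, tableau.S_int, processed_with_col, exact):
            seen.add(key)
            new_rows.append(cand)
    if filter_fn is not None:
        new_rows = filter_fn(new_rows)

    kept = [r for r in tableau.rows if _is_zero(r.met[col], exact)]
    tableau.rows = kept + new_rows
    tableau.processed.append(col)
    return tableau


def extract_modes(tableau: Tableau) -> list[ElementaryMode]:
    """Convert the fully processed tableau into normalized elementary modes."""
    if tableau.unprocessed():
        raise RuntimeError("tableau still has unprocessed internal metabolites")
    modes = []
    for row in tableau.rows:
        met = np.array([float(x) for x in row.met]) if tableau.exact \
            else row.met
        if met.size and np.abs(met).max() > RESIDUAL_TOL:
            raise RuntimeError("row with nonzero residual metabolite part")
        rxn = np.array([float(x) for x in row.rxn]) if tableau.exact \
            else row.rxn
        modes.append(ElementaryMode.from_vector(rxn, row.reversible))
    return dedupe_modes(modes)


def _resolve_order(tableau: Tableau,
                   order: Sequence[int] | str | None) -> list[int] | str:
    if order is None:
        return list(range(tableau.n_internal))
    if isinstance(order, str):
        if order != "fewest":
            raise ValueError(f"unknown processing order {order!r}")
        return order
    order = list(order)
    if sorted(order) != list(range(tableau.n_internal)):
        raise ValueError("order must be a permutation of internal metabolites")
    return order


def _next_fewest(tableau: Tableau) -> int:
    """Unprocessed metabolite with fewest nonzero rows (fewest combinations)."""
    exact = tableau.exact

    def n_active(col: int) -> int:
        return sum(not _is_zero(r.met[col], exact) for r in tableau.rows)

    return min(tableau.unprocessed(), key=lambda c: (n_active(c), c))


def run_tableau(model: MetabolicModel,
                filter_fn: FilterFn | None = None,
                order: Sequence[int] | str | None = None,
                exact: bool = False) -> list[ElementaryMode]:
    """Run the full elimination with an optional candidate filter."""
    tableau = init_tableau(model, exact=exact)
    plan = _resolve_order(tableau, order)
    for _ in range(tableau.n_internal):
        col = _next_fewest(tableau) if plan == "fewest" else plan[len(tableau.processed)]
        process_metabolite(tableau, col, filter_fn)
    return extract_modes(tableau)


def enumerate_ems(model: MetabolicModel,
                  order: Sequence[int] | str | None = None,
                  exact: bool = False) -> list[ElementaryMode]:
    """Complete elementary-mode enumeration (identity filter)."""
    return run_tableau(model, filter_fn=None, order=order, exact=exact)
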