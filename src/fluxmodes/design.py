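"""Elementary-mode based strain design with MOMA rate prediction.

Given an EM set (full or sampled), a knockout strategy removes every mode
using a knocked reaction.  A good production strategy keeps at least one
biomass-viable mode, keeps many target-producing modes, and removes competing
(non-producing) modes.  The search maximises

    score(ko) = producing_survivors - lambda * non_producing_survivors

subject to >= 1 surviving biomass-viable mode, over knockout sets of at most
``max_ko`` internal reactions, exhaustively when the space is small and by
greedy forward selection otherwise.  Mutant production rates are then
estimated with MOMA: the flux vector closest (squared Euclidean distance) to
a wild-type reference that satisfies steady state, bounds and the knockouts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import MetabolicModel, internal_stoichiometry
from .modes import ZERO_TOL, ElementaryMode
from .preprocess import fba


@dataclass
class KnockoutStrategy:
    knocked_reactions: frozenset[str]
    surviving_ems: int
    producing_ems: int
    biomass_viable_ems: int
    score: float
    predicted_rate: float | None = None


def _indices(model_or_ids, ids: Sequence[str]) -> list[int]:
    if isinstance(model_or_ids, MetabolicModel):
        return [model_or_ids.reaction_index(r) for r in ids]
    index = {r: i for i, r in enumerate(model_or_ids)}
    out = []
    for r in ids:
        if r not in index:
            raise KeyError(f"unknown reaction id: {r!r}")
        out.append(index[r])
    return out


def apply_knockouts(ems: Sequence[ElementaryMode], ko: Sequence[str],
                    reaction_ids: Sequence[str]) -> list[ElementaryMode]:
    """Modes with nonzero flux through any knocked reaction are removed."""
    cols = _indices(list(reaction_ids), list(ko))
    if not cols:
        return list(ems)
    return [m for m in ems
            if not np.any(np.abs(m.coeffs[cols]) > ZERO_TOL)]


def production_counts(ems: Sequence[ElementaryMode], target_id: str,
                      biomass_id: str, reaction_ids: Sequence[str]
                      ) -> tuple[int, int, int]:
    """(total, target-producing, biomass-viable) mode counts."""
    t, b = _indices(list(reaction_ids), [target_id, biomass_id])
    producing = sum(1 for m in ems if abs(m.coeffs[t]) > ZERO_TOL)
    viable = sum(1 for m in ems if abs(m.coeffs[b]) > ZERO_TOL)
    return len(ems), producing, viable


def _score_counts(ems: Sequence[ElementaryMode], t: int, b: int,
                  lam: float) -> tuple[float, int, int, int]:
    producing = sum(1 for m in ems if abs(m.coeffs[t]) > ZERO_TOL)
    viable = sum(1 for m in ems if abs(m.coeffs[b]) > ZERO_TOL)
    score = producing - lam * (len(ems) - producing)
    return score, len(ems), producing, viable


def knockout_search(ems: Sequence[ElementaryMode], target_id: str,
                    biomass_id: str, reaction_ids: Sequence[str],
                    candidate_ids: Sequence[str],
                    max_ko: int = 8, lam: float = 1.0,
                    exhaustive_budget: int = 20000) -> KnockoutStrategy:
    """Best knockout set of size <= max_ko among ``candidate_ids``.

    Exhaustive over all subsets when their number fits the budget, otherwise
    greedy forward selection (best improvement, lexicographic tie-break).
    The target and biomass reactions are never knockout candidates.
    """
    reaction_ids = list(reaction_ids)
    t, b = _indices(reaction_ids, [target_id, biomass_id])
    candidates = sorted(set(candidate_ids) - {target_id, biomass_id})
    _indices(reaction_ids, candidates)  # validate ids

    base = _score_counts(ems, t, b, lam)
    if base[2] == 0 or base[3] == 0:
        raise ValueError("no biomass-viable producing mode in the input set")

    col_of = {r: reaction_ids.index(r) for r in candidates}

    def evaluate(ko: tuple[str, ...]):
        cols = [col_of[r] for r in ko]
        kept = [m for m in ems
                if not np.any(np.abs(m.coeffs[cols]) > ZERO_TOL)] \
            if cols else list(ems)
        return _score_counts(kept, t, b, lam)

    n_subsets = sum(math.comb(len(candidates), k)
                    for k in range(0, max_ko + 1))
    best_ko: tuple[str, ...] = ()
    best = base
    if n_subsets <= exhaustive_budget:
        for k in range(1, max_ko + 1):
            for ko in itertools.combinations(candidates, k):
                sc = evaluate(ko)
                if sc[3] >= 1 and sc[0] > best[0]:
                    best, best_ko = sc, ko
    else:
        current: tuple[str, ...] = ()
        while len(current) < max_ko:
            step_best, step_ko = None, None
            for r in candidates:
                if r in current:
                    continue
                ko = tuple(sorted(current + (r,)))
                sc = evaluate(ko)
                if sc[3] >= 1 and (step_best is None or sc[0] > step_best[0]):
                    step_best, step_ko = sc, ko
            if step_best is None or step_best[0] <= best[0]:
                break
            best, best_ko, current = step_best, step_ko, step_ko
    score, total, producing, viable = best
    return KnockoutStrategy(
        knocked_reactions=frozenset(best_ko),
        surviving_ems=total, producing_ems=producing,
        biomass_viable_ems=viable, score=score,
    )


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def moma_predict(model: MetabolicModel, wildtype_flux: np.ndarray,
                 ko: Sequence[str], target_id: str | None = None
                 ) -> tuple[np.ndarray, float | None]:
    """Minimize ||v - wildtype||^2 s.t. S_int v = 0, bounds, v[ko] = 0.

    Solved exactly by least squares on the nullspace of the constrained
    stoichiometry; if that minimiser violates a flux bound, an SLSQP solve
    with explicit bounds is used instead.  Returns the mutant flux vector and
    the flux through ``target_id`` (or None).
    """
    from scipy.linalg import null_space
    from scipy.optimize import minimize

    wt = np.asarray(wildtype_flux, dtype=float)
    n = model.n_reactions
    if wt.shape != (n,):
        raise ValueError("wildtype flux length does not match model")
    S_int = internal_stoichiometry(model)
    ko_cols = _indices(model, list(ko))
    bounds = model.effective_bounds()

    # equality system: steady state + knocked fluxes pinned to zero
    A = np.vstack([S_int] + [np.eye(n)[j][None, :] for j in ko_cols]) \
        if ko_cols else S_int
    N = null_space(A)
    if N.size == 0:
        v = np.zeros(n)
    else:
        z, *_ = np.linalg.lstsq(N, wt, rcond=None)
        v = N @ z
    tol = 1e-7
    if np.any(v < bounds[:, 0] - tol) or np.any(v > bounds[:, 1] + tol):
        lb, ub = bounds[:, 0].copy(), bounds[:, 1].copy()
        lb[ko_cols] = 0.0
        ub[ko_cols] = 0.0
        x0 = np.clip(wt, lb, ub)
        res = minimize(
            lambda x: float(np.sum((x - wt) ** 2)),
            x0,
            jac=lambda x: 2 * (x - wt),
            method="SLSQP",
            bounds=list(zip(lb, ub)),
            constraints=[{"type": "eq", "fun": lambda x: S_int @ x,
                          "jac": lambda x: S_int}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not res.success:
            raise RuntimeError(f"MOMA QP failed: {res.message}")
        v = res.x
    v = np.where(np.abs(v) <= ZERO_TOL, 0.0, v)
    rate = float(v[model.reaction_index(target_id)]) if target_id else None
    return v, rate


def wildtype_reference(model: MetabolicModel, biomass_id: str) -> np.ndarray:
    """FBA biomass-maximising flux used as the MOMA wild-type reference."""
    return fba(model, biomass_id, maximize=True)
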