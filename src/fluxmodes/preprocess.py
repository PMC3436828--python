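"""Model preprocessing: flux variability analysis and blocked-reaction removal.

Before enumerating or sampling elementary modes, reactions that can never
carry steady-state flux ("blocked" reactions) are detected by FVA — a pair of
LPs per reaction minimising/maximising its flux subject to the internal
steady-state constraint and the flux bounds — and removed, together with any
metabolite that no remaining reaction touches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError, internal_stoichiometry

#: Fluxes within this magnitude at both FVA extremes count as blocked.
BLOCKED_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """The steady-state LP has no feasible flux (inconsistent bounds)."""


@dataclass
class FvaResult:
    reaction_ids: list[str]
    min_flux: np.ndarray
    max_flux: np.ndarray
    blocked: np.ndarray  # bool per reaction

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            r: (float(lo), float(hi))
            for r, lo, hi in zip(self.reaction_ids, self.min_flux, self.max_flux)
        }


def _solve_lp(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleModelError(f"LP failed: {res.message}")
    return res


def fba(model: MetabolicModel, objective_id: str,
        maximize: bool = True) -> np.ndarray:
    """Flux balance analysis: optimise one reaction's flux; returns the flux
    vector of the optimum found by the LP solver."""
    S_int = internal_stoichiometry(model)
    n = model.n_reactions
    bounds = [tuple(b) for b in model.effective_bounds()]
    c = np.zeros(n)
    c[model.reaction_index(objective_id)] = -1.0 if maximize else 1.0
    res = _solve_lp(c, S_int, np.zeros(S_int.shape[0]), bounds)
    return res.x


def flux_variability(model: MetabolicModel,
                     objective_id: str | None = None,
                     fraction_of_optimum: float | None = None,
                     blocked_tol: float = BLOCKED_TOL) -> FvaResult:
    """Per-reaction flux ranges under steady state and bounds.

    When ``objective_id`` and ``fraction_of_optimum`` are given, the objective
    flux is additionally constrained to at least that fraction of its FBA
    optimum (classic FVA); by default no objective constraint is applied,
    which is the right setting for blocked-reaction detection.
    """
    S_int = internal_stoichiometry(model)
    n = model.n_reactions
    bounds = [tuple(b) for b in model.effective_bounds()]
    if objective_id is not None and fraction_of_optimum is not None:
        opt_flux = fba(model, objective_id)[model.reaction_index(objective_id)]
        j = model.reaction_index(objective_id)
        lo = fraction_of_optimum * opt_flux
        bounds[j] = (max(bounds[j][0], lo), bounds[j][1])

    b_eq = np.zeros(S_int.shape[0])
    vmin = np.empty(n)
    vmax = np.empty(n)
    c = np.zeros(n)
    for j in range(n):
        c[:] = 0.0
        c[j] = 1.0
        vmin[j] = _solve_lp(c, S_int, b_eq, bounds).x[j]
        c[j] = -1.0
        vmax[j] = _solve_lp(c, S_int, b_eq, bounds).x[j]
    blocked = np.maximum(np.abs(vmin), np.abs(vmax)) <= blocked_tol
    return FvaResult(list(model.reaction_ids), vmin, vmax, blocked)


def remove_blocked(model: MetabolicModel, fva: FvaResult) -> MetabolicModel:
    """Drop blocked reactions and orphaned metabolites."""
    if fva.reaction_ids != list(model.reaction_ids):
        raise ModelError("FVA result computed on a different model")
    keep_rxn = ~fva.blocked
    S = model.S[:, keep_rxn]
    keep_met = np.abs(S).sum(axis=1) > 0
    return MetabolicModel(
        metabolite_ids=[m for m, k in zip(model.metabolite_ids, keep_met) if k],
        internal=model.internal[keep_met],
        reaction_ids=[r for r, k in zip(model.reaction_ids, keep_rxn) if k],
        reversible=model.reversible[keep_rxn],
        S=S[keep_met, :],
        bounds=model.bounds[keep_rxn] if model.bounds is not None else None,
        name=model.name,
    )


def preprocess(model: MetabolicModel,
               objective_id: str | None = None,
               fraction_of_optimum: float | None = None
               ) -> tuple[MetabolicModel, FvaResult]:
    """FVA + blocked removal in one call; returns (reduced model, FVA)."""
    fva = flux_variability(model, objective_id, fraction_of_optimum)
    return remove_blocked(model, fva), fva
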