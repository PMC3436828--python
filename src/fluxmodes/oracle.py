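"""Brute-force elementary-mode oracle by exhaustive support enumeration.

Independent of the tableau algorithm: for every nonempty reaction subset the
restricted internal stoichiometry is examined; a subset is an EM support iff
its nullspace is one-dimensional, the spanning vector has no zero on the
subset, and the vector (or its negation) satisfies the irreversibility signs.
One-dimensionality makes support-minimality automatic: any steady-state
vector on a sub-support would also lie in that nullspace but with a smaller
support, contradicting full support of the spanning vector.

Exponential in the reaction count — guarded to small networks; used only to
cross-validate the tableau implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import null_space

from .model import MetabolicModel, internal_stoichiometry
from .modes import ZERO_TOL, ElementaryMode, dedupe_modes

MAX_ORACLE_REACTIONS = 15


def brute_force_ems(model: MetabolicModel,
                    max_reactions: int = MAX_ORACLE_REACTIONS
                    ) -> list[ElementaryMode]:
    n = model.n_reactions
    if n > max_reactions:
        raise ValueError(
            f"oracle limited to {max_reactions} reactions (model has {n})"
        )
    S_int = internal_stoichiometry(model)
    rev = model.reversible
    modes = []
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            sub = S_int[:, subset]
            ns = null_space(sub, rcond=1e-10)
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            v = v / np.abs(v).max()
            if np.any(np.abs(v) <= 1e-7):   # zero inside support: not this one
                continue
            irrev_local = ~rev[list(subset)]
            if np.all(v[irrev_local] >= -ZERO_TOL):
                pass
            elif np.all(v[irrev_local] <= ZERO_TOL):
                v = -v
            else:
                continue                    # sign-infeasible direction
            full = np.zeros(n)
            full[list(subset)] = v
            modes.append(
                ElementaryMode.from_vector(full, bool(rev[list(subset)].all()))
            )
    return dedupe_modes(modes)
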