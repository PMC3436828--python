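"""Elementary flux modes: container, normalization and elementarity check.

An elementary mode (EM) is a support-minimal steady-state flux vector that
respects the irreversibility of reactions.  Modes are stored normalized so
that the largest absolute coefficient is 1 and, for fully reversible modes,
the first nonzero coefficient is positive; this gives a canonical
representative for deduplication and comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import MetabolicModel, internal_stoichiometry

ZERO_TOL = 1e-9
RANK_RTOL = 1e-9
STEADY_TOL = 1e-6


def normalize_mode(coeffs: np.ndarray, reversible: bool = False) -> np.ndarray:
    """Scale so max |coefficient| is 1; orient reversible modes so the first
    nonzero coefficient is positive.  Raises on the zero vector."""
    v = np.asarray(coeffs, dtype=float).copy()
    v[np.abs(v) <= ZERO_TOL] = 0.0
    nz = np.flatnonzero(v)
    if nz.size == 0:
        raise ValueError("cannot normalize the zero vector")
    v /= np.abs(v).max()
    if reversible and v[nz[0]] < 0:
        v = -v
    v[np.abs(v) <= ZERO_TOL] = 0.0
    return v


def matrix_rank(A: np.ndarray, rtol: float = RANK_RTOL) -> int:
    """Rank from singular values with a relative tolerance."""
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    if s.size == 0 or s[0] <= ZERO_TOL:
        return 0
    return int(np.sum(s > rtol * s[0]))


@dataclass(frozen=True)
class ElementaryMode:
    """Normalized flux vector over the model's reactions."""

    coeffs: np.ndarray
    reversible: bool

    @classmethod
    def from_vector(cls, coeffs: Sequence[float],
                    reversible: bool) -> "ElementaryMode":
        return cls(normalize_mode(np.asarray(coeffs, float), reversible),
                   bool(reversible))

    @property
    def support(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.coeffs).tolist())

    def key(self, decimals: int = 9) -> tuple:
        """Hashable canonical key for deduplication."""
        nz = np.flatnonzero(self.coeffs)
        return tuple(
            (int(i), round(float(self.coeffs[i]), decimals)) for i in nz
        )

    def __eq__(self, other) -> bool:  # value semantics on the canonical form
        return isinstance(other, ElementaryMode) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __len__(self) -> int:
        return int(np.count_nonzero(self.coeffs))


def dedupe_modes(modes: Iterable[ElementaryMode]) -> list[ElementaryMode]:
    """Normalization-aware deduplication, order-preserving."""
    seen: dict[tuple, ElementaryMode] = {}
    for mode in modes:
        seen.setdefault(mode.key(), mode)
    return list(seen.values())


def verify_elementary(mode: ElementaryMode, model: MetabolicModel,
                      steady_tol: float = STEADY_TOL) -> bool:
    """True iff the mode balances all internal metabolites, respects
    irreversibility, and passes the rank test on its support:
    rank(S_int[:, support]) == |support| - 1."""
    v = mode.coeffs
    if v.shape != (model.n_reactions,):
        raise ValueError("mode dimension does not match model")
    S_int = internal_stoichiometry(model)
    if np.abs(S_int @ v).max(initial=0.0) > steady_tol:
        return False
    irrev = ~model.reversible
    if np.any(v[irrev] < -ZERO_TOL):
        return False
    support = sorted(mode.support)
    if not support:
        return False
    return matrix_rank(S_int[:, support]) == len(support) - 1


# ---------------------------------------------------------------------------
# TSV serialisation: one normalized mode per row, columns = reaction ids
# ---------------------------------------------------------------------------

def write_modes_tsv(modes: Sequence[ElementaryMode], model: MetabolicModel,
                    path: str | Path) -> None:
    lines = ["\t".join(model.reaction_ids)]
    for mode in modes:
        lines.append("\t".join(f"{c:.10g}" for c in mode.coeffs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_modes_tsv(path: str | Path,
                   model: MetabolicModel) -> list[ElementaryMode]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header != list(model.reaction_ids):
        raise ValueError("mode file header does not match model reactions")
    rev = model.reversible
    modes = []
    for line in lines[1:]:
        if not line.strip():
            continue
        v = np.array([float(x) for x in line.split("\t")])
        support = np.flatnonzero(np.abs(v) > ZERO_TOL)
        modes.append(
            ElementaryMode.from_vector(v, bool(rev[support].all()))
        )
    return modes
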