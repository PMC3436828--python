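"""Constraint-based metabolic model container and file I/O.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (metabolites
x reactions), per-metabolite internal/external flags, per-reaction
reversibility and optional flux bounds.  Elementary-mode computation balances
only the internal metabolites; external (boundary) metabolites are sources and
sinks of the network.

Two file formats are supported: SBML (read via libSBML; species with
``boundaryCondition=true`` or in a boundary compartment are external) and a
flat TSV dialect used for packaged fixtures::

    metabolite<TAB>A<TAB>internal
    metabolite<TAB>X<TAB>external
    reaction<TAB>R1<TAB>irreversible<TAB>-1 X 1 A
    reaction<TAB>R2<TAB>reversible<TAB>-1 A 1 B<TAB>-10<TAB>10

The optional trailing fields of a reaction row are the lower and upper flux
bound (mmol/gDW/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Default magnitude used when a file provides no flux bounds.
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for malformed or inconsistent model files."""


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites (rows of S) x reactions (columns)."""

    metabolite_ids: list[str]
    internal: np.ndarray          # bool per metabolite
    reaction_ids: list[str]
    reversible: np.ndarray        # bool per reaction
    S: np.ndarray                 # (m, n) stoichiometric coefficients
    bounds: np.ndarray | None = None   # (n, 2) lower/upper flux bounds
    name: str = ""
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.internal = np.asarray(self.internal, dtype=bool)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ModelError("id lists do not match S dimensions")
        if len(set(self.metabolite_ids)) != m:
            raise ModelError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n:
            raise ModelError("duplicate reaction ids")
        if self.internal.shape != (m,) or self.reversible.shape != (n,):
            raise ModelError("flag arrays do not match S dimensions")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)
            if self.bounds.shape != (n, 2):
                raise ModelError("bounds must be (n, 2)")
            bad = (~self.reversible) & (self.bounds[:, 0] < 0)
            if bad.any():
                raise ModelError(
                    "irreversible reactions with negative lower bound: "
                    + ", ".join(np.asarray(self.reaction_ids)[bad])
                )
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_internal(self) -> int:
        return int(self.internal.sum())

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id: {rxn_id!r}") from None

    def effective_bounds(self) -> np.ndarray:
        """Bounds for LP/QP use, filling defaults where the file had none."""
        if self.bounds is not None:
            return self.bounds.copy()
        lb = np.where(self.reversible, -DEFAULT_BOUND, 0.0)
        ub = np.full(self.n_reactions, DEFAULT_BOUND)
        return np.column_stack([lb, ub])

    def with_bounds(self, bounds: np.ndarray) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            internal=self.internal.copy(),
            reaction_ids=list(self.reaction_ids),
            reversible=self.reversible.copy(),
            S=self.S.copy(),
            bounds=np.asarray(bounds, dtype=float),
            name=self.name,
        )


def internal_stoichiometry(model: MetabolicModel) -> np.ndarray:
    """Submatrix of S over internal metabolites only (column order kept)."""
    if model.n_internal == 0:
        raise ModelError("model has no internal metabolites")
    return model.S[model.internal, :]


# ---------------------------------------------------------------------------
# flat TSV dialect
# ---------------------------------------------------------------------------

def _parse_terms(text: str, met_pos: dict[str, int], m: int) -> np.ndarray:
    col = np.zeros(m)
    tokens = text.split()
    if len(tokens) % 2:
        raise ModelError(f"odd token count in stoichiometry terms: {text!r}")
    for coef, met in zip(tokens[::2], tokens[1::2]):
        if met not in met_pos:
            raise ModelError(f"reaction references undeclared metabolite {met!r}")
        col[met_pos[met]] += float(coef)
    return col


def read_flat_model(path: str | Path) -> MetabolicModel:
    """Read the flat TSV model dialect (see module docstring)."""
    path = Path(path)
    met_ids: list[str] = []
    met_internal: list[bool] = []
    rxn_rows: list[tuple[str, bool, str, float | None, float | None]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0].lower()
        if kind == "metabolite":
            if len(fields) != 3:
                raise ModelError(f"{path}:{lineno}: metabolite row needs 3 fields")
            flag = fields[2].lower()
            if flag not in ("internal", "external"):
                raise ModelError(f"{path}:{lineno}: flag must be internal|external")
            met_ids.append(fields[1])
            met_internal.append(flag == "internal")
        elif kind == "reaction":
            if len(fields) not in (4, 6):
                raise ModelError(f"{path}:{lineno}: reaction row needs 4 or 6 fields")
            rev_txt = fields[2].lower()
            if rev_txt in ("reversible", "1", "true"):
                rev = True
            elif rev_txt in ("irreversible", "0", "false"):
                rev = False
            else:
                raise ModelError(f"{path}:{lineno}: bad reversibility {fields[2]!r}")
            lb = float(fields[4]) if len(fields) == 6 else None
            ub = float(fields[5]) if len(fields) == 6 else None
            rxn_rows.append((fields[1], rev, fields[3], lb, ub))
        else:
            raise ModelError(f"{path}:{lineno}: unknown row type {fields[0]!r}")
    if len(set(met_ids)) != len(met_ids):
        raise ModelError("duplicate metabolite ids")
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    m = len(met_ids)
    cols, rids, revs = [], [], []
    have_bounds = any(r[3] is not None for r in rxn_rows)
    bounds = []
    for rid, rev, terms, lb, ub in rxn_rows:
        rids.append(rid)
        revs.append(rev)
        cols.append(_parse_terms(terms, met_pos, m))
        if have_bounds:
            bounds.append(
                [lb if lb is not None else (-DEFAULT_BOUND if rev else 0.0),
                 ub if ub is not None else DEFAULT_BOUND]
            )
    if not cols:
        raise ModelError("model has no reactions")
    return MetabolicModel(
        metabolite_ids=met_ids,
        internal=np.array(met_internal),
        reaction_ids=rids,
        reversible=np.array(revs),
        S=np.column_stack(cols),
        bounds=np.array(bounds) if have_bounds else None,
        name=path.stem,
    )


def write_flat_model(model: MetabolicModel, path: str | Path) -> None:
    lines = []
    for mid, flag in zip(model.metabolite_ids, model.internal):
        lines.append(f"metabolite\t{mid}\t{'internal' if flag else 'external'}")
    for j, rid in enumerate(model.reaction_ids):
        terms = " ".join(
            f"{model.S[i, j]:g} {model.metabolite_ids[i]}"
            for i in range(model.n_metabolites)
            if model.S[i, j] != 0
        )
        row = [
            "reaction", rid,
            "reversible" if model.reversible[j] else "irreversible",
            terms,
        ]
        if model.bounds is not None:
            row += [f"{model.bounds[j, 0]:g}", f"{model.bounds[j, 1]:g}"]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml_model(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 2/3 file; boundary species are flagged external."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelError(f"libSBML failed to parse {path}: "
                         f"{doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"{path}: no model element")

    met_ids, met_internal = [], []
    for sp in sbml_model.getListOfSpecies():
        met_ids.append(sp.getId())
        met_internal.append(not sp.getBoundaryCondition())
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    m = len(met_ids)

    rids, revs, cols, bounds, have_bounds = [], [], [], [], False
    fbc = sbml_model.getPlugin("fbc")
    for rxn in sbml_model.getListOfReactions():
        rids.append(rxn.getId())
        revs.append(rxn.getReversible())
        col = np.zeros(m)
        for ref in rxn.getListOfReactants():
            sid = ref.getSpecies()
            if sid not in met_pos:
                raise ModelError(f"reaction {rxn.getId()} references unknown {sid}")
            col[met_pos[sid]] -= ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            sid = ref.getSpecies()
            if sid not in met_pos:
                raise ModelError(f"reaction {rxn.getId()} references unknown {sid}")
            col[met_pos[sid]] += ref.getStoichiometry()
        cols.append(col)
        lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        ub = DEFAULT_BOUND
        rplug = rxn.getPlugin("fbc")
        if rplug is not None and fbc is not None:
            lo = sbml_model.getParameter(rplug.getLowerFluxBound() or "")
            hi = sbml_model.getParameter(rplug.getUpperFluxBound() or "")
            if lo is not None and hi is not None:
                lb, ub, have_bounds = lo.getValue(), hi.getValue(), True
        bounds.append([lb, ub])
    if not cols:
        raise ModelError(f"{path}: model has no reactions")
    return MetabolicModel(
        metabolite_ids=met_ids,
        internal=np.array(met_internal),
        reaction_ids=rids,
        reversible=np.array(revs),
        S=np.column_stack(cols),
        bounds=np.clip(np.array(bounds), -DEFAULT_BOUND, DEFAULT_BOUND)
        if have_bounds else None,
        name=sbml_model.getId() or Path(path).stem,
    )


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML or flat TSV, sniffing the format if not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        head = path.read_text()[:200].lstrip()
        format = "sbml" if head.startswith("<?xml") or head.startswith("<sbml") \
            else "flat"
    if format == "sbml":
        return read_sbml_model(path)
    if format == "flat":
        return read_flat_model(path)
    raise ValueError(f"unknown format {format!r} (expected 'sbml' or 'flat')")
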