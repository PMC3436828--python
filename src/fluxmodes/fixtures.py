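"""Packaged toy networks and a seeded random-network generator.

The toy models ship as flat TSV files in ``fluxmodes/data`` so every other
module is testable without downloading any external reconstruction.  The
layered builders create symmetric multi-branch networks whose EM counts are
known in closed form by path counting, which gives enumerable fixtures of any
size for sampling statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model import MetabolicModel, read_flat_model
from .modes import ElementaryMode

TOY_NAMES = ("chain", "diamond", "rev_cycle", "deadend", "branched")


@dataclass
class FixtureSpec:
    name: str
    model: MetabolicModel
    expected_count: int | None = None
    expected_modes: list[ElementaryMode] | None = None


def _data_path(name: str):
    return resources.files("fluxmodes.data").joinpath(f"{name}.tsv")


def toy_network(name: str) -> FixtureSpec:
    """Load a packaged toy model with its expected elementary modes."""
    if name not in TOY_NAMES:
        raise ValueError(f"unknown toy network {name!r}; choose from {TOY_NAMES}")
    with resources.as_file(_data_path(name)) as path:
        model = read_flat_model(path)

    expected: list[ElementaryMode] | None = None
    if name == "chain":
        expected = [ElementaryMode.from_vector([1, 1], False)]
    elif name == "diamond":
        expected = [
            ElementaryMode.from_vector([1, 1, 0, 1], False),
            ElementaryMode.from_vector([1, 0, 1, 1], False),
        ]
    elif name == "rev_cycle":
        expected = [ElementaryMode.from_vector([1, 1], True)]
    elif name == "branched":
        from .oracle import brute_force_ems

        expected = brute_force_ems(model)
    elif name == "deadend":
        from .oracle import brute_force_ems

        expected = brute_force_ems(model)
    return FixtureSpec(name, model,
                       len(expected) if expected is not None else None,
                       expected)


def layered_network(widths: list[int], skips: bool = False,
                    name: str = "layered") -> FixtureSpec:
    """Linear cascade of metabolite pools with parallel isozyme branches.

    ``widths[i]`` parallel irreversible reactions convert pool i to pool i+1;
    an input drain feeds the first pool and an output drain empties the last.
    With ``skips`` a single extra reaction bridges pools i -> i+2 for every i,
    so pathway lengths vary.  The EM count is the number of source-to-sink
    paths, computed here by dynamic programming.
    """
    L = len(widths)
    if L < 1 or any(w < 1 for w in widths):
        raise ValueError("need at least one layer, widths >= 1")
    n_pools = L + 1
    met_ids = [f"M{i}" for i in range(n_pools)]
    cols, rids = [], []

    def col(src: int | None, dst: int | None) -> np.ndarray:
        c = np.zeros(n_pools)
        if src is not None:
            c[src] -= 1
        if dst is not None:
            c[dst] += 1
        return c

    rids.append("IN")
    cols.append(col(None, 0))
    for i, w in enumerate(widths):
        for b in range(w):
            rids.append(f"L{i}_{b}")
            cols.append(col(i, i + 1))
    n_skips = 0
    if skips:
        for i in range(L - 1):
            rids.append(f"SKIP{i}")
            cols.append(col(i, i + 2))
            n_skips += 1
    rids.append("OUT")
    cols.append(col(L, None))

    model = MetabolicModel(
        metabolite_ids=met_ids,
        internal=np.ones(n_pools, dtype=bool),
        reaction_ids=rids,
        reversible=np.zeros(len(rids), dtype=bool),
        S=np.column_stack(cols),
        name=name,
    )
    # path count by DP: ways[i] = number of paths from pool 0 to pool i
    ways = [0] * n_pools
    ways[0] = 1
    for i in range(1, n_pools):
        ways[i] = ways[i - 1] * widths[i - 1]
        if skips and i >= 2:
            ways[i] += ways[i - 2]
    return FixtureSpec(name, model, expected_count=ways[-1])


def layered_length_counts(widths: list[int],
                          skips: bool = False) -> dict[int, int]:
    """Exact pathway-length histogram of :func:`layered_network` by dynamic
    programming over source-to-sink paths (support size includes the two
    drains).  Closed-form companion to the generated fixture, independent of
    any EM algorithm."""
    L = len(widths)
    f: list[dict[int, int]] = [{} for _ in range(L + 1)]
    f[0] = {0: 1}
    for i in range(L + 1):
        for length, count in f[i].items():
            if i + 1 <= L:
                f[i + 1][length + 1] = f[i + 1].get(length + 1, 0) \
                    + count * widths[i]
            if skips and i + 2 <= L:
                f[i + 2][length + 1] = f[i + 2].get(length + 1, 0) + count
    return {length + 2: count for length, count in sorted(f[L].items())}


def random_network(m_internal: int, n_reactions: int,
                   rev_fraction: float = 0.0, seed: int = 0
                   ) -> MetabolicModel:
    """Seeded sparse random network: a spanning conversion chain through all
    internal metabolites plus random single-substrate conversions and drains.

    Requires ``n_reactions >= m_internal + 1`` so the chain with its input and
    output drains fits.  Dimensions calibrated so small instances stay within
    oracle-tractable EM counts.
    """
    if m_internal < 1:
        raise ValueError("need at least one internal metabolite")
    if not 0 <= rev_fraction <= 1:
        raise ValueError("rev_fraction must be in [0, 1]")
    if n_reactions < m_internal + 1:
        raise ValueError("need n_reactions >= m_internal + 1 for connectivity")
    rng = np.random.default_rng(seed)
    m = m_internal
    cols, rids = [], []

    def col(entries: dict[int, float]) -> np.ndarray:
        c = np.zeros(m)
        for i, x in entries.items():
            c[i] += x
        return c

    rids.append("IN0")
    cols.append(col({0: 1.0}))
    for i in range(m - 1):
        rids.append(f"C{i}")
        cols.append(col({i: -1.0, i + 1: 1.0}))
    rids.append(f"OUT{m - 1}")
    cols.append(col({m - 1: -1.0}))

    k = 0
    while len(rids) < n_reactions:
        src = int(rng.integers(m))
        kind = rng.random()
        coef = 2.0 if rng.random() < 0.2 else 1.0
        if kind < 0.2:                      # extra output drain
            rids.append(f"X{k}")
            cols.append(col({src: -coef}))
        elif kind < 0.35:                   # extra input drain
            rids.append(f"X{k}")
            cols.append(col({src: coef}))
        else:                               # internal conversion
            dst = int(rng.integers(m))
            if dst == src:
                dst = (src + 1) % m
            rids.append(f"X{k}")
            cols.append(col({src: -coef, dst: 1.0}))
        k += 1
    reversible = rng.random(n_reactions) < rev_fraction
    return MetabolicModel(
        metabolite_ids=[f"M{i}" for i in range(m)],
        internal=np.ones(m, dtype=bool),
        reaction_ids=rids,
        reversible=reversible,
        S=np.column_stack(cols),
        name=f"random_m{m}_n{n_reactions}_s{seed}",
    )
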