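"""Random sampling of elementary modes by per-iteration candidate filtering.

The tableau elimination grows combinatorially because each metabolite's batch
of new candidate rows feeds the next.  Sampling tempers this with a single
knob ``K``: after each metabolite is processed, every new candidate is kept
independently with probability

    P = min(1, K / N)

where ``N`` is the batch size, so the expected number of survivors is
``min(N, K)``.  Because every candidate in a batch gets the same probability,
the resulting sample carries no per-candidate selection bias; the survivors of
the full run are genuine elementary modes of the complete set (each still had
to pass the rank test).  Independent trials with distinct seeds are merged and
deduplicated into one larger sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import MetabolicModel
from .modes import ElementaryMode, dedupe_modes, verify_elementary
from .tableau import TableauRow, run_tableau


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling run parameters.

    K: expected upper bound on new candidates kept per elimination step
       (``math.inf`` disables filtering and yields complete enumeration).
    selection_mode: "binomial" keeps each candidate independently with
       probability P (expected batch size min(N, K)); "exact_size" draws
       exactly min(N, ceil(K)) survivors uniformly without replacement
       (hard cap reading of the bound).
    order: metabolite processing order passed to the tableau
       (None = input order, "fewest" = fewest-combinations-first).
    """

    K: float = math.inf
    seed: int = 0
    trials: int = 1
    selection_mode: str = "binomial"
    order: Sequence[int] | str | None = None

    def __post_init__(self):
        if not (self.K >= 1):
            raise ValueError("K must be >= 1 (or infinity)")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.selection_mode not in ("binomial", "exact_size"):
            raise ValueError("selection_mode must be 'binomial' or 'exact_size'")


@dataclass
class EMSample:
    """Deduplicated elementary modes with sampling provenance."""

    modes: list[ElementaryMode]
    config: SamplerConfig
    reaction_ids: list[str]
    trial_sizes: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modes)


def selection_probability(N: int, K: float) -> float:
    """P = min(1, K/N): uniform per-candidate probability giving an expected
    selection size of min(N, K)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if N < 0:
        raise ValueError("N must be >= 0")
    if N == 0 or math.isinf(K):
        return 1.0
    return min(1.0, K / N)


def filter_candidates(candidates: list, P: float,
                      rng: np.random.Generator,
                      selection_mode: str = "binomial",
                      K: float = math.inf) -> list:
    """Uniform random subselection of a candidate batch, order preserved."""
    if not (0 < P <= 1):
        raise ValueError("P must be in (0, 1]")
    N = len(candidates)
    if N == 0 or P == 1.0:
        return list(candidates)
    if selection_mode == "binomial":
        keep = rng.random(N) < P
        return [c for c, k in zip(candidates, keep) if k]
    if selection_mode == "exact_size":
        size = min(N, int(math.ceil(K)))
        idx = np.sort(rng.choice(N, size=size, replace=False))
        return [candidates[i] for i in idx]
    raise ValueError(f"unknown selection mode {selection_mode!r}")


def _make_filter(config: SamplerConfig, rng: np.random.Generator):
    if math.isinf(config.K):
        return None

    def filter_fn(batch: list[TableauRow]) -> list[TableauRow]:
        P = selection_probability(len(batch), config.K)
        return filter_candidates(batch, P, rng, config.selection_mode, config.K)

    return filter_fn


def sample_ems(model: MetabolicModel, config: SamplerConfig,
               verify: bool = True) -> EMSample:
    """Run ``config.trials`` independent filtered tableau runs and merge them.

    Trial t uses seed ``config.seed + t``.  Every mode in the merged sample is
    verified elementary against the full internal stoichiometry unless
    ``verify=False`` (the check is redundant with the per-step rank test and
    exists as a guarantee, not a correction).
    """
    all_modes: list[ElementaryMode] = []
    trial_sizes: list[int] = []
    seeds: list[int] = []
    for t in range(config.trials):
        seed = config.seed + t
        rng = np.random.default_rng(seed)
        modes = run_tableau(model, filter_fn=_make_filter(config, rng),
                            order=config.order)
        trial_sizes.append(len(modes))
        seeds.append(seed)
        all_modes.extend(modes)
    merged = dedupe_modes(all_modes)
    if verify:
        bad = [m for m in merged if not verify_elementary(m, model)]
        if bad:
            raise RuntimeError(
                f"{len(bad)} sampled modes failed the elementarity check"
            )
    return EMSample(modes=merged, config=config,
                    reaction_ids=list(model.reaction_ids),
                    trial_sizes=trial_sizes, seeds=seeds)


def merge_samples(samples: Sequence[EMSample]) -> EMSample:
    """Union of samples from the same model, deduplicated."""
    if not samples:
        raise ValueError("no samples to merge")
    ref = samples[0].reaction_ids
    for s in samples[1:]:
        if s.reaction_ids != ref:
            raise ValueError("samples come from models with different reactions")
    merged = dedupe_modes(m for s in samples for m in s.modes)
    return EMSample(
        modes=merged,
        config=samples[0].config,
        reaction_ids=list(ref),
        trial_sizes=[n for s in samples for n in s.trial_sizes],
        seeds=[x for s in samples for x in s.seeds],
    )
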