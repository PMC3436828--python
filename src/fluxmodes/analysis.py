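"""Sample-quality statistics for elementary-mode sets.

A representative EM sample should preserve structural properties of the full
set: the reaction participation profile (fraction of modes each reaction
carries flux in), the pathway length distribution (support sizes), and the
spread of modes in a phenotypic phase plane (per-mode flux ratios such as
oxygen uptake and growth, each normalized by substrate uptake).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .modes import ZERO_TOL, ElementaryMode
from .sampling import EMSample


@dataclass
class ParticipationProfile:
    """Per-reaction fraction of modes in which the reaction participates."""

    reaction_ids: list[str]
    fraction: np.ndarray
    n_modes: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.fraction, index=self.reaction_ids,
                         name="participation")


@dataclass(frozen=True)
class PhasePoint:
    """One mode's coordinates in the phase plane (ratios are scale-free)."""

    x: float       # |v_oxygen| / |v_substrate|
    y: float       # v_growth / |v_substrate|
    mode_index: int


def _mode_list(sample: EMSample | Sequence[ElementaryMode]
               ) -> list[ElementaryMode]:
    return list(sample.modes) if isinstance(sample, EMSample) else list(sample)


def reaction_participation(sample: EMSample | Sequence[ElementaryMode],
                           reaction_ids: Sequence[str] | None = None
                           ) -> ParticipationProfile:
    modes = _mode_list(sample)
    if not modes:
        raise ValueError("cannot compute participation of an empty sample")
    if reaction_ids is None:
        if not isinstance(sample, EMSample):
            raise ValueError("reaction_ids required for a bare mode list")
        reaction_ids = sample.reaction_ids
    counts = np.zeros(len(reaction_ids))
    for mode in modes:
        counts[np.abs(mode.coeffs) > ZERO_TOL] += 1
    return ParticipationProfile(list(reaction_ids), counts / len(modes),
                                len(modes))


def participation_correlation(p: ParticipationProfile,
                              q: ParticipationProfile) -> float:
    """Pearson r between two participation profiles over the same reactions."""
    if p.reaction_ids != q.reaction_ids:
        raise ValueError("profiles cover different reaction sets")
    if np.std(p.fraction) == 0 or np.std(q.fraction) == 0:
        raise ValueError("participation profile has zero variance")
    return float(stats.pearsonr(p.fraction, q.fraction).statistic)


def pathway_length_distribution(sample: EMSample | Sequence[ElementaryMode]
                                ) -> tuple[dict[int, int], int]:
    """Histogram of support sizes and the modal length (smallest on ties)."""
    modes = _mode_list(sample)
    if not modes:
        raise ValueError("empty sample")
    hist: dict[int, int] = {}
    for mode in modes:
        hist[len(mode)] = hist.get(len(mode), 0) + 1
    modal = min(sorted(hist), key=lambda L: (-hist[L], L))
    return dict(sorted(hist.items())), modal


def mean_pathway_length(sample: EMSample | Sequence[ElementaryMode]) -> float:
    modes = _mode_list(sample)
    return float(np.mean([len(m) for m in modes]))


def phase_plane(sample: EMSample,
                substrate_id: str, oxygen_id: str, growth_id: str
                ) -> tuple[list[PhasePoint], int]:
    """Per-mode (O2/substrate, growth/substrate) ratios.

    Modes with zero substrate flux have no defined coordinates and are
    skipped; their count is returned alongside the points.  Exchange fluxes
    are negative for uptake by convention, so magnitudes are used for the
    uptake terms.
    """
    idx = {r: i for i, r in enumerate(sample.reaction_ids)}
    for rid in (substrate_id, oxygen_id, growth_id):
        if rid not in idx:
            raise KeyError(f"unknown reaction id: {rid!r}")
    s, o, g = idx[substrate_id], idx[oxygen_id], idx[growth_id]
    points, skipped = [], 0
    for i, mode in enumerate(sample.modes):
        v_s = abs(mode.coeffs[s])
        if v_s <= ZERO_TOL:
            skipped += 1
            continue
        points.append(PhasePoint(x=float(abs(mode.coeffs[o]) / v_s),
                                 y=float(mode.coeffs[g] / v_s),
                                 mode_index=i))
    return points, skipped


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_participation_tsv(profile: ParticipationProfile,
                            path: str | Path) -> None:
    profile.as_series().rename_axis("reaction").to_csv(path, sep="\t")


def write_length_histogram_tsv(hist: dict[int, int], path: str | Path) -> None:
    pd.Series(hist, name="count").rename_axis("length").to_csv(path, sep="\t")


def write_phase_plane_tsv(points: Sequence[PhasePoint],
                          path: str | Path) -> None:
    pd.DataFrame(
        [(p.mode_index, p.x, p.y) for p in points],
        columns=["mode", "o2_per_substrate", "growth_per_substrate"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# optional plots (matplotlib)
# ---------------------------------------------------------------------------

def plot_participation_scatter(p: ParticipationProfile,
                               q: ParticipationProfile,
                               path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = participation_correlation(p, q)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(p.fraction, q.fraction, s=12, alpha=0.7)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("reference participation")
    ax.set_ylabel("sample participation")
    ax.set_title(f"r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_length_histogram(hist: dict[int, int], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(list(hist), list(hist.values()))
    ax.set_xlabel("pathway length (support size)")
    ax.set_ylabel("modes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phase_plane(points: Sequence[PhasePoint], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter([p.x for p in points], [p.y for p in points], s=10, alpha=0.6)
    ax.set_xlabel("O2 uptake / substrate uptake")
    ax.set_ylabel("growth / substrate uptake")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
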