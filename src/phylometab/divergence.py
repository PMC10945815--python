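"""Metabolome-divergence statistics and yield-profile comparison.

The central quantity is the **metabolome divergence** between two profiles
*a* and *b* over N metabolites,

    D(a, b) = (1/N) * sum_i (m_a,i - m_b,i)^2 ,

with m the log-scale, normalized metabolite levels. Between populations (or
species), D is averaged over all *cross* strain pairs — one strain from each
group; within-group pairs never enter. Dividing a population pair's
divergence by the patristic distance between the populations gives the
**phylogenetic-distance-adjusted divergence**, an empirical rate of
metabolome evolution per unit of sequence divergence.

Yield profiles (maximum theoretical production capacity per amino acid) are
compared with the same mean-squared-difference statistic; two profiles are
declared *identical* when their distance is strictly below 1e-3, absorbing
finite-precision noise in the yield calculations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import ProfileTable

__all__ = [
    "DistanceMatrix",
    "metabolome_divergence",
    "pairwise_divergence",
    "group_divergence",
    "phylo_adjusted_divergence",
    "yield_distance_and_identity",
    "wild_pairs",
    "same_clade_pairs",
    "distance_capped_pairs",
]


@dataclass
class DistanceMatrix:
    """Symmetric labeled matrix with a zero diagonal and a kind tag."""

    labels: list[str]
    values: np.ndarray
    kind: str = "divergence"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be nonnegative")

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "divergence") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col="label")
        return cls(list(frame.index), frame.to_numpy(dtype=float), kind)


def metabolome_divergence(profiles: ProfileTable, a: str, b: str) -> float:
    """Mean squared difference in log metabolite levels between two labels."""
    levels = profiles.levels
    for lab in (a, b):
        if lab not in levels.index:
            raise KeyError(f"label {lab!r} not in profile table")
    diff = levels.loc[a].to_numpy() - levels.loc[b].to_numpy()
    return float(np.mean(diff**2))


def pairwise_divergence(profiles: ProfileTable) -> DistanceMatrix:
    """All-pairs metabolome divergence at the table's own aggregation level."""
    X = profiles.levels.to_numpy(dtype=float)
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2) / X.shape[1]
    np.fill_diagonal(sq, 0.0)
    return DistanceMatrix(profiles.labels, sq, kind="metabolome_divergence")


def group_divergence(
    strain_profiles: ProfileTable, groups: Mapping[str, str]
) -> DistanceMatrix:
    """Between-group divergence as the mean over cross strain pairs.

    ``groups`` maps every strain label to its population (or species). Entry
    (P, Q) is the average of D(k, l) over all pairs with strain k in P and
    strain l in Q; within-group pairs are excluded, and the diagonal is 0.
    """
    labels = strain_profiles.labels
    missing = [s for s in labels if s not in groups]
    if missing:
        raise KeyError(f"strains without a group assignment: {missing}")
    group_names = sorted(set(groups[s] for s in labels))
    members: dict[str, list[int]] = {g: [] for g in group_names}
    for i, s in enumerate(labels):
        members[groups[s]].append(i)
    empty = [g for g, m in members.items() if not m]
    if empty:
        raise ValueError(f"groups with no member strains: {empty}")
    strain_D = pairwise_divergence(strain_profiles).values
    n = len(group_names)
    out = np.zeros((n, n))
    for gi in range(n):
        for gj in range(gi + 1, n):
            block = strain_D[np.ix_(members[group_names[gi]], members[group_names[gj]])]
            out[gi, gj] = out[gj, gi] = block.mean()
    return DistanceMatrix(group_names, out, kind="metabolome_divergence")


def phylo_adjusted_divergence(
    div: DistanceMatrix, patristic: DistanceMatrix
) -> DistanceMatrix:
    """Divide each pair's divergence by its patristic distance.

    Off-diagonal patristic distances must be positive; a zero distance
    between distinct labels means the rate is undefined for that pair.
    """
    if div.labels != patristic.labels:
        patristic = patristic.reorder(div.labels)
    n = len(div.labels)
    off = ~np.eye(n, dtype=bool)
    zero = off & (patristic.values <= 0)
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise ValueError(
            f"zero patristic distance between {div.labels[i]!r} and {div.labels[j]!r}"
        )
    out = np.zeros_like(div.values)
    out[off] = div.values[off] / patristic.values[off]
    return DistanceMatrix(div.labels, out, kind="phylo_adjusted_divergence")


def yield_distance_and_identity(
    yields: pd.DataFrame, threshold: float = 1e-3
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Mean-squared yield distance and the strict identity classification.

    ``yields`` is a label × amino-acid table of maximum theoretical yields.
    Two profiles are *identical* iff their distance is strictly lower than
    ``threshold`` (a distance exactly at the threshold counts as different).
    """
    if yields.isna().any().any():
        raise ValueError("yield table contains missing values")
    X = yields.to_numpy(dtype=float)
    labels = list(yields.index)
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2) / X.shape[1]
    np.fill_diagonal(sq, 0.0)
    dist = DistanceMatrix(labels, sq, kind="yield_distance")
    identical = pd.DataFrame(sq < threshold, index=labels, columns=labels)
    return dist, identical


# ---------------------------------------------------------------------------------
# pair filters (which population pairs enter a comparison)
# ---------------------------------------------------------------------------------


def wild_pairs(
    groups: Mapping[str, str], exclude: Sequence[str] = ()
) -> list[tuple[str, str]]:
    """All unordered pairs of wild populations, minus named exclusions.

    ``exclude`` removes populations whose closest relatives are domesticated
    and would blur the wild-only comparison.
    """
    wild = sorted(p for p, g in groups.items() if g == "wild" and p not in set(exclude))
    return list(combinations(wild, 2))


def same_clade_pairs(clades: Sequence[Sequence[str]]) -> list[tuple[str, str]]:
    """Pairs of domesticated populations drawn from within the same clade."""
    pairs: list[tuple[str, str]] = []
    for clade in clades:
        pairs.extend(combinations(sorted(clade), 2))
    return pairs


def distance_capped_pairs(
    pairs: Sequence[tuple[str, str]],
    patristic: DistanceMatrix,
    cap: float,
) -> list[tuple[str, str]]:
    """Keep only pairs whose patristic distance does not exceed ``cap``.

    Used to drop wild pairs that are phylogenetically more distant than any
    domesticated pair, so rate comparisons span comparable timescales.
    """
    return [p for p in pairs if patristic.loc(*p) <= cap]
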