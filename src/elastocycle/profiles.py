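"""Per-residue pseudoenergy trajectories and mechanically active regions.

A residue's trajectory is its pseudoenergy across the ordered cycle
conformations. The most variable residues (top decile of trajectory
variance by default) are clustered into regions: pairwise Pearson
correlations between trajectories are computed, and hierarchical clustering
on the Euclidean distances between correlation rows groups residues whose
energies rise and fall together. Group-level comparisons use rank tests
(Kruskal-Wallis omnibus, pairwise Mann-Whitney U with Bonferroni
correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kruskal, mannwhitneyu

logger = logging.getLogger(__name__)


def energy_trajectories(
    per_residue_energies: pd.DataFrame, cycle_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Residue-by-conformation energy matrix in cycle order.

    ``per_residue_energies`` has one row per residue and one column per
    cycle conformation (kBT). Missing values are an error (every residue in
    the ensemble is resolvable in every conformation by construction).
    """
    df = per_residue_energies.copy()
    if cycle_order is not None:
        missing_cols = set(cycle_order) - set(df.columns)
        if missing_cols:
            raise ValueError(f"missing cycle conformations: {sorted(missing_cols)}")
        df = df[list(cycle_order)]
    if df.shape[1] < 2:
        raise ValueError("a trajectory needs at least two cycle conformations")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing energy values for residues {bad[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError("pseudoenergies must be non-negative")
    return df


def trajectory_summary(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Mean, standard deviation, and variance of each residue trajectory."""
    return pd.DataFrame(
        {
            "mean": trajectories.mean(axis=1),
            "std": trajectories.std(axis=1, ddof=0),
            "variance": trajectories.var(axis=1, ddof=0),
        }
    )


def select_variable_residues(
    trajectories: pd.DataFrame, quantile: float = 0.90
) -> pd.DataFrame:
    """Residues whose trajectory variance reaches the given quantile.

    The threshold is the ``quantile`` of the variance distribution over all
    residues; residues at or above it are returned (ties at the threshold
    are all included).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    if len(trajectories) < 2:
        raise ValueError("need at least two residues to select from")
    variances = trajectories.var(axis=1, ddof=0)
    threshold = float(np.quantile(variances.to_numpy(), quantile))
    return trajectories.loc[variances >= threshold]


@dataclass
class RegionSet:
    """Disjoint groups of residues with correlated energy trajectories."""

    regions: dict[int, list]
    linkage: str
    n_regions: int
    dropped: list

    def membership(self) -> pd.Series:
        rows = {res: rid for rid, members in self.regions.items() for res in members}
        return pd.Series(rows, name="region")


def cluster_regions(
    trajectories: pd.DataFrame, n_regions: int = 4, linkage: str = "average"
) -> RegionSet:
    """Group selected residues into mechanically active regions.

    Pairwise Pearson correlations between trajectories are computed; rows of
    the correlation matrix are clustered hierarchically on their Euclidean
    distances and the tree is cut at ``n_regions`` clusters. Residues with a
    constant trajectory (undefined correlation) are dropped with a warning.
    Input rows are sorted lexicographically by residue key first so the
    result does not depend on input order.
    """
    df = trajectories.sort_index()
    constant = df.index[df.std(axis=1, ddof=0) == 0].tolist()
    if constant:
        logger.warning(
            "dropping %d residues with constant trajectories from clustering", len(constant)
        )
        df = df.drop(index=constant)
    if len(df) < n_regions:
        raise ValueError(
            f"need at least n_regions={n_regions} non-constant residues, have {len(df)}"
        )
    corr = np.corrcoef(df.to_numpy())
    distances = pdist(corr, metric="euclidean")
    Z = hierarchy.linkage(distances, method=linkage)
    cut = hierarchy.fcluster(Z, t=n_regions, criterion="maxclust")
    regions: dict[int, list] = {}
    for residue, cluster_id in zip(df.index, cut):
        regions.setdefault(int(cluster_id), []).append(residue)
    return RegionSet(regions=regions, linkage=linkage, n_regions=n_regions, dropped=constant)


def compare_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    """Rank-based group comparison with Bonferroni-corrected pairwise tests.

    Returns the Kruskal-Wallis omnibus statistic and p-value plus, for each
    pair of groups, the Mann-Whitney U statistic with raw and
    Bonferroni-corrected (two-sided) p-values.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = {k: np.asarray(v, float) for k, v in groups.items()}
    for name, values in samples.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    H, p_omnibus = kruskal(*samples.values())
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        U, p_raw = mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        pairwise.append(
            {
                "groups": (a, b),
                "U": float(U),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * m)),
            }
        )
    return {
        "omnibus": {"test": "kruskal-wallis", "H": float(H), "p": float(p_omnibus)},
        "pairwise": pairwise,
        "bonferroni_factor": m,
    }
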