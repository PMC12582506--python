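"""Cycle reconstruction from pairwise strain dissimilarities.

All conformation pairs are compared by mean strain (or total pseudoenergy),
giving an n x n dissimilarity matrix; metric multidimensional scaling embeds
it in two dimensions, and a cyclic order is read off as the polar angle
about the embedding centroid. Because stress-minimising MDS starts from
random configurations, many realisations are computed, rigidly aligned
(rotation/reflection/translation Procrustes) to the first, and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.stats import spearmanr
from sklearn.manifold import MDS

from .energy import ElasticParameters, default_parameters, pseudoenergy_field
from .io import ConformationEnsemble
from .strain import NeighborhoodMap, PairStrainEngine

METRICS = ("mean-eps3", "mean-neg-eps1", "total-pseudoenergy")


class DegenerateEmbeddingError(ValueError):
    """All embedded points coincide; no angular order exists."""


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # (n, n), zero diagonal, >= 0
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def symmetrized(self) -> np.ndarray:
        """Arithmetic-mean symmetrisation (strain is not exactly symmetric
        in the roles of deformed and reference)."""
        return 0.5 * (self.values + self.values.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def dissimilarity_matrix(
    ensemble: ConformationEnsemble,
    metric: str = "mean-eps3",
    neighborhoods: NeighborhoodMap | None = None,
    params: ElasticParameters | None = None,
    radius: float = 9.0,
) -> DissimilarityMatrix:
    """All-pairs dissimilarity over the ensemble's conformations.

    Entry (a, b) compares deformed=a against reference=b: the mean over
    shared atoms of eps3 ("mean-eps3"), of -eps1 ("mean-neg-eps1"), or the
    total elastic pseudoenergy ("total-pseudoenergy"). Diagonal is exactly
    zero.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    from .strain import build_neighborhoods

    if neighborhoods is None:
        neighborhoods = build_neighborhoods(ensemble, radius=radius, mode="intersect-all")
    engine = PairStrainEngine(ensemble, neighborhoods)
    labels = ensemble.labels
    n = len(labels)
    values = np.zeros((n, n))
    params = params or default_parameters()
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            if metric == "total-pseudoenergy":
                values[i, j] = pseudoenergy_field(
                    ensemble, a, b, neighborhoods, params, engine=engine
                ).total
            else:
                eps = np.linalg.eigvalsh(engine.strain_tensors(a, b))
                if metric == "mean-eps3":
                    values[i, j] = float(np.mean(eps[:, 2]))
                else:
                    values[i, j] = float(np.mean(-eps[:, 0]))
    return DissimilarityMatrix(labels=list(labels), values=values, metric=metric)


@dataclass
class Embedding:
    labels: list[str]
    coords: np.ndarray  # (n, 2) mean over aligned realisations
    realisations: np.ndarray  # (r, n, 2), aligned
    stresses: np.ndarray  # (r,)
    seed: int | None

    @property
    def n_realisations(self) -> int:
        return len(self.realisations)

    def to_frame(self) -> pd.DataFrame:
        spread = self.realisations.std(axis=0).mean(axis=1)
        return pd.DataFrame(
            {"label": self.labels, "x": self.coords[:, 0], "y": self.coords[:, 1], "spread": spread}
        )


def mds_embed(
    D: DissimilarityMatrix,
    n_realisations: int = 100,
    seed: int | None = None,
) -> Embedding:
    """Metric (SMACOF) MDS of a dissimilarity matrix into the plane.

    Runs ``n_realisations`` stress minimisations from random starts, aligns
    each to the first by centred orthogonal Procrustes (rotation and
    reflection), and averages. A master ``seed`` makes the whole set of
    realisations reproducible.
    """
    values = D.symmetrized()
    if not np.all(np.isfinite(values)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if n_realisations < 1:
        raise ValueError("need at least one realisation")
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_realisations)
    runs = []
    stresses = []
    for s in rng_seeds:
        mds = MDS(
            n_components=2,
            metric_mds=True,
            n_init=1,
            init="random",
            metric="precomputed",
            random_state=int(s % (2**32 - 1)),
            normalized_stress=False,
        )
        coords = mds.fit_transform(values)
        runs.append(coords - coords.mean(axis=0))
        stresses.append(mds.stress_)
    aligned = [runs[0]]
    for coords in runs[1:]:
        R, _ = orthogonal_procrustes(coords, runs[0])
        aligned.append(coords @ R)
    aligned_arr = np.array(aligned)
    return Embedding(
        labels=list(D.labels),
        coords=aligned_arr.mean(axis=0),
        realisations=aligned_arr,
        stresses=np.array(stresses),
        seed=seed,
    )


def cyclic_order(embedding: Embedding) -> list[str]:
    """Labels sorted by polar angle about the embedding centroid.

    Ties in angle break lexicographically by label. Raises
    :class:`DegenerateEmbeddingError` when all points coincide.
    """
    coords = embedding.coords - embedding.coords.mean(axis=0)
    radii = np.hypot(coords[:, 0], coords[:, 1])
    if np.max(radii) < 1e-12:
        raise DegenerateEmbeddingError("all embedded points coincide")
    angles = np.arctan2(coords[:, 1], coords[:, 0])
    order = sorted(range(len(angles)), key=lambda i: (angles[i], embedding.labels[i]))
    return [embedding.labels[i] for i in order]


def circular_agreement(order: Sequence[str], ground_truth: Sequence[str]) -> float:
    """Agreement between two cyclic orders of the same labels.

    The maximal Spearman rank correlation between the ground-truth sequence
    and the candidate over all rotations and both orientations; 1.0 means
    the cycles coincide up to rotation and reflection.
    """
    if set(order) != set(ground_truth) or len(order) != len(ground_truth):
        raise ValueError("orders must be permutations of the same labels")
    n = len(order)
    if n < 3:
        raise ValueError("need at least three labels for a cyclic order")
    truth_pos = {label: i for i, label in enumerate(ground_truth)}
    ranks = np.arange(n)
    best = -1.0
    for candidate in (list(order), list(reversed(order))):
        pos = np.array([truth_pos[label] for label in candidate])
        for shift in range(n):
            rho = spearmanr(ranks, (pos + shift) % n).statistic
            best = max(best, float(rho))
    return best
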