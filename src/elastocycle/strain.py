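"""Residue-scale finite-strain analysis between conformations.

For each atom i, the local deformation between a reference and a deformed
conformation is summarised by the deformation gradient F_i, the linear map
that best sends the reference displacement vectors to atom i's neighbours
onto the deformed ones (weighted least squares, solved in closed form by the
normal equations). From F the Lagrangian strain tensor

    E = (F^T F - I) / 2

is formed; E vanishes identically for any rigid motion, so the analysis
needs no structural superposition. Its eigenvalues, the principal strains
eps1 <= eps2 <= eps3, quantify local compression and extension along
orthogonal axes.

Neighbourhoods default to a 9 A radius with the "intersect-all" mode: the
neighbour list of an atom is the set of atoms within the radius in *every*
conformation of the ensemble, so all pairwise comparisons use identical
geometry supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import AtomKey, ConformationEnsemble

#: relative eigenvalue threshold below which a neighbour covariance is
#: treated as rank-deficient (collinear/coplanar neighbourhood)
_RANK_RTOL = 1e-9
#: required symmetry of a strain tensor
SYMMETRY_TOL = 1e-10

MIN_NEIGHBORS = 4


class UnderdeterminedNeighborhoodError(ValueError):
    """An atom has too few or geometrically degenerate neighbours."""


class SingularGeometryError(ValueError):
    """The neighbour covariance is rank-deficient; F cannot be estimated."""


@dataclass
class NeighborhoodMap:
    """Neighbour lists (indices into the ensemble's shared atoms)."""

    neighbors: list[np.ndarray]
    radius: float
    mode: str
    weights: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.neighbors)


def build_neighborhoods(
    ensemble: ConformationEnsemble,
    radius: float = 9.0,
    mode: str = "intersect-all",
    reference_label: str | None = None,
    weights: list[np.ndarray] | None = None,
) -> NeighborhoodMap:
    """Build neighbour lists over the ensemble's shared atoms.

    mode="intersect-all": an atom j is a neighbour of i only if it lies
    within ``radius`` of i in every conformation. mode="per-pair": within
    ``radius`` in the reference conformation only (``reference_label``,
    default the first).

    Raises :class:`UnderdeterminedNeighborhoodError` if any atom ends up
    with fewer than four neighbours or with neighbours that do not span 3-D
    space in some conformation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("intersect-all", "per-pair"):
        raise ValueError(f"unknown neighbourhood mode {mode!r}")

    if mode == "per-pair":
        source_labels = [reference_label or ensemble.labels[0]]
    else:
        source_labels = ensemble.labels

    pair_sets: list[set[tuple[int, int]]] = []
    for label in source_labels:
        tree = cKDTree(ensemble.coords(label))
        pair_sets.append(set(map(tuple, tree.query_pairs(radius, output_type="ndarray"))))
    common = set.intersection(*pair_sets)

    n = ensemble.n_atoms
    lists: list[list[int]] = [[] for _ in range(n)]
    for i, j in common:
        lists[i].append(j)
        lists[j].append(i)
    neighbors = [np.array(sorted(l), dtype=np.intp) for l in lists]

    for i, nb in enumerate(neighbors):
        if len(nb) < MIN_NEIGHBORS:
            raise UnderdeterminedNeighborhoodError(
                f"atom {ensemble.shared_keys[i]} has {len(nb)} neighbours "
                f"(need >= {MIN_NEIGHBORS}) at radius {radius} A"
            )

    # the neighbour cloud must span 3-D space in every conformation
    for label in ensemble.labels:
        xyz = ensemble.coords(label)
        for i, nb in enumerate(neighbors):
            d = xyz[nb] - xyz[i]
            cov = d.T @ d
            ev = np.linalg.eigvalsh(cov)
            if ev[0] <= _RANK_RTOL * max(ev[-1], 1.0):
                raise UnderdeterminedNeighborhoodError(
                    f"neighbourhood of atom {ensemble.shared_keys[i]} is "
                    f"rank-deficient in conformation {label!r}"
                )

    if weights is not None:
        if len(weights) != n:
            raise ValueError("one weight array per atom required")
        for i, (w, nb) in enumerate(zip(weights, neighbors)):
            w = np.asarray(w, float)
            if len(w) != len(nb) or np.any(w < 0):
                raise ValueError(f"invalid weights for atom {ensemble.shared_keys[i]}")
        weights = [np.asarray(w, float) for w in weights]

    return NeighborhoodMap(neighbors=neighbors, radius=radius, mode=mode, weights=weights)


def deformation_gradient(
    reference_coords: np.ndarray,
    deformed_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate F from one atom and its neighbours.

    Row 0 of each coordinate array is the centre atom i; the remaining rows
    are its neighbours. F minimises sum_j w_j ||dx_ij - F dX_ij||^2 and is
    obtained from the normal equations. Rank-deficient neighbour geometry
    raises :class:`SingularGeometryError` rather than being regularised.
    """
    ref = np.asarray(reference_coords, float)
    cur = np.asarray(deformed_coords, float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if ref.shape[0] < MIN_NEIGHBORS + 1:
        raise UnderdeterminedNeighborhoodError(
            f"need >= {MIN_NEIGHBORS} neighbours, got {ref.shape[0] - 1}"
        )
    dX = ref[1:] - ref[0]
    dx = cur[1:] - cur[0]
    if weights is None:
        w = np.ones(len(dX))
    else:
        w = np.asarray(weights, float)
        if w.shape != (len(dX),) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per neighbour")
    wdX = dX * w[:, None]
    M = dX.T @ wdX  # sum w dX dX^T
    C = dx.T @ wdX  # sum w dx dX^T
    ev = np.linalg.eigvalsh(M)
    if ev[0] <= _RANK_RTOL * max(ev[-1], 1.0):
        raise SingularGeometryError("neighbour covariance is rank-deficient")
    # F M = C  =>  F = C M^{-1}; M symmetric
    return np.linalg.solve(M, C.T).T


def lagrange_strain(F: np.ndarray) -> np.ndarray:
    """Lagrangian strain E = (F^T F - I)/2; exactly zero for rotations."""
    F = np.asarray(F, float)
    if F.shape != (3, 3) or not np.all(np.isfinite(F)):
        raise ValueError("F must be a finite 3x3 matrix")
    E = 0.5 * (F.T @ F - np.eye(3))
    return 0.5 * (E + E.T)  # numerical symmetrisation


def principal_strains(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose a strain tensor.

    Returns (eps, axes) with eps ascending (eps1 <= eps2 <= eps3) and axes
    the corresponding orthonormal eigenvectors as columns.
    """
    E = np.asarray(E, float)
    if E.shape != (3, 3):
        raise ValueError("E must be 3x3")
    if np.max(np.abs(E - E.T)) > SYMMETRY_TOL:
        raise ValueError("strain tensor is not symmetric within tolerance")
    eps, axes = np.linalg.eigh(0.5 * (E + E.T))
    return eps, axes


@dataclass
class StrainRecord:
    atom_key: AtomKey
    F: np.ndarray
    E: np.ndarray
    principal_strains: np.ndarray  # ascending (eps1, eps2, eps3)
    principal_axes: np.ndarray  # eigenvectors as columns


@dataclass
class StrainField:
    """Per-atom strain for one (deformed, reference) conformation pair."""

    deformed_label: str
    reference_label: str
    atom_keys: list[AtomKey]
    F: np.ndarray  # (n, 3, 3)
    E: np.ndarray  # (n, 3, 3)
    principal: np.ndarray  # (n, 3) ascending
    axes: np.ndarray  # (n, 3, 3)

    @property
    def mean_eps3(self) -> float:
        return float(np.mean(self.principal[:, 2]))

    @property
    def mean_neg_eps1(self) -> float:
        return float(np.mean(-self.principal[:, 0]))

    def records(self) -> Iterator[StrainRecord]:
        for i, key in enumerate(self.atom_keys):
            yield StrainRecord(key, self.F[i], self.E[i], self.principal[i], self.axes[i])

    def to_frame(self):
        import pandas as pd

        chains, resnums, icodes, names = zip(*self.atom_keys)
        return pd.DataFrame(
            {
                "chain_id": chains,
                "residue_index": resnums,
                "insertion_code": icodes,
                "atom_name": names,
                "eps1": self.principal[:, 0],
                "eps2": self.principal[:, 1],
                "eps3": self.principal[:, 2],
            }
        )


class PairStrainEngine:
    """Vectorised strain computation over all conformation pairs.

    Precomputes, per conformation, the flat neighbour-displacement arrays and
    the per-atom covariances sum_j w_j dX dX^T, so that each pairwise
    comparison reduces to one batched cross-covariance, one batched 3x3
    solve, and one batched symmetric eigen-decomposition.
    """

    def __init__(self, ensemble: ConformationEnsemble, neighborhoods: NeighborhoodMap):
        if len(neighborhoods) != ensemble.n_atoms:
            raise ValueError("neighbourhood map does not match the ensemble's shared atoms")
        self.ensemble = ensemble
        self.neighborhoods = neighborhoods
        counts = np.array([len(nb) for nb in neighborhoods.neighbors])
        self._offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self._nbr_idx = np.concatenate(neighborhoods.neighbors)
        self._center_idx = np.repeat(np.arange(ensemble.n_atoms), counts)
        if neighborhoods.weights is None:
            self._w = np.ones(len(self._nbr_idx))
        else:
            self._w = np.concatenate(neighborhoods.weights)
        self._disp: dict[str, np.ndarray] = {}
        self._cov: dict[str, np.ndarray] = {}

    def _displacements(self, label: str) -> np.ndarray:
        if label not in self._disp:
            xyz = self.ensemble.coords(label)
            self._disp[label] = xyz[self._nbr_idx] - xyz[self._center_idx]
        return self._disp[label]

    def _covariance(self, label: str) -> np.ndarray:
        """Per-atom (n,3,3) weighted covariance sum_j w dX dX^T."""
        if label not in self._cov:
            dX = self._displacements(label)
            wdX = dX * self._w[:, None]
            outer = dX[:, :, None] * wdX[:, None, :]
            M = np.add.reduceat(outer, self._offsets, axis=0)
            ev = np.linalg.eigvalsh(M)
            bad = ev[:, 0] <= _RANK_RTOL * np.maximum(ev[:, -1], 1.0)
            if np.any(bad):
                i = int(np.argmax(bad))
                raise SingularGeometryError(
                    f"rank-deficient neighbourhood at atom "
                    f"{self.ensemble.shared_keys[i]} in conformation {label!r}"
                )
            self._cov[label] = M
        return self._cov[label]

    def deformation_gradients(self, deformed_label: str, reference_label: str) -> np.ndarray:
        """All per-atom F for one pair, shape (n, 3, 3)."""
        dX = self._displacements(reference_label)
        dx = self._displacements(deformed_label)
        wdX = dX * self._w[:, None]
        cross = dx[:, :, None] * wdX[:, None, :]
        C = np.add.reduceat(cross, self._offsets, axis=0)  # (n,3,3) sum w dx dX^T
        M = self._covariance(reference_label)
        # F_i = C_i M_i^{-1}; M symmetric
        return np.linalg.solve(M, C.transpose(0, 2, 1)).transpose(0, 2, 1)

    def strain_tensors(self, deformed_label: str, reference_label: str) -> np.ndarray:
        F = self.deformation_gradients(deformed_label, reference_label)
        E = 0.5 * (np.einsum("nji,njk->nik", F, F) - np.eye(3))
        return 0.5 * (E + E.transpose(0, 2, 1))

    def field(self, deformed_label: str, reference_label: str) -> StrainField:
        F = self.deformation_gradients(deformed_label, reference_label)
        E = 0.5 * (np.einsum("nji,njk->nik", F, F) - np.eye(3))
        E = 0.5 * (E + E.transpose(0, 2, 1))
        eps, axes = np.linalg.eigh(E)
        return StrainField(
            deformed_label=deformed_label,
            reference_label=reference_label,
            atom_keys=list(self.ensemble.shared_keys),
            F=F,
            E=E,
            principal=eps,
            axes=axes,
        )


def strain_field(
    ensemble: ConformationEnsemble,
    deformed_label: str,
    reference_label: str,
    neighborhoods: NeighborhoodMap,
) -> StrainField:
    """Per-atom strain of ``deformed_label`` against ``reference_label``."""
    for label in (deformed_label, reference_label):
        if label not in ensemble.conformations:
            raise KeyError(f"no conformation labelled {label!r} in ensemble")
    return PairStrainEngine(ensemble, neighborhoods).field(deformed_label, reference_label)
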