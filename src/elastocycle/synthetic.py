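"""Synthetic ensembles and toy landscapes with known ground truth.

These generators provide the oracle layer for the analysis pipeline: atomic
point clouds deformed by known affine maps (whose strain is available in
closed form), planted conformational cycles with a known cyclic order, and
smooth single-barrier periodic landscapes for the kinetic model. Clouds are
labelled as poly-alanine backbones so residue-level aggregation runs on
realistic keys; no attempt is made to mimic real fold geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Conformation, ConformationEnsemble, build_ensemble
from .vdw import vdw_volume

FIXTURE_FORMAT_VERSION = "1"

_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))  # name, element


def _base_cloud(n_atoms: int, rng: np.random.Generator, density: float = 0.05) -> pd.DataFrame:
    """Compact uniform-ball cloud labelled as a poly-alanine backbone.

    The ball radius follows from ``density`` (atoms per A^3, default near
    protein heavy-atom packing) so neighbourhood counts stay stable across
    cloud sizes.
    """
    if n_atoms < 20:
        raise ValueError("need at least 20 atoms for a non-degenerate cloud")
    radius = (3.0 * n_atoms / (4.0 * np.pi * density)) ** (1.0 / 3.0)
    directions = rng.normal(size=(n_atoms, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.random(n_atoms) ** (1.0 / 3.0)
    coords = directions * radii[:, None]
    rows = []
    for i in range(n_atoms):
        name, element = _BACKBONE[i % 4]
        rows.append(
            (
                "A",
                i // 4 + 1,
                "",
                "ALA",
                name,
                element,
                coords[i, 0],
                coords[i, 1],
                coords[i, 2],
                vdw_volume(element),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chain_id",
            "residue_index",
            "insertion_code",
            "residue_name",
            "atom_name",
            "element",
            "x",
            "y",
            "z",
            "vdw_volume",
        ],
    )


def _apply_map(atoms: pd.DataFrame, linear: np.ndarray, offset: np.ndarray) -> pd.DataFrame:
    out = atoms.copy()
    xyz = atoms[["x", "y", "z"]].to_numpy(float) @ np.asarray(linear, float).T + offset
    out[["x", "y", "z"]] = xyz
    return out


def ground_truth_strain(linear: np.ndarray) -> np.ndarray:
    """Lagrangian strain of a global affine map: E = (A^T A - I)/2.

    Depends only on the stretch part of the map; any rotation factor drops
    out, which is what makes affine fixtures exact oracles.
    """
    A = np.asarray(linear, float)
    return 0.5 * (A.T @ A - np.eye(3))


@dataclass
class AffineFixture:
    ensemble: ConformationEnsemble
    maps: list[tuple[np.ndarray, np.ndarray]]  # (linear, offset) per conformation
    ground_truth: dict[str, np.ndarray]  # label -> uniform strain tensor
    seed: int

    def sidecar(self) -> dict:
        return {
            "format_version": FIXTURE_FORMAT_VERSION,
            "kind": "affine",
            "seed": self.seed,
            "ground_truth_strain": {k: v.tolist() for k, v in self.ground_truth.items()},
        }


def make_affine_ensemble(
    n_atoms: int,
    maps: Sequence[np.ndarray | tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    reference_label: str = "ref",
) -> AffineFixture:
    """Ensemble of affinely deformed copies of one random cloud.

    ``maps`` are 3x3 linear parts or (linear, offset) pairs; conformation k
    is map_k applied to the base cloud, whose untouched copy is included
    under ``reference_label``. The ground-truth strain of conformation k
    against the reference is (A_k^T A_k - I)/2 at every atom.
    """
    rng = np.random.default_rng(seed)
    base = _base_cloud(n_atoms, rng)
    normalised: list[tuple[np.ndarray, np.ndarray]] = []
    for m in maps:
        if isinstance(m, tuple):
            linear, offset = m
        else:
            linear, offset = m, np.zeros(3)
        linear = np.asarray(linear, float)
        if abs(np.linalg.det(linear)) < 1e-12:
            raise ValueError("affine linear part is singular")
        normalised.append((linear, np.asarray(offset, float)))

    conformations = [Conformation(label=reference_label, atoms=base)]
    truth = {}
    reference_map = {}
    for k, (linear, offset) in enumerate(normalised):
        label = f"def{k}"
        conformations.append(Conformation(label=label, atoms=_apply_map(base, linear, offset)))
        truth[label] = ground_truth_strain(linear)
        reference_map[label] = reference_label
    ensemble = build_ensemble(conformations, reference_labels=reference_map)
    return AffineFixture(ensemble=ensemble, maps=normalised, ground_truth=truth, seed=seed)


@dataclass
class PlantedCycleFixture:
    ensemble: ConformationEnsemble
    order: list[str]  # ground-truth cyclic order
    amplitude: float
    noise_sigma: float
    seed: int

    def sidecar(self) -> dict:
        return {
            "format_version": FIXTURE_FORMAT_VERSION,
            "kind": "planted-cycle",
            "seed": self.seed,
            "order": self.order,
            "amplitude": self.amplitude,
            "noise_sigma": self.noise_sigma,
        }


def make_cycle_ensemble(
    n: int = 30,
    amplitude: float = 0.1,
    noise_sigma: float = 0.0,
    n_atoms: int = 100,
    seed: int = 0,
) -> PlantedCycleFixture:
    """Planted conformational cycle of ``n`` deformed copies of one cloud.

    Conformation j is the base cloud under a uniaxial stretch of magnitude
    ``amplitude`` along a direction at angle pi*j/n in the xy plane (a
    stretch axis has period pi, so the schedule closes into a cycle over j =
    0..n-1), plus isotropic Gaussian coordinate noise of ``noise_sigma`` A.
    For small amplitudes the strain between conformations j and k grows like
    amplitude*sin(pi*d(j,k)/n) with d the cyclic label distance, so adjacent
    conformations are the least deformed relative to each other.
    """
    if n < 6:
        raise ValueError("a planted cycle needs at least 6 conformations")
    if noise_sigma < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    base = _base_cloud(n_atoms, rng)
    labels = [f"c{j:02d}" for j in range(n)]
    conformations = []
    for j, label in enumerate(labels):
        phi = np.pi * j / n
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        linear = np.eye(3) + amplitude * np.outer(u, u)
        atoms = _apply_map(base, linear, np.zeros(3))
        if noise_sigma > 0:
            atoms[["x", "y", "z"]] += rng.normal(scale=noise_sigma, size=(len(atoms), 3))
        conformations.append(Conformation(label=label, atoms=atoms))
    ensemble = build_ensemble(conformations, reference_labels={}, cycle_order=labels)
    return PlantedCycleFixture(
        ensemble=ensemble,
        order=labels,
        amplitude=amplitude,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_toy_landscape(
    n_states: int = 30,
    barrier_height: float = 6.0,
    barrier_position: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Smooth single-barrier periodic landscape, max - min = barrier_height.

    A raised-cosine bump peaking at ``barrier_position`` (default N//2):
    dE_el(s) = h/2 (1 + cos(2 pi (s - s0)/N)), mimicking a steady energy
    build-up and release around the cycle. Deterministic; ``seed`` is kept
    in the signature for fixture-manifest uniformity.
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    if barrier_height < 0:
        raise ValueError("barrier height must be non-negative")
    s0 = n_states // 2 if barrier_position is None else barrier_position % n_states
    s = np.arange(n_states)
    values = 0.5 * barrier_height * (1.0 + np.cos(2.0 * np.pi * (s - s0) / n_states))
    if n_states % 2 == 0:
        return values  # grid hits both extrema exactly
    # odd grids miss the cosine minimum; rescale to make max - min exact
    if barrier_height > 0:
        values = (values - values.min()) * (barrier_height / (values.max() - values.min()))
    return values


def write_fixture(fixture: AffineFixture | PlantedCycleFixture, out_dir: str | Path) -> None:
    """Emit the fixture as PDB files plus a JSON ground-truth sidecar."""
    from .io import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, conf in fixture.ensemble.conformations.items():
        write_pdb(conf, out / f"{label}.pdb")
    (out / "ground_truth.json").write_text(json.dumps(fixture.sidecar(), indent=2))
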