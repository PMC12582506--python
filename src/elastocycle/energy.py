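"""Saint Venant-Kirchhoff elastic pseudoenergy from strain fields.

The protein is treated as a homogeneous, isotropic hyperelastic material
with energy density

    Psi(E) = (lambda/2) tr(E)^2 + mu tr(E^2),

a strictly non-negative function of the Lagrangian strain E for admissible
Lame constants. The pseudoenergy attributed to atom i is

    dE_el,i = Psi(E_i) * v_i * phi,    phi = V / sum_j v_j,

where v_i is the atom's van der Waals volume, V the whole-molecule vdW
volume, and phi rescales the sum over the analysed atom subset (e.g.
backbone only) to whole-molecule extensivity. Energies are reported in kBT.

This is a *pseudo*energy: a deformation proxy under strong material
assumptions, not a free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AtomKey, ConformationEnsemble
from .strain import NeighborhoodMap, PairStrainEngine

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class ElasticParameters:
    """Isotropic Lame constants, in energy per cubic Angstrom.

    ``kBT`` is the thermal energy in the same energy unit as ``lam``/``mu``
    (so energies divide out to kBT). With lam/mu already expressed in
    kBT/A^3, use kBT=1.
    """

    lam: float
    mu: float
    kBT: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.lam < -2.0 / 3.0 * self.mu:
            raise ValueError("lambda < -(2/3) mu violates thermodynamic stability")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")


def lame_from_moduli(
    young_modulus: float, poisson_ratio: float, kBT: float = 1.0, note: str = ""
) -> ElasticParameters:
    """Lame constants from Young modulus and Poisson ratio.

    lambda = E nu / ((1+nu)(1-2 nu)),  mu = E / (2 (1+nu)).
    ``young_modulus`` must be in energy/A^3 (use
    :func:`pascal_to_energy_per_A3` for Pa).
    """
    if young_modulus <= 0:
        raise ValueError("Young modulus must be positive")
    if not -1.0 < poisson_ratio < 0.5:
        raise ValueError(
            "Poisson ratio must lie in (-1, 0.5); the incompressible limit 0.5 "
            "makes lambda diverge"
        )
    lam = young_modulus * poisson_ratio / ((1 + poisson_ratio) * (1 - 2 * poisson_ratio))
    mu = young_modulus / (2 * (1 + poisson_ratio))
    return ElasticParameters(lam=lam, mu=mu, kBT=kBT, note=note)


def pascal_to_energy_per_A3(value_pa: float) -> float:
    """Convert a modulus in Pa (J/m^3) to J/A^3."""
    return value_pa * 1e-30


def default_parameters(temperature: float = 298.15) -> ElasticParameters:
    """Young modulus 1 GPa, Poisson ratio 0.3, energies in kBT at ``temperature``.

    The 1 GPa default is a round number within the measured range for
    globular proteins; reported energies are calibration-sensitive and scale
    linearly with the modulus, so quantitative work should set constants
    deliberately.
    """
    kbt_joule = BOLTZMANN_J_PER_K * temperature
    young_kbt = pascal_to_energy_per_A3(1e9) / kbt_joule  # kBT / A^3
    return lame_from_moduli(
        young_kbt, 0.3, kBT=1.0, note=f"E=1 GPa, nu=0.3, T={temperature} K"
    )


def svk_density(E: np.ndarray, params: ElasticParameters) -> np.ndarray | float:
    """Saint Venant-Kirchhoff energy density Psi(E), elementwise over a batch.

    Accepts a single 3x3 tensor or an (n, 3, 3) batch; returns a float or an
    (n,) array, in the energy units of ``params`` per A^3.
    """
    E = np.asarray(E, float)
    single = E.ndim == 2
    batch = E[None] if single else E
    tr = np.trace(batch, axis1=-2, axis2=-1)
    tr_sq = np.einsum("nij,nji->n", batch, batch)
    psi = 0.5 * params.lam * tr**2 + params.mu * tr_sq
    return float(psi[0]) if single else psi


def volume_scale_factor(total_volume: float, selected_volumes: Sequence[float]) -> float:
    """phi = V / sum(v_j) over the atoms used in the analysis."""
    selected = np.asarray(selected_volumes, float)
    if selected.size == 0 or selected.sum() <= 0:
        raise ValueError("selected atom volumes are empty or sum to zero")
    return float(total_volume / selected.sum())


def atom_pseudoenergy(
    E: np.ndarray, params: ElasticParameters, vdw_volume: float, phi: float
) -> float:
    """dE_el = Psi(E) * v * phi, in kBT."""
    return float(svk_density(E, params)) * vdw_volume * phi / params.kBT


@dataclass
class PseudoenergyField:
    """Per-atom and per-residue pseudoenergy for one conformation pair."""

    deformed_label: str
    reference_label: str
    atom_keys: list[AtomKey]
    per_atom: np.ndarray  # kBT
    phi: float

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def to_frame(self) -> pd.DataFrame:
        chains, resnums, icodes, names = zip(*self.atom_keys)
        return pd.DataFrame(
            {
                "chain_id": chains,
                "residue_index": resnums,
                "insertion_code": icodes,
                "atom_name": names,
                "energy_kBT": self.per_atom,
            }
        )

    def per_residue(self, how: str = "sum") -> pd.Series:
        """Aggregate atom energies per residue (sum by default; energy is
        extensive). ``how="mean"`` gives the mean per atom instead."""
        df = self.to_frame()
        grouped = df.groupby(["chain_id", "residue_index", "insertion_code"])["energy_kBT"]
        if how == "sum":
            return grouped.sum()
        if how == "mean":
            return grouped.mean()
        raise ValueError("how must be 'sum' or 'mean'")


def pseudoenergy_field(
    ensemble: ConformationEnsemble,
    deformed_label: str,
    reference_label: str,
    neighborhoods: NeighborhoodMap,
    params: ElasticParameters | None = None,
    engine: PairStrainEngine | None = None,
) -> PseudoenergyField:
    """Pseudoenergy of ``deformed_label`` relative to ``reference_label``.

    phi is computed from the deformed conformation: its whole-molecule vdW
    volume over the summed volumes of the shared (analysed) atoms.
    """
    params = params or default_parameters()
    engine = engine or PairStrainEngine(ensemble, neighborhoods)
    E = engine.strain_tensors(deformed_label, reference_label)
    psi = svk_density(E, params)
    volumes = ensemble.shared_volumes(deformed_label)
    phi = volume_scale_factor(
        ensemble.conformation(deformed_label).total_vdw_volume, volumes
    )
    per_atom = psi * volumes * phi / params.kBT
    return PseudoenergyField(
        deformed_label=deformed_label,
        reference_label=reference_label,
        atom_keys=list(ensemble.shared_keys),
        per_atom=per_atom,
        phi=phi,
    )


@dataclass
class Landscape:
    """Total pseudoenergy per cycle conformation, in cycle order."""

    labels: list[str]
    totals: np.ndarray  # kBT

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, float)
        if len(self.labels) != len(self.totals):
            raise ValueError("labels and totals differ in length")

    @property
    def barrier_height(self) -> float:
        return float(self.totals.max() - self.totals.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "energy_kBT": self.totals})


def landscape(
    ensemble: ConformationEnsemble,
    params: ElasticParameters | None = None,
    neighborhoods: NeighborhoodMap | None = None,
    radius: float = 9.0,
) -> Landscape:
    """Pseudoenergy landscape over the ensemble's conformational cycle.

    Each cycle conformation is compared against its cognate reference from
    the ensemble's ``reference_map`` (e.g. F1, F2, ... against F0) and the
    per-atom energies are summed. Requires ``cycle_order`` to be set.
    """
    if ensemble.cycle_order is None:
        raise ValueError("ensemble has no cycle_order")
    from .strain import build_neighborhoods

    params = params or default_parameters()
    if neighborhoods is None:
        neighborhoods = build_neighborhoods(ensemble, radius=radius, mode="intersect-all")
    engine = PairStrainEngine(ensemble, neighborhoods)
    totals = []
    for label in ensemble.cycle_order:
        reference = ensemble.reference_map.get(label)
        if reference is None:
            raise ValueError(f"no reference cognate for cycle label {label!r}")
        field_ = pseudoenergy_field(
            ensemble, label, reference, neighborhoods, params, engine=engine
        )
        totals.append(field_.total)
    return Landscape(labels=list(ensemble.cycle_order), totals=np.array(totals))
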