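"""Structure input and ensemble construction.

Reads atomic models (PDB or mmCIF, via gemmi), applies an atom selection,
assigns van der Waals volumes, and assembles several conformations of the
same molecule into a :class:`ConformationEnsemble` with a shared atom
indexing. Residues that are not modelled in every conformation are excluded
from all conformations, so that every downstream pairwise comparison uses
exactly the same atoms.

Atom identity is the tuple ``(chain_id, residue_index, insertion_code,
atom_name)``; residues are never renumbered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .vdw import vdw_volume

logger = logging.getLogger(__name__)

#: atom-name sets for the supported selections
SELECTIONS = {
    "alpha-carbon": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
    "all-atom": None,  # all heavy atoms
}

#: molecule classes a chain may carry
MOLECULE_CLASSES = ("motor-subunit", "substrate", "nucleotide", "partner")

AtomKey = tuple[str, int, str, str]  # chain, residue number, icode, atom name
ResidueKey = tuple[str, int, str]

_ATOM_COLUMNS = [
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
]


class FormatError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """Selection matched no atoms."""


class IncompatibleEnsembleError(ValueError):
    """Conformations share no atoms after filtering."""


@dataclass
class Conformation:
    """Atoms of one conformation, after selection and volume assignment.

    ``total_vdw_volume`` is the summed volume of *all* heavy atoms present in
    the source model (before selection), i.e. the whole-molecule volume V
    entering the pseudoenergy scaling factor phi.
    """

    label: str
    atoms: pd.DataFrame
    chain_classes: dict[str, str] = field(default_factory=dict)
    total_vdw_volume: float = 0.0

    def __post_init__(self) -> None:
        coords = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in conformation {self.label!r}")
        keys = self.atom_keys()
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"duplicate (chain, residue, atom) keys in conformation {self.label!r}"
            )
        if self.total_vdw_volume == 0.0 and len(self.atoms):
            self.total_vdw_volume = float(self.atoms["vdw_volume"].sum())

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_keys(self) -> list[AtomKey]:
        return list(
            zip(
                self.atoms["chain_id"],
                self.atoms["residue_index"],
                self.atoms["insertion_code"],
                self.atoms["atom_name"],
            )
        )

    def residue_keys(self) -> list[ResidueKey]:
        return list(
            zip(
                self.atoms["chain_id"],
                self.atoms["residue_index"],
                self.atoms["insertion_code"],
            )
        )

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def subset(self, keys: Sequence[AtomKey]) -> "Conformation":
        """Return a copy restricted to ``keys``, in the order given."""
        index = {k: i for i, k in enumerate(self.atom_keys())}
        rows = [index[k] for k in keys]
        return Conformation(
            label=self.label,
            atoms=self.atoms.iloc[rows].reset_index(drop=True),
            chain_classes=dict(self.chain_classes),
            total_vdw_volume=self.total_vdw_volume,
        )


def load_conformation(
    path: str | Path,
    selection: str = "backbone",
    chain_class_map: Mapping[str, str] | None = None,
    label: str | None = None,
    radii_table: Mapping[str, float] | None = None,
    keep_hydrogens: bool = False,
) -> Conformation:
    """Read one structure file into a :class:`Conformation`.

    Hydrogens are dropped by default (cryo-EM and most crystallographic
    models lack them). For alternate locations only the blank or 'A' altloc
    is kept; others are dropped with a warning. Waters (HOH) are excluded.
    """
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; choose from {list(SELECTIONS)}")
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"{path} contains no models")

    wanted = SELECTIONS[selection]
    rows: list[tuple] = []
    total_volume = 0.0
    dropped_altloc = 0
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            icode = residue.seqid.icode.strip()
            for atom in residue:
                if atom.is_hydrogen() and not keep_hydrogens:
                    continue
                altloc = atom.altloc.strip("\x00").strip()
                if altloc not in ("", "A"):
                    dropped_altloc += 1
                    continue
                volume = vdw_volume(atom.element.name, dict(radii_table) if radii_table else None)
                total_volume += volume
                if wanted is not None and atom.name not in wanted:
                    continue
                rows.append(
                    (
                        chain.name,
                        residue.seqid.num,
                        icode,
                        residue.name,
                        atom.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        volume,
                    )
                )
    if dropped_altloc:
        logger.warning("%s: dropped %d alternate-location atoms", path.name, dropped_altloc)
    if not rows:
        raise EmptyStructureError(f"selection {selection!r} matched no atoms in {path}")
    atoms = pd.DataFrame(rows, columns=_ATOM_COLUMNS)

    if selection == "backbone":
        per_res = atoms.groupby(["chain_id", "residue_index", "insertion_code"]).size()
        partial = per_res[per_res < 4]
        if len(partial):
            logger.warning(
                "%s: %d residues have an incomplete backbone (kept with fewer atoms)",
                path.name,
                len(partial),
            )

    chains = atoms["chain_id"].unique()
    class_map = dict(chain_class_map or {})
    chain_classes = {c: class_map.get(c, "motor-subunit") for c in chains}
    return Conformation(
        label=label or path.stem,
        atoms=atoms,
        chain_classes=chain_classes,
        total_vdw_volume=total_volume,
    )


def assign_vdw_volumes(
    conformation: Conformation, radii_table: Mapping[str, float]
) -> Conformation:
    """Reassign atomic volumes from an alternative radii table."""
    table = dict(radii_table)
    volumes = [vdw_volume(e, table) for e in conformation.atoms["element"]]
    atoms = conformation.atoms.copy()
    atoms["vdw_volume"] = volumes
    return Conformation(
        label=conformation.label,
        atoms=atoms,
        chain_classes=dict(conformation.chain_classes),
        total_vdw_volume=float(sum(volumes)),
    )


def _parse_label(label: str) -> tuple[str, int] | None:
    """Split a label like 'F1' into position letter(s) and assembly index."""
    head = label.rstrip("0123456789")
    tail = label[len(head):]
    if head and tail:
        return head, int(tail)
    return None


@dataclass
class ConformationEnsemble:
    """Several conformations with a shared, consistently ordered atom set."""

    conformations: dict[str, Conformation]
    shared_keys: list[AtomKey]
    reference_map: dict[str, str]
    cycle_order: list[str] | None = None
    dropped_residues: list[ResidueKey] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.conformations)

    @property
    def n_atoms(self) -> int:
        return len(self.shared_keys)

    def conformation(self, label: str) -> Conformation:
        try:
            return self.conformations[label]
        except KeyError:
            raise KeyError(f"no conformation labelled {label!r} in ensemble") from None

    def coords(self, label: str) -> np.ndarray:
        """(n_shared, 3) coordinates of the shared atoms, in shared order."""
        conf = self.conformation(label)
        index = {k: i for i, k in enumerate(conf.atom_keys())}
        rows = [index[k] for k in self.shared_keys]
        return conf.coords()[rows]

    def shared_volumes(self, label: str) -> np.ndarray:
        conf = self.conformation(label)
        index = {k: i for i, k in enumerate(conf.atom_keys())}
        rows = [index[k] for k in self.shared_keys]
        return conf.atoms["vdw_volume"].to_numpy(float)[rows]

    def shared_residue_keys(self) -> list[ResidueKey]:
        return [(c, r, i) for (c, r, i, _a) in self.shared_keys]

    def manifest(self) -> dict:
        return {
            "labels": self.labels,
            "n_shared_atoms": self.n_atoms,
            "per_conformation_atoms": {l: len(c) for l, c in self.conformations.items()},
            "chains": {l: sorted(c.atoms["chain_id"].unique()) for l, c in self.conformations.items()},
            "chain_classes": {l: c.chain_classes for l, c in self.conformations.items()},
            "reference_map": self.reference_map,
            "cycle_order": self.cycle_order,
            "dropped_residues": [list(r) for r in self.dropped_residues],
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def build_ensemble(
    conformations: Iterable[Conformation],
    labels: Sequence[str] | None = None,
    reference_labels: Mapping[str, str] | None = None,
    cycle_order: Sequence[str] | None = None,
) -> ConformationEnsemble:
    """Assemble conformations into an ensemble with a shared atom set.

    A residue absent from any conformation is dropped from all of them, then
    the atom key sets are intersected, so every conformation resolves exactly
    the same atoms. When ``reference_labels`` is not given, a cognate map is
    derived from the labels: a label '<Position><k>' is referred to
    '<Position>0' when that label exists in the ensemble.
    """
    confs = list(conformations)
    if labels is not None:
        if len(labels) != len(confs):
            raise ValueError("labels and conformations differ in length")
        confs = [
            Conformation(l, c.atoms, dict(c.chain_classes), c.total_vdw_volume)
            for l, c in zip(labels, confs)
        ]
    if len(confs) < 2:
        raise ValueError("an ensemble needs at least two conformations")
    names = [c.label for c in confs]
    if len(set(names)) != len(names):
        raise ValueError(f"conformation labels are not unique: {names}")

    residue_sets = [set(c.residue_keys()) for c in confs]
    common_residues = set.intersection(*residue_sets)
    dropped = sorted(set.union(*residue_sets) - common_residues)
    if dropped:
        logger.warning("excluding %d residues not modelled in every conformation", len(dropped))

    key_sets = []
    for conf in confs:
        key_sets.append(
            {k for k in conf.atom_keys() if (k[0], k[1], k[2]) in common_residues}
        )
    shared = set.intersection(*key_sets)
    if not shared:
        raise IncompatibleEnsembleError("conformations share no atoms after filtering")
    shared_keys = sorted(shared)

    if reference_labels is not None:
        reference_map = dict(reference_labels)
    else:
        reference_map = {}
        for name in names:
            parsed = _parse_label(name)
            if parsed is None:
                continue
            position, index = parsed
            cognate = f"{position}0"
            if index != 0 and cognate in names:
                reference_map[name] = cognate
    for deformed, reference in reference_map.items():
        if deformed not in names or reference not in names:
            raise ValueError(f"reference_map entry {deformed!r}->{reference!r} not in ensemble")

    return ConformationEnsemble(
        conformations={c.label: c for c in confs},
        shared_keys=shared_keys,
        reference_map=reference_map,
        cycle_order=list(cycle_order) if cycle_order is not None else None,
        dropped_residues=dropped,
    )


def write_pdb(conformation: Conformation, path: str | Path) -> None:
    """Write a conformation to a PDB file (coordinates to 3 decimals)."""
    structure = gemmi.Structure()
    structure.name = conformation.label
    model = gemmi.Model("1")
    serial = 1
    for chain_id, chain_atoms in conformation.atoms.groupby("chain_id", sort=False):
        chain = gemmi.Chain(str(chain_id))
        res_groups = chain_atoms.groupby(
            ["residue_index", "insertion_code", "residue_name"], sort=False
        )
        for (res_num, icode, res_name), group in res_groups:
            residue = gemmi.Residue()
            residue.name = str(res_name)
            residue.seqid = gemmi.SeqId(int(res_num), icode if icode else " ")
            for row in group.itertuples():
                atom = gemmi.Atom()
                atom.name = row.atom_name
                atom.element = gemmi.Element(row.element)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.serial = serial
                serial += 1
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
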