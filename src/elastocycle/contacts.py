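"""Polar contacts and interface pseudoenergy.

A polar contact is a pair of nitrogen/oxygen heavy atoms from different
residues within 3.9 A; pairs within 3.5 A are graded "optimal", the rest
"suboptimal". No hydrogen geometry is used (the models carry none) and
donor/acceptor roles are not distinguished. Intra-residue pairs and the
covalent peptide-bond N(i+1)-O(i) pair are excluded.

A residue's pseudoenergy is split across the interfaces it participates in,
weighted by the fraction of its contacts made with each partner molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import SELECTIONS, AtomKey, Conformation, ResidueKey

logger = logging.getLogger(__name__)

PARTNER_CLASSES = (
    "cis",
    "trans-forward",
    "trans-backward",
    "substrate",
    "nucleotide",
    "partner-protein",
)

OPTIMAL_CUTOFF = 3.5
SUBOPTIMAL_CUTOFF = 3.9


@dataclass(frozen=True)
class Contact:
    atom_a: AtomKey
    atom_b: AtomKey
    distance: float
    grade: str  # "optimal" (<= 3.5 A) or "suboptimal" (<= 3.9 A)

    @property
    def residue_a(self) -> ResidueKey:
        return self.atom_a[:3]

    @property
    def residue_b(self) -> ResidueKey:
        return self.atom_b[:3]


def _is_peptide_bond(a: AtomKey, b: AtomKey) -> bool:
    """Backbone N(i+1)-O(i) of the peptide bond on the same chain."""
    for n_atom, o_atom in ((a, b), (b, a)):
        if (
            n_atom[3] == "N"
            and o_atom[3] == "O"
            and n_atom[0] == o_atom[0]
            and n_atom[2] == ""
            and o_atom[2] == ""
            and n_atom[1] == o_atom[1] + 1
        ):
            return True
    return False


def find_polar_contacts(
    conformation: Conformation,
    cutoffs: tuple[float, float] = (OPTIMAL_CUTOFF, SUBOPTIMAL_CUTOFF),
    polar_elements: Sequence[str] = ("N", "O"),
) -> list[Contact]:
    """All polar heavy-atom contacts in one conformation.

    Candidate pairs are atoms of ``polar_elements`` (add "S" to include
    sulfur) from different residues within the larger cutoff, graded by the
    smaller one. Returns contacts sorted by atom keys, each pair reported
    once with atom_a < atom_b.
    """
    optimal, suboptimal = cutoffs
    if not 0 < optimal <= suboptimal:
        raise ValueError("cutoffs must satisfy 0 < optimal <= suboptimal")
    atoms = conformation.atoms
    names = set(atoms["atom_name"].unique())
    if names <= set(SELECTIONS["backbone"]):
        logger.warning(
            "conformation %r appears backbone-only; sidechain polar contacts "
            "are unavailable",
            conformation.label,
        )
    polar = atoms[atoms["element"].str.upper().isin([e.upper() for e in polar_elements])]
    if polar.empty:
        return []
    keys = list(
        zip(polar["chain_id"], polar["residue_index"], polar["insertion_code"], polar["atom_name"])
    )
    xyz = polar[["x", "y", "z"]].to_numpy(float)
    tree = cKDTree(xyz)
    contacts = []
    for i, j in tree.query_pairs(suboptimal, output_type="ndarray"):
        a, b = keys[i], keys[j]
        if a[:3] == b[:3]:  # same residue
            continue
        if _is_peptide_bond(a, b):
            continue
        if b < a:
            a, b = b, a
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        grade = "optimal" if d <= optimal else "suboptimal"
        contacts.append(Contact(atom_a=a, atom_b=b, distance=d, grade=grade))
    return sorted(contacts, key=lambda c: (c.atom_a, c.atom_b))


def classify_partner(
    home_chain: str,
    partner_chain: str,
    chain_classes: Mapping[str, str],
    ring_order: Sequence[str] | None = None,
) -> str:
    """Class of a contact partner relative to a home motor chain.

    ``ring_order`` lists the motor chains around the ring in cycle
    orientation: the forward neighbour of ``ring_order[i]`` is
    ``ring_order[i-1]`` (e.g. order (A, B, C, D, E, F) puts A forward of B).
    Non-adjacent motor chains are labelled "motor-nonadjacent".
    """
    if partner_chain == home_chain:
        return "cis"
    try:
        partner_class = chain_classes[partner_chain]
    except KeyError:
        raise KeyError(f"chain {partner_chain!r} has no molecule class") from None
    if partner_class == "substrate":
        return "substrate"
    if partner_class == "nucleotide":
        return "nucleotide"
    if partner_class == "partner":
        return "partner-protein"
    if partner_class != "motor-subunit":
        raise ValueError(f"unknown molecule class {partner_class!r}")
    if ring_order is None or home_chain not in ring_order or partner_chain not in ring_order:
        raise ValueError(
            f"ring order needed to classify motor-motor contact {home_chain}-{partner_chain}"
        )
    n = len(ring_order)
    i = list(ring_order).index(home_chain)
    if partner_chain == ring_order[(i - 1) % n]:
        return "trans-forward"
    if partner_chain == ring_order[(i + 1) % n]:
        return "trans-backward"
    return "motor-nonadjacent"


@dataclass
class InterfaceEnergy:
    interface: str
    total: float  # kBT
    residue_weights: pd.DataFrame  # residue, weight, energy, contribution


def interface_pseudoenergy(
    contacts: Sequence[Contact],
    per_residue_energy: Mapping[ResidueKey, float],
    chain_classes: Mapping[str, str],
    ring_order: Sequence[str] | None = None,
    home_chains: Sequence[str] | None = None,
) -> dict[str, InterfaceEnergy]:
    """Split residue pseudoenergies across interfaces by contact fractions.

    For every residue of a home (motor) chain with at least one contact, its
    weight toward interface class I is (its contacts in class I) / (all its
    contacts); the interface total is the weighted sum of residue energies.
    Each residue's weights sum to one, so its full energy is distributed.
    """
    if home_chains is None:
        home_chains = [c for c, cls in chain_classes.items() if cls == "motor-subunit"]
    home = set(home_chains)

    counts: dict[ResidueKey, dict[str, int]] = {}
    for contact in contacts:
        for res, partner_res in (
            (contact.residue_a, contact.residue_b),
            (contact.residue_b, contact.residue_a),
        ):
            if res[0] not in home:
                continue
            partner_class = classify_partner(res[0], partner_res[0], chain_classes, ring_order)
            counts.setdefault(res, {})
            counts[res][partner_class] = counts[res].get(partner_class, 0) + 1

    rows: dict[str, list] = {}
    for res in sorted(counts):
        if res not in per_residue_energy:
            raise KeyError(f"no pseudoenergy value for contacting residue {res}")
        energy = float(per_residue_energy[res])
        total_contacts = sum(counts[res].values())
        for cls, n in sorted(counts[res].items()):
            weight = n / total_contacts
            rows.setdefault(cls, []).append(
                {
                    "residue": res,
                    "n_contacts": n,
                    "weight": weight,
                    "energy_kBT": energy,
                    "contribution_kBT": energy * weight,
                }
            )

    result = {}
    for cls, entries in rows.items():
        df = pd.DataFrame(entries)
        result[cls] = InterfaceEnergy(
            interface=cls, total=float(df["contribution_kBT"].sum()), residue_weights=df
        )
    return result
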