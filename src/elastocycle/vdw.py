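"""Van der Waals radii and atomic volumes.

Default radii are the Bondi set (Bondi 1964), in Angstrom. The table can be
overridden per call; entries cover the elements found in protein, nucleic
acid and common cofactor models. Volumes are the spheres v = (4/3) pi r^3,
used as the per-atom weight of the elastic pseudoenergy.
"""

from __future__ import annotations

import math

# Bondi (1964) van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "MG": 1.73,
    "ZN": 1.39,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,  # calcium ion (atom element, not the alpha-carbon name)
    "MN": 2.05,
    "FE": 2.04,
    "CU": 1.40,
    "NI": 1.63,
}


class UnknownElementError(KeyError):
    """Raised when an element has no entry in the radii table."""


def vdw_radius(element: str, radii_table: dict[str, float] | None = None) -> float:
    """Look up the van der Waals radius (A) of an element symbol."""
    table = BONDI_RADII if radii_table is None else radii_table
    key = element.strip().upper()
    try:
        return table[key]
    except KeyError:
        raise UnknownElementError(
            f"no van der Waals radius for element {element!r}"
        ) from None


def vdw_volume(element: str, radii_table: dict[str, float] | None = None) -> float:
    """Van der Waals sphere volume (A^3) of an element symbol."""
    r = vdw_radius(element, radii_table)
    return (4.0 / 3.0) * math.pi * r**3
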