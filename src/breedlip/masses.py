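"""Monoisotopic atomic masses and physical constants for accurate-mass work.

Values are IUPAC 2021 monoisotopic masses (most abundant isotope), in Da.
The electron mass matters at the ~0.5 mDa level for singly charged ions and
is therefore always applied when converting neutral masses to m/z.
"""

from __future__ import annotations

#: Monoisotopic mass of the most abundant isotope, Da (IUPAC 2021 / AME2020).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

#: Electron rest mass, Da (CODATA).
ELECTRON_MASS: float = 0.00054857990907

#: Mass difference between 13C and 12C, Da. One 13C isotopologue sits this
#: far above its monoisotopic parent.
C13_DELTA: float = 1.0033548
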