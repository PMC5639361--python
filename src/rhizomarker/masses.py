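"""Monoisotopic element masses and formula arithmetic.

The mass table covers the elements that occur in the bundled compound
library (CHNOPS plus the salt-adduct elements Na, K, Cl). Values are IUPAC
monoisotopic masses in Da.
"""

from __future__ import annotations

import re

from .errors import ValidationError

# monoisotopic masses, Da
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.968852682,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS  # 1.007276...
C13_C12_DELTA = 1.00336  # Da, one 13C substitution

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_to_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula like ``C9H9NO5``.

    Raises :class:`ValidationError` on unknown element symbols or a formula
    that does not parse cleanly.
    """
    if not formula or not formula.strip():
        raise ValidationError("empty elemental formula")
    formula = formula.strip()
    pos = 0
    mass = 0.0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        element, count = m.group(1), m.group(2)
        if element not in MONOISOTOPIC:
            raise ValidationError(
                f"unknown element {element!r} in formula {formula!r}; "
                f"supported: {', '.join(MONOISOTOPIC)}"
            )
        mass += MONOISOTOPIC[element] * (int(count) if count else 1)
    if pos != len(formula):
        raise ValidationError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return mass
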