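"""Monoisotopic peptide mass arithmetic and B/Y fragment ion m/z computation.

Modified sequences are encoded with bracketed delta masses, e.g.
``"M[+15.994915]PEPTIDEK"``. Cysteine carbamidomethylation is treated as a
fixed modification and is folded into the cysteine residue mass.
"""

from __future__ import annotations

import re
from typing import NamedTuple

PROTON = 1.00727646688
WATER = 18.010564684
NEUTRON = 1.00335483507  # C13 - C12 spacing used for isotope envelopes

CARBAMIDOMETHYL = 57.021464

#: Monoisotopic residue masses; C includes fixed carbamidomethylation.
RESIDUE_MASSES = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185 + CARBAMIDOMETHYL,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

_TOKEN_RE = re.compile(r"([A-Z])(\[[+-]?\d+(?:\.\d+)?\])?")


class FragmentAnnotation(NamedTuple):
    """Identity of a backbone fragment ion: ('B'|'Y', ordinal index, charge)."""

    ion_type: str
    index: int
    charge: int

    def __str__(self) -> str:  # e.g. "y5^2"
        return f"{self.ion_type.lower()}{self.index}^{self.charge}"


def tokenize(modseq: str) -> list[str]:
    """Split a modified sequence into residue tokens keeping mods attached.

    >>> tokenize("PM[+15.994915]K")
    ['P', 'M[+15.994915]', 'K']
    """
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(modseq):
        if m.start() != pos:
            raise ValueError(f"cannot parse modified sequence {modseq!r}")
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(modseq):
        raise ValueError(f"cannot parse modified sequence {modseq!r}")
    return tokens


def stripped_sequence(modseq: str) -> str:
    """Bare amino-acid sequence with modification brackets removed."""
    return "".join(t[0] for t in tokenize(modseq))


def residue_mass(token: str) -> float:
    aa = token[0]
    try:
        mass = RESIDUE_MASSES[aa]
    except KeyError:
        raise ValueError(f"unknown residue {aa!r}") from None
    if len(token) > 1:
        mass += float(token[2:-1])
    return mass


def peptide_mass(modseq: str) -> float:
    """Neutral monoisotopic mass of the (modified) peptide."""
    return sum(residue_mass(t) for t in tokenize(modseq)) + WATER


def precursor_mz(modseq: str, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(modseq) + charge * PROTON) / charge


def fragment_mz(modseq: str, annotation: FragmentAnnotation) -> float:
    """Theoretical m/z of a B- or Y-type fragment of the peptide."""
    tokens = tokenize(modseq)
    ion, idx, z = annotation
    if not 1 <= idx < len(tokens):
        raise ValueError(f"fragment index {idx} out of range for {modseq}")
    if ion == "B":
        neutral = sum(residue_mass(t) for t in tokens[:idx])
    elif ion == "Y":
        neutral = sum(residue_mass(t) for t in tokens[-idx:]) + WATER
    else:
        raise ValueError(f"unsupported ion type {ion!r}")
    return (neutral + z * PROTON) / z


def theoretical_fragments(
    modseq: str, precursor_charge: int, max_fragment_charge: int | None = None
) -> list[tuple[FragmentAnnotation, float]]:
    """All B/Y fragment ions considered for a peptide.

    +1 fragments always; +2 fragments only when the precursor charge exceeds
    +2. A-type ions and water/ammonia losses are never generated.
    """
    if max_fragment_charge is None:
        max_fragment_charge = 2 if precursor_charge > 2 else 1
    tokens = tokenize(modseq)
    out = []
    for idx in range(1, len(tokens)):
        for ion in ("B", "Y"):
            for z in range(1, max_fragment_charge + 1):
                ann = FragmentAnnotation(ion, idx, z)
                out.append((ann, fragment_mz(modseq, ann)))
    return out


def averagine_isotopes(neutral_mass: float, n: int = 4) -> list[float]:
    """Approximate relative isotope abundances of an average peptide.

    Poisson model with rate proportional to mass; adequate for envelope
    dot-product features, not for fine structure.
    """
    import math

    lam = 4.43e-4 * neutral_mass
    raw = [math.exp(-lam) * lam**k / math.factorial(k) for k in range(n)]
    total = sum(raw)
    return [r / total for r in raw]


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6
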