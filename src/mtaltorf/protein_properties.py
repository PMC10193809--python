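"""Peptide length and molecular-mass computation.

Masses are for unmodified, neutral peptides: the sum of residue masses plus
one water.  Average residue masses are derived in-code from residue
elemental compositions and the 2009 IUPAC standard atomic weights — the
convention used by ExPASy's Compute pI/MW and by peptide-synthesis vendors,
which reproduces vendor-quoted molecular weights to 0.01 Da.  Monoisotopic
masses use CODATA/AME most-abundant-isotope masses (the MS search
convention).  No PTMs, isotope envelopes, or charge states.
"""

from __future__ import annotations

from dataclasses import dataclass

# residue (= amino acid minus water) elemental compositions, CHNOS order
_RESIDUE_COMPOSITION: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

# 2009 IUPAC standard atomic weights (ExPASy convention)
_AVG_ATOM = {"C": 12.0107, "H": 1.00794, "N": 14.0067, "O": 15.9994, "S": 32.065}
# most-abundant-isotope masses
_MONO_ATOM = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def _mass_of(comp: tuple[int, int, int, int, int], atoms: dict[str, float]) -> float:
    return sum(n * atoms[el] for n, el in zip(comp, "CHNOS"))


AVERAGE_RESIDUE_MASS = {
    aa: _mass_of(c, _AVG_ATOM) for aa, c in _RESIDUE_COMPOSITION.items()
}
MONOISOTOPIC_RESIDUE_MASS = {
    aa: _mass_of(c, _MONO_ATOM) for aa, c in _RESIDUE_COMPOSITION.items()
}
WATER_AVERAGE = _mass_of((0, 2, 0, 1, 0), _AVG_ATOM)  # 18.01528
WATER_MONOISOTOPIC = _mass_of((0, 2, 0, 1, 0), _MONO_ATOM)  # 18.0105646


@dataclass(frozen=True)
class PeptideProfile:
    aa_sequence: str
    aa_length: int
    average_mass: float
    monoisotopic_mass: float
    mass_kda_1dp: float


def _check_sequence(aa: str) -> None:
    for i, ch in enumerate(aa):
        if ch not in _RESIDUE_COMPOSITION:
            raise ValueError(
                f"nonstandard residue {ch!r} at position {i + 1}; "
                "only the 20 standard one-letter codes are supported"
            )
    if not aa:
        raise ValueError("empty peptide")


def average_mass(aa: str) -> float:
    """Neutral average mass in Da (residue masses + one water)."""
    _check_sequence(aa)
    return sum(AVERAGE_RESIDUE_MASS[c] for c in aa) + WATER_AVERAGE


def monoisotopic_mass(aa: str) -> float:
    """Neutral monoisotopic mass in Da."""
    _check_sequence(aa)
    return sum(MONOISOTOPIC_RESIDUE_MASS[c] for c in aa) + WATER_MONOISOTOPIC


def peptide_profile(aa: str) -> PeptideProfile:
    avg = average_mass(aa)
    return PeptideProfile(
        aa_sequence=aa,
        aa_length=len(aa),
        average_mass=avg,
        monoisotopic_mass=monoisotopic_mass(aa),
        mass_kda_1dp=round(avg / 1000.0, 1),
    )
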