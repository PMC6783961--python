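"""Elemental masses and residue compositions for protein average/monoisotopic mass.

Average masses use the IUPAC 2021 standard atomic weights (abridged), frozen
here so that every theoretical subunit mass in the package is bit-reproducible.
At the 23-26 kDa subunit level the deconvolved quantity is the isotope-averaged
mass, so the average scale is the matching currency throughout; monoisotopic
values are kept for cross-checks.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping

# IUPAC 2021 standard atomic weights (abridged to the precision the tables print).
AVERAGE_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

# Monoisotopic masses of the principal isotopes (CODATA/AME).
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of a proton, Da, used for ESI charge-state arithmetic.
PROTON_MASS = 1.00728

# Residue (dehydrated) elemental compositions of the 20 canonical amino acids.
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

CANONICAL_RESIDUES = frozenset(RESIDUE_FORMULAS)

WATER: dict[str, int] = {"H": 2, "O": 1}
AMMONIA: dict[str, int] = {"N": 1, "H": 3}
OXYGEN: dict[str, int] = {"O": 1}

# Monosaccharide residue (anhydro) compositions for N-glycan mass deltas.
MONOSACCHARIDE_FORMULAS: dict[str, dict[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "Fuc": {"C": 6, "H": 10, "O": 4},
}


def combine(*formulas: Mapping[str, int], scale: int = 1) -> dict[str, int]:
    """Sum elemental formulas (each atom count multiplied by ``scale``)."""
    total: Counter[str] = Counter()
    for f in formulas:
        for el, n in f.items():
            total[el] += n * scale
    return {el: n for el, n in total.items() if n != 0}


def formula_mass(formula: Mapping[str, int], *, average: bool = True) -> float:
    """Mass of an elemental formula in Da (average or monoisotopic scale)."""
    table = AVERAGE_WEIGHTS if average else MONOISOTOPIC_MASSES
    try:
        return sum(table[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guards table typos
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


def peptide_formula(sequence: str) -> dict[str, int]:
    """Elemental composition of a free peptide chain (residues + one water)."""
    counts: Counter[str] = Counter(WATER)
    for pos, aa in enumerate(sequence, start=1):
        try:
            residue = RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(
                f"invalid residue {aa!r} at position {pos}: not one of the "
                "20 canonical amino acids"
            ) from None
        for el, n in residue.items():
            counts[el] += n
    return dict(counts)


def peptide_mass(sequence: str, *, average: bool = True) -> float:
    """Neutral mass of an unmodified peptide chain."""
    return formula_mass(peptide_formula(sequence), average=average)
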