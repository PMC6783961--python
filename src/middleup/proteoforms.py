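"""Proteoform mass library: modification deltas, enumeration, ppm matching.

A proteoform is a subunit chain plus a modification state — N-glycan (G0F or
G1F on Fc/2), n oxidation events (+O each), N-terminal pyroglutamate (−NH3
from Gln, −H2O from Glu) and an additional C-terminal lysine on Fc/2. All
deltas are computed from elemental / monosaccharide compositions rather than
hard-coded, so an independent composition oracle can verify them.

Matching of deconvoluted zero-charge masses against the library uses a ±70 ppm
window on the average-mass scale; each accepted match additionally carries the
star notation grading the absolute mass error (|Δ| ≤ 0.5 Da = "*",
0.5–1.5 Da = "**", 1.5–4.0 Da = "***", above 4 Da rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import chem
from .mab_model import SubunitChain

GLYCAN_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G0F": {"HexNAc": 4, "Hex": 3, "Fuc": 1},
    "G1F": {"HexNAc": 4, "Hex": 4, "Fuc": 1},
}

#: star-notation bands on |observed - theoretical| in Da
STAR_BANDS: tuple[tuple[float, str], ...] = ((0.5, "*"), (1.5, "**"), (4.0, "***"))
REJECTED = "rejected"

DEFAULT_MATCH_TOL_PPM = 70.0
DEFAULT_UNSPECIFIC_OX_CAP = 4


@dataclass(frozen=True)
class ModificationState:
    """Modification state of one subunit proteoform."""

    glycan: str | None = None
    n_ox: int = 0
    pyroglu: bool = False
    cterm_lys: bool = False

    def __post_init__(self) -> None:
        if self.glycan is not None and self.glycan not in GLYCAN_COMPOSITIONS:
            raise ValueError(f"unknown glycan {self.glycan!r}")
        if self.n_ox < 0:
            raise ValueError("n_ox must be >= 0")

    def suffix(self) -> str:
        parts = []
        if self.glycan:
            parts.append(self.glycan)
        if self.cterm_lys:
            parts.append("+ K")
        if self.pyroglu:
            parts.append("pG")
        if self.n_ox:
            parts.append(f"{self.n_ox} Ox")
        return " ".join(parts)


@dataclass(frozen=True)
class Proteoform:
    """A subunit + modification state with its theoretical masses (Da)."""

    subunit_kind: str
    mods: ModificationState
    avg_mass: float
    mono_mass: float
    display_name: str


@dataclass(frozen=True)
class Assignment:
    """An observed deconvoluted mass matched to a library proteoform."""

    proteoform: Proteoform
    observed_mass: float
    delta_da: float      # observed - theoretical, signed
    delta_ppm: float
    stars: str
    abundance: float = 0.0


def glycan_delta(name: str, *, average: bool = True) -> float:
    """Mass added by an N-glycan, from its monosaccharide residue composition."""
    comp = GLYCAN_COMPOSITIONS[name]
    return sum(
        chem.formula_mass(chem.MONOSACCHARIDE_FORMULAS[sugar], average=average) * n
        for sugar, n in comp.items()
    )


def modification_delta(
    mod_kind: str, *, nterm: str | None = None, average: bool = True
) -> float:
    """Mass delta (Da) of a single modification event.

    ``mod_kind`` is one of ``"ox"``, ``"pyroglu"``, ``"cterm_lys"``, ``"G0F"``,
    ``"G1F"``. Pyroglutamate needs the chain's N-terminal residue (``nterm``):
    Gln cyclization loses NH3, Glu cyclization loses H2O.
    """
    if mod_kind == "ox":
        return chem.formula_mass(chem.OXYGEN, average=average)
    if mod_kind == "pyroglu":
        if nterm == "Q":
            return -chem.formula_mass(chem.AMMONIA, average=average)
        if nterm == "E":
            return -chem.formula_mass(chem.WATER, average=average)
        raise ValueError(
            "pyroglutamate requires an N-terminal Q or E, got "
            f"{nterm!r}"
        )
    if mod_kind == "cterm_lys":
        return chem.formula_mass(chem.RESIDUE_FORMULAS["K"], average=average)
    if mod_kind in GLYCAN_COMPOSITIONS:
        return glycan_delta(mod_kind, average=average)
    raise ValueError(f"unknown modification kind {mod_kind!r}")


def _mods_delta(mods: ModificationState, nterm: str, *, average: bool) -> float:
    delta = mods.n_ox * modification_delta("ox", average=average)
    if mods.glycan:
        delta += modification_delta(mods.glycan, average=average)
    if mods.pyroglu:
        delta += modification_delta("pyroglu", nterm=nterm, average=average)
    if mods.cterm_lys:
        delta += modification_delta("cterm_lys", average=average)
    return delta


def average_mass(sequence: str, mods: ModificationState | None = None) -> float:
    """Average neutral mass of a (modified) chain: residues + water + deltas."""
    m = chem.peptide_mass(sequence, average=True)
    if mods is not None and sequence:
        m += _mods_delta(mods, sequence[0], average=True)
    elif mods is not None:
        m += _mods_delta(mods, "", average=True)
    return m


def monoisotopic_mass(sequence: str, mods: ModificationState | None = None) -> float:
    """Monoisotopic variant of :func:`average_mass` (used for cross-checks)."""
    m = chem.peptide_mass(sequence, average=False)
    if mods is not None:
        m += _mods_delta(mods, sequence[0] if sequence else "", average=False)
    return m


@dataclass(frozen=True)
class LibraryConfig:
    """What modification states to enumerate for each subunit kind."""

    unspecific_ox_cap: int = DEFAULT_UNSPECIFIC_OX_CAP
    #: glycans allowed on Fc/2 (None = unglycosylated form)
    fc_glycans: tuple[str | None, ...] = (None, "G0F", "G1F")
    #: subunit kinds on which an additional C-terminal K is considered
    lys_kinds: tuple[str, ...] = ("Fc/2",)
    #: subunit kinds on which N-terminal pyroglutamate is considered
    pyroglu_kinds: tuple[str, ...] = ("Fd'",)


def enumerate_proteoforms(
    subunit: SubunitChain, config: LibraryConfig | None = None
) -> list[Proteoform]:
    """Deterministic cross-product of valid modification states for a subunit.

    Oxidation counts run from 0 to (number of methionines + unspecific cap);
    glycans and the extra C-terminal lysine are Fc/2-only; pyroglutamate is
    offered only where configured and chemically possible (N-terminal Q/E).
    Ordering is (glycan, cterm_lys, pyroglu, n_ox).
    """
    cfg = config or LibraryConfig()
    glycans: tuple[str | None, ...] = (
        cfg.fc_glycans if subunit.kind == "Fc/2" else (None,)
    )
    lys_opts = (False, True) if subunit.kind in cfg.lys_kinds else (False,)
    pg_possible = (
        subunit.kind in cfg.pyroglu_kinds
        and bool(subunit.sequence)
        and subunit.sequence[0] in ("Q", "E")
    )
    pg_opts = (False, True) if pg_possible else (False,)
    max_ox = subunit.n_met + cfg.unspecific_ox_cap

    forms: list[Proteoform] = []
    for glycan in glycans:
        for lys in lys_opts:
            for pg in pg_opts:
                for n_ox in range(max_ox + 1):
                    mods = ModificationState(
                        glycan=glycan, n_ox=n_ox, pyroglu=pg, cterm_lys=lys
                    )
                    suffix = mods.suffix()
                    name = f"{subunit.kind} {suffix}".strip()
                    forms.append(
                        Proteoform(
                            subunit_kind=subunit.kind,
                            mods=mods,
                            avg_mass=average_mass(subunit.sequence, mods),
                            mono_mass=monoisotopic_mass(subunit.sequence, mods),
                            display_name=name,
                        )
                    )
    return forms


def annotate_mass_error(delta_da: float) -> str:
    """Star notation for an absolute mass error in Da (total on any input)."""
    a = abs(delta_da)
    for bound, stars in STAR_BANDS:
        if a <= bound:
            return stars
    return REJECTED


def match_mass(
    observed: float,
    library: Sequence[Proteoform],
    tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    abundance: float = 0.0,
) -> list[Assignment]:
    """All library proteoforms within ±``tol_ppm`` of an observed mass.

    Sorted by |delta_ppm| ascending, so the first entry is the annotation.
    Returns an empty list when nothing is in the window.
    """
    if not library:
        raise ValueError("proteoform library is empty")
    hits = []
    for pf in library:
        delta = observed - pf.avg_mass
        ppm = delta / pf.avg_mass * 1e6
        if abs(ppm) <= tol_ppm:
            hits.append(
                Assignment(
                    proteoform=pf,
                    observed_mass=observed,
                    delta_da=delta,
                    delta_ppm=ppm,
                    stars=annotate_mass_error(delta),
                    abundance=abundance,
                )
            )
    hits.sort(key=lambda a: (abs(a.delta_ppm), a.proteoform.display_name))
    return hits


def library_table(library: Iterable[Proteoform]) -> pd.DataFrame:
    """Proteoform library as a DataFrame (exportable to CSV)."""
    rows = [
        {
            "subunit": pf.subunit_kind,
            "display_name": pf.display_name,
            "glycan": pf.mods.glycan or "",
            "n_ox": pf.mods.n_ox,
            "pyroglu": pf.mods.pyroglu,
            "cterm_lys": pf.mods.cterm_lys,
            "avg_mass": pf.avg_mass,
            "mono_mass": pf.mono_mass,
        }
        for pf in library
    ]
    return pd.DataFrame(rows)
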