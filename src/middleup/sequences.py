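"""Synthetic IgG1-like fixture sequences for the two model antibodies.

Real bevacizumab/infliximab chain sequences are not distributed with this
package, so the default workflow runs on a deterministic *synthetic*
bevacizumab-like /
infliximab-like pair. The pair reproduces everything the middle-up oxidation
analysis is sensitive to — subunit sizes (~23-26 kDa), a unique IgG1 lower
hinge motif, Q-starting heavy chains (pyroglutamate-capable), and exactly the
documented methionine maps:

========  ==================  ====================
subunit   bevacizumab-like    infliximab-like
========  ==================  ====================
LC        M4                  M55
Fd'       M34, M83            M18, M34, M85
Fc/2      M252, M358, M428    M255, M431
========  ==================  ====================

Fc/2 site labels follow EU numbering via per-mAb label offsets (the offset is
the Fd' length, i.e. subunit-local position + offset = heavy-chain numbering).
Everything else about the sequences (the filler residues) is arbitrary and
carries no biological meaning. Real sequences can be supplied as FASTA through
:func:`middleup.mab_model.load_mab_fasta` plus a config block with offsets.
"""

from __future__ import annotations

from .mab_model import (
    MAbDefinition,
    SubunitChain,
    ides_digest,
    map_methionines,
)

# Methionine-free, leucine-free filler tile (no accidental hinge motifs).
_TILE = "ASTKGPSVFDEQNRHYWIVA"

_FD_SUFFIX = "SCDKTHTCPPCPAPELLG"   # lower hinge; ends one G before the cut
_FC_PREFIX = "GPSVFLFPP"            # starts at the post-cut glycine
_FC_SUFFIX = "QKSLSLSPG"            # C-terminus with lysine already clipped


def _chain(length: int, prefix: str, suffix: str, met_positions: tuple[int, ...]) -> str:
    if length < len(prefix) + len(suffix):
        raise ValueError("chain length shorter than prefix+suffix")
    n_fill = length - len(prefix) - len(suffix)
    body = list(prefix + (_TILE * (n_fill // len(_TILE) + 1))[:n_fill] + suffix)
    for p in met_positions:
        if not len(prefix) < p <= length - len(suffix):
            raise ValueError(f"methionine position {p} falls outside the filler region")
        body[p - 1] = "M"
    return "".join(body)


def bevacizumab_like(role: str = "BS", cterm_lys_fraction: float | None = None) -> MAbDefinition:
    """Synthetic bevacizumab-like mAb (LC M4; Fd' M34/M83; Fc/2 M252/M358/M428)."""
    if cterm_lys_fraction is None:
        cterm_lys_fraction = 0.02
    lc = _chain(214, "DIQ", "", (4,))
    fd = _chain(236, "QVQL", _FD_SUFFIX, (34, 83))
    fc = _chain(210, _FC_PREFIX, _FC_SUFFIX, (16, 122, 192))
    return MAbDefinition(
        name="bevacizumab-like",
        heavy_chain=fd + fc,
        light_chain=lc,
        product_role=role,
        cterm_lys_fraction=cterm_lys_fraction,
    )


def infliximab_like(role: str = "BS", cterm_lys_fraction: float | None = None) -> MAbDefinition:
    """Synthetic infliximab-like mAb (LC M55; Fd' M18/M34/M85; Fc/2 M255/M431).

    Lysine clipping defaults mirror the two products: incomplete in the RP
    (a substantial +K fraction), near-complete in the BS.
    """
    if cterm_lys_fraction is None:
        cterm_lys_fraction = 0.30 if role == "RP" else 0.03
    lc = _chain(214, "DIQ", "", (55,))
    fd = _chain(239, "QVQL", _FD_SUFFIX, (18, 34, 85))
    fc = _chain(210, _FC_PREFIX, _FC_SUFFIX, (16, 192))
    return MAbDefinition(
        name="infliximab-like",
        heavy_chain=fd + fc,
        light_chain=lc,
        product_role=role,
        cterm_lys_fraction=cterm_lys_fraction,
    )


_BUILDERS = {
    "bevacizumab-like": bevacizumab_like,
    "infliximab-like": infliximab_like,
}

#: label offset per (mAb name, subunit kind): site label = local position + offset
LABEL_OFFSETS: dict[str, dict[str, int]] = {
    "bevacizumab-like": {"LC": 0, "Fd'": 0, "Fc/2": 236},
    "infliximab-like": {"LC": 0, "Fd'": 0, "Fc/2": 239},
}

#: homologous sites whose labels differ only through numbering (bev vs inf)
FD_EQUIVALENCES: tuple[tuple[str, str, str], ...] = (("Fd'", "M83", "M85"),)


def make_mab(name: str, role: str = "BS") -> MAbDefinition:
    try:
        return _BUILDERS[name](role)
    except KeyError:
        raise ValueError(
            f"unknown fixture mAb {name!r}; available: {sorted(_BUILDERS)}"
        ) from None


def reference_pair(role: str = "BS") -> tuple[MAbDefinition, MAbDefinition]:
    """The (bevacizumab-like, infliximab-like) pair with the given role."""
    return bevacizumab_like(role), infliximab_like(role)


def digest_and_map(mab: MAbDefinition) -> dict[str, SubunitChain]:
    """IdeS-digest a fixture mAb and attach its configured site labels."""
    offsets = LABEL_OFFSETS.get(mab.name, {})
    return {
        s.kind: map_methionines(s, offsets.get(s.kind, 0))
        for s in ides_digest(mab)
    }


def write_fasta(mab: MAbDefinition, path) -> None:
    """Write the HC/LC pair as a two-record FASTA."""
    with open(path, "w") as fh:
        fh.write(f">{mab.name}|HC synthetic heavy chain\n{mab.heavy_chain}\n")
        fh.write(f">{mab.name}|LC synthetic light chain\n{mab.light_chain}\n")
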