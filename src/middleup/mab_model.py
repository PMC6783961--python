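"""IgG1 antibody model: sequences, in-silico IdeS digestion, methionine maps.

IdeS cleaves the IgG1 heavy chain in the lower hinge between the paired
glycines of the ``...CPAPELLG | GPSV...`` motif. Together with disulfide
reduction this liberates three subunits, each present twice per antibody:
the light chain (LC), the heavy-chain N-terminal fragment (Fd', variable
domain + CH1 + hinge stub) and half of the constant fragment (Fc/2).
Reduction is modelled implicitly: subunits are emitted as free chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .chem import CANONICAL_RESIDUES

#: IgG1 lower-hinge motif; cleavage falls between its two C-terminal glycines.
HINGE_MOTIF = "LLGG"

SUBUNIT_KINDS = ("LC", "Fd'", "Fc/2")


class FormatError(ValueError):
    """Raised for malformed input files (wrong record cardinality etc.)."""


class ValidationError(ValueError):
    """Raised when a sequence or parameter violates the model's invariants."""


class DigestionError(ValueError):
    """Raised when the heavy chain does not present a unique hinge motif."""


def _check_sequence(sequence: str, what: str) -> None:
    for pos, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise ValidationError(
                f"{what}: invalid residue {aa!r} at position {pos}"
            )


@dataclass(frozen=True)
class MAbDefinition:
    """A named mAb: heavy/light chain pair plus its product role (RP or BS).

    ``cterm_lys_fraction`` is the fraction of heavy chains still carrying the
    C-terminal lysine (clipping during production is usually near-complete,
    but can differ between a reference product and its biosimilar).
    """

    name: str
    heavy_chain: str
    light_chain: str
    product_role: str
    cterm_lys_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.product_role not in ("RP", "BS"):
            raise ValidationError(
                f"product_role must be 'RP' or 'BS', got {self.product_role!r}"
            )
        _check_sequence(self.heavy_chain, f"{self.name} heavy chain")
        _check_sequence(self.light_chain, f"{self.name} light chain")
        if not 0.0 <= self.cterm_lys_fraction <= 1.0:
            raise ValidationError("cterm_lys_fraction must lie in [0, 1]")
        n_motif = self.heavy_chain.count(HINGE_MOTIF)
        if n_motif != 1:
            raise ValidationError(
                f"heavy chain must contain exactly one {HINGE_MOTIF!r} hinge "
                f"motif, found {n_motif}"
            )


@dataclass(frozen=True)
class SubunitChain:
    """One of the three middle-up subunits with its methionine site map."""

    kind: str
    sequence: str
    copies_per_mab: int = 2
    methionine_positions: tuple[int, ...] = ()  # 1-based indices into sequence
    site_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in SUBUNIT_KINDS:
            raise ValidationError(f"unknown subunit kind {self.kind!r}")
        expected = tuple(
            i for i, aa in enumerate(self.sequence, start=1) if aa == "M"
        )
        if self.methionine_positions and self.methionine_positions != expected:
            raise ValidationError(
                "methionine_positions do not match 'M' locations in sequence"
            )
        if self.site_labels and len(self.site_labels) != len(
            self.methionine_positions
        ):
            raise ValidationError("one site label required per methionine")

    @property
    def n_met(self) -> int:
        return self.sequence.count("M")


@dataclass(frozen=True)
class MethionineSite:
    """A methionine with its oxidation susceptibility class and rate.

    Surface-exposed methionines (the conserved Fc pair, and solvent-accessible
    Fab sites) oxidize fast under peroxide stress; buried ones slowly.
    ``rate_constant`` is the pseudo-first-order oxidation rate, per hour.
    """

    subunit_kind: str
    site_label: str
    exposure_class: str  # "fast" | "slow"
    rate_constant: float

    def __post_init__(self) -> None:
        if self.exposure_class not in ("fast", "slow"):
            raise ValidationError("exposure_class must be 'fast' or 'slow'")
        if self.rate_constant < 0:
            raise ValidationError("rate_constant must be >= 0")


def load_mab_fasta(
    path,
    role: str,
    *,
    name: str | None = None,
    cterm_lys_fraction: float = 0.0,
) -> MAbDefinition:
    """Read a two-record FASTA (headers tagged ``HC`` / ``LC``) into a mAb.

    Raises :class:`FormatError` on wrong record count or missing chain tags and
    :class:`ValidationError` on non-canonical residues.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(
            f"expected exactly 2 FASTA records (HC and LC), found {len(records)}"
        )
    chains: dict[str, str] = {}
    for rec in records:
        header = f"{rec.id} {rec.description}"
        tokens = header.replace("|", " ").replace("_", " ").split()
        tagged = [t for t in ("HC", "LC") if t in tokens]
        if len(tagged) != 1:
            raise FormatError(
                f"record {rec.id!r}: header must contain exactly one of the "
                "tokens 'HC' or 'LC'"
            )
        if tagged[0] in chains:
            raise FormatError(f"duplicate {tagged[0]} record in FASTA")
        chains[tagged[0]] = str(rec.seq).upper()
    if set(chains) != {"HC", "LC"}:
        raise FormatError("FASTA must provide one HC and one LC record")
    return MAbDefinition(
        name=name or records[0].id.split("|")[0],
        heavy_chain=chains["HC"],
        light_chain=chains["LC"],
        product_role=role,
        cterm_lys_fraction=cterm_lys_fraction,
    )


def ides_digest(mab: MAbDefinition) -> list[SubunitChain]:
    """In-silico IdeS digestion + reduction: LC, Fd' and Fc/2 free chains.

    The cut is placed between the two glycines of the unique ``LLGG``
    occurrence, so ``Fd' + Fc/2`` reconstructs the heavy chain exactly.
    """
    hc = mab.heavy_chain
    n_motif = hc.count(HINGE_MOTIF)
    if n_motif != 1:
        raise DigestionError(
            f"heavy chain of {mab.name!r} has {n_motif} occurrences of "
            f"{HINGE_MOTIF!r}; exactly one is required"
        )
    i = hc.index(HINGE_MOTIF)
    fd_seq = hc[: i + 3]   # ...LLG
    fc_seq = hc[i + 3:]    # G...
    subunits = [
        SubunitChain(kind="LC", sequence=mab.light_chain),
        SubunitChain(kind="Fd'", sequence=fd_seq),
        SubunitChain(kind="Fc/2", sequence=fc_seq),
    ]
    return [
        replace(
            s,
            methionine_positions=tuple(
                i for i, aa in enumerate(s.sequence, start=1) if aa == "M"
            ),
        )
        for s in subunits
    ]


def map_methionines(subunit: SubunitChain, label_offset: int) -> SubunitChain:
    """Attach conventional site labels (e.g. EU numbering for Fc/2).

    ``label_offset`` converts subunit-local 1-based positions into the
    antibody-numbering scheme: label = "M" + (local position + offset).
    """
    positions = tuple(
        i for i, aa in enumerate(subunit.sequence, start=1) if aa == "M"
    )
    labels = tuple(f"M{p + label_offset}" for p in positions)
    return replace(subunit, methionine_positions=positions, site_labels=labels)


@dataclass(frozen=True)
class MapComparison:
    """Shared/unique methionine site labels for one subunit kind."""

    subunit_kind: str
    shared: tuple[str, ...]
    unique_to_a: tuple[str, ...]
    unique_to_b: tuple[str, ...]


def compare_methionine_maps(
    subunits_a: dict[str, SubunitChain],
    subunits_b: dict[str, SubunitChain],
    equivalences: tuple[tuple[str, str, str], ...] = (),
) -> dict[str, MapComparison]:
    """Per-subunit shared and unique methionine sites between two mAbs.

    ``equivalences`` declares homologous positions whose labels differ only
    through numbering, as ``(subunit_kind, label_in_a, label_in_b)`` triples;
    such pairs are reported as shared with a combined label like ``M83/85``.
    """
    out: dict[str, MapComparison] = {}
    for kind in SUBUNIT_KINDS:
        a = set(subunits_a[kind].site_labels) if kind in subunits_a else set()
        b = set(subunits_b[kind].site_labels) if kind in subunits_b else set()
        shared = sorted(a & b, key=_label_key)
        rest_a, rest_b = a - b, b - a
        for ekind, la, lb in equivalences:
            if ekind == kind and la in rest_a and lb in rest_b:
                shared.append(f"{la}/{lb.lstrip('M')}")
                rest_a.discard(la)
                rest_b.discard(lb)
        out[kind] = MapComparison(
            subunit_kind=kind,
            shared=tuple(sorted(shared, key=_label_key)),
            unique_to_a=tuple(sorted(rest_a, key=_label_key)),
            unique_to_b=tuple(sorted(rest_b, key=_label_key)),
        )
    return out


def _label_key(label: str) -> tuple[int, str]:
    core = label.lstrip("M").split("/")[0]
    return (int(core) if core.isdigit() else 0, label)
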