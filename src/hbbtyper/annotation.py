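"""HGVS naming and molecular consequence annotation for substitutions.

Coding substitutions are translated with the standard genetic code
(initiator Met = residue 1, current HGVS protein numbering), intronic
substitutions at offsets ±1/±2 are annotated as splice-site lesions, and
legacy aliases used in the haemoglobinopathy literature are emitted
alongside (``IVS1-1G>A`` for c.92+1G>A; ``Glu6Val`` style legacy protein
numbering that counts from the mature chain, i.e. current residue − 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .reference_model import CdsCoord, LocusModel, parse_cds_coord

__all__ = ["Annotation", "Variant", "parse_hgvs_c", "annotate", "truncation_fraction"]

CONSEQUENCES = (
    "synonymous",
    "missense",
    "stop_gain",
    "start_loss",
    "splice_donor",
    "splice_acceptor",
    "intronic",
    "noncoding",
)

#: rendering of a stop gained, matching the short clinical convention.
STOP_SYMBOL = "X"


@dataclass(frozen=True)
class Variant:
    """A substitution in genomic locus coordinates (0-based)."""

    gpos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base substitutions are supported")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class Annotation:
    hgvs_c: str
    hgvs_p: str  # empty for non-coding consequences
    consequence: str
    legacy_alias: str = ""
    codon_index: int = 0  # 0 when not coding

    @property
    def protein_name(self) -> str:
        """Short protein-change name without the ``p.`` prefix (e.g. Glu7Val)."""
        return self.hgvs_p[2:] if self.hgvs_p.startswith("p.") else self.hgvs_p


def parse_hgvs_c(text: str, model: LocusModel) -> Variant:
    """Resolve an HGVS c. substitution (e.g. ``c.20A>T``, ``c.92+1G>A``)
    to a genomic Variant, validating the stated reference base."""
    m = re.match(r"^c\.(\d+(?:[+-]\d+)?)\s*([ACGT])\s*>\s*([ACGT])$", text.strip())
    if not m:
        raise ValueError(f"cannot parse HGVS substitution {text!r}")
    coord = parse_cds_coord("c." + m.group(1))
    ref, alt = m.group(2), m.group(3)
    if coord.kind == "coding":
        gpos = model.c_to_g(coord.coding_pos)
    else:
        anchor = model.c_to_g(coord.coding_pos)
        gpos = anchor + coord.intron_offset
        got = model.g_to_c(gpos)
        if got != coord:
            raise ValueError(f"{text}: intronic offset does not map back ({got})")
    actual = model.sequence[gpos]
    if actual != ref:
        raise ValueError(
            f"{text}: reference base at that position is {actual}, not {ref}"
        )
    return Variant(gpos, ref, alt)


def _render_hgvs_c(coord: CdsCoord, ref: str, alt: str) -> str:
    return f"{coord}{ref}>{alt}"


def annotate(variant: Variant | "object", model: LocusModel) -> Annotation:
    """Annotate a substitution with HGVS c./p. names and its consequence.

    Accepts a :class:`Variant` or any object with ``gpos``/``ref``/``alt``
    attributes (e.g. a VariantCall).
    """
    gpos, ref, alt = variant.gpos, variant.ref, variant.alt
    if model.sequence[gpos] != ref:
        raise ValueError(f"ref base mismatch at {gpos}: locus has {model.sequence[gpos]}")
    try:
        coord = model.g_to_c(gpos)
    except ValueError:
        return Annotation(hgvs_c="", hgvs_p="", consequence="noncoding")

    hgvs_c = _render_hgvs_c(coord, ref, alt)

    if coord.kind == "intronic":
        off = coord.intron_offset
        if off in (1, 2):
            consequence = "splice_donor"
        elif off in (-1, -2):
            consequence = "splice_acceptor"
        else:
            consequence = "intronic"
        alias = ""
        if consequence in ("splice_donor", "splice_acceptor"):
            ivs = model.intron_number(gpos)
            legacy_pos = off if off > 0 else off  # IVS counts 1,2,... / -1,-2 from 3' end
            alias = f"IVS{ivs}-{abs(legacy_pos)}{ref}>{alt}" if off > 0 else (
                f"IVS{ivs}(3')-{abs(off)}{ref}>{alt}"
            )
        return Annotation(hgvs_c=hgvs_c, hgvs_p="", consequence=consequence,
                          legacy_alias=alias)

    # coding substitution
    idx, codon, off_in_codon = model.codon_at(coord.coding_pos)
    mutant = codon[:off_in_codon] + alt + codon[off_in_codon + 1 :]
    ref_aa = _translate(codon)
    alt_aa = _translate(mutant)

    ref_name = STOP_SYMBOL if ref_aa == "*" else seq3(ref_aa)
    alt_name = STOP_SYMBOL if alt_aa == "*" else seq3(alt_aa)

    if alt_aa == ref_aa:
        consequence = "synonymous"
        hgvs_p = f"p.{ref_name}{idx}{ref_name}"
    elif idx == 1 and ref_aa == "M":
        consequence = "start_loss"
        hgvs_p = f"p.{ref_name}{idx}{alt_name}"
    elif alt_aa == "*":
        consequence = "stop_gain"
        hgvs_p = f"p.{ref_name}{idx}{STOP_SYMBOL}"
    else:
        consequence = "missense"
        hgvs_p = f"p.{ref_name}{idx}{alt_name}"

    # legacy numbering counts from the mature chain (initiator Met cleaved)
    alias = ""
    if consequence in ("missense", "stop_gain") and idx > 1:
        alias = f"{ref_name}{idx - 1}{STOP_SYMBOL if alt_aa == '*' else alt_name}"
    return Annotation(hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence=consequence,
                      legacy_alias=alias, codon_index=idx)


def _translate(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def truncation_fraction(annotation: Annotation, model: LocusModel) -> float:
    """Fraction of the protein-coding region lost to a premature stop.

    A stop at codon *k* removes residues *k*..*L* of an *L*-residue protein
    (L counts the initiator Met, the natural stop codon is excluded), i.e.
    ``(L - (k - 1)) / L``.
    """
    if annotation.consequence != "stop_gain":
        raise ValueError("truncation_fraction requires a stop_gain annotation")
    L = model.protein_length
    k = annotation.codon_index
    return (L - (k - 1)) / L
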