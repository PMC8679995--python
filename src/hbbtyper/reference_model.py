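"""Locus reference model and coordinate arithmetic.

The β-globin (HBB) gene is modelled on its sense strand as a single short
locus: an ordered set of exons and a CDS interval over one reference
sequence.  Everything downstream (variant calling, HGVS annotation,
haplotype construction) expresses positions either in genomic locus
coordinates (0-based, half-open internally) or in HGVS coding ("c.")
coordinates (1-based over the spliced CDS, with ``+``/``-`` offsets for
intronic positions).

The bundled fixture is a synthetic HBB-like locus: a sequence constructed
so that the clinically important codons of real HBB are reproduced exactly
(initiator Met1, His3, Glu7 — the sickle codon, Glu23, Trp38, Gln40,
Lys60, a 147-residue protein, and exon 1 ending at c.92 so that the first
intron-1 base is c.92+1), without requiring any external download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "CdsCoord",
    "LocusModel",
    "load_locus",
    "bundled_locus",
    "bundled_reference_path",
    "bundled_transcript_path",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdsCoord:
    """A position in HGVS coding coordinates.

    ``coding_pos`` is the 1-based position of the nearest coding base
    (the base itself for coding positions); ``intron_offset`` is the
    signed distance into the intron (0 for coding positions), so the
    first base of intron 1 after an exon ending at c.92 renders as
    ``c.92+1``.
    """

    kind: str  # "coding" | "intronic"
    coding_pos: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("coding", "intronic"):
            raise ValueError(f"unknown CdsCoord kind {self.kind!r}")
        if (self.intron_offset != 0) != (self.kind == "intronic"):
            raise ValueError("intron_offset must be nonzero iff kind is intronic")
        if self.coding_pos < 1:
            raise ValueError("coding_pos must be >= 1")

    def __str__(self) -> str:
        if self.kind == "coding":
            return f"c.{self.coding_pos}"
        sign = "+" if self.intron_offset > 0 else "-"
        return f"c.{self.coding_pos}{sign}{abs(self.intron_offset)}"


_CDS_COORD_RE = re.compile(r"^c\.(\d+)(?:([+-])(\d+))?$")


def parse_cds_coord(text: str) -> CdsCoord:
    """Parse ``c.20`` or ``c.92+1`` style coordinate strings."""
    m = _CDS_COORD_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse CDS coordinate {text!r}")
    pos = int(m.group(1))
    if m.group(2):
        off = int(m.group(3)) * (1 if m.group(2) == "+" else -1)
        return CdsCoord("intronic", pos, off)
    return CdsCoord("coding", pos)


@dataclass
class LocusModel:
    """Reference sequence plus transcript structure for one gene locus."""

    locus_name: str
    sequence: str
    exons: list[tuple[int, int]]  # 0-based half-open genomic intervals
    cds_start: int  # genomic position of the A of ATG
    cds_end: int  # genomic position one past the last CDS base

    # derived, filled in __post_init__
    coding_segments: list[tuple[int, int]] = field(default_factory=list, repr=False)
    coding_length: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        exons = sorted(self.exons)
        for (s, e) in exons:
            if not (0 <= s < e <= n):
                raise ValueError(f"exon ({s},{e}) outside locus of length {n}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"exons ({s1},{e1}) and ({s2},{e2}) overlap")
        self.exons = exons
        if not (exons[0][0] <= self.cds_start < exons[0][1]):
            raise ValueError("cds_start must lie in the first exon")
        if not (exons[-1][0] < self.cds_end <= exons[-1][1]):
            raise ValueError("cds_end must lie in the last exon")
        segs = []
        for (s, e) in exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                segs.append((cs, ce))
        self.coding_segments = segs
        self.coding_length = sum(e - s for s, e in segs)
        if self.coding_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.coding_length} is not a multiple of 3"
            )

    # ------------------------------------------------------------------
    # coordinate conversion
    # ------------------------------------------------------------------

    def c_to_g(self, coding_pos: int) -> int:
        """Genomic (0-based) position of 1-based coding position."""
        if not (1 <= coding_pos <= self.coding_length):
            raise ValueError(
                f"coding position {coding_pos} outside 1..{self.coding_length}"
            )
        remaining = coding_pos - 1
        for (s, e) in self.coding_segments:
            if remaining < e - s:
                return s + remaining
            remaining -= e - s
        raise AssertionError("unreachable")

    def g_to_c(self, gpos: int) -> CdsCoord:
        """HGVS c. coordinate of a genomic position inside the transcript.

        Coding positions map to ``c.N``; intronic positions to the nearest
        exon boundary with a ``+``/``-`` offset.  Positions outside the
        CDS-bearing exon span (UTR-less model) raise ``ValueError``.
        """
        if not (0 <= gpos < len(self.sequence)):
            raise ValueError(f"position {gpos} outside locus")
        # coding?
        c = 0
        for (s, e) in self.coding_segments:
            if s <= gpos < e:
                return CdsCoord("coding", c + (gpos - s) + 1)
            c += e - s
        # intronic: between which coding segments?
        for i, ((s1, e1), (s2, e2)) in enumerate(
            zip(self.coding_segments, self.coding_segments[1:])
        ):
            if e1 <= gpos < s2:
                last_c = self._coding_pos_at_segment_end(i)
                dist_left = gpos - e1 + 1  # offset from exon end (+)
                dist_right = s2 - gpos  # offset to next exon start (-)
                if dist_left <= dist_right:
                    return CdsCoord("intronic", last_c, dist_left)
                return CdsCoord("intronic", last_c + 1, -dist_right)
        raise ValueError(f"position {gpos} is outside the modelled transcript")

    def _coding_pos_at_segment_end(self, seg_index: int) -> int:
        return sum(e - s for s, e in self.coding_segments[: seg_index + 1])

    def intron_number(self, gpos: int) -> int:
        """1-based index of the intron containing gpos (for legacy names)."""
        for i, ((_, e1), (s2, _)) in enumerate(zip(self.exons, self.exons[1:])):
            if e1 <= gpos < s2:
                return i + 1
        raise ValueError(f"position {gpos} is not intronic")

    # ------------------------------------------------------------------
    # codons
    # ------------------------------------------------------------------

    @property
    def cds_sequence(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.coding_segments)

    @property
    def n_codons(self) -> int:
        return self.coding_length // 3

    @property
    def protein_length(self) -> int:
        """Number of residues including the initiator Met (stop excluded)."""
        return self.n_codons - 1

    def codon_at(self, coding_pos: int) -> tuple[int, str, int]:
        """Return (codon_index, codon_bases, offset_in_codon) for a coding position.

        Codons are numbered with the initiator Met as 1; offset_in_codon is
        0..2 within the codon.
        """
        if not (1 <= coding_pos <= self.coding_length):
            raise ValueError(
                f"coding position {coding_pos} outside 1..{self.coding_length}"
            )
        idx = (coding_pos - 1) // 3 + 1
        off = (coding_pos - 1) % 3
        codon = self.cds_sequence[(idx - 1) * 3 : idx * 3]
        return idx, codon, off

    def iter_coding_positions(self) -> Iterator[tuple[int, int]]:
        """Yield (coding_pos, gpos) pairs over the whole CDS."""
        c = 1
        for (s, e) in self.coding_segments:
            for g in range(s, e):
                yield c, g
                c += 1


# ----------------------------------------------------------------------
# loading
# ----------------------------------------------------------------------

def load_locus(reference_fasta: str | Path, transcript_spec: str | Path) -> LocusModel:
    """Build a LocusModel from a single-record FASTA and a transcript spec.

    The transcript spec is tab-delimited with columns ``feature  start  end``
    (0-based half-open).  ``exon`` rows give the exon intervals; a single
    ``CDS`` row gives the translated span.  Lines starting with ``#`` are
    comments.
    """
    reference_fasta = Path(reference_fasta)
    transcript_spec = Path(transcript_spec)
    records = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{reference_fasta} must contain exactly one record, found {len(records)}"
        )
    rec = records[0]

    exons: list[tuple[int, int]] = []
    cds: tuple[int, int] | None = None
    for line_no, raw in enumerate(transcript_spec.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{transcript_spec}:{line_no}: expected 3 tab-separated fields"
            )
        feature, start, end = parts[0], int(parts[1]), int(parts[2])
        if feature.lower() == "exon":
            exons.append((start, end))
        elif feature.upper() == "CDS":
            if cds is not None:
                raise ValueError(f"{transcript_spec}: multiple CDS rows")
            cds = (start, end)
        else:
            raise ValueError(f"{transcript_spec}:{line_no}: unknown feature {feature!r}")
    if not exons:
        raise ValueError(f"{transcript_spec}: no exon rows")
    if cds is None:
        raise ValueError(f"{transcript_spec}: no CDS row")
    return LocusModel(
        locus_name=rec.id,
        sequence=str(rec.seq),
        exons=exons,
        cds_start=cds[0],
        cds_end=cds[1],
    )


def bundled_reference_path() -> Path:
    return Path(resources.files("hbbtyper.data") / "hbb_synthetic.fasta")


def bundled_transcript_path() -> Path:
    return Path(resources.files("hbbtyper.data") / "hbb_synthetic_transcript.tsv")


def bundled_locus() -> LocusModel:
    """The synthetic HBB-like locus shipped with the package."""
    return load_locus(bundled_reference_path(), bundled_transcript_path())
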