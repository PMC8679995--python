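"""Pileup construction, substitution calling, and VAF-based zygosity.

The caller mirrors a constitutional diagnostic workflow on a deeply
sequenced single amplicon: build a per-position tally of base-quality-
filtered read bases, take the strongest non-reference base at each
position as a candidate, and genotype by variant allele fraction (VAF):

* VAF within the heterozygous window (default 0.40–0.60, inclusive) → het;
* VAF at or above the homozygous threshold (default 0.75) → hom;
* anything else above the noise floor (default 0.25) is reported as
  ``ambiguous_vaf`` — neither silently dropped nor given a genotype.

Sites with fewer than ``min_depth`` (default 200) quality-passing bases
are flagged ``low_depth``.  Insertion/deletion evidence is tallied and
reported through a side channel but not genotyped: the assay targets
substitution lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demux_align import Alignment
from .reference_model import LocusModel

__all__ = [
    "CallerConfig",
    "Pileup",
    "PileupColumn",
    "VariantCall",
    "build_pileup",
    "call_variants",
    "classify_zygosity",
    "write_vcf",
]

_BASE_ORDER = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASE_ORDER):
    _BASE_INDEX[ord(_b)] = _i


@dataclass(frozen=True)
class CallerConfig:
    min_depth: int = 200
    min_base_quality: int = 15
    het_low: float = 0.40
    het_high: float = 0.60
    hom_threshold: float = 0.75
    min_call_vaf: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.min_call_vaf <= self.het_low < self.het_high
                < self.hom_threshold <= 1):
            raise ValueError(
                "require 0 < min_call_vaf <= het_low < het_high < hom_threshold <= 1"
            )


@dataclass(frozen=True)
class PileupColumn:
    gpos: int
    ref_base: str
    counts: dict  # base -> int, plus "del"
    qual_sum: dict  # base -> summed Phred
    depth_pass: int


class Pileup:
    """Column-major pileup over the locus: base counts and quality sums
    restricted to bases at or above the quality threshold."""

    def __init__(self, model: LocusModel, min_base_quality: int):
        self.model = model
        self.min_base_quality = min_base_quality
        n = len(model.sequence)
        self.base_counts = np.zeros((n, 4), dtype=np.int64)
        self.qual_sums = np.zeros((n, 4), dtype=np.int64)
        self.del_counts = np.zeros(n, dtype=np.int64)
        self.ins_counts: dict[int, int] = {}

    @property
    def depth_pass(self) -> np.ndarray:
        return self.base_counts.sum(axis=1)

    def add_alignment(self, aln: Alignment) -> None:
        ok = aln.quals >= self.min_base_quality
        pos = aln.ref_positions[ok]
        bidx = _BASE_INDEX[aln.bases[ok]]
        valid = bidx >= 0
        np.add.at(self.base_counts, (pos[valid], bidx[valid]), 1)
        np.add.at(self.qual_sums, (pos[valid], bidx[valid]),
                  aln.quals[ok][valid].astype(np.int64))
        deleted = getattr(aln, "deleted_ref", None)
        if deleted is not None and deleted.size:
            np.add.at(self.del_counts, deleted, 1)
        for anchor, _length in getattr(aln, "insertions", []):
            self.ins_counts[anchor] = self.ins_counts.get(anchor, 0) + 1

    def column(self, gpos: int) -> PileupColumn:
        counts = {b: int(self.base_counts[gpos, i]) for i, b in enumerate(_BASE_ORDER)}
        counts["del"] = int(self.del_counts[gpos])
        quals = {b: int(self.qual_sums[gpos, i]) for i, b in enumerate(_BASE_ORDER)}
        return PileupColumn(
            gpos=gpos,
            ref_base=self.model.sequence[gpos],
            counts=counts,
            qual_sum=quals,
            depth_pass=int(self.base_counts[gpos].sum()),
        )


def build_pileup(
    alignments: list[Alignment], model: LocusModel, min_base_quality: int = 15
) -> Pileup:
    pileup = Pileup(model, min_base_quality)
    for aln in alignments:
        pileup.add_alignment(aln)
    return pileup


@dataclass(frozen=True)
class VariantCall:
    gpos: int
    ref: str
    alt: str
    depth: int  # quality-passing depth at the site
    alt_count: int
    vaf: float
    zygosity: str  # het | hom | ambiguous
    filter: str  # PASS | low_depth | ambiguous_vaf

    @property
    def is_pass(self) -> bool:
        return self.filter == "PASS"


def classify_zygosity(vaf: float, config: CallerConfig = CallerConfig()) -> str:
    """Genotype from allele fraction alone: the diagnostic VAF windows.

    Both het window bounds are inclusive; the hom threshold is inclusive.
    """
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if vaf >= config.hom_threshold:
        return "hom"
    if config.het_low <= vaf <= config.het_high:
        return "het"
    return "ambiguous"


def call_variants(
    pileup: Pileup, config: CallerConfig = CallerConfig()
) -> list[VariantCall]:
    """One candidate per column: the strongest non-reference base above the
    noise floor, genotyped by the VAF windows and depth filter."""
    if pileup.min_base_quality != config.min_base_quality:
        raise ValueError(
            "pileup was built with a different base-quality threshold than the caller"
        )
    model = pileup.model
    ref_codes = np.frombuffer(model.sequence.encode(), dtype=np.uint8)
    ref_idx = _BASE_INDEX[ref_codes]  # -1 for N
    counts = pileup.base_counts
    depth = counts.sum(axis=1)

    masked = counts.copy()
    rows = np.arange(len(model.sequence))
    ok_rows = ref_idx >= 0
    masked[rows[ok_rows], ref_idx[ok_rows]] = -1  # exclude the reference base
    alt_idx = masked.argmax(axis=1)
    alt_count = counts[rows, alt_idx]

    calls: list[VariantCall] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf_arr = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    cand = np.nonzero((vaf_arr >= config.min_call_vaf) & (alt_count > 0))[0]
    for gpos in cand:
        vaf = float(vaf_arr[gpos])
        d = int(depth[gpos])
        zyg = classify_zygosity(vaf, config)
        if d < config.min_depth:
            filt = "low_depth"
        elif zyg == "ambiguous":
            filt = "ambiguous_vaf"
        else:
            filt = "PASS"
        calls.append(
            VariantCall(
                gpos=int(gpos),
                ref=model.sequence[gpos],
                alt=_BASE_ORDER[alt_idx[gpos]],
                depth=d,
                alt_count=int(alt_count[gpos]),
                vaf=vaf,
                zygosity=zyg,
                filter=filt,
            )
        )
    return calls


# ----------------------------------------------------------------------
# VCF output
# ----------------------------------------------------------------------

def write_vcf(
    calls: list[VariantCall],
    model: LocusModel,
    sample_id: str,
    path: str | Path,
    annotations: dict[int, str] | None = None,
    phased_gt: dict[int, str] | None = None,
) -> None:
    """VCF 4.2 with DP/VAF INFO, optional CSQ-style annotation strings and
    phased GT overrides (gpos -> e.g. ``0|1``)."""
    annotations = annotations or {}
    phased_gt = phased_gt or {}
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={model.locus_name},length={len(model.sequence)}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-passing depth">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="hgvs_c|hgvs_p|consequence">',
        '##FILTER=<ID=low_depth,Description="Quality-passing depth below minimum">',
        '##FILTER=<ID=ambiguous_vaf,Description="VAF outside the het window and below the hom threshold">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    for call in sorted(calls, key=lambda c: c.gpos):
        info = f"DP={call.depth};VAF={call.vaf:.4f}"
        if call.gpos in annotations:
            info += f";CSQ={annotations[call.gpos]}"
        gt = phased_gt.get(call.gpos)
        if gt is None:
            gt = {"het": "0/1", "hom": "1/1"}.get(call.zygosity, "./.")
        lines.append(
            f"{model.locus_name}\t{call.gpos + 1}\t.\t{call.ref}\t{call.alt}\t.\t"
            f"{call.filter}\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
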