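"""Nanopore-like read simulation over the β-globin locus.

Generates barcoded, noisy long reads from diploid genotypes so that the
whole downstream pipeline (demultiplexing → alignment → pileup calling →
phasing → interpretation) can be exercised without instrument data.

The error model is deliberately simple: i.i.d. per-base substitutions,
single-base insertions and deletions at configurable rates, with per-base
Phred qualities drawn around a configurable mean.  Defaults (2%
substitutions, 0.5% insertions, 0.5% deletions, mean quality Q20) are
substitution-dominant, which keeps the pileup caller and its quality
filter honestly exercised without overwhelming indel handling.  Reads
span the full locus by default, as in amplicon sequencing of a short
gene; a truncation option exists to test partial spanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import Variant, parse_hgvs_c
from .reference_model import LocusModel, revcomp

__all__ = [
    "DiploidGenotype",
    "SimulationConfig",
    "FastqRecord",
    "make_haplotypes",
    "simulate_reads",
    "simulate_cohort",
    "write_fastq",
    "load_cohort_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DiploidGenotype:
    """A sample's two haplotypes, each a list of HGVS c. substitutions.

    Homozygous variants appear in both lists; a compound heterozygote in
    trans has its two variants on opposite lists.
    """

    sample_id: str
    hap1: tuple[str, ...] = ()
    hap2: tuple[str, ...] = ()

    def zygosity_of(self, hgvs_c: str) -> str:
        on1, on2 = hgvs_c in self.hap1, hgvs_c in self.hap2
        if on1 and on2:
            return "hom"
        if on1 or on2:
            return "het"
        return "absent"

    @property
    def variants(self) -> list[str]:
        out = list(self.hap1)
        out.extend(v for v in self.hap2 if v not in out)
        return out


@dataclass(frozen=True)
class SimulationConfig:
    depth: int = 500
    sub_rate: float = 0.02
    ins_rate: float = 0.005
    del_rate: float = 0.005
    read_fraction: float = 1.0  # minimum fraction of the locus spanned
    base_quality_mean: float = 20.0
    base_quality_sd: float = 5.0
    barcode: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 0.2):
                raise ValueError(f"{name}={r} outside [0, 0.2]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 < self.read_fraction <= 1.0):
            raise ValueError("read_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    description: str
    sequence: str
    qualities: np.ndarray = field(compare=False)  # Phred values, uint8

    def to_fastq(self) -> str:
        qual = "".join(chr(q + 33) for q in self.qualities)
        return f"@{self.read_id} {self.description}\n{self.sequence}\n+\n{qual}\n"


def make_haplotypes(
    genotype: DiploidGenotype, model: LocusModel
) -> tuple[str, str]:
    """Render the two haplotype sequences (reference with substitutions)."""
    return (
        _apply_variants(genotype.hap1, model),
        _apply_variants(genotype.hap2, model),
    )


def _apply_variants(hgvs_list: tuple[str, ...], model: LocusModel) -> str:
    seq = list(model.sequence)
    seen: dict[int, str] = {}
    for text in hgvs_list:
        v: Variant = parse_hgvs_c(text, model)
        if v.gpos in seen and seen[v.gpos] != v.alt:
            raise ValueError(
                f"conflicting alleles at genomic position {v.gpos} on one haplotype"
            )
        seen[v.gpos] = v.alt
        seq[v.gpos] = v.alt
    return "".join(seq)


def _corrupt(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitution/insertion/deletion errors to a sequence."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    if cfg.sub_rate > 0:
        mask = rng.random(n) < cfg.sub_rate
        idx = np.nonzero(mask)[0]
        if idx.size:
            # shift by 1..3 positions in the base alphabet: always a different base
            cur = np.searchsorted(_BASES, arr[idx])
            arr[idx] = _BASES[(cur + rng.integers(1, 4, idx.size)) % 4]
    keep = np.ones(n, dtype=bool)
    if cfg.del_rate > 0:
        keep = rng.random(n) >= cfg.del_rate
    if cfg.ins_rate > 0:
        ins_after = rng.random(n) < cfg.ins_rate
        pieces: list[np.ndarray] = []
        bounds = np.nonzero(ins_after)[0]
        prev = 0
        for b in bounds:
            pieces.append(arr[prev : b + 1][keep[prev : b + 1]])
            pieces.append(_BASES[rng.integers(0, 4, 1)])
            prev = b + 1
        pieces.append(arr[prev:][keep[prev:]])
        arr = np.concatenate(pieces)
    else:
        arr = arr[keep]
    return arr.tobytes().decode()


def simulate_reads(
    haplotypes: tuple[str, str], config: SimulationConfig
) -> list[FastqRecord]:
    """Draw reads uniformly over haplotypes and strands with i.i.d. errors.

    Each read is (optionally a window of) a uniformly chosen haplotype on a
    uniformly chosen strand, corrupted by the error model, with the sample
    barcode prepended before corruption (so the barcode also carries
    sequencing error, as it would on an instrument).  Deterministic for a
    fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    reads: list[FastqRecord] = []
    L = len(haplotypes[0])
    for i in range(config.depth):
        hap_idx = int(rng.integers(0, 2))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        template = haplotypes[hap_idx]
        if config.read_fraction < 1.0:
            span = int(L * (config.read_fraction + (1 - config.read_fraction) * rng.random()))
            start = int(rng.integers(0, L - span + 1))
            template = template[start : start + span]
        if strand == "-":
            template = revcomp(template)
        raw = config.barcode + template
        seq = _corrupt(raw, config, rng)
        quals = np.clip(
            np.rint(rng.normal(config.base_quality_mean, config.base_quality_sd, len(seq))),
            2, 41,
        ).astype(np.uint8)
        reads.append(
            FastqRecord(
                read_id=f"sim_{config.barcode or 'NA'}_{i:06d}",
                description=f"hap={hap_idx + 1} strand={strand}",
                sequence=seq,
                qualities=quals,
            )
        )
    return reads


def write_fastq(records: list[FastqRecord], path: str | Path, header_comment: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(rec.to_fastq())


def pair_phase(genotype: DiploidGenotype, var_a: str, var_b: str) -> str:
    """True cis/trans configuration of two het variants in a genotype."""
    a1 = var_a in genotype.hap1
    b1 = var_b in genotype.hap1
    return "cis" if a1 == b1 else "trans"


def simulate_cohort(
    genotypes: list[DiploidGenotype],
    model: LocusModel,
    configs: dict[str, SimulationConfig],
    out_fastq: str | Path,
    out_truth: str | Path,
) -> None:
    """Simulate a multiplexed run: one interleaved FASTQ plus a truth table.

    ``configs`` maps sample_id to its SimulationConfig; each must carry a
    distinct non-empty barcode.  The truth TSV lists one row per (sample,
    variant) with zygosity, plus the true cis/trans configuration for every
    het variant pair — the oracle downstream tests compare against.
    """
    barcodes = [configs[g.sample_id].barcode for g in genotypes]
    if len(set(barcodes)) != len(barcodes) or "" in barcodes:
        raise ValueError("every sample needs a distinct non-empty barcode")

    all_reads: list[FastqRecord] = []
    truth_rows: list[str] = []
    for g in genotypes:
        cfg = configs[g.sample_id]
        haps = make_haplotypes(g, model)
        all_reads.extend(simulate_reads(haps, cfg))
        het = [v for v in g.variants if g.zygosity_of(v) == "het"]
        for v in g.variants:
            truth_rows.append(f"{g.sample_id}\t{v}\t{g.zygosity_of(v)}\t")
        for i, va in enumerate(het):
            for vb in het[i + 1 :]:
                truth_rows.append(
                    f"{g.sample_id}\t{va}|{vb}\tphase\t{pair_phase(g, va, vb)}"
                )
    # interleave deterministically across samples so demux has real work
    order = np.random.default_rng(
        sum(configs[g.sample_id].seed for g in genotypes) % (2**31) if genotypes else 0
    ).permutation(len(all_reads))
    write_fastq([all_reads[i] for i in order], out_fastq)
    with Path(out_truth).open("w") as fh:
        fh.write("sample_id\tvariant\trecord_type\tphase\n")
        for row in truth_rows:
            fh.write(row + "\n")


def load_cohort_spec(path: str | Path) -> list[DiploidGenotype]:
    """Read a cohort spec TSV: sample_id, hap1, hap2 (comma-separated HGVS,
    ``-`` or empty for no variants)."""
    genotypes: list[DiploidGenotype] = []
    lines = Path(path).read_text().splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if body and body[0].lower().startswith("sample_id"):
        body = body[1:]
    for raw in body:
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed cohort spec row: {raw!r}")
        sid, h1, h2 = parts[0], parts[1].strip(), parts[2].strip()

        def _split(s: str) -> tuple[str, ...]:
            return tuple(v.strip() for v in s.split(",") if v.strip() and v.strip() != "-")

        genotypes.append(DiploidGenotype(sid, _split(h1), _split(h2)))
    if not genotypes:
        raise ValueError(f"cohort spec {path} contains no samples")
    return genotypes
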