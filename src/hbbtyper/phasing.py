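"""Read-backed phasing of heterozygous variant pairs.

With full-locus amplicon reads, every informative read spans both sites
of a pair, so pairwise majority counting over spanning reads is complete
phasing evidence — no minimum-error-correction graph solver is needed.
For each unordered pair of heterozygous PASS calls, spanning reads are
partitioned by the (ref/alt, ref/alt) alleles they carry at the two
sites; the pair is called *cis* when reads overwhelmingly carry both
alternate alleles together (and both references together), *trans* when
the alternates segregate onto opposite reads, and *unphased* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .demux_align import Alignment
from .variant_caller import VariantCall

__all__ = ["PhaseEvidence", "PhaseCall", "collect_phase_evidence", "phase_pair",
           "phase_sample"]


@dataclass(frozen=True)
class PhaseEvidence:
    """Spanning-read allele counts for a het variant pair (a before b in
    genomic order): n_xy counts reads carrying allele x at a and y at b,
    with r = reference, a = alternate."""

    var_a: VariantCall
    var_b: VariantCall
    n_rr: int = 0
    n_ra: int = 0
    n_ar: int = 0
    n_aa: int = 0
    n_uninformative: int = 0

    @property
    def n_informative(self) -> int:
        return self.n_rr + self.n_ra + self.n_ar + self.n_aa


@dataclass(frozen=True)
class PhaseCall:
    var_a: VariantCall
    var_b: VariantCall
    configuration: str  # cis | trans | unphased
    support_fraction: float
    n_informative: int


def collect_phase_evidence(
    alignments: list[Alignment],
    var_a: VariantCall,
    var_b: VariantCall,
    min_base_quality: int = 15,
) -> PhaseEvidence:
    """Tally spanning-read allele pairs at two heterozygous sites.

    Only reads covering both sites with an aligned base of quality ≥
    ``min_base_quality`` at each are informative; reads carrying a base
    that is neither the reference nor the called alternate at either site
    (sequencing error or deletion) count as uninformative.
    """
    if var_a.gpos == var_b.gpos:
        raise ValueError("cannot phase a variant against itself")
    if var_a.gpos > var_b.gpos:
        var_a, var_b = var_b, var_a
    pa, pb = var_a.gpos, var_b.gpos
    counts = {"rr": 0, "ra": 0, "ar": 0, "aa": 0}
    uninf = 0
    for aln in alignments:
        ba = _base_at(aln, pa, min_base_quality)
        bb = _base_at(aln, pb, min_base_quality)
        if ba is None or bb is None:
            if aln.ref_start <= pa and aln.ref_end > pb:
                uninf += 1
            continue
        ka = "r" if ba == var_a.ref else ("a" if ba == var_a.alt else None)
        kb = "r" if bb == var_b.ref else ("a" if bb == var_b.alt else None)
        if ka is None or kb is None:
            uninf += 1
            continue
        counts[ka + kb] += 1
    return PhaseEvidence(
        var_a=var_a, var_b=var_b,
        n_rr=counts["rr"], n_ra=counts["ra"], n_ar=counts["ar"], n_aa=counts["aa"],
        n_uninformative=uninf,
    )


def _base_at(aln: Alignment, gpos: int, min_q: int) -> str | None:
    i = int(np.searchsorted(aln.ref_positions, gpos))
    if i >= aln.ref_positions.size or aln.ref_positions[i] != gpos:
        return None
    if aln.quals[i] < min_q:
        return None
    return chr(aln.bases[i])


def phase_pair(
    evidence: PhaseEvidence,
    min_informative: int = 20,
    min_support: float = 0.8,
) -> PhaseCall:
    """Majority verdict over the spanning-read partition.

    cis when (rr + aa) reads dominate, trans when (ra + ar) dominate;
    unphased when informative reads are too few or neither configuration
    reaches ``min_support``.
    """
    n = evidence.n_informative
    if n < min_informative:
        return PhaseCall(evidence.var_a, evidence.var_b, "unphased", 0.0, n)
    cis_frac = (evidence.n_rr + evidence.n_aa) / n
    trans_frac = (evidence.n_ra + evidence.n_ar) / n
    if cis_frac >= min_support:
        return PhaseCall(evidence.var_a, evidence.var_b, "cis", cis_frac, n)
    if trans_frac >= min_support:
        return PhaseCall(evidence.var_a, evidence.var_b, "trans", trans_frac, n)
    return PhaseCall(evidence.var_a, evidence.var_b, "unphased",
                     max(cis_frac, trans_frac), n)


def phase_sample(
    alignments: list[Alignment],
    calls: list[VariantCall],
    min_base_quality: int = 15,
    min_informative: int = 20,
    min_support: float = 0.8,
) -> list[PhaseCall]:
    """Phase every unordered pair of heterozygous PASS calls in a sample."""
    hets = [c for c in calls if c.is_pass and c.zygosity == "het"]
    out: list[PhaseCall] = []
    for a, b in combinations(sorted(hets, key=lambda c: c.gpos), 2):
        ev = collect_phase_evidence(alignments, a, b, min_base_quality)
        out.append(phase_pair(ev, min_informative, min_support))
    return out
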