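"""Pileup and variant calling: quality filters, VAF windows, VCF output."""

import numpy as np
import pysam
import pytest
from hypothesis import given, strategies as st

from hbbtyper.demux_align import align_read
from hbbtyper.read_simulator import (DiploidGenotype, FastqRecord,
                                     SimulationConfig, make_haplotypes,
                                     simulate_reads)
from hbbtyper.reference_model import revcomp
from hbbtyper.variant_caller import (CallerConfig, build_pileup, call_variants,
                                     classify_zygosity, write_vcf)


def _reads_to_alignments(reads, model):
    out = []
    for r in reads:
        aln = align_read(r, model)
        assert aln is not None
        out.append(aln)
    return out


def _record(seq, qual=40, read_id="r"):
    return FastqRecord(read_id=read_id, description="", sequence=seq,
                       qualities=np.full(len(seq), qual, dtype=np.uint8))


def test_hom_alt_column_counts_every_read(model):
    g = DiploidGenotype("s", hap1=("c.2T>C",), hap2=("c.2T>C",))
    h1, h2 = make_haplotypes(g, model)
    reads = [_record(h1, read_id=f"r{i}") for i in range(100)]
    pile = build_pileup(_reads_to_alignments(reads, model), model, 15)
    col = pile.column(model.c_to_g(2))
    assert col.counts["C"] == 100
    assert col.depth_pass == 100
    assert col.ref_base == "T"


def test_low_quality_bases_excluded_from_depth_pass(model):
    reads = [_record(model.sequence, qual=10)]
    pile = build_pileup(_reads_to_alignments(reads, model), model, 15)
    assert pile.depth_pass.sum() == 0
    pile = build_pileup(_reads_to_alignments(reads, model), model, 10)
    assert pile.depth_pass.sum() == len(model.sequence)


def test_pileup_strand_invariance(model):
    g = DiploidGenotype("s", hap1=("c.20A>T",), hap2=())
    h1, _ = make_haplotypes(g, model)
    fwd = [_record(h1, read_id=f"f{i}") for i in range(10)]
    rev = [_record(revcomp(h1), read_id=f"v{i}") for i in range(10)]
    p_fwd = build_pileup(_reads_to_alignments(fwd, model), model, 15)
    p_rev = build_pileup(_reads_to_alignments(rev, model), model, 15)
    assert (p_fwd.base_counts == p_rev.base_counts).all()


def test_quality_threshold_monotonicity(model):
    cfg = SimulationConfig(depth=30, seed=17)
    reads = simulate_reads((model.sequence, model.sequence), cfg)
    alns = _reads_to_alignments(reads, model)
    depths = [build_pileup(alns, model, q).depth_pass for q in (5, 15, 25)]
    assert (depths[0] >= depths[1]).all()
    assert (depths[1] >= depths[2]).all()


@pytest.mark.parametrize(
    "vaf, expected",
    [
        (0.46, "het"),  # printed het call
        (0.55, "het"),
        (0.40, "het"),  # window edge inclusive
        (0.60, "het"),
        (0.77, "hom"),
        (0.95, "hom"),
        (0.75, "hom"),  # hom boundary inclusive
        (0.70, "ambiguous"),  # in the gap between window and threshold
        (0.30, "ambiguous"),
        (0.10, "ambiguous"),
    ],
)
def test_zygosity_windows(vaf, expected):
    assert classify_zygosity(vaf) == expected


@given(st.floats(min_value=0.0, max_value=1.0))
def test_zygosity_total_function(vaf):
    assert classify_zygosity(vaf) in ("het", "hom", "ambiguous")


def test_caller_config_ordering_enforced():
    with pytest.raises(ValueError):
        CallerConfig(het_low=0.7, het_high=0.6)
    with pytest.raises(ValueError):
        CallerConfig(hom_threshold=0.5)


def _synthetic_pileup(model, gpos, alt, n_ref, n_alt, config):
    """Pileup with a single mixed column, built from bare reference reads
    plus single-substitution reads."""
    from hbbtyper.variant_caller import Pileup

    pile = Pileup(model, config.min_base_quality)
    ref_idx = "ACGT".index(model.sequence[gpos])
    alt_idx = "ACGT".index(alt)
    pile.base_counts[gpos, ref_idx] = n_ref
    pile.base_counts[gpos, alt_idx] = n_alt
    return pile


@pytest.mark.parametrize(
    "n_ref, n_alt, expected_zyg, expected_filter",
    [
        (888, 757, "het", "PASS"),  # VAF 0.46 at depth 1645
        (230, 770, "hom", "PASS"),  # VAF 0.77
        (600, 400, "het", "PASS"),  # VAF 0.40 window edge
        (300, 700, "ambiguous", "ambiguous_vaf"),  # VAF 0.70 in the gap
        (90, 60, "het", "low_depth"),  # depth 150 < 200
    ],
)
def test_call_filters_and_zygosity(model, n_ref, n_alt, expected_zyg,
                                   expected_filter):
    cfg = CallerConfig()
    gpos = model.c_to_g(20)
    pile = _synthetic_pileup(model, gpos, "T", n_ref, n_alt, cfg)
    calls = call_variants(pile, cfg)
    assert len(calls) == 1
    call = calls[0]
    assert call.gpos == gpos and call.alt == "T"
    assert call.zygosity == expected_zyg
    assert call.filter == expected_filter
    assert call.vaf == pytest.approx(n_alt / (n_ref + n_alt))


def test_zero_error_calls_equal_injected_variants_exactly(model):
    """Oracle equivalence: on error-free reads the PASS call set matches
    the injected variants in position, allele and zygosity, nothing else."""
    g = DiploidGenotype("s", hap1=("c.20A>T", "c.9T>C"), hap2=("c.9T>C",))
    haps = make_haplotypes(g, model)
    cfg = SimulationConfig(depth=400, sub_rate=0, ins_rate=0, del_rate=0, seed=13)
    reads = simulate_reads(haps, cfg)
    alns = _reads_to_alignments(reads, model)
    calls = call_variants(build_pileup(alns, model, 15), CallerConfig())
    passing = {(c.gpos, c.alt, c.zygosity) for c in calls if c.is_pass}
    assert passing == {
        (model.c_to_g(20), "T", "het"),
        (model.c_to_g(9), "C", "hom"),
    }
    assert all(c.is_pass for c in calls)


def test_mismatched_quality_threshold_rejected(model):
    pile = build_pileup([], model, 20)
    with pytest.raises(ValueError, match="quality threshold"):
        call_variants(pile, CallerConfig(min_base_quality=15))


def test_vcf_output_roundtrips_through_pysam(model, tmp_path):
    cfg = CallerConfig()
    gpos_het = model.c_to_g(20)
    gpos_hom = model.c_to_g(9)
    pile = _synthetic_pileup(model, gpos_het, "T", 500, 500, cfg)
    alt_idx = "ACGT".index("C")
    pile.base_counts[gpos_hom, alt_idx] = 990
    calls = call_variants(pile, cfg)
    path = tmp_path / "calls.vcf"
    write_vcf(calls, model, "sampleA", path,
              annotations={gpos_het: "c.20A>T|p.Glu7Val|missense"})
    with pysam.VariantFile(str(path)) as vf:
        recs = list(vf)
    by_pos = {r.pos: r for r in recs}
    het = by_pos[gpos_het + 1]
    assert het.ref == "A" and het.alts == ("T",)
    assert het.samples["sampleA"]["GT"] == (0, 1)
    assert het.info["CSQ"] == "c.20A>T|p.Glu7Val|missense"
    hom = by_pos[gpos_hom + 1]
    assert hom.samples["sampleA"]["GT"] == (1, 1)


def test_empty_call_set_gives_header_only_vcf(model, tmp_path):
    path = tmp_path / "empty.vcf"
    write_vcf([], model, "s", path)
    with pysam.VariantFile(str(path)) as vf:
        assert list(vf) == []
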