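"""Read-backed phasing: evidence collection, majority verdicts, recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hbbtyper.demux_align import align_read
from hbbtyper.phasing import (PhaseEvidence, collect_phase_evidence, phase_pair,
                              phase_sample)
from hbbtyper.read_simulator import (DiploidGenotype, FastqRecord,
                                     SimulationConfig, make_haplotypes,
                                     simulate_reads)
from hbbtyper.variant_caller import VariantCall


def _call(model, hgvs, alt):
    from hbbtyper.annotation import parse_hgvs_c

    v = parse_hgvs_c(hgvs, model)
    return VariantCall(gpos=v.gpos, ref=v.ref, alt=v.alt, depth=1000,
                       alt_count=500, vaf=0.5, zygosity="het", filter="PASS")


def _alignments(model, reads):
    out = []
    for r in reads:
        aln = align_read(r, model)
        if aln is not None:
            out.append(aln)
    return out


def test_evidence_partition_pure_cis_and_ref(model):
    g_cis = DiploidGenotype("s", hap1=("c.20A>T", "c.114G>A"), hap2=())
    haps = make_haplotypes(g_cis, model)
    cfg = SimulationConfig(depth=100, sub_rate=0, ins_rate=0, del_rate=0, seed=3)
    alns = _alignments(model, simulate_reads(haps, cfg))
    va, vb = _call(model, "c.20A>T", "T"), _call(model, "c.114G>A", "A")
    ev = collect_phase_evidence(alns, va, vb, 15)
    assert ev.n_ra == ev.n_ar == 0
    # reads failing the Q15 gate at either site are counted uninformative
    assert ev.n_aa + ev.n_rr + ev.n_uninformative == len(alns)
    assert ev.n_aa > 0 and ev.n_rr > 0  # both haplotypes sampled


def test_trans_simulation_yields_only_discordant_reads(model):
    g = DiploidGenotype("s", hap1=("c.20A>T",), hap2=("c.114G>A",))
    haps = make_haplotypes(g, model)
    cfg = SimulationConfig(depth=100, sub_rate=0, ins_rate=0, del_rate=0, seed=4)
    alns = _alignments(model, simulate_reads(haps, cfg))
    ev = collect_phase_evidence(alns, _call(model, "c.20A>T", "T"),
                                _call(model, "c.114G>A", "A"), 15)
    assert ev.n_aa == ev.n_rr == 0
    assert ev.n_ra + ev.n_ar + ev.n_uninformative == len(alns)
    assert ev.n_informative >= 0.5 * len(alns)
    verdict = phase_pair(ev)
    assert verdict.configuration == "trans"
    assert verdict.support_fraction == 1.0


def test_no_spanning_reads_gives_zero_counts(model):
    va, vb = _call(model, "c.20A>T", "T"), _call(model, "c.114G>A", "A")
    ev = collect_phase_evidence([], va, vb, 15)
    assert ev.n_informative == 0
    assert phase_pair(ev).configuration == "unphased"


def test_identical_positions_rejected(model):
    va = _call(model, "c.20A>T", "T")
    with pytest.raises(ValueError):
        collect_phase_evidence([], va, va, 15)


@pytest.mark.parametrize(
    "counts, expected, support",
    [
        (dict(n_rr=50, n_aa=50, n_ra=0, n_ar=0), "cis", 1.0),
        (dict(n_ra=48, n_ar=47, n_rr=3, n_aa=2), "trans", 0.95),
        (dict(n_rr=5, n_aa=5, n_ra=0, n_ar=0), "unphased", 0.0),  # < min_informative
        (dict(n_rr=30, n_ra=30, n_ar=0, n_aa=0), "unphased", 0.5),  # no majority
    ],
)
def test_phase_pair_majority_rule(model, counts, expected, support):
    va, vb = _call(model, "c.20A>T", "T"), _call(model, "c.114G>A", "A")
    ev = PhaseEvidence(var_a=va, var_b=vb, **counts)
    verdict = phase_pair(ev)
    assert verdict.configuration == expected
    assert verdict.support_fraction == pytest.approx(support)


@given(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200),
    st.integers(0, 200),
)
def test_phase_pair_matches_independent_recount(model, rr, ra, ar, aa):
    """The verdict equals exhaustive majority counting recomputed here."""
    va, vb = _call(model, "c.20A>T", "T"), _call(model, "c.114G>A", "A")
    ev = PhaseEvidence(var_a=va, var_b=vb, n_rr=rr, n_ra=ra, n_ar=ar, n_aa=aa)
    verdict = phase_pair(ev, min_informative=20, min_support=0.8)
    n = rr + ra + ar + aa
    if n < 20:
        expected = "unphased"
    elif (rr + aa) / n >= 0.8:
        expected = "cis"
    elif (ra + ar) / n >= 0.8:
        expected = "trans"
    else:
        expected = "unphased"
    assert verdict.configuration == expected


def test_swapping_variant_order_swaps_counts_keeps_verdict(model):
    g = DiploidGenotype("s", hap1=("c.20A>T",), hap2=("c.114G>A",))
    haps = make_haplotypes(g, model)
    cfg = SimulationConfig(depth=60, sub_rate=0.01, ins_rate=0, del_rate=0, seed=5)
    alns = _alignments(model, simulate_reads(haps, cfg))
    va, vb = _call(model, "c.20A>T", "T"), _call(model, "c.114G>A", "A")
    ev_ab = collect_phase_evidence(alns, va, vb, 15)
    ev_ba = collect_phase_evidence(alns, vb, va, 15)
    # order convention is ascending genomic position, so both give (a, b)
    assert (ev_ab.n_ra, ev_ab.n_ar) == (ev_ba.n_ra, ev_ba.n_ar)
    assert phase_pair(ev_ab).configuration == phase_pair(ev_ba).configuration


def test_phase_sample_enumerates_het_pairs_and_skips_homs(model):
    g = DiploidGenotype("s", hap1=("c.20A>T", "c.9T>C"), hap2=("c.114G>A", "c.9T>C"))
    haps = make_haplotypes(g, model)
    cfg = SimulationConfig(depth=80, sub_rate=0, ins_rate=0, del_rate=0, seed=6)
    alns = _alignments(model, simulate_reads(haps, cfg))
    calls = [
        _call(model, "c.20A>T", "T"),
        _call(model, "c.114G>A", "A"),
        VariantCall(gpos=model.c_to_g(9), ref="T", alt="C", depth=80, alt_count=80,
                    vaf=1.0, zygosity="hom", filter="PASS"),
    ]
    phases = phase_sample(alns, calls)
    assert len(phases) == 1  # only the het/het pair
    assert phases[0].configuration == "trans"


def test_single_het_gives_empty_phase_list(model):
    phases = phase_sample([], [_call(model, "c.20A>T", "T")])
    assert phases == []


def test_recovery_across_seeds_at_depth(model):
    """Simulated cis and trans configurations are recovered under the
    default error model across seeds."""
    for seed in range(5):
        for config, g in [
            ("trans", DiploidGenotype("s", ("c.20A>T",), ("c.114G>A",))),
            ("cis", DiploidGenotype("s", ("c.20A>T", "c.114G>A"), ())),
        ]:
            haps = make_haplotypes(g, model)
            cfg = SimulationConfig(depth=200, seed=seed * 7 + 1)
            alns = _alignments(model, simulate_reads(haps, cfg))
            ev = collect_phase_evidence(alns, _call(model, "c.20A>T", "T"),
                                        _call(model, "c.114G>A", "A"), 15)
            assert phase_pair(ev).configuration == config
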