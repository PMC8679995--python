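"""Demultiplexing and alignment: assignment rules, mismatch purity, SAM I/O."""

import numpy as np
import pysam
import pytest

from hbbtyper.cohorts import barcodes_path
from hbbtyper.demux_align import (align_read, demultiplex, load_barcodes,
                                  read_fastq, semiglobal_align, write_sam)
from hbbtyper.read_simulator import (DiploidGenotype, FastqRecord,
                                     SimulationConfig, make_haplotypes,
                                     simulate_reads)
from hbbtyper.reference_model import revcomp


def _record(seq, read_id="r1", qual=40):
    return FastqRecord(read_id=read_id, description="",
                       sequence=seq,
                       qualities=np.full(len(seq), qual, dtype=np.uint8))


# ----------------------------------------------------------------------
# demultiplexing
# ----------------------------------------------------------------------

def test_exact_prefix_assignment(model):
    wl = load_barcodes(barcodes_path())
    sid, bc = next(iter(wl.items()))
    read = _record(bc + model.sequence)
    res = demultiplex([read], wl, max_edit_distance=2)
    assert len(res.assigned[sid]) == 1
    # barcode trimmed from the assigned read
    assert res.assigned[sid][0].sequence == model.sequence


def test_ambiguous_barcodes_go_unassigned():
    wl = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAT"}
    read = _record("AAAAAAAAAA" + "C" * 300)
    res = demultiplex([read], wl, max_edit_distance=2)
    assert res.unassigned == [read]
    assert res.counts["unassigned"] == 1


def test_demux_conservation_and_accuracy_on_noisy_cohort(model):
    """≥95% of default-error reads land in their true sample bin."""
    wl = load_barcodes(barcodes_path())
    sids = list(wl)[:3]
    reads, truth = [], []
    for i, sid in enumerate(sids):
        cfg = SimulationConfig(depth=100, barcode=wl[sid], seed=100 + i)
        for r in simulate_reads((model.sequence, model.sequence), cfg):
            reads.append(r)
            truth.append(sid)
    res = demultiplex(reads, wl, max_edit_distance=2)
    assert res.n_total == len(reads)  # conservation
    correct = 0
    for sid in sids:
        ids = {r.read_id for r in res.assigned[sid]}
        correct += sum(1 for r, t in zip(reads, truth) if t == sid and r.read_id in ids)
    assert correct / len(reads) >= 0.95


def test_empty_whitelist_rejected():
    with pytest.raises(ValueError):
        demultiplex([], {}, 2)


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------

def test_error_free_read_aligns_perfectly(model):
    aln = align_read(_record(model.sequence), model)
    assert aln.identity == 1.0
    assert aln.cigar == f"{len(model.sequence)}="
    assert aln.strand == "+"
    assert (aln.ref_start, aln.ref_end) == (0, len(model.sequence))


def test_single_variant_read_has_one_mismatch_at_the_variant(model):
    g = DiploidGenotype("s", hap1=("c.20A>T",), hap2=())
    h1, _ = make_haplotypes(g, model)
    aln = align_read(_record(h1), model)
    mismatch_cols = _mismatch_positions(aln)
    assert mismatch_cols == [model.c_to_g(20)]


def test_reverse_complement_read_gives_same_mismatch_columns(model):
    g = DiploidGenotype("s", hap1=("c.20A>T",), hap2=())
    h1, _ = make_haplotypes(g, model)
    fwd = align_read(_record(h1), model)
    rev = align_read(_record(revcomp(h1)), model)
    assert rev.strand == "-"
    assert (rev.ref_start, rev.ref_end) == (fwd.ref_start, fwd.ref_end)
    assert _mismatch_positions(rev) == _mismatch_positions(fwd)


def _mismatch_positions(aln):
    out = []
    rp, i = aln.ref_start, 0
    num = ""
    for ch in aln.cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "X":
            out.extend(range(rp, rp + n))
        if ch in ("=", "X", "D"):
            rp += n
    return out


def test_short_and_garbage_reads_rejected(model):
    assert align_read(_record("ACGT" * 10), model) is None  # below min length
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), 800))
    assert align_read(_record(junk), model, min_identity=0.7) is None


def test_zero_error_mismatch_purity_across_variants(model):
    """On error-free reads, mismatch columns equal the injected variant
    sites exactly — no spurious columns."""
    g = DiploidGenotype("s", hap1=("c.20A>T", "c.9T>C"), hap2=())
    h1, _ = make_haplotypes(g, model)
    aln = align_read(_record(h1), model)
    assert set(_mismatch_positions(aln)) == {model.c_to_g(9), model.c_to_g(20)}


def test_builtin_and_edlib_backends_agree_on_mismatch_columns(model):
    g = DiploidGenotype("s", hap1=("c.114G>A",), hap2=())
    h1, _ = make_haplotypes(g, model)
    cfg = SimulationConfig(depth=5, sub_rate=0.01, ins_rate=0.002, del_rate=0.002,
                           seed=21)
    for read in simulate_reads((h1, h1), cfg):
        a_ed = align_read(read, model, backend="edlib")
        a_bi = align_read(read, model, backend="builtin")
        assert a_ed is not None and a_bi is not None
        assert a_ed.strand == a_bi.strand
        # both must see the injected variant site as a mismatch
        assert model.c_to_g(114) in _mismatch_positions(a_ed)
        assert model.c_to_g(114) in _mismatch_positions(a_bi)


def test_semiglobal_align_affine_gap_scores():
    score, cigar, start = semiglobal_align("ACGTACGT", "TTACGTACGTTT")
    assert (score, cigar, start) == (16, "8=", 2)
    score, cigar, _ = semiglobal_align("ACGGACGT", "TTACGTACGTTT")
    assert cigar == "3=1X4="
    # a single 2-base insertion: 8 matches, one gap open, two extensions
    score2, cigar2, _ = semiglobal_align("ACGTAAACGT", "TTACGTACGTTT")
    assert score2 == 8 * 2 - 4 - 2 * 2
    assert cigar2 in ("5=2I3=", "4=2I4=", "3=2I5=")


# ----------------------------------------------------------------------
# SAM output
# ----------------------------------------------------------------------

def test_sam_roundtrip_preserves_cigar_and_positions(model, tmp_path):
    g = DiploidGenotype("s", hap1=("c.20A>T",), hap2=())
    h1, _ = make_haplotypes(g, model)
    aln_fwd = align_read(_record(h1, "fwd"), model, sample_id="s")
    aln_rev = align_read(_record(revcomp(h1), "rev"), model, sample_id="s")
    path = tmp_path / "out.sam"
    write_sam([aln_fwd, aln_rev], model, path,
              unmapped=[_record("ACGT" * 60, "junk")])
    with pysam.AlignmentFile(str(path)) as fh:
        assert fh.header.nreferences == 1
        assert fh.header.get_reference_length(model.locus_name) == len(model.sequence)
        recs = list(fh)
    assert len(recs) == 3
    by_name = {r.query_name: r for r in recs}
    assert by_name["fwd"].reference_start == aln_fwd.ref_start
    assert by_name["fwd"].cigarstring == aln_fwd.cigar
    assert by_name["rev"].is_reverse
    assert by_name["junk"].is_unmapped


def test_fastq_roundtrip(model, tmp_path):
    from hbbtyper.read_simulator import write_fastq

    cfg = SimulationConfig(depth=5, seed=2, barcode="ACGTACGTACGTACGT")
    reads = simulate_reads((model.sequence, model.sequence), cfg)
    path = tmp_path / "r.fastq"
    write_fastq(reads, path)
    back = read_fastq(path)
    assert [r.sequence for r in back] == [r.sequence for r in reads]
    assert all((a.qualities == b.qualities).all() for a, b in zip(back, reads))
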