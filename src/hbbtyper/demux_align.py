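"""Barcode demultiplexing and single-locus read alignment.

Reads are binned to samples by edit-distance matching of whitelist
barcodes against a window at the read start (either barcode orientation);
ambiguous or unmatched reads go to an unassigned bin.  Alignment is
pairwise semi-global against the one short locus — a general-purpose
mapper is unnecessary for a single amplicon.  The default engine is
edlib (fast bit-parallel edit-distance alignment with a full path);
a self-contained affine-gap (Gotoh) aligner is provided both as an
alternative backend and as an independent cross-check in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pysam

from .read_simulator import FastqRecord
from .reference_model import LocusModel, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "DemuxResult",
    "read_fastq",
    "load_barcodes",
    "demultiplex",
    "align_read",
    "align_sample",
    "write_sam",
    "semiglobal_align",
]


# ----------------------------------------------------------------------
# FASTQ / barcode I/O
# ----------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[FastqRecord]:
    records: list[FastqRecord] = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            quals = np.array(entry.get_quality_array() or [], dtype=np.uint8)
            records.append(
                FastqRecord(
                    read_id=entry.name,
                    description=entry.comment or "",
                    sequence=entry.sequence,
                    qualities=quals,
                )
            )
    return records


def load_barcodes(path: str | Path) -> dict[str, str]:
    """Whitelist TSV (sample_id, barcode) → ordered mapping."""
    out: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for raw in lines:
        if not raw.strip() or raw.startswith("#") or raw.lower().startswith("sample_id"):
            continue
        sid, bc = raw.split("\t")[:2]
        if sid in out:
            raise ValueError(f"duplicate sample id {sid} in barcode whitelist")
        out[sid] = bc.strip().upper()
    if not out:
        raise ValueError(f"barcode whitelist {path} is empty")
    bcs = list(out.values())
    if len(set(bcs)) != len(bcs):
        raise ValueError("barcodes must be unique")
    if len({len(b) for b in bcs}) != 1:
        raise ValueError("barcodes must have equal length")
    return out


# ----------------------------------------------------------------------
# demultiplexing
# ----------------------------------------------------------------------

@dataclass
class DemuxResult:
    assigned: dict[str, list[FastqRecord]]
    unassigned: list[FastqRecord]
    counts: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.assigned.values()) + len(self.unassigned)


def demultiplex(
    reads: list[FastqRecord],
    whitelist: dict[str, str],
    max_edit_distance: int = 2,
    window_pad: int = 10,
) -> DemuxResult:
    """Assign reads to samples by barcode prefix matching.

    A read is assigned to a sample iff exactly one whitelist barcode
    (in either orientation) matches within ``max_edit_distance`` of the
    read's first ``barcode_length + window_pad`` bases; the matched prefix
    is trimmed from the assigned read.  Ties (two barcodes within the
    threshold) and misses go to the unassigned bin.
    """
    if not whitelist:
        raise ValueError("empty barcode whitelist")
    bc_len = len(next(iter(whitelist.values())))
    window = bc_len + window_pad
    probes = {
        sid: (bc, revcomp(bc)) for sid, bc in whitelist.items()
    }
    assigned: dict[str, list[FastqRecord]] = {sid: [] for sid in whitelist}
    unassigned: list[FastqRecord] = []

    for read in reads:
        prefix = read.sequence[:window]
        hits: list[tuple[int, str, int]] = []  # (distance, sample, trim_end)
        for sid, (fwd, rc) in probes.items():
            best: tuple[int, int] | None = None
            for probe in (fwd, rc):
                res = edlib.align(probe, prefix, mode="HW", task="locations",
                                  k=max_edit_distance)
                if res["editDistance"] != -1:
                    end = res["locations"][0][1] + 1
                    if best is None or res["editDistance"] < best[0]:
                        best = (res["editDistance"], end)
            if best is not None:
                hits.append((best[0], sid, best[1]))
        if len(hits) == 1:
            d, sid, trim = hits[0]
            assigned[sid].append(
                FastqRecord(
                    read_id=read.read_id,
                    description=read.description,
                    sequence=read.sequence[trim:],
                    qualities=read.qualities[trim:],
                )
            )
        else:
            unassigned.append(read)

    counts = {sid: len(v) for sid, v in assigned.items()}
    counts["unassigned"] = len(unassigned)
    logger.info("demultiplexed %d reads: %s", len(reads), counts)
    return DemuxResult(assigned=assigned, unassigned=unassigned, counts=counts)


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------

@dataclass
class Alignment:
    """A read aligned to the locus, reoriented to the reference strand.

    ``ref_positions``/``bases``/``quals`` are parallel arrays over the
    aligned (non-gap) read bases; ``deleted_ref`` lists reference positions
    covered by deletions; ``insertions`` lists (anchor_ref_pos, length).
    """

    read_id: str
    sample_id: str
    strand: str
    ref_start: int
    ref_end: int
    cigar: str
    identity: float
    ref_positions: np.ndarray = field(repr=False)
    bases: np.ndarray = field(repr=False)  # uint8 ASCII codes
    quals: np.ndarray = field(repr=False)
    sequence: str = field(default="", repr=False)
    full_quals: np.ndarray | None = field(default=None, repr=False)


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def align_read(
    read: FastqRecord,
    model: LocusModel,
    sample_id: str = "",
    min_read_length: int = 200,
    min_identity: float = 0.7,
    backend: str = "edlib",
) -> Alignment | None:
    """Best-strand semi-global alignment of one read against the locus.

    Returns ``None`` (a counted rejection, not an error) for reads shorter
    than ``min_read_length`` or aligning below ``min_identity``.
    """
    if len(read.sequence) < min_read_length:
        return None
    ref = model.sequence
    fwd_d = _distance(read.sequence, ref, backend)
    rc_seq = revcomp(read.sequence)
    rev_d = _distance(rc_seq, ref, backend)
    if rev_d < fwd_d:
        strand, seq = "-", rc_seq
        quals = read.qualities[::-1].copy()
    else:
        strand, seq = "+", read.sequence
        quals = read.qualities.copy()

    if backend == "edlib":
        res = edlib.align(seq, ref, mode="HW", task="path")
        cigar = res["cigar"]
        ref_start = res["locations"][0][0]
    elif backend == "builtin":
        _, cigar, ref_start = semiglobal_align(seq, ref)
    else:
        raise ValueError(f"unknown alignment backend {backend!r}")

    ops = _parse_cigar(cigar)
    n_cols = sum(n for n, _ in ops)
    n_match = sum(n for n, op in ops if op == "=")
    identity = n_match / n_cols if n_cols else 0.0
    if identity < min_identity:
        return None

    ref_pos_list = []
    base_idx_list = []
    deleted = []
    insertions = []
    rp, qp = ref_start, 0
    for n, op in ops:
        if op in ("=", "X", "M"):
            ref_pos_list.append(np.arange(rp, rp + n, dtype=np.int32))
            base_idx_list.append(np.arange(qp, qp + n, dtype=np.int32))
            rp += n
            qp += n
        elif op == "D":
            deleted.append(np.arange(rp, rp + n, dtype=np.int32))
            rp += n
        elif op == "I":
            insertions.append((rp, n))
            qp += n
        else:
            raise ValueError(f"unexpected cigar op {op}")
    ref_positions = np.concatenate(ref_pos_list) if ref_pos_list else np.empty(0, np.int32)
    base_idx = np.concatenate(base_idx_list) if base_idx_list else np.empty(0, np.int32)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    aln = Alignment(
        read_id=read.read_id,
        sample_id=sample_id,
        strand=strand,
        ref_start=ref_start,
        ref_end=rp,
        cigar=cigar,
        identity=identity,
        ref_positions=ref_positions,
        bases=seq_arr[base_idx],
        quals=quals[base_idx] if quals.size else np.full(base_idx.size, 40, np.uint8),
        sequence=seq,
        full_quals=quals,
    )
    aln.deleted_ref = np.concatenate(deleted) if deleted else np.empty(0, np.int32)
    aln.insertions = insertions
    return aln


def _distance(query: str, ref: str, backend: str) -> int:
    if backend == "builtin":
        score, _, _ = semiglobal_align(query, ref)
        return -score  # lower is better for comparison purposes
    return edlib.align(query, ref, mode="HW", task="distance")["editDistance"]


def align_sample(
    reads: list[FastqRecord],
    model: LocusModel,
    sample_id: str = "",
    **kwargs,
) -> tuple[list[Alignment], int]:
    """Align a sample's reads; returns (alignments, n_rejected)."""
    alignments = []
    rejected = 0
    for read in reads:
        aln = align_read(read, model, sample_id=sample_id, **kwargs)
        if aln is None:
            rejected += 1
        else:
            alignments.append(aln)
    return alignments, rejected


# ----------------------------------------------------------------------
# built-in affine-gap semi-global aligner (Gotoh), numpy row recurrence
# ----------------------------------------------------------------------

def semiglobal_align(
    query: str,
    ref: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -4,
    gap_extend: int = -2,
) -> tuple[int, str, int]:
    """Affine-gap semi-global alignment: the query is consumed entirely,
    gaps at the reference ends are free.  Returns (score, cigar, ref_start).

    The dynamic programme is the standard three-matrix Gotoh recurrence
    (M: residue aligned; I: gap in reference, query base consumed; D: gap
    in query, reference base consumed), vectorised along the query axis.
    The in-row dependency of I is resolved with a running-maximum scan.
    Intended for the short amplicon setting (locus ~1 kb) and as an
    independent check on the edlib path.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    nq, nr = q.size, r.size
    NEG = -(10**9)
    go, ge = gap_open, gap_extend

    M = np.full((nr + 1, nq + 1), NEG, dtype=np.int64)
    I = np.full((nr + 1, nq + 1), NEG, dtype=np.int64)
    D = np.full((nr + 1, nq + 1), NEG, dtype=np.int64)
    M[:, 0] = 0  # free leading reference gap: a path may start at any ref row
    I[0, 1:] = go + ge * np.arange(1, nq + 1)

    sub = np.where(r[:, None] == q[None, :], match, mismatch)
    js = np.arange(nq + 1)
    for i in range(1, nr + 1):
        diag = np.maximum(np.maximum(M[i - 1, :-1], I[i - 1, :-1]), D[i - 1, :-1])
        M[i, 1:] = diag + sub[i - 1]
        D[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], I[i - 1, 1:]) + go + ge, D[i - 1, 1:] + ge
        )
        # I[i, j] = max_{k<j} (bestMD[i, k] + go + ge*(j-k)); running max over
        # bestMD - ge*k turns the horizontal recurrence into one scan.
        best_md = np.maximum(M[i], D[i])
        run = np.maximum.accumulate(best_md - ge * js)
        I[i, 1:] = go + ge * js[1:] + run[:-1]

    final = np.maximum(np.maximum(M[:, nq], I[:, nq]), D[:, nq])
    end_row = int(np.argmax(final))
    score = int(final[end_row])

    # traceback by score consistency (no pointer matrices needed)
    i, j = end_row, nq
    state = int(np.argmax([M[i, j], I[i, j], D[i, j]]))
    ops: list[str] = []
    while j > 0:
        if state == 0:  # M: diagonal
            ops.append("=" if r[i - 1] == q[j - 1] else "X")
            i -= 1
            j -= 1
            if j == 0:
                break
            state = int(np.argmax([M[i, j], I[i, j], D[i, j]]))
        elif state == 1:  # I: gap in ref
            ops.append("I")
            if I[i, j] == I[i, j - 1] + ge:
                state = 1
            else:
                state = 0 if M[i, j - 1] >= D[i, j - 1] else 2
            j -= 1
        else:  # D: gap in query
            ops.append("D")
            if D[i, j] == D[i - 1, j] + ge:
                state = 2
            else:
                state = 0 if M[i - 1, j] >= I[i - 1, j] else 1
            i -= 1
    ref_start = i
    ops.reverse()
    # run-length encode
    cigar_parts = []
    for op in ops:
        if cigar_parts and cigar_parts[-1][1] == op:
            cigar_parts[-1][0] += 1
        else:
            cigar_parts.append([1, op])
    cigar = "".join(f"{n}{op}" for n, op in cigar_parts)
    return score, cigar, ref_start


# ----------------------------------------------------------------------
# SAM output
# ----------------------------------------------------------------------

def write_sam(
    alignments: list[Alignment],
    model: LocusModel,
    path: str | Path,
    unmapped: list[FastqRecord] | None = None,
) -> None:
    """Write alignments (and optionally unmapped reads) as a SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": model.locus_name, "LN": len(model.sequence)}],
        "PG": [{"ID": "hbbtyper", "PN": "hbbtyper"}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.sequence
            seg.reference_id = 0
            seg.reference_start = aln.ref_start
            seg.mapping_quality = 60
            seg.flag = 16 if aln.strand == "-" else 0
            seg.cigarstring = _clip_terminal_insertions(aln.cigar)
            if aln.full_quals is not None and aln.full_quals.size:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in aln.full_quals)
                )
            seg.set_tag("RG", aln.sample_id or "NA")
            out.write(seg)
        for read in unmapped or []:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.sequence
            seg.flag = 4
            seg.reference_id = -1
            seg.reference_start = -1
            if read.qualities.size:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.qualities)
                )
            out.write(seg)


def _clip_terminal_insertions(cigar: str) -> str:
    """SAM convention: unaligned read ends are soft clips, not insertions."""
    ops = _parse_cigar(cigar)
    if ops and ops[0][1] == "I":
        ops[0] = (ops[0][0], "S")
    if ops and ops[-1][1] == "I":
        ops[-1] = (ops[-1][0], "S")
    return "".join(f"{n}{op}" for n, op in ops)
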