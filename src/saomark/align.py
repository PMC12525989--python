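"""Read-to-reference alignment used by the consensus stage.

Alignments are global in the read and local in the reference (free end
gaps on the reference flanks), with affine gap penalties. Callers bound
the reference to a seed-anchored segment of ``read length + 2 * band``,
which is what makes the overall procedure banded; the dynamic program on
that segment is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2


@dataclass
class Alignment:
    """CIGAR-style alignment of a read against a reference segment.

    ops are (op, length) with op in {'M', 'I', 'D'}: M aligned columns
    (match or mismatch), I read bases absent from the reference,
    D reference bases absent from the read. ref_start/ref_end are 0-based
    on the segment that was aligned.
    """

    score: float
    ref_start: int
    ref_end: int
    ops: list[tuple[str, int]]


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    # free end gaps on the reference side only (glocal)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            a.open_end_deletion_score = 0.0
            a.extend_end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            a.query_end_open_gap_score = 0.0
            a.query_end_extend_gap_score = 0.0
    return a


_ALIGNER = _make_aligner()


def banded_align(read_seq: str, ref_seq: str, band: int = 25) -> Alignment:
    """Align a read (global) against a reference segment (local).

    ``band`` documents the indel budget the caller used to size
    ``ref_seq``; the DP itself explores the full segment, so results on a
    properly sized segment equal the unbanded optimum. Tie-breaking is the
    aligner's deterministic first-traceback order.
    """
    aln = _ALIGNER.align(ref_seq, read_seq)[0]
    tgt_blocks, qry_blocks = aln.aligned
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    ref_start = int(tgt_blocks[0][0]) if len(tgt_blocks) else 0
    prev_t = ref_start
    prev_q = int(qry_blocks[0][0]) if len(qry_blocks) else 0
    push("I", prev_q)  # read bases hanging before the reference start
    for (t0, t1), (q0, q1) in zip(tgt_blocks, qry_blocks):
        push("D", int(t0) - prev_t)
        push("I", int(q0) - prev_q)
        push("M", int(t1) - int(t0))
        prev_t, prev_q = int(t1), int(q1)
    read_len = len(read_seq)
    push("I", read_len - prev_q)  # read bases hanging past the reference end
    return Alignment(float(aln.score), ref_start, prev_t, ops)


def cigar_string(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)
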