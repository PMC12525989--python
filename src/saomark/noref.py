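"""Assembly-free recovery of target-species oligo sequences.

Short reads from the target (wild) species are anchored to windows of the
reference around the retained single-copy oligos, piled up via a banded
glocal alignment, and summarized into a reference-projected majority
consensus. Differences between consensus and reference become a SNP/InDel
catalog, and each retained oligo is rewritten with the target alleles --
no genome assembly involved.

Overlapping per-oligo windows (oligo +/- flank) are merged into disjoint
consensus regions before read assignment, so each read contributes
evidence exactly once while every oligo still sees the full local depth.
Columns without a confident majority keep the reference base and emit no
variant, so sparsely covered stretches degrade to "no call" rather than
to wrong calls.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, banded_align
from .oligo_select import Oligo
from .seqio import Genome, Read, reverse_complement

logger = logging.getLogger(__name__)

SNP = "SNP"
INS = "INS"
DEL = "DEL"

_SYMBOLS = "ACGT-"
_SYM_IDX = {c: i for i, c in enumerate(_SYMBOLS)}


@dataclass
class Window:
    """A consensus region: one or more retained oligos plus flanks, merged
    with any overlapping neighbors so regions are disjoint."""

    chrom: str
    start: int  # 0-based, region proper
    end: int
    ref_seq: str
    oligos: list[Oligo] = field(default_factory=list)
    pad_start: int = 0  # start of the padded alignment context
    pad_seq: str = ""

    def __post_init__(self) -> None:
        if not self.pad_seq:
            self.pad_seq = self.ref_seq
            self.pad_start = self.start


@dataclass
class AnchoredRead:
    """A read placed on a window: orientation-resolved sequence plus its
    alignment to a segment of the window's padded reference context."""

    read_id: str
    seq: str  # oriented to the reference + strand
    strand: str
    col_start: int  # window column of the first aligned reference base (may be < 0 in the pad)
    aln: Alignment


@dataclass
class Consensus:
    """Reference-projected majority consensus over one window."""

    window: Window
    calls: list[str]  # per reference column: A/C/G/T or '-' (deleted)
    insertions: dict[int, str]  # junction column -> sequence inserted before it
    counts: np.ndarray  # 5 x W support counts (A, C, G, T, deletion)
    coverage: np.ndarray  # per-column depth (sum of counts)
    ins_support: dict[int, tuple[int, int]]  # junction -> (n_supporting, n_spanning)
    low_conf: np.ndarray  # columns where no confident call was possible
    min_cov: int
    complete: bool  # every column of every source oligo interval has depth >= min_cov

    @property
    def consensus_seq(self) -> str:
        parts: list[str] = []
        n = len(self.calls)
        for c in range(n):
            if c in self.insertions:
                parts.append(self.insertions[c])
            if self.calls[c] != "-":
                parts.append(self.calls[c])
        if n in self.insertions:
            parts.append(self.insertions[n])
        return "".join(parts)

    def interval_complete(self, start: int, end: int) -> bool:
        """Coverage completeness of a chromosome interval inside the window."""
        c0 = max(0, start - self.window.start)
        c1 = min(len(self.calls), end - self.window.start)
        return bool((self.coverage[c0:c1] >= self.min_cov).all())


@dataclass
class Variant:
    """A SNP or anchored InDel between target consensus and reference,
    left-normalized, with 1-based position (VCF convention)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vclass: str
    depth: int
    allele_fraction: float

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval of reference bases involved."""
        return self.pos0, self.pos0 + len(self.ref_allele)


@dataclass
class TargetOligo:
    """A retained reference oligo rewritten with the target's alleles."""

    source: Oligo
    target_seq: str
    variant_ids: list[int] = field(default_factory=list)
    n_snps: int = 0
    n_indels: int = 0
    # intervals of target_seq touched by each variant: (variant_id, t0, t1)
    variant_spans: list[tuple[int, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def build_windows(
    genome: Genome,
    oligos: list[Oligo],
    flank: int = 100,
    pad: int = 160,
) -> list[Window]:
    """Merge per-oligo windows (oligo +/- flank) into disjoint regions.

    ``pad`` extends the alignment context beyond the region so reads that
    only partially overlap a region still align without artificial end
    gaps; padded columns are never part of the consensus.
    """
    windows: list[Window] = []
    by_chrom: dict[str, list[Oligo]] = {}
    for o in oligos:
        by_chrom.setdefault(o.chrom, []).append(o)
    for chrom, seq in genome:
        olist = sorted(by_chrom.get(chrom, []), key=lambda o: o.start)
        if not olist:
            continue
        L = len(seq)
        cur: list[Oligo] = [olist[0]]
        cur_s = max(0, olist[0].start - flank)
        cur_e = min(L, olist[0].end + flank)
        for o in olist[1:]:
            s, e = max(0, o.start - flank), min(L, o.end + flank)
            if s <= cur_e:
                cur_e = max(cur_e, e)
                cur.append(o)
            else:
                windows.append(_make_window(chrom, seq, cur_s, cur_e, cur, pad))
                cur, cur_s, cur_e = [o], s, e
        windows.append(_make_window(chrom, seq, cur_s, cur_e, cur, pad))
    return windows


def _make_window(chrom: str, seq: str, s: int, e: int, oligos: list[Oligo], pad: int) -> Window:
    ps, pe = max(0, s - pad), min(len(seq), e + pad)
    return Window(chrom, s, e, seq[s:e], sorted(oligos, key=lambda o: o.start), ps, seq[ps:pe])


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

class _SeedIndex:
    """k-mer -> (window index, offset in padded context) occurrence lists."""

    def __init__(self, windows: list[Window], seed_len: int = 15, max_occ: int = 20):
        self.seed_len = seed_len
        self.table: dict[str, list[tuple[int, int]]] = {}
        k = seed_len
        for wi, w in enumerate(windows):
            s = w.pad_seq
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" in kmer:
                    continue
                occ = self.table.setdefault(kmer, [])
                if len(occ) < max_occ:
                    occ.append((wi, i))

    def candidates(self, seq: str, stride: int) -> dict[tuple[int, int], int]:
        """Vote for (window, diagonal bucket) anchors from sampled k-mers."""
        k = self.seed_len
        votes: dict[tuple[int, int], int] = {}
        for i in range(0, len(seq) - k + 1, stride):
            for wi, p in self.table.get(seq[i : i + k], ()):
                key = (wi, (p - i) // 16)
                votes[key] = votes.get(key, 0) + 1
        return votes


def assign_reads(
    reads: list[Read],
    windows: list[Window],
    seed_len: int = 15,
    band: int = 25,
    max_candidates: int = 4,
    min_score_frac: float = 0.85,
) -> tuple[dict[int, list[AnchoredRead]], int]:
    """Anchor each read to at most one window by best alignment score.

    A read is considered for a window when it shares a seed k-mer with the
    window's reference context (either strand); the alignment runs on a
    seed-anchored segment of width read length + 2 * band. Score ties go
    to the lowest window coordinate. Reads whose best score falls below
    ``min_score_frac`` of a perfect match are left unassigned -- this
    keeps reads originating from diverged repeat paralogs (~10%
    mismatches) out of windows that happen to flank a repeat copy, while
    comfortably admitting true-locus reads carrying species divergence.
    Returns (window index -> anchored reads, number of unassigned reads).
    """
    from .align import MATCH

    index = _SeedIndex(windows, seed_len)
    assigned: dict[int, list[AnchoredRead]] = {}
    n_unassigned = 0
    for rd in reads:
        best: tuple | None = None  # (sort key, window index, AnchoredRead)
        for strand in "+-":
            seq = rd.sequence if strand == "+" else reverse_complement(rd.sequence)
            votes = index.candidates(seq, stride=max(1, seed_len // 2))
            ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:max_candidates]
            for (wi, bucket), _ in ranked:
                w = windows[wi]
                diag = bucket * 16
                s0 = max(0, diag - band - 8)
                s1 = min(len(w.pad_seq), diag + len(seq) + band + 24)
                seg = w.pad_seq[s0:s1]
                if len(seg) < seed_len:
                    continue
                aln = banded_align(seq, seg, band)
                col = (s0 + aln.ref_start) - (w.start - w.pad_start)
                cand = AnchoredRead(rd.id, seq, strand, col, aln)
                if _overlap_cols(cand, w) <= 0:
                    continue
                key = (-aln.score, w.chrom, w.start, strand, col)
                if best is None or key < best[0]:
                    best = (key, wi, cand)
        if best is None or best[2].aln.score < min_score_frac * MATCH * len(rd.sequence):
            n_unassigned += 1
            continue
        assigned.setdefault(best[1], []).append(best[2])
    return assigned, n_unassigned


def _overlap_cols(ar: AnchoredRead, w: Window) -> int:
    ref_len = sum(n for op, n in ar.aln.ops if op in "MD")
    lo = max(ar.col_start, 0)
    hi = min(ar.col_start + ref_len, w.end - w.start)
    return hi - lo


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def local_consensus(
    window: Window,
    anchored_reads: list[AnchoredRead],
    min_cov: int = 3,
    min_af: float = 0.7,
    end_trim: int = 5,
) -> Consensus:
    """Column-majority consensus of anchored reads over a window.

    Each reference column takes its majority symbol (base or deletion)
    when depth >= min_cov and the majority fraction >= min_af; otherwise
    the reference base is kept and the column is flagged low-confidence.
    Insertions are called per junction under the same thresholds against
    the junction-spanning depth. Zero reads yield consensus == reference.

    The first and last ``end_trim`` bases of every read are excluded from
    the pileup: a read ending a few bases past an indel junction aligns
    those bases as mismatches rather than opening a gap, and untrimmed
    ends would dilute the indel's allele fraction with that artifact.
    """
    W = window.end - window.start
    counts = np.zeros((5, W), dtype=np.int32)
    ins_counter: dict[int, Counter] = {}
    junction_cov = np.zeros(W + 2, dtype=np.int32)

    for ar in anchored_reads:
        col = ar.col_start
        qpos = 0
        first_col = last_col = None
        read_len = len(ar.seq)
        q_lo, q_hi = end_trim, read_len - end_trim
        for op, n in ar.aln.ops:
            if op == "M":
                for t in range(n):
                    c = col + t
                    q = qpos + t
                    if 0 <= c < W and q_lo <= q < q_hi:
                        b = ar.seq[q]
                        if b in _SYM_IDX:
                            counts[_SYM_IDX[b], c] += 1
                            if first_col is None:
                                first_col = c
                            last_col = c
                col += n
                qpos += n
            elif op == "D":
                if q_lo <= qpos <= q_hi:
                    for t in range(n):
                        c = col + t
                        if 0 <= c < W:
                            counts[4, c] += 1
                            if first_col is None:
                                first_col = c
                            last_col = c
                col += n
            else:  # I
                # only well-anchored internal insertions carry evidence;
                # overhangs and near-end placements are alignment noise
                if qpos >= q_lo and qpos + n <= q_hi and 0 < col <= W:
                    ins_counter.setdefault(col, Counter())[ar.seq[qpos : qpos + n]] += 1
                qpos += n
        if first_col is not None and last_col is not None and last_col > first_col:
            junction_cov[first_col + 1 : last_col + 1] += 1

    coverage = counts.sum(axis=0)
    calls: list[str] = []
    low_conf = np.zeros(W, dtype=bool)
    for c in range(W):
        cov = int(coverage[c])
        if cov >= min_cov:
            top = int(np.argmax(counts[:, c]))
            if counts[top, c] / cov >= min_af:
                calls.append(_SYMBOLS[top])
                continue
        calls.append(window.ref_seq[c])
        low_conf[c] = True

    insertions: dict[int, str] = {}
    ins_support: dict[int, tuple[int, int]] = {}
    for c, ctr in sorted(ins_counter.items()):
        seq, n = ctr.most_common(1)[0]
        jcov = max(int(junction_cov[c]), n)
        ins_support[c] = (n, jcov)
        if n >= min_cov and n / jcov >= min_af:
            insertions[c] = seq

    complete = all(
        bool(
            (
                coverage[max(0, o.start - window.start) : max(0, min(W, o.end - window.start))]
                >= min_cov
            ).all()
        )
        for o in window.oligos
    )
    return Consensus(
        window, calls, insertions, counts, coverage, ins_support, low_conf, min_cov, complete
    )


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

def left_normalize(chrom_seq: str, pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """VCF-style left normalization against the chromosome sequence.

    Trims shared trailing bases, shifts anchored indels left through
    repetitive context, and trims shared leading bases down to a single
    anchor. Re-normalizing an already normalized variant is a no-op.
    """
    while True:
        if ref[-1:] == alt[-1:] and ref and alt and (len(ref) > 1 or len(alt) > 1):
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
            elif pos0 > 0:
                prev = chrom_seq[pos0 - 1]
                pos0 -= 1
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
            else:
                break
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def call_variants(
    consensus: Consensus,
    window: Window,
    chrom_seq: str | None = None,
) -> list[Variant]:
    """Decompose consensus-vs-reference differences into SNP/INS/DEL
    variants, anchored and left-normalized (against the full chromosome
    when given, else within the window). Low-confidence columns keep the
    reference and emit nothing, so an uncovered window yields no calls.
    """
    W = window.end - window.start
    ref = window.ref_seq
    calls = consensus.calls
    counts = consensus.counts
    coverage = consensus.coverage
    variants: list[Variant] = []

    def _norm(pos0: int, r: str, a: str) -> tuple[int, str, str]:
        if chrom_seq is not None:
            return left_normalize(chrom_seq, pos0, r, a)
        p, rr, aa = left_normalize(ref, pos0 - window.start, r, a)
        return p + window.start, rr, aa

    c = 0
    while c < W:
        if calls[c] == "-":
            c0 = c
            while c < W and calls[c] == "-":
                c += 1
            if c0 == 0:
                continue  # deletion truncated by the window edge; not placeable
            anchor = c0 - 1
            ref_allele = ref[anchor:c]
            alt_allele = calls[anchor] if calls[anchor] != "-" else ref[anchor]
            depth = int(coverage[c0])
            af = counts[4, c0] / depth if depth else 0.0
            p0, r, a = _norm(window.start + anchor, ref_allele, alt_allele)
            variants.append(Variant(window.chrom, p0 + 1, r, a, DEL, depth, af))
            continue
        if calls[c] != ref[c]:
            # a base change at the anchor of a following deletion is folded
            # into that deletion's alt allele
            if not (c + 1 < W and calls[c + 1] == "-"):
                depth = int(coverage[c])
                af = counts[_SYM_IDX[calls[c]], c] / depth if depth else 0.0
                variants.append(
                    Variant(window.chrom, window.start + c + 1, ref[c], calls[c], SNP, depth, af)
                )
        c += 1

    for c, ins_seq in sorted(consensus.insertions.items()):
        if c == 0:
            continue  # insertion before the first column; not placeable
        anchor = c - 1
        if calls[anchor] == "-":
            continue  # adjacent deletion+insertion: keep the deletion only
        n_sup, jcov = consensus.ins_support[c]
        alt_allele = calls[anchor] + ins_seq
        p0, r, a = _norm(window.start + anchor, ref[anchor], alt_allele)
        variants.append(
            Variant(window.chrom, p0 + 1, r, a, INS, jcov, n_sup / jcov if jcov else 0.0)
        )

    variants.sort(key=lambda v: (v.pos, v.ref_allele, v.alt_allele))
    return variants


# ---------------------------------------------------------------------------
# Oligo rewriting
# ---------------------------------------------------------------------------

def rewrite_oligo(
    oligo: Oligo,
    variants: list[Variant],
    consensus: Consensus,
    variant_offset: int = 0,
) -> TargetOligo | None:
    """Project the consensus through the oligo interval, producing the
    target-species oligo. Returns None (oligo dropped from the target
    pool) when the interval is not completely covered."""
    w = consensus.window
    c0, c1 = oligo.start - w.start, oligo.end - w.start
    if c0 < 0 or c1 > len(consensus.calls):
        return None
    if not consensus.interval_complete(oligo.start, oligo.end):
        return None

    parts: list[str] = []
    col_to_t: dict[int, int] = {}
    t = 0
    for c in range(c0, c1):
        if c > c0 and c in consensus.insertions:
            parts.append(consensus.insertions[c])
            t += len(consensus.insertions[c])
        col_to_t[c] = t
        if consensus.calls[c] != "-":
            parts.append(consensus.calls[c])
            t += 1
    target_seq = "".join(parts)

    ids: list[int] = []
    spans: list[tuple[int, int, int]] = []
    n_snps = n_indels = 0
    for vi, v in enumerate(variants):
        if v.chrom != oligo.chrom:
            continue
        vs, ve = v.ref_span
        if ve <= oligo.start or vs >= oligo.end:
            continue
        vid = vi + variant_offset
        ids.append(vid)
        anchor_col = max(c0, min(c1 - 1, v.pos0 - w.start))
        ta = col_to_t.get(anchor_col, 0)
        if v.vclass == SNP:
            n_snps += 1
            spans.append((vid, ta, min(len(target_seq), ta + 1)))
        elif v.vclass == INS:
            n_indels += 1
            span_len = 1 + (len(v.alt_allele) - len(v.ref_allele))
            spans.append((vid, ta, min(len(target_seq), ta + span_len)))
        else:  # DEL: the anchor base plus the base after the deleted run
            n_indels += 1
            spans.append((vid, ta, min(len(target_seq), ta + 2)))
    return TargetOligo(oligo, target_seq, ids, n_snps, n_indels, spans)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class NoRefResult:
    target_oligos: list[TargetOligo]
    variants: list[Variant]
    windows: list[Window]
    consensuses: list[Consensus]
    n_unassigned: int
    n_incomplete_oligos: int

    def variant_counts(self, genome: Genome) -> list[tuple[str, int, int]]:
        """(chrom, n_snp, n_indel) rows per chromosome."""
        out = []
        for chrom in genome.chrom_ids:
            n_snp = sum(1 for v in self.variants if v.chrom == chrom and v.vclass == SNP)
            n_ind = sum(1 for v in self.variants if v.chrom == chrom and v.vclass != SNP)
            out.append((chrom, n_snp, n_ind))
        return out


def noref_pipeline(
    genome: Genome,
    retained_oligos: list[Oligo],
    reads: list[Read],
    flank: int = 100,
    seed_len: int = 15,
    band: int = 25,
    min_cov: int = 3,
    min_af: float = 0.7,
    reach: int = 200,
) -> NoRefResult:
    """assign -> consensus -> call -> rewrite for every window.

    Variants farther than ``reach`` nt from any retained oligo are dropped
    (they can never sit under a primer). Deterministic for fixed inputs.
    """
    windows = build_windows(genome, retained_oligos, flank=flank)
    assigned, n_unassigned = assign_reads(reads, windows, seed_len=seed_len, band=band)

    chrom_seqs = dict(genome.records)
    all_variants: list[Variant] = []
    target_oligos: list[TargetOligo] = []
    consensuses: list[Consensus] = []
    n_incomplete = 0

    for wi, w in enumerate(windows):
        cons = local_consensus(w, assigned.get(wi, []), min_cov=min_cov, min_af=min_af)
        consensuses.append(cons)
        variants = call_variants(cons, w, chrom_seqs[w.chrom])
        variants = [
            v
            for v in variants
            if any(o.start - reach <= v.pos0 < o.end + reach for o in w.oligos)
        ]
        off = len(all_variants)
        all_variants.extend(variants)
        for o in w.oligos:
            to = rewrite_oligo(o, variants, cons, variant_offset=off)
            if to is None:
                n_incomplete += 1
            else:
                target_oligos.append(to)

    order = {ch: i for i, ch in enumerate(genome.chrom_ids)}
    indexed = sorted(enumerate(all_variants), key=lambda iv: (order[iv[1].chrom], iv[1].pos, iv[1].ref_allele, iv[1].alt_allele))
    remap = {old: new for new, (old, _) in enumerate(indexed)}
    variants_final = [v for _, v in indexed]
    for to in target_oligos:
        to.variant_ids = sorted(remap[i] for i in to.variant_ids)
        to.variant_spans = sorted((remap[i], a, b) for i, a, b in to.variant_spans)
    target_oligos.sort(key=lambda t: (order[t.source.chrom], t.source.start))

    logger.info(
        "noref: %d windows, %d unassigned reads, %d variants, %d target oligos, %d oligos dropped",
        len(windows), n_unassigned, len(variants_final), len(target_oligos), n_incomplete,
    )
    return NoRefResult(
        target_oligos, variants_final, windows, consensuses, n_unassigned, n_incomplete
    )
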