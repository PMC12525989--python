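"""Chromosome-specific single-copy oligo selection.

A reference genome is tiled into fixed-length oligos (45 nt, step 25 nt by
default) and each tile is kept only if it is

* free of ambiguous bases (N),
* not repetitive by a canonical k-mer copy-number criterion,
* single-copy: exactly one genomic location (both strands) matches the
  full oligo gap-free at >= 80% identity,
* thermodynamically well-behaved: duplex Tm minus the best hairpin-stem
  Tm (dTm) is at least 10 degC.

The surviving pool is the per-chromosome set of single-copy oligos that
anchors all downstream marker design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .seqio import Genome, reverse_complement

logger = logging.getLogger(__name__)

# oligo filter states
RETAINED = "RETAINED"
FAIL_HOMOLOGY = "FAIL_HOMOLOGY"
FAIL_KMER = "FAIL_KMER"
FAIL_THERMO = "FAIL_THERMO"
FAIL_N = "FAIL_N"

DEFAULT_OLIGO_LEN = 45
DEFAULT_STEP = 25


@dataclass
class Oligo:
    """A fixed-length reference tile with its filter verdict."""

    chrom: str
    start: int  # 0-based
    end: int  # start + oligo_len
    sequence: str
    tm: float = float("nan")
    hairpin_tm: float = float("nan")
    dtm: float = float("nan")
    status: str = RETAINED

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class HomologyHit:
    """One gap-free full-length match of an oligo in the genome."""

    chrom: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    identity: float


@dataclass
class KmerIndex:
    """Genome-wide canonical (strand-collapsed) k-mer occurrence counts."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, kmer: str) -> int:
        return self.counts.get(canonical_kmer(kmer), 0)


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_oligos(
    genome: Genome,
    oligo_len: int = DEFAULT_OLIGO_LEN,
    step: int = DEFAULT_STEP,
) -> list[Oligo]:
    """Tile every chromosome on the + strand.

    A chromosome of length L yields floor((L - oligo_len)/step) + 1 tiles at
    starts 0, step, 2*step, ... Tiles containing N are marked FAIL_N
    immediately. Chromosomes shorter than ``oligo_len`` yield nothing.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    oligos: list[Oligo] = []
    for chrom, seq in genome:
        L = len(seq)
        if L < oligo_len:
            logger.warning("chromosome %s shorter than oligo length; skipped", chrom)
            continue
        n = (L - oligo_len) // step + 1
        for i in range(n):
            s = i * step
            sub = seq[s : s + oligo_len]
            status = FAIL_N if "N" in sub else RETAINED
            oligos.append(Oligo(chrom, s, s + oligo_len, sub, status=status))
    return oligos


# ---------------------------------------------------------------------------
# k-mer repeat filter
# ---------------------------------------------------------------------------

def build_kmer_index(genome: Genome, k: int = 17) -> KmerIndex:
    """Count canonical k-mers of the whole genome by a sliding window.

    k must be odd so no k-mer equals its own reverse complement. k-mers
    containing N are skipped.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts: dict[str, int] = {}
    for _, seq in genome:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            ck = canonical_kmer(kmer)
            counts[ck] = counts.get(ck, 0) + 1
    return KmerIndex(k, counts)


def kmer_filter(
    oligo: Oligo,
    index: KmerIndex,
    max_mean_count: float = 1.5,
    max_single_count: int = 4,
) -> bool:
    """Keep an oligo iff its k-mer copy numbers look single-copy.

    Keep iff mean canonical k-mer count over the oligo <= max_mean_count and
    no single k-mer exceeds max_single_count. Oligos containing N fail.
    """
    seq = oligo.sequence
    if "N" in seq:
        return False
    k = index.k
    counts = [index.count(seq[i : i + k]) for i in range(len(seq) - k + 1)]
    if not counts:
        return False
    return (sum(counts) / len(counts) <= max_mean_count) and max(counts) <= max_single_count


# ---------------------------------------------------------------------------
# Homology (single-copy) filter: exact full-genome scan
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class HomologySearcher:
    """Exhaustive both-strands identity scan over a whole genome.

    Each genome window of oligo length is packed into two 64-bit planes
    (one bit per position per base-code bit), so the gap-free mismatch
    count of an oligo against *every* genome position is an XOR/OR plus a
    popcount over three uint64 arrays. This is a literal all-positions
    scan -- no seeding heuristics -- just vectorized, and it is exact for
    oligo lengths up to 64.
    """

    def __init__(self, genome: Genome, oligo_len: int = DEFAULT_OLIGO_LEN, min_identity: float = 0.80):
        if oligo_len > 64:
            raise ValueError("bit-packed scan supports oligo lengths up to 64")
        self.genome = genome
        self.oligo_len = oligo_len
        self.min_identity = min_identity
        # matches >= ceil(min_identity * L); 0.80 * 45 -> 36 (boundary inclusive)
        self.min_matches = int(math.ceil(min_identity * oligo_len - 1e-9))
        self.max_mismatches = oligo_len - self.min_matches

        spacer = np.full(oligo_len, 4, dtype=np.uint8)
        parts: list[np.ndarray] = []
        chrom_idx_parts: list[np.ndarray] = []
        self._chrom_names: list[str] = []
        self._chrom_offsets: list[int] = []
        off = 0
        for ci, (chrom, seq) in enumerate(genome):
            if ci > 0:
                parts.append(spacer)
                chrom_idx_parts.append(np.full(oligo_len, -1, dtype=np.int32))
                off += oligo_len
            self._chrom_names.append(chrom)
            self._chrom_offsets.append(off)
            arr = _encode(seq)
            parts.append(arr)
            chrom_idx_parts.append(np.full(len(arr), ci, dtype=np.int32))
            off += len(arr)
        code = np.concatenate(parts)
        chrom_idx = np.concatenate(chrom_idx_parts)
        L = len(code)
        M = L - oligo_len + 1
        if M <= 0:
            raise ValueError("genome shorter than oligo length")

        bit0 = (code & 1).astype(np.uint64)
        bit1 = ((code >> 1) & 1).astype(np.uint64)
        isn = (code == 4).astype(np.uint64)
        p0 = np.zeros(M, dtype=np.uint64)
        p1 = np.zeros(M, dtype=np.uint64)
        pn = np.zeros(M, dtype=np.uint64)
        for j in range(oligo_len):
            sh = np.uint64(j)
            p0 |= bit0[j : j + M] << sh
            p1 |= bit1[j : j + M] << sh
            pn |= isn[j : j + M] << sh
        self._p0, self._p1, self._pn = p0, p1, pn
        # a window is a real alignment position iff fully inside one chromosome
        self._valid = chrom_idx[:M] == chrom_idx[oligo_len - 1 :]
        self._valid &= chrom_idx[:M] >= 0
        self._chrom_idx = chrom_idx
        # scratch buffers reused across queries
        self._buf = np.empty(M, dtype=np.uint64)
        self._cnt = np.empty(M, dtype=np.uint64)

    def _pack(self, seq: str) -> tuple[np.uint64, np.uint64]:
        code = _encode(seq)
        if (code == 4).any():
            raise ValueError("oligo contains N")
        w = np.uint64(0)
        o0 = o1 = 0
        for j, c in enumerate(code):
            o0 |= int(c & 1) << j
            o1 |= int(c >> 1) << j
        del w
        return np.uint64(o0), np.uint64(o1)

    def _scan(self, o0: np.uint64, o1: np.uint64) -> tuple[np.ndarray, np.ndarray]:
        buf, cnt = self._buf, self._cnt
        np.bitwise_xor(self._p0, o0, out=buf)
        np.bitwise_xor(self._p1, o1, out=cnt)
        np.bitwise_or(buf, cnt, out=buf)
        np.bitwise_or(buf, self._pn, out=buf)
        np.bitwise_count(buf, out=cnt)
        hit = (cnt <= self.max_mismatches) & self._valid
        pos = np.flatnonzero(hit)
        return pos, cnt[pos]

    def hits(self, oligo_seq: str) -> list[HomologyHit]:
        """All genome locations matching the oligo gap-free at >= min_identity,
        on either strand. Locations hit in both orientations are reported
        once (as '+')."""
        if len(oligo_seq) != self.oligo_len:
            raise ValueError("oligo length does not match searcher")
        L = self.oligo_len
        out: dict[tuple[int, int], HomologyHit] = {}
        for strand, seq in (("+", oligo_seq), ("-", reverse_complement(oligo_seq))):
            o0, o1 = self._pack(seq)
            pos, mism = self._scan(o0, o1)
            for p, m in zip(pos.tolist(), mism.tolist()):
                ci = int(self._chrom_idx[p])
                key = (ci, p)
                if key in out:
                    continue
                start = p - self._chrom_offsets[ci]
                out[key] = HomologyHit(
                    self._chrom_names[ci], start, strand, (L - m) / L
                )
        return sorted(out.values(), key=lambda h: (h.chrom, h.start, h.strand))


def homology_hits(
    oligo: Oligo | str,
    genome: Genome,
    min_identity: float = 0.80,
    seed_len: int = 12,  # retained for interface compatibility; scan is exhaustive
    searcher: HomologySearcher | None = None,
) -> list[HomologyHit]:
    """Gap-free full-length matches of an oligo anywhere in the genome.

    The scan visits every position on both strands, so the result equals a
    brute-force all-positions identity scan by construction. Pass a
    prebuilt ``HomologySearcher`` when querying many oligos.
    """
    seq = oligo.sequence if isinstance(oligo, Oligo) else oligo
    if searcher is None:
        searcher = HomologySearcher(genome, oligo_len=len(seq), min_identity=min_identity)
    return searcher.hits(seq)


def homology_filter(oligo: Oligo, hits: Sequence[HomologyHit]) -> bool:
    """Keep iff the oligo maps to exactly one location (itself)."""
    if len(hits) == 0:
        raise RuntimeError(
            f"homology scan of {oligo.chrom}:{oligo.start} lost its own origin"
        )
    return len(hits) == 1


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------

def _duplex_tm(seq: str, Na_mM: float, oligo_nM: float) -> float:
    # strand-canonical so Tm(seq) == Tm(revcomp(seq)) bit-for-bit
    rc = reverse_complement(seq)
    s = seq if seq <= rc else rc
    return _mt.Tm_NN(s, Na=Na_mM, dnac1=oligo_nM, dnac2=0)


def melting_temperature(seq: str, Na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    """Nearest-neighbor duplex Tm (degC), unified parameter set, monovalent
    salt correction. Requires N-free DNA of length >= 8."""
    if len(seq) < 8:
        raise ValueError("sequence too short for nearest-neighbor Tm (need >= 8 nt)")
    if "N" in seq or not set(seq) <= set("ACGT"):
        raise ValueError("Tm undefined for sequences containing N or non-DNA characters")
    return _duplex_tm(seq, Na_mM, oligo_nM)


_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def hairpin_tm(
    seq: str,
    min_loop: int = 3,
    min_stem: int = 3,
    Na_mM: float = 50.0,
    oligo_nM: float = 250.0,
) -> float:
    """Tm of the most stable self-complementary hairpin stem.

    Enumerates every gap-free Watson-Crick stem of length >= min_stem whose
    loop spans >= min_loop unpaired bases, computes the nearest-neighbor Tm
    of each stem arm as a duplex, and returns the maximum, floored at 0 degC
    (a stem cannot stabilize beyond no structure at all). This is a
    maximal-stem approximation, not a partition-function fold.
    """
    if len(seq) < 8:
        raise ValueError("sequence too short (need >= 8 nt)")
    if "N" in seq or not set(seq) <= set("ACGT"):
        raise ValueError("hairpin Tm undefined for sequences containing N")
    n = len(seq)
    best = 0.0
    # stems pair (i+t, j-t): both ends on one anti-diagonal s = i + j
    for s in range(2 * min_stem + min_loop, 2 * n - 2):
        i = max(0, s - n + 1)
        run = 0
        while True:
            j = s - i
            if j <= i:
                # flush final run
                if run >= min_stem:
                    best = max(best, _best_stem_tm(seq, i - run, s, run, min_loop, min_stem, Na_mM, oligo_nM))
                break
            if (seq[i], seq[j]) in _PAIR:
                run += 1
            else:
                if run >= min_stem:
                    best = max(best, _best_stem_tm(seq, i - run, s, run, min_loop, min_stem, Na_mM, oligo_nM))
                run = 0
            i += 1
    return best


def _best_stem_tm(
    seq: str, i0: int, s: int, run: int, min_loop: int, min_stem: int,
    Na_mM: float, oligo_nM: float,
) -> float:
    """Best duplex Tm over all sub-stems of a maximal complementary run.

    The run pairs (i0+t, s-i0-t) for t in [0, run). A sub-stem starting at
    offset a with length l leaves a loop of (s - 2*(i0+a) - 2*l + 1) bases,
    which must be >= min_loop.
    """
    best = 0.0
    for a in range(run - min_stem + 1):
        i = i0 + a
        j = s - i
        l_loop_max = (j - i + 1 - min_loop) // 2
        l_max = min(run - a, l_loop_max)
        for l in range(min_stem, l_max + 1):
            arm = seq[i : i + l]
            tm = _duplex_tm(arm, Na_mM, oligo_nM)
            if tm > best:
                best = tm
    return best


def thermo_filter(oligo: Oligo, dtm_min: float = 10.0) -> bool:
    """Keep iff dTm = Tm - hairpin Tm >= dtm_min (boundary kept: only
    dTm strictly below the threshold is eliminated)."""
    return (oligo.tm - oligo.hairpin_tm) >= dtm_min


# ---------------------------------------------------------------------------
# Full selection pipeline
# ---------------------------------------------------------------------------

def select_specific_oligos(
    genome: Genome,
    oligo_len: int = DEFAULT_OLIGO_LEN,
    step: int = DEFAULT_STEP,
    kmer: int = 17,
    max_mean_count: float = 1.5,
    max_single_count: int = 4,
    min_identity: float = 0.80,
    dtm_min: float = 10.0,
    Na_mM: float = 50.0,
    oligo_nM: float = 250.0,
) -> list[Oligo]:
    """Run tile -> k-mer filter -> homology filter -> thermo filter.

    Returns every tile with its final status; the retained pool is the
    subset with status RETAINED. Filters act as independent predicates:
    the order (cheap first) only determines which failure is recorded for
    oligos failing several.
    """
    oligos = tile_oligos(genome, oligo_len, step)
    index = build_kmer_index(genome, kmer)
    searcher = HomologySearcher(genome, oligo_len, min_identity)

    for o in oligos:
        if o.status == FAIL_N:
            continue
        if not kmer_filter(o, index, max_mean_count, max_single_count):
            o.status = FAIL_KMER
            continue
        hits = searcher.hits(o.sequence)
        if not homology_filter(o, hits):
            o.status = FAIL_HOMOLOGY
            continue
        o.tm = melting_temperature(o.sequence, Na_mM, oligo_nM)
        o.hairpin_tm = hairpin_tm(o.sequence, Na_mM=Na_mM, oligo_nM=oligo_nM)
        o.dtm = o.tm - o.hairpin_tm
        if not thermo_filter(o, dtm_min):
            o.status = FAIL_THERMO

    by_chrom: dict[str, int] = {}
    for o in oligos:
        if o.status == RETAINED:
            by_chrom[o.chrom] = by_chrom.get(o.chrom, 0) + 1
    for chrom in genome.chrom_ids:
        logger.info("chromosome %s: %d oligos retained", chrom, by_chrom.get(chrom, 0))
    return oligos


def retained(oligos: Iterable[Oligo]) -> list[Oligo]:
    return [o for o in oligos if o.status == RETAINED]


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def oligos_to_rows(oligos: Iterable[Oligo]) -> list[tuple]:
    """TSV rows (1-based inclusive coordinates)."""
    rows = []
    for o in oligos:
        tm = "" if math.isnan(o.tm) else f"{o.tm:.3f}"
        htm = "" if math.isnan(o.hairpin_tm) else f"{o.hairpin_tm:.3f}"
        dtm = "" if math.isnan(o.dtm) else f"{o.dtm:.3f}"
        rows.append((o.chrom, o.start + 1, o.end, o.sequence, tm, htm, dtm, o.status))
    return rows


OLIGO_TSV_HEADER = ("chrom", "start1", "end1", "sequence", "tm", "hairpin_tm", "dtm", "status")


def oligos_to_bed(oligos: Iterable[Oligo]) -> list[tuple]:
    return [(o.chrom, o.start, o.end, o.status, 0, "+") for o in oligos]
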