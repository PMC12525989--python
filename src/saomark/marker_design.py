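"""PCR marker design over adjacent target oligos and in-silico typing.

A marker is a primer pair bridging two single-copy target oligos less
than 500 nt apart: the forward primer sits on the left oligo's
target-species sequence, the reverse primer on the right one, and at
least one primer must cover a site where the target species diverges
from the reference. In-silico PCR on both genomes stands in for gel
electrophoresis, and each marker is classified by its band pattern:

* Type I   -- product on the target (wild) genome only,
* Type II  -- product on the reference (cultivated) genome only,
* Type III -- products on both, resolvably different lengths,
* Type IV  -- indistinguishable or unusable (no bands / same length /
              multiple bands).

Types I-III are polymorphic ("specific"); types I and III diagnose the
presence of the wild chromosome in a mixed sample, while type II only
reports its absence and is flagged non-diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noref import SNP, TargetOligo, Variant
from .oligo_select import melting_temperature
from .seqio import Genome, reverse_complement

logger = logging.getLogger(__name__)

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"
TYPE_IV = "IV"
SPECIFIC_TYPES = (TYPE_I, TYPE_II, TYPE_III)

PRESENT = "PRESENT"
ABSENT = "ABSENT"
UNTESTABLE = "UNTESTABLE"


@dataclass
class Primer:
    """A candidate primer: ``start`` is its binding-site start within the
    oligo's target sequence; ``seq`` is the synthesized 5'->3' sequence."""

    seq: str
    start: int
    tm: float
    gc: float
    ends_gc: bool

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PrimerPair:
    marker_id: str
    chrom: str
    fwd_seq: str
    fwd_start: int  # within the left oligo's target sequence
    rev_seq: str  # reverse-complement primer as synthesized
    rev_start: int  # binding-site start within the right oligo's target sequence
    tm_f: float
    tm_r: float
    overlaps_divergence: bool = True
    product_target: int | None = None
    product_reference: int | None = None


@dataclass
class Marker(PrimerPair):
    mtype: str = TYPE_IV
    homoeologous_group: int = 0
    multi_band: bool = False
    left_start: int = 0  # reference start of the left source oligo
    right_end: int = 0  # reference end of the right source oligo

    @property
    def specific(self) -> bool:
        return self.mtype in SPECIFIC_TYPES

    @property
    def diagnostic(self) -> bool:
        """Whether the marker can positively identify the wild chromosome."""
        return self.mtype in (TYPE_I, TYPE_III)


@dataclass
class Amplicon:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Oligo pairing
# ---------------------------------------------------------------------------

def pair_adjacent_oligos(
    target_oligos: list[TargetOligo],
    max_gap: int = 500,
) -> list[tuple[TargetOligo, TargetOligo]]:
    """All same-chromosome ordered oligo pairs separated by a gap of
    0 <= (right.start - left.end) < max_gap in reference coordinates.
    Overlapping tiles (negative gap) are never paired."""
    by_chrom: dict[str, list[TargetOligo]] = {}
    for to in target_oligos:
        by_chrom.setdefault(to.source.chrom, []).append(to)
    pairs: list[tuple[TargetOligo, TargetOligo]] = []
    for chrom in sorted(by_chrom):
        olist = sorted(by_chrom[chrom], key=lambda t: t.source.start)
        for i, left in enumerate(olist):
            for right in olist[i + 1 :]:
                gap = right.source.start - left.source.end
                if gap < 0:
                    continue
                if gap >= max_gap:
                    break
                pairs.append((left, right))
    return pairs


# ---------------------------------------------------------------------------
# Candidate primers
# ---------------------------------------------------------------------------

def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def candidate_primers(
    region_seq: str,
    min_len: int = 18,
    max_len: int = 25,
    tm_min: float = 52.0,
    tm_max: float = 60.0,
    gc_min: float = 0.35,
    gc_max: float = 0.65,
    max_homopolymer: int = 4,
) -> list[Primer]:
    """Every substring of the region satisfying standard PCR primer
    constraints: length 18-25 nt, Tm within the protocol's annealing
    range, 35-65% GC, no homopolymer run over 4. A G/C 3' end is recorded
    as a soft preference, not a hard filter."""
    out: list[Primer] = []
    n = len(region_seq)
    for length in range(min_len, max_len + 1):
        for start in range(0, n - length + 1):
            s = region_seq[start : start + length]
            if "N" in s:
                continue
            gc = (s.count("G") + s.count("C")) / length
            if not gc_min <= gc <= gc_max:
                continue
            if _max_run(s) > max_homopolymer:
                continue
            tm = melting_temperature(s)
            if not tm_min <= tm <= tm_max:
                continue
            out.append(Primer(s, start, tm, gc, s[-1] in "GC"))
    return out


# ---------------------------------------------------------------------------
# Divergence constraint
# ---------------------------------------------------------------------------

def divergence_constraint(
    fwd_interval: tuple[int, int],
    rev_interval: tuple[int, int],
    left_spans: list[tuple[int, int]],
    right_spans: list[tuple[int, int]],
) -> bool:
    """True iff the forward primer covers a divergent site on the left
    oligo or the reverse primer covers one on the right oligo. Spans are
    target-sequence intervals of variants (for deletions: the flanking
    bases around the removed run)."""

    def _hits(iv: tuple[int, int], spans: list[tuple[int, int]]) -> bool:
        a, b = iv
        return any(a < t1 and t0 < b for t0, t1 in spans)

    return _hits(fwd_interval, left_spans) or _hits(rev_interval, right_spans)


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


class PCRTemplate:
    """A genome prepared for repeated primer-binding scans."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.arrays = [
            (chrom, _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)])
            for chrom, seq in genome
        ]


def _scan_sites(
    arr: np.ndarray,
    primer: str,
    max_total_mm: int,
    max_3prime_mm: int,
    window3: int,
    three_prime_right: bool,
) -> np.ndarray:
    """Positions where the primer binds the + strand sequence of ``arr``.

    ``three_prime_right`` selects which end of the match window carries
    the primer's 3' terminus (right for a forward-oriented primer, left
    for a reverse-complemented one)."""
    k = len(primer)
    if len(arr) < k:
        return np.empty(0, dtype=int)
    pc = _CODE[np.frombuffer(primer.encode(), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    eq = win == pc
    mm = k - eq.sum(axis=1)
    if three_prime_right:
        mm3 = window3 - eq[:, -window3:].sum(axis=1)
    else:
        mm3 = window3 - eq[:, :window3].sum(axis=1)
    return np.flatnonzero((mm <= max_total_mm) & (mm3 <= max_3prime_mm))


def insilico_pcr(
    fwd: str,
    rev: str,
    template: Genome | PCRTemplate,
    max_total_mm: int = 2,
    max_3prime_mm: int = 0,
    three_prime_window: int = 5,
    max_product: int = 2000,
) -> list[Amplicon]:
    """Predict every amplicon the primer pair can produce on a genome.

    Binding sites of both primers are located on both strands allowing up
    to ``max_total_mm`` mismatches but none in the 3'-terminal
    ``three_prime_window``. Any convergent left/right site combination
    (including same-primer pairings) within ``max_product`` is an
    amplicon. Design-time amplification "succeeds" iff exactly one
    amplicon results.
    """
    if isinstance(template, Genome):
        template = PCRTemplate(template)
    amplicons: list[Amplicon] = []
    primers = [p for p in (fwd, rev) if p]
    for chrom, arr in template.arrays:
        lefts: list[tuple[int, int]] = []  # (pos, primer_len), 3' pointing right
        rights: list[tuple[int, int]] = []  # binding window start, 3' pointing left
        for p in primers:
            for pos in _scan_sites(arr, p, max_total_mm, max_3prime_mm,
                                   three_prime_window, True):
                lefts.append((int(pos), len(p)))
            for pos in _scan_sites(arr, reverse_complement(p), max_total_mm,
                                   max_3prime_mm, three_prime_window, False):
                rights.append((int(pos), len(p)))
        seen: set[tuple[int, int]] = set()
        for li, ll in lefts:
            for rj, rl in rights:
                end = rj + rl
                length = end - li
                if rj < li or length > max_product or length < max(ll, rl):
                    continue
                if (li, end) in seen:
                    continue
                seen.add((li, end))
                amplicons.append(Amplicon(chrom, li, end))
    amplicons.sort(key=lambda a: (a.chrom, a.start, a.end))
    return amplicons


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_marker(
    product_target: int | None,
    product_reference: int | None,
    min_len_diff_frac: float = 0.025,
    min_len_diff_bp: int = 10,
) -> str:
    """Band-pattern type from the two predicted product lengths.

    Type III requires a length difference of at least
    max(min_len_diff_bp, min_len_diff_frac * shorter product) -- an
    explicit stand-in for what a 2% agarose gel resolves (about 2.5% of
    fragment size below ~1 kb, never less than 10 bp).
    """
    if product_target is not None and product_reference is None:
        return TYPE_I
    if product_target is None and product_reference is not None:
        return TYPE_II
    if product_target is None and product_reference is None:
        return TYPE_IV
    delta = abs(product_target - product_reference)
    thr = max(min_len_diff_bp, min_len_diff_frac * min(product_target, product_reference))
    return TYPE_III if delta >= thr else TYPE_IV


# ---------------------------------------------------------------------------
# Marker design
# ---------------------------------------------------------------------------

@dataclass
class DesignConfig:
    max_gap: int = 500
    markers_per_chrom: int | None = 120  # evenly spaced loci per chromosome
    use_snps: bool = False  # if False, a locus must contain an InDel site
    max_total_mm: int = 2
    max_3prime_mm: int = 0
    three_prime_window: int = 5
    max_product: int = 2000
    min_len_diff_frac: float = 0.025
    min_len_diff_bp: int = 10
    target_product: int = 300  # preferred amplicon length for scoring
    max_candidates_per_oligo: int = 12


def _spans_of(to: TargetOligo, variants: list[Variant], indel_only: bool) -> list[tuple[int, int]]:
    out = []
    for vid, t0, t1 in to.variant_spans:
        if indel_only and variants[vid].vclass == SNP:
            continue
        out.append((t0, t1))
    return out


def _rev_candidates(target_seq: str, cfg: DesignConfig) -> list[Primer]:
    """Reverse-primer candidates; ``start`` is rewritten to the binding
    interval start in the oligo's own (forward) coordinates."""
    L = len(target_seq)
    cands = candidate_primers(reverse_complement(target_seq))
    for p in cands:
        p.start = L - p.start - len(p)
    return cands


def design_markers(
    target_oligos: list[TargetOligo],
    variants: list[Variant],
    ref_genome: Genome,
    target_template: Genome,
    cfg: DesignConfig | None = None,
) -> list[Marker]:
    """Design, amplify in silico, and classify one marker per eligible
    locus.

    For each oligo pair under the gap limit (restricted by default to
    loci whose amplified span contains at least one InDel site, and
    thinned to an even spacing along the chromosome), the best primer
    pair satisfying the divergence constraint is chosen by Tm balance,
    then by product length closest to the preferred size, then by a G/C
    3'-end preference. The chosen pair is amplified on both genomes and
    typed I-IV.
    """
    cfg = cfg or DesignConfig()
    ref_template = PCRTemplate(ref_genome)
    tgt_template = PCRTemplate(target_template)
    chrom_lens = dict((c, len(s)) for c, s in ref_genome)

    indel_pos: dict[str, list[int]] = {}
    for v in variants:
        if v.vclass != SNP:
            indel_pos.setdefault(v.chrom, []).append(v.pos0)

    cand_cache: dict[int, tuple[list[Primer], list[Primer]]] = {}

    def _cands(to: TargetOligo) -> tuple[list[Primer], list[Primer]]:
        key = id(to)
        if key not in cand_cache:
            fwd = candidate_primers(to.target_seq)
            rev = _rev_candidates(to.target_seq, cfg)
            fwd.sort(key=lambda p: (abs(p.tm - 56.0), p.start))
            rev.sort(key=lambda p: (abs(p.tm - 56.0), p.start))
            m = cfg.max_candidates_per_oligo
            cand_cache[key] = (fwd[:m], rev[:m])
        return cand_cache[key]

    markers: list[Marker] = []
    pairs = pair_adjacent_oligos(target_oligos, cfg.max_gap)
    by_chrom: dict[str, list[tuple[TargetOligo, TargetOligo]]] = {}
    for lp in pairs:
        by_chrom.setdefault(lp[0].source.chrom, []).append(lp)

    for chrom in ref_genome.chrom_ids:
        group = ref_genome.group_of(chrom)
        spacing = 0
        if cfg.markers_per_chrom:
            spacing = max(1, chrom_lens[chrom] // cfg.markers_per_chrom)
        next_allowed = 0
        n_chrom = 0
        ipos = indel_pos.get(chrom, [])
        for left, right in by_chrom.get(chrom, []):
            ls = left.source.start
            if ls < next_allowed:
                continue
            if not cfg.use_snps:
                lo, hi = left.source.start, right.source.end
                if not any(lo <= p < hi for p in ipos):
                    continue
            chosen = _choose_pair(left, right, variants, cfg, _cands)
            if chosen is None:
                continue
            fwd, rev = chosen
            mid = f"SAO_{chrom}_{n_chrom + 1}"
            marker = _amplify_and_type(
                mid, chrom, group, left, right, fwd, rev, ref_template, tgt_template, cfg
            )
            markers.append(marker)
            n_chrom += 1
            next_allowed = ls + spacing
        logger.info("chromosome %s: %d markers designed", chrom, n_chrom)
    return markers


def _choose_pair(
    left: TargetOligo,
    right: TargetOligo,
    variants: list[Variant],
    cfg: DesignConfig,
    cands,
) -> tuple[Primer, Primer] | None:
    fwd_c, _ = cands(left)
    _, rev_c = cands(right)
    if not fwd_c or not rev_c:
        return None
    left_spans = _spans_of(left, variants, indel_only=False)
    right_spans = _spans_of(right, variants, indel_only=False)
    offset = right.source.start - left.source.start  # reference-frame estimate
    best = None
    best_key = None
    for f in fwd_c:
        f_iv = (f.start, f.start + len(f))
        for r in rev_c:
            r_iv = (r.start, r.start + len(r))
            if not divergence_constraint(f_iv, r_iv, left_spans, right_spans):
                continue
            est = offset + r.start + len(r) - f.start
            key = (
                round(abs(f.tm - r.tm), 6),
                abs(est - cfg.target_product),
                -(f.ends_gc + r.ends_gc),
                f.start,
                r.start,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (f, r)
    return best


def _amplify_and_type(
    marker_id: str,
    chrom: str,
    group: int,
    left: TargetOligo,
    right: TargetOligo,
    fwd: Primer,
    rev: Primer,
    ref_template: PCRTemplate,
    tgt_template: PCRTemplate,
    cfg: DesignConfig,
) -> Marker:
    fwd_seq = fwd.seq
    rev_seq = reverse_complement(right.target_seq[rev.start : rev.start + len(rev)])
    prods_t = insilico_pcr(fwd_seq, rev_seq, tgt_template, cfg.max_total_mm,
                           cfg.max_3prime_mm, cfg.three_prime_window, cfg.max_product)
    prods_r = insilico_pcr(fwd_seq, rev_seq, ref_template, cfg.max_total_mm,
                           cfg.max_3prime_mm, cfg.three_prime_window, cfg.max_product)
    multi = len(prods_t) > 1 or len(prods_r) > 1
    pt = prods_t[0].length if len(prods_t) == 1 else None
    pr = prods_r[0].length if len(prods_r) == 1 else None
    mtype = TYPE_IV if multi else classify_marker(pt, pr, cfg.min_len_diff_frac, cfg.min_len_diff_bp)
    return Marker(
        marker_id=marker_id,
        chrom=chrom,
        fwd_seq=fwd_seq,
        fwd_start=fwd.start,
        rev_seq=rev_seq,
        rev_start=rev.start,
        tm_f=fwd.tm,
        tm_r=rev.tm,
        overlaps_divergence=True,
        product_target=pt,
        product_reference=pr,
        mtype=mtype,
        homoeologous_group=group,
        multi_band=multi,
        left_start=left.source.start,
        right_end=right.source.end,
    )


# ---------------------------------------------------------------------------
# Alien-chromosome detection
# ---------------------------------------------------------------------------

def detect_alien(
    markers: list[Marker],
    sample: Genome,
    groups: list[int] | None = None,
    tol_bp: int = 0,
    max_total_mm: int = 2,
    max_3prime_mm: int = 0,
    three_prime_window: int = 5,
    max_product: int = 2000,
) -> dict[int, str]:
    """Per-homoeologous-group presence of the wild chromosome in a sample.

    A group is PRESENT when at least one of its diagnostic (type I/III)
    markers yields its target-length product somewhere in the sample
    genome; a group without diagnostic markers is UNTESTABLE. A mixed
    sample may also show the reference-length band -- only the
    target-diagnostic length counts.
    """
    template = PCRTemplate(sample)
    if groups is None:
        groups = sorted({m.homoeologous_group for m in markers})
    result: dict[int, str] = {}
    for g in groups:
        diag = [m for m in markers
                if m.homoeologous_group == g and m.diagnostic and m.product_target]
        if not diag:
            result[g] = UNTESTABLE
            continue
        status = ABSENT
        for m in diag:
            prods = insilico_pcr(m.fwd_seq, m.rev_seq, template, max_total_mm,
                                 max_3prime_mm, three_prime_window, max_product)
            if any(abs(a.length - m.product_target) <= tol_bp for a in prods):
                status = PRESENT
                break
        result[g] = status
    return result


def detection_table(results: dict[str, dict[int, str]]) -> pd.DataFrame:
    """Rows = homoeologous groups, columns = samples."""
    groups = sorted({g for r in results.values() for g in r})
    return pd.DataFrame(
        {sample: [r.get(g, UNTESTABLE) for g in groups] for sample, r in results.items()},
        index=pd.Index(groups, name="group"),
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(
    markers: list[Marker],
    variants: list[Variant],
    genome: Genome,
) -> pd.DataFrame:
    """Per-chromosome marker summary.

    Columns: InDel site count, designed primer pairs, specific markers
    (types I-III) and the polymorphism rate (specific / designed,
    formatted to one decimal; NA when nothing was designed)."""
    rows = []
    for chrom in genome.chrom_ids:
        n_indel = sum(1 for v in variants if v.chrom == chrom and v.vclass != SNP)
        designed = [m for m in markers if m.chrom == chrom]
        n_design = len(designed)
        n_spec = sum(1 for m in designed if m.specific)
        rate = f"{100 * n_spec / n_design:.1f}%" if n_design else "NA"
        rows.append((chrom, genome.group_of(chrom), n_indel, n_design, n_spec, rate))
    n_indel = sum(1 for v in variants if v.vclass != SNP)
    n_design = len(markers)
    n_spec = sum(1 for m in markers if m.specific)
    rate = f"{100 * n_spec / n_design:.1f}%" if n_design else "NA"
    rows.append(("total", 0, n_indel, n_design, n_spec, rate))
    return pd.DataFrame(
        rows,
        columns=["chrom", "group", "n_indel_sites", "n_designed_pairs",
                 "n_specific", "polymorphism_rate"],
    )


MARKER_TSV_HEADER = (
    "marker_id", "chrom", "group", "fwd_seq", "rev_seq", "tm_f", "tm_r",
    "fwd_start", "rev_start", "product_target", "product_reference",
    "type", "multi_band", "left_start1", "right_end1",
)


def markers_to_rows(markers: list[Marker]) -> list[tuple]:
    rows = []
    for m in markers:
        rows.append((
            m.marker_id, m.chrom, m.homoeologous_group, m.fwd_seq, m.rev_seq,
            f"{m.tm_f:.3f}", f"{m.tm_r:.3f}", m.fwd_start, m.rev_start,
            m.product_target if m.product_target is not None else "NA",
            m.product_reference if m.product_reference is not None else "NA",
            m.mtype, int(m.multi_band), m.left_start + 1, m.right_end,
        ))
    return rows


def markers_to_bed(markers: list[Marker]) -> list[tuple]:
    return [
        (m.chrom, m.left_start, m.right_end, f"{m.marker_id}|{m.mtype}", 0, "+")
        for m in markers
    ]
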