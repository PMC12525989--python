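# Methods

This note records the models, parameter choices and numerical decisions
behind saomark, and what the simulation-based tests do and do not
demonstrate.

## Single-copy oligo selection

The reference is tiled on the + strand only (45 nt / 25 nt step; a
chromosome of length L yields ⌊(L−45)/25⌋+1 tiles). Reverse-strand
specificity is enforced where it matters — the homology scan and
in-silico PCR search both strands — so tiling one strand avoids double
counting without losing sensitivity.

**Homology (single-copy) filter.** "Single copy" is operationalized as
gap-free full-length identity: a location counts as a hit when at least
⌈0.80·45⌉ = 36 of 45 positions match, on either strand (boundary
inclusive). Gap-free identity has two virtues over a gapped model: it is
the convention of oligo-probe design tools, and it is cheap to verify
against a literal brute-force scan. The implementation packs every
genome window into 64-bit planes and evaluates *all* positions with
XOR + popcount — an exhaustive scan, not a seed heuristic, so it equals
brute force by construction (seed anchoring cannot be made exact here:
9 mismatches spread over 45 nt can break every k-mer seed for any
k > 4). The test suite cross-checks it against two independent
implementations (a per-position comparison scan and a one-hot matmul
scan). Oligo lengths up to 64 nt are supported by the packed scan.

**k-mer filter.** Canonical (strand-collapsed) 17-mer counts over the
whole genome; an oligo passes when its mean k-mer count is ≤ 1.5 and no
k-mer exceeds 4. These thresholds are deliberately permissive: the k-mer
stage is a cheap pre-filter for heavy repeats, and the homology scan is
the decisive single-copy test. k must be odd so no k-mer is its own
reverse complement.

**Thermodynamics.** Duplex Tm uses unified nearest-neighbor parameters
(biopython's implementation) at 50 mM Na⁺ and 250 nM oligo; Tm is
evaluated on the lexicographically smaller of (sequence,
reverse complement) so strand symmetry holds exactly. The hairpin model
enumerates every gap-free Watson–Crick stem (stem ≥ 3 bp, loop ≥ 3 nt)
and takes the maximum stem-duplex Tm, floored at 0 °C. This is a
maximal-stem approximation, not a partition-function fold: it will
underestimate the stability of multi-branch or bulged structures, which
is acceptable because the filter only needs a monotone self-structure
penalty. An oligo is eliminated only when dTm = Tm − hairpin Tm falls
strictly below 10 °C (dTm = 10.0 is kept). Oligos containing N are
discarded before any computation — thermodynamics is undefined on N.

Filters run cheap-first (N → k-mer → homology → thermo), but they are
independent predicates: the retained set does not depend on the order,
only the recorded failure reason does.

## Assembly-free consensus ("no-reference" stage)

Windows are built per retained oligo (oligo ± 100 nt flank) and
overlapping windows are merged into disjoint consensus regions. This
merging is load-bearing: adjacent tiles overlap by 20 nt, so per-oligo
windows overlap massively, and assigning each read to only one *per-oligo*
window would starve every window of coverage. Merged regions keep the
one-read-one-vote property (no variant is supported twice by the same
read) while every oligo sees full local depth.

**Read anchoring.** Reads are matched to regions by shared 15-mers
(either strand), then aligned with an affine-gap dynamic program that is
global in the read and local in the reference, on a seed-anchored
segment of width read-length + 2·band (band 25 ≥ max simulated indel
plus margin) — this segment restriction is what makes the alignment
banded; the DP on the segment is exact (scores +2/−3, gap −5/−2). A read
goes to its best-scoring region (ties to the lowest coordinate) and is
dropped when its best score is below 0.85 of a perfect match: reads from
~10 %-diverged repeat paralogs score far below this line, while
true-locus reads carrying realistic species divergence (≈ 0.5 % SNPs,
one short indel) stay comfortably above it. Without this gate, reads
from a repeat copy whose own locus has no window contaminate
repeat-flanking windows and can produce high-fraction false SNPs.

**Pileup and consensus.** Per reference column the majority symbol
(base or deletion) is called when depth ≥ 3 and the majority fraction is
≥ 0.7; otherwise the reference base is kept and the column is flagged
low-confidence, so sparse coverage degrades to "no call", never to a
call. Insertions are called per junction against the junction-spanning
depth under the same thresholds. The first and last 5 aligned bases of
every read are excluded from the pileup: a read that ends a few bases
past an indel junction aligns those bases as mismatches rather than
paying a gap-open, and untrimmed ends dilute the indel's allele fraction
below the 0.7 threshold (this is the standard end-clip argument from
short-read variant calling). Base qualities are ignored — counts at
these depths carry the same information — and mates of a pair are
treated as independent reads.

**Variant calls.** Consensus-vs-reference differences decompose into
SNPs and anchored InDels (VCF conventions: 1-based, anchor base, REF/ALT
minimal), left-normalized against the chromosome; re-normalizing any
emitted variant is a no-op, and the same normalization routine defines
the simulator's truth representation so exact-match comparison is
well-defined. A base change immediately before a deletion run is folded
into the deletion's alt allele rather than emitted as a separate
overlapping SNP. Variants farther than 200 nt from any retained oligo
are dropped — they can never sit under a primer. An oligo is rewritten
to its target (wild) sequence only when its whole interval has depth ≥ 3;
otherwise it is dropped from the target pool and counted.

## Marker design and typing

Oligo pairs with an inter-tile gap of 0 ≤ gap < 500 nt are candidate
loci. By default a locus must contain at least one InDel site between
the two tiles (inclusive) — InDels are what gel electrophoresis can see —
while the primer-placement constraint accepts any divergent site
(SNP or InDel) under a primer; `use_snps` lifts the InDel-locus
requirement. Loci are thinned to an even spacing along each chromosome
(default 120 per chromosome, mirroring how a practitioner picks evenly
distributed loci; `markers_per_chrom=None` designs every locus).

Candidate primers are substrings of the *rewritten* oligo sequences:
18–25 nt, Tm within the 52–60 °C annealing range of the PCR protocol,
GC 35–65 %, no homopolymer run over 4; a G/C 3' end is a soft
preference. Among pairs satisfying the divergence rule, the winner
minimizes |Tm_f − Tm_r|, then the distance of the estimated product from
300 bp, then prefers G/C 3' ends.

**In-silico PCR** stands in for the wet protocol: a primer binds where
it matches with ≤ 2 total mismatches and none in the 3'-terminal 5 nt;
every convergent site pair (both strands, including same-primer
pairings) within 2 kb is an amplicon, and design-time amplification
"succeeds" only when exactly one amplicon results. The mismatch model is
a deliberate simplification of polymerase extension behavior — the
3'-end zero-tolerance is the mechanistically important part.

**Typing.** Type I: wild-only product. Type II: reference-only
(emitted but flagged non-diagnostic — it cannot positively identify the
wild chromosome). Type III: products on both genomes whose lengths
differ by at least max(10 bp, 2.5 % of the shorter product) — a stand-in
for 2 % agarose resolvability, which separates roughly 2–3 % length
differences below ~1 kb and never less than ~10 bp. Type IV: everything
else, including multi-band outcomes. Detection then scores a sample per
homoeologous group (= chromosome number): PRESENT when any type I/III
marker of the group yields its wild-length product (exact length in the
error-free in-silico setting), UNTESTABLE when a group has no diagnostic
marker. Reported polymorphism rates are specific/designed, formatted to
one decimal, NA when nothing was designed.

## Simulator

The generator emulates the study conditions end to end: i.i.d. 50 % GC
background; 20 % of each chromosome covered by planted 500-bp duplicated
blocks, alternating exact and 90 %-identity copies (both above the 80 %
single-copy threshold, so they must be caught); wild divergence of 0.5 %
SNPs and 0.05 % InDels (the ~10:1 ratio typical of intra-genus
comparisons), InDel lengths geometric (p = 0.3) capped at 15 nt to stay
within the alignment band; events rejection-sampled to be non-overlapping
with a guard margin so their left-normalized forms cannot collide.
Reads are uniform 150-bp pairs (insert 400 ± 40) with substitution-only
errors at 0.2 % by default; total bases equal depth × genome size up to
rounding. Hybrids carry all cultivated chromosomes plus a chosen subset
of wild ones. Applying the truth catalog to the reference reconstructs
the wild genome byte-exactly, which is the anchor for every recovery
test.

What the simulator does *not* model — and what passing tests therefore
do not show: real repeat taxonomies (transposon families, tandem
satellites), indel sequencing errors and quality-score structure,
heterozygosity (wild accessions are treated as effectively homozygous
inbreds), homoeologous subgenome cross-talk in polyploids, and PCR
competition/efficiency effects. Results on real data will be worse than
the planted-truth numbers, in roughly the order listed.

## Problem sizes and determinism

Default test and demonstration scales are 8–100 kb chromosomes — large
enough that every per-chromosome quantity (thousands of tiles, hundreds
of variants, dozens of markers) is in its asymptotic regime, while the
full suite stays fast enough to run routinely. The acceptance script
uses 3 × 30 kb at 20× depth with read errors. All randomness descends
from one root seed via spawned seed sequences; outputs are sorted before
writing and floats are formatted to fixed precision, so identical
inputs give byte-identical tables.

## Known limitations

* The hairpin model ignores bulges, internal loops and multi-branch
  structures; primer cross-dimer screening is out of scope.
* One marker is designed per locus; no multiplex compatibility scoring.
* The in-silico PCR mismatch model is binary; it does not grade partial
  extension efficiency or thermodynamic binding strength at mismatched
  sites.
* Detection requires exact product-length match by default (`tol_bp`
  exposes a tolerance); on real gels, near-equal lengths within a few
  percent would be indistinguishable even for type I calls scored by
  presence alone.
* For a tetraploid reference, homoeolog policy is "run the pipeline per
  chromosome set"; no merge rule across subgenomes is attempted.
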