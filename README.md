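# saomark

Chromosome-specific **single-copy oligo (SAO) PCR markers** for tracking
alien-chromosome introgression — computed from a reference genome plus
low-coverage short reads of a related (wild) species, with **no genome
assembly** of that species.

## The problem

Crop breeding programs introgress chromosomes from wild relatives into a
cultivated background, but verifying *which* wild chromosomes an F1 hybrid
actually carries is hard when the wild species has no assembled genome.
Classical marker systems (SSR, SNP panels) need assemblies or give low
design success rates. This package implements a marker system that needs
only (i) the cultivated reference assembly and (ii) ~10× short reads of the
wild accession:

1. **Single-copy oligo selection.** Each reference chromosome is tiled
   into 45-nt oligos at 25-nt steps. A tile survives if it is
   single-copy — exactly one genomic location matches it gap-free at
   ≥ 80 % identity on either strand — passes a canonical *k*-mer
   copy-number filter (k = 17), and is thermodynamically clean:
   dTm = Tm − hairpin Tm ≥ 10 °C, with Tm from nearest-neighbor
   thermodynamics (50 mM Na⁺, 250 nM oligo).
2. **Assembly-free oligo rewriting.** Wild-species reads are anchored to
   windows around the retained oligos (oligo ± 100 nt), piled up with a
   banded glocal alignment, and reduced to a reference-projected majority
   consensus (depth ≥ 3, majority fraction ≥ 0.7). Consensus-vs-reference
   differences become a left-normalized SNP/InDel catalog, and each oligo
   is rewritten with the wild alleles.
3. **Marker design and in-silico typing.** For two rewritten oligos less
   than 500 nt apart, a forward primer is placed on the left oligo and a
   reverse primer on the right one (18–25 nt, Tm 52–60 °C, GC 35–65 %),
   with at least one primer covering a divergent site. In-silico PCR on
   both genomes (≤ 2 mismatches per primer, none in the 3'-terminal 5 nt)
   predicts the band pattern, and each marker is typed:
   **I** wild-only band, **II** reference-only band, **III** both bands at
   resolvably different lengths, **IV** uninformative. Types I–III are
   polymorphic ("specific"); types I/III positively diagnose the wild
   chromosome. The per-chromosome **polymorphism rate** is
   specific ÷ designed.
4. **Detection.** A sample genome is scored per homoeologous group:
   a group is PRESENT when any of its type I/III markers yields its
   wild-diagnostic product length.

A seeded simulator generates every input (repeat-bearing reference,
diverged wild genome with known truth, 150-bp paired reads, F1 hybrids),
so the whole system is testable against planted ground truth.

## Worked example

One command simulates a 3 × 100 kb study (20 % planted repeats, 0.5 % SNP
and 0.05 % InDel divergence, 10× paired 150-bp reads) and runs the whole
pipeline:

```bash
saomark run-all --out demo --seed 4242
```

```
simulate: 3 chromosomes, 1707 truth variants, 20000 reads
select-oligos: 7435/11997 oligos retained
noref: 244 windows, 1577 unassigned reads, 1279 variants, 7291 target oligos, 144 oligos dropped
design: 93 markers (type I: 56, type II: 0, type III: 0, type IV: 37)
run-all complete: 93 markers, detection table written
```

`demo/summary.tsv` — per-chromosome InDel sites, designed pairs, specific
markers, and the polymorphism rate:

```
chrom   group  n_indel_sites  n_designed_pairs  n_specific  polymorphism_rate
chr1    1      36             29                18          62.1%
chr2    2      46             37                24          64.9%
chr3    3      35             27                14          51.9%
total   0      117            93                56          60.2%
```

`demo/detect.tsv` — the F1 hybrid (all wild chromosomes) is positive for
every homoeologous group while the reference-only control is clean:

```
group   hybrid   reference_only
1       PRESENT  ABSENT
2       PRESENT  ABSENT
3       PRESENT  ABSENT
```

Each stage is also available separately (`saomark simulate`,
`select-oligos`, `noref`, `design`, `detect`, `report`) over plain-text
formats: FASTA/FASTQ in, BED/TSV/minimal-VCF out. The effective
configuration is echoed to `config.echo.txt` in every output directory,
and a rerun with the same seed reproduces every table byte for byte.

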