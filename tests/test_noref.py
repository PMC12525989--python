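"""Assembly-free consensus and variant calling."""

import numpy as np
import pytest

from conftest import rand_seq, shift_left_oracle
from saomark import noref as nr
from saomark.oligo_select import Oligo, retained, select_specific_oligos
from saomark.seqio import Genome, Read, reverse_complement
from saomark.simulate import apply_variants, diverge_genome, make_reference, simulate_reads


def _oligo_at(genome: Genome, chrom: str, start: int, length: int = 45) -> Oligo:
    seq = genome.seq(chrom)[start : start + length]
    return Oligo(chrom, start, start + length, seq)


def _reads_tiling(seq: str, read_len: int = 100, step: int = 10, prefix="r") -> list[Read]:
    out = []
    for i, s in enumerate(range(0, len(seq) - read_len + 1, step)):
        out.append(Read(f"{prefix}{i}", seq[s : s + read_len]))
    return out


class TestWindows:
    def test_windows_contain_their_oligos_and_merge(self, rng):
        g = Genome([("c", rand_seq(rng, 3000))])
        oligos = [_oligo_at(g, "c", 500), _oligo_at(g, "c", 600), _oligo_at(g, "c", 2000)]
        windows = nr.build_windows(g, oligos, flank=100)
        assert len(windows) == 2  # first two merge (gap 55 < 2*flank)
        for w in windows:
            for o in w.oligos:
                assert w.start <= o.start and o.end <= w.end
        starts = sorted(w.start for w in windows)
        assert starts == [400, 1900]


class TestAssignReads:
    def test_exact_substring_read_assigned(self, rng):
        g = Genome([("c", rand_seq(rng, 2000))])
        oligos = [_oligo_at(g, "c", 800)]
        windows = nr.build_windows(g, oligos)
        read = Read("r", g.seq("c")[780:880])
        assigned, n_un = nr.assign_reads([read], windows)
        assert n_un == 0
        [ar] = assigned[0]
        assert ar.strand == "+"
        assert ar.col_start == 780 - windows[0].start

    def test_reverse_strand_read_assigned(self, rng):
        g = Genome([("c", rand_seq(rng, 2000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 800)])
        read = Read("r", reverse_complement(g.seq("c")[780:880]))
        assigned, n_un = nr.assign_reads([read], windows)
        assert n_un == 0
        assert assigned[0][0].strand == "-"

    def test_read_without_window_unassigned(self, rng):
        g = Genome([("c", rand_seq(rng, 4000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 200)])
        read = Read("r", g.seq("c")[3000:3100])
        assigned, n_un = nr.assign_reads([read], windows)
        assert n_un == 1 and not assigned

    def test_read_spanning_deletion_gets_del_op(self, rng):
        g = Genome([("c", rand_seq(rng, 2000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 800)])
        chrom = g.seq("c")
        read = Read("r", chrom[750:800] + chrom[805:855])  # 5 bp deletion
        assigned, _ = nr.assign_reads([read], windows)
        [ar] = assigned[0]
        assert ("D", 5) in ar.aln.ops

    def test_diverged_paralog_read_rejected(self, rng):
        from conftest import mutate

        g = Genome([("c", rand_seq(rng, 2000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 800)])
        # a 10%-diverged copy of the window region, as from a repeat paralog
        paralog = mutate(rng, g.seq("c")[780:880], 10)
        assigned, n_un = nr.assign_reads([Read("r", paralog)], windows)
        assert n_un == 1


class TestConsensus:
    def test_identical_reads_reproduce_reference(self, rng):
        g = Genome([("c", rand_seq(rng, 1000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 400)])
        w = windows[0]
        reads = _reads_tiling(g.seq("c")[250:650])
        assigned, _ = nr.assign_reads(reads, windows)
        cons = nr.local_consensus(w, assigned[0])
        assert cons.consensus_seq == w.ref_seq
        assert cons.complete
        assert nr.call_variants(cons, w, g.seq("c")) == []

    def test_unanimous_snp_called(self, rng):
        g = Genome([("c", rand_seq(rng, 1000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 400)])
        w = windows[0]
        chrom = g.seq("c")
        alt = "A" if chrom[420] != "A" else "G"
        target = chrom[250:420] + alt + chrom[421:650]
        assigned, _ = nr.assign_reads(_reads_tiling(target), windows)
        cons = nr.local_consensus(w, assigned[0])
        variants = nr.call_variants(cons, w, chrom)
        assert [(v.pos, v.ref_allele, v.alt_allele, v.vclass) for v in variants] == [
            (421, chrom[420], alt, nr.SNP)
        ]
        assert variants[0].allele_fraction == 1.0

    def test_fifty_fifty_column_keeps_reference(self, rng):
        g = Genome([("c", rand_seq(rng, 1000))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 400)])
        w = windows[0]
        chrom = g.seq("c")
        alt = "A" if chrom[420] != "A" else "G"
        target = chrom[250:420] + alt + chrom[421:650]
        half_ref = _reads_tiling(chrom[250:650], prefix="a")
        half_alt = _reads_tiling(target, prefix="b")
        assigned, _ = nr.assign_reads(half_ref + half_alt, windows)
        cons = nr.local_consensus(w, assigned[0])
        col = 420 - w.start
        assert cons.calls[col] == chrom[420]  # fraction 0.5 < 0.7
        assert cons.low_conf[col]
        assert nr.call_variants(cons, w, chrom) == []

    def test_zero_reads_yield_reference_and_incomplete(self, rng):
        g = Genome([("c", rand_seq(rng, 1000))])
        w = nr.build_windows(g, [_oligo_at(g, "c", 400)])[0]
        cons = nr.local_consensus(w, [])
        assert cons.consensus_seq == w.ref_seq
        assert not cons.complete
        assert nr.call_variants(cons, w, g.seq("c")) == []


class TestVariantCalling:
    def _run(self, rng, edit):
        """Build a window, apply ``edit`` to the target copy, pile reads."""
        g = Genome([("c", rand_seq(rng, 1200))])
        windows = nr.build_windows(g, [_oligo_at(g, "c", 500)])
        w = windows[0]
        chrom = g.seq("c")
        target = edit(chrom)
        assigned, _ = nr.assign_reads(_reads_tiling(target[300:800], step=7), windows)
        cons = nr.local_consensus(w, assigned[0])
        return w, chrom, nr.call_variants(cons, w, chrom)

    def test_planted_deletion_left_normalized(self, rng):
        # delete 4 bases at 520
        w, chrom, variants = self._run(rng, lambda s: s[:520] + s[524:])
        dels = [v for v in variants if v.vclass == nr.DEL]
        assert len(dels) == 1
        v = dels[0]
        p, r, a = shift_left_oracle(chrom, 519, chrom[519:524], chrom[519])
        assert (v.pos0, v.ref_allele, v.alt_allele) == (p, r, a)

    def test_planted_insertion_left_normalized(self, rng):
        ins = "TGGA"
        w, chrom, variants = self._run(rng, lambda s: s[:520] + ins + s[520:])
        inss = [v for v in variants if v.vclass == nr.INS]
        assert len(inss) == 1
        v = inss[0]
        p, r, a = shift_left_oracle(chrom, 519, chrom[519], chrom[519] + ins)
        assert (v.pos0, v.ref_allele, v.alt_allele) == (p, r, a)

    def test_homopolymer_deletion_shifts_left(self, rng):
        # deletion anywhere inside a T run must normalize to the run's
        # leftmost anchored placement
        left, right = rand_seq(rng, 20), rand_seq(rng, 400)
        left = left[:-1] + "C"  # ensure the run is bounded on the left
        chrom = left + "TTTTTT" + right
        g = Genome([("c", chrom)])
        w = nr.build_windows(g, [Oligo("c", 0, 45, chrom[:45])], flank=0)[0]
        target = chrom[:22] + chrom[23:]  # delete one T mid-run
        reads = _reads_tiling(target[:150], read_len=60, step=1)
        assigned, _ = nr.assign_reads(reads, [w])
        cons = nr.local_consensus(w, assigned[0], min_cov=2)
        variants = nr.call_variants(cons, w, chrom)
        dels = [v for v in variants if v.vclass == nr.DEL]
        assert len(dels) == 1
        p, r, a = shift_left_oracle(chrom, 21, chrom[21:23], chrom[21])
        assert (dels[0].pos0, dels[0].ref_allele, dels[0].alt_allele) == (p, r, a)
        assert p == 19  # anchored at the base before the T run

    def test_renormalizing_emitted_indels_is_noop(self, rng):
        g = Genome([("c", rand_seq(rng, 1200))])
        _, chrom, variants = self._run(rng, lambda s: s[:520] + s[526:])
        for v in variants:
            assert nr.left_normalize(chrom, v.pos0, v.ref_allele, v.alt_allele) == (
                v.pos0, v.ref_allele, v.alt_allele,
            )


class TestRewriteOligo:
    def _pipeline(self, rng, edit=None, **kw):
        g = Genome([("c", rand_seq(rng, 1500))])
        chrom = g.seq("c")
        target_genome = Genome([("c", edit(chrom) if edit else chrom)])
        oligo = _oligo_at(g, "c", 700)
        reads = _reads_tiling(target_genome.seq("c")[500:1000], step=5)
        return g, oligo, nr.noref_pipeline(g, [oligo], reads, **kw)

    def test_no_variants_returns_source_sequence(self, rng):
        g, oligo, res = self._pipeline(rng)
        assert len(res.target_oligos) == 1
        assert res.target_oligos[0].target_seq == oligo.sequence
        assert res.variants == []

    def test_snp_inside_oligo_changes_one_base(self, rng):
        def edit(s):
            alt = "A" if s[720] != "A" else "G"
            return s[:720] + alt + s[721:]

        g, oligo, res = self._pipeline(rng, edit)
        [to] = res.target_oligos
        assert to.n_snps == 1 and to.n_indels == 0
        diffs = sum(a != b for a, b in zip(to.target_seq, oligo.sequence))
        assert diffs == 1 and len(to.target_seq) == 45

    def test_deletion_inside_oligo_shortens_target(self, rng):
        g, oligo, res = self._pipeline(rng, lambda s: s[:720] + s[724:])
        [to] = res.target_oligos
        assert to.n_indels == 1
        assert len(to.target_seq) == 41

    def test_insertion_inside_oligo_lengthens_target(self, rng):
        g, oligo, res = self._pipeline(rng, lambda s: s[:720] + "ACGTT" + s[720:])
        [to] = res.target_oligos
        assert to.n_indels == 1
        assert len(to.target_seq) == 50

    def test_variant_spans_point_at_divergent_target_bases(self, rng):
        def edit(s):
            alt = "A" if s[720] != "A" else "G"
            return s[:720] + alt + s[721:]

        g, oligo, res = self._pipeline(rng, edit)
        [to] = res.target_oligos
        [(vid, t0, t1)] = to.variant_spans
        assert to.target_seq[t0:t1] != oligo.sequence[t0:t1]


class TestPipelineInvariants:
    def test_zero_divergence_fixed_point(self, rng):
        ref, _ = make_reference(n_chrom=1, chrom_len=20000, repeat_fraction=0.1, seed=5)
        kept = retained(select_specific_oligos(ref))
        reads = simulate_reads(ref, depth=15, error_rate=0.0, seed=6)
        res = nr.noref_pipeline(ref, kept, reads)
        assert res.variants == []
        assert all(t.target_seq == t.source.sequence for t in res.target_oligos)

    def test_catalog_reconstructs_consensus(self, rng):
        """Applying the called variants to the reference reproduces every
        complete window's consensus sequence."""
        ref, _ = make_reference(n_chrom=1, chrom_len=15000, repeat_fraction=0.0, seed=7)
        wild, truth = diverge_genome(ref, seed=8)
        kept = retained(select_specific_oligos(ref))
        reads = simulate_reads(wild, depth=25, error_rate=0.0, seed=9)
        res = nr.noref_pipeline(ref, kept, reads, reach=10_000)
        checked = 0
        for w, cons in zip(res.windows, res.consensuses):
            vs = [v for v in res.variants
                  if v.chrom == w.chrom and w.start <= v.pos0 and v.ref_span[1] <= w.end]
            sub = Genome([(w.chrom, w.ref_seq)])
            shifted = [
                nr.Variant(w.chrom, v.pos - w.start, v.ref_allele, v.alt_allele,
                           v.vclass, v.depth, v.allele_fraction)
                for v in vs
            ]
            rebuilt = apply_variants(sub, shifted).seq(w.chrom)
            assert rebuilt == cons.consensus_seq
            checked += 1
        assert checked >= 1

    def test_recall_monotone_in_depth(self):
        ref, _ = make_reference(n_chrom=1, chrom_len=20000, repeat_fraction=0.1, seed=21)
        wild, truth = diverge_genome(ref, seed=22)
        kept = retained(select_specific_oligos(ref))
        wins = [(o.chrom, o.start - 100, o.end + 100) for o in kept]
        truth_in = [
            v for v in truth.variants
            if any(c == v.chrom and s <= v.pos0 < e for c, s, e in wins)
        ]
        recalls = []
        for depth in (5, 10, 20):
            reads = simulate_reads(wild, depth=depth, error_rate=0.0, seed=23)
            res = nr.noref_pipeline(ref, kept, reads)
            called = {(v.chrom, v.pos, v.ref_allele, v.alt_allele) for v in res.variants}
            hit = sum(
                1 for v in truth_in
                if (v.chrom, v.pos, v.ref_allele, v.alt_allele) in called
            )
            recalls.append(hit / len(truth_in))
        assert recalls[0] <= recalls[1] <= recalls[2]
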