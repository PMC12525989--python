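"""Synthetic study inputs: reference genome, diverged wild genome with
known truth, short reads, and F1 hybrid mixtures.

The generator emulates the study conditions of the marker system: a
repeat-bearing cultivated reference, a wild relative diverging by roughly
ten SNPs per InDel, 150 bp paired-end sequencing at ~10x depth with a
small substitution error rate, and hybrids that carry the full cultivated
complement plus a chosen subset of wild chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .noref import DEL, INS, SNP, Variant, left_normalize
from .seqio import Genome, Read, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimTruth:
    """Planted ground truth: variants (reference coordinates, left-
    normalized, VCF-anchored) and repeat block locations."""

    variants: list[Variant] = field(default_factory=list)
    repeats: list[tuple[str, int, int, tuple[str, int]]] = field(default_factory=list)
    seed: int | None = None
    params: dict = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=n, p=p)]).decode()


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    n_mut = int(round(len(seq) * (1 - identity)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    arr = bytearray(seq.encode())
    for p in pos:
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return arr.decode()


def make_reference(
    n_chrom: int = 3,
    chrom_len: int = 100_000,
    repeat_fraction: float = 0.2,
    repeat_unit: int = 500,
    gc: float = 0.5,
    seed: int | None = None,
) -> tuple[Genome, SimTruth]:
    """An i.i.d. background genome with planted duplicated blocks.

    Roughly ``repeat_fraction`` of each chromosome is covered by copies of
    earlier blocks; half the copies are exact, half at 90% identity (both
    trip an 80%-identity single-copy filter). Copy coordinates are
    recorded in the returned truth object.
    """
    if not 0 <= repeat_fraction < 0.8:
        raise ValueError("repeat_fraction must be in [0, 0.8)")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth = SimTruth(seed=seed, params=dict(
        n_chrom=n_chrom, chrom_len=chrom_len, repeat_fraction=repeat_fraction,
        repeat_unit=repeat_unit, gc=gc,
    ))
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        arr = bytearray(_rand_seq(rng, chrom_len, gc).encode())
        n_copies = int(repeat_fraction * chrom_len / repeat_unit)
        occupied: list[tuple[int, int]] = []

        def _place(rng_local=rng) -> int | None:
            for _ in range(200):
                s = int(rng_local.integers(0, chrom_len - repeat_unit))
                if all(e <= s or s + repeat_unit <= b for b, e in occupied):
                    occupied.append((s, s + repeat_unit))
                    occupied.sort()
                    return s
            return None

        for rep in range(n_copies):
            src = _place()
            dst = _place()
            if src is None or dst is None:
                break
            block = bytes(arr[src : src + repeat_unit]).decode()
            identity = 1.0 if rep % 2 == 0 else 0.9
            copy = _mutate(rng, block, identity)
            arr[dst : dst + repeat_unit] = copy.encode()
            truth.repeats.append((chrom, dst, dst + repeat_unit, (chrom, src)))
        records.append((chrom, bytes(arr).decode()))
    return Genome(records), truth


def diverge_genome(
    ref: Genome,
    snp_rate: float = 0.005,
    indel_rate: float = 0.0005,
    indel_len_geom_p: float = 0.3,
    max_indel: int = 15,
    seed: int | None = None,
) -> tuple[Genome, SimTruth]:
    """Derive a wild genome from the reference with planted SNPs and
    InDels (non-overlapping, rejection-sampled, left-normalized truth).

    The default rates keep the field-typical ~10:1 SNP:InDel balance.
    Applying the truth variants to the reference reconstructs the wild
    genome byte-exactly.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed, params=dict(
        snp_rate=snp_rate, indel_rate=indel_rate,
        indel_len_geom_p=indel_len_geom_p, max_indel=max_indel,
    ))
    wild_records: list[tuple[str, str]] = []
    for chrom, seq in ref:
        L = len(seq)
        n_snp = rng.binomial(L, snp_rate)
        n_indel = rng.binomial(L, indel_rate)
        # sample event anchors with a guard margin so events (and their
        # left-normalized representations) cannot collide
        margin = max_indel + 5
        events: list[tuple[int, str, str, str]] = []  # (pos0, ref, alt, vclass)
        taken: list[tuple[int, int]] = []

        def _free(p: int, width: int) -> bool:
            return all(e + margin <= p or p + width + margin <= b for b, e in taken)

        for _ in range(n_indel):
            for _attempt in range(50):
                length = min(max_indel, int(rng.geometric(indel_len_geom_p)))
                is_del = bool(rng.integers(2))
                p = int(rng.integers(margin, L - margin - length - 1))
                width = length + 1 if is_del else 1
                if not _free(p, width):
                    continue
                if is_del:
                    ref_a = seq[p : p + 1 + length]
                    alt_a = seq[p]
                    vclass = DEL
                else:
                    ins = _rand_seq(rng, length)
                    ref_a = seq[p]
                    alt_a = seq[p] + ins
                    vclass = INS
                p_n, ref_n, alt_n = left_normalize(seq, p, ref_a, alt_a)
                if not _free(p_n, len(ref_n)):
                    continue
                taken.append((min(p, p_n), max(p + width, p_n + len(ref_n))))
                taken.sort()
                events.append((p_n, ref_n, alt_n, vclass))
                break
        for _ in range(n_snp):
            for _attempt in range(50):
                p = int(rng.integers(1, L - 1))
                if not _free(p, 1):
                    continue
                old = seq[p]
                new = "ACGT"[int(rng.integers(4))]
                while new == old:
                    new = "ACGT"[int(rng.integers(4))]
                taken.append((p, p + 1))
                taken.sort()
                events.append((p, old, new, SNP))
                break

        events.sort(key=lambda e: e[0])
        for p, r, a, vc in events:
            truth.variants.append(Variant(chrom, p + 1, r, a, vc, 0, 1.0))
        wild_records.append((chrom, _apply_events(seq, events)))
    wild = Genome(wild_records)
    return wild, truth


def _apply_events(seq: str, events: list[tuple[int, str, str, str]]) -> str:
    parts: list[str] = []
    cur = 0
    for p, r, a, _vc in events:
        parts.append(seq[cur:p])
        parts.append(a)
        cur = p + len(r)
    parts.append(seq[cur:])
    return "".join(parts)


def apply_variants(ref: Genome, variants: list[Variant]) -> Genome:
    """Apply a (non-overlapping) variant set to a reference genome."""
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out: list[tuple[str, str]] = []
    for chrom, seq in ref:
        evs = sorted(by_chrom.get(chrom, []), key=lambda v: v.pos0)
        out.append((chrom, _apply_events(seq, [(v.pos0, v.ref_allele, v.alt_allele, v.vclass) for v in evs])))
    return Genome(out)


def simulate_reads(
    genome: Genome,
    depth: float = 10.0,
    read_len: int = 150,
    paired: bool = True,
    insert_mean: int = 400,
    insert_sd: int = 40,
    error_rate: float = 0.002,
    seed: int | None = None,
) -> list[Read]:
    """Uniform-coverage short reads with substitution-only errors.

    Fragments start uniformly on either strand; total read bases come out
    at ``depth`` times the genome size (to within rounding). Paired mode
    emits both 150 bp ends of a normally distributed insert.
    """
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for chrom, seq in genome:
        L = len(seq)
        if L < read_len:
            continue
        if paired:
            min_insert = read_len
            n_frag = int(round(depth * L / (2 * read_len)))
            inserts = np.clip(
                rng.normal(insert_mean, insert_sd, n_frag).round().astype(int),
                min_insert, max(min_insert, L - 1),
            )
            starts = (rng.random(n_frag) * (L - inserts)).astype(int)
            strands = rng.integers(2, size=n_frag)
            for i in range(n_frag):
                s, ins = int(starts[i]), int(inserts[i])
                frag = seq[s : s + ins]
                if strands[i]:
                    frag = reverse_complement(frag)
                r1 = frag[:read_len]
                r2 = reverse_complement(frag[-read_len:])
                base = f"{chrom}_f{i}"
                reads.append(Read(base, _add_errors(rng, r1, error_rate), 1))
                reads.append(Read(base, _add_errors(rng, r2, error_rate), 2))
        else:
            n = int(round(depth * L / read_len))
            starts = rng.integers(0, L - read_len + 1, size=n)
            strands = rng.integers(2, size=n)
            for i in range(n):
                s = int(starts[i])
                sub = seq[s : s + read_len]
                if strands[i]:
                    sub = reverse_complement(sub)
                reads.append(Read(f"{chrom}_r{i}", _add_errors(rng, sub, error_rate)))
    return reads


def _add_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr = bytearray(seq.encode())
    for p in pos:
        if arr[p] not in b"ACGT":
            continue
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return arr.decode()


def write_fastq(reads: list[Read], path, quality: str = "I") -> None:
    """Write reads as FASTQ (gzipped when the path ends in .gz)."""
    import gzip as _gzip
    from pathlib import Path as _Path

    path = _Path(path)
    opener = _gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            rid = r.id if r.mate is None else f"{r.id}/{r.mate}"
            fh.write(f"@{rid}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")


def make_hybrid(
    cultivated: Genome,
    wild: Genome,
    wild_chroms: list[str] | None = None,
    suffix: str = "_wild",
) -> Genome:
    """An F1-style genome: all cultivated chromosomes plus the selected
    wild chromosomes (renamed with ``suffix`` to keep ids unique)."""
    if wild_chroms is None:
        wild_chroms = wild.chrom_ids
    known = set(wild.chrom_ids)
    for c in wild_chroms:
        if c not in known:
            raise KeyError(f"unknown wild chromosome {c}")
    records = list(cultivated.records)
    for chrom, seq in wild:
        if chrom in wild_chroms:
            records.append((chrom + suffix, seq))
    return Genome(records)
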