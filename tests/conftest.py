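"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (brute-force scans, full DP, direct
recomputation) so they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from saomark.seqio import Genome, reverse_complement

_BASES = "ACGT"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute exactly n_mut positions (never back to the original)."""
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


def naive_homology_scan(oligo_seq: str, genome: Genome, min_identity: float = 0.80):
    """Brute-force all-positions, both-strands, gap-free identity scan.

    The independent oracle for the single-copy filter: O(genome * oligo)
    literal comparison, no packing, no seeding.
    """
    L = len(oligo_seq)
    rc = reverse_complement(oligo_seq)
    hits = []
    for chrom, seq in genome:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        fwd = np.frombuffer(oligo_seq.encode(), dtype=np.uint8)
        rev = np.frombuffer(rc.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, L)
        is_n = win == ord("N")
        m_f = ((win == fwd) & ~is_n).sum(axis=1)
        m_r = ((win == rev) & ~is_n).sum(axis=1)
        best = np.maximum(m_f, m_r)
        for p in np.flatnonzero(best / L >= min_identity - 1e-12):
            hits.append((chrom, int(p)))
    return sorted(hits)


def full_dp_align(read: str, ref: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Exhaustive affine-gap DP, global in the read, free end gaps in the
    reference. Returns the optimal score only (oracle for scores)."""
    n, m = len(ref), len(read)
    NEG = -1e18
    # states: M (diagonal), X (gap in read / ref consumed), Y (gap in ref / read consumed)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free leading reference gap
        M[i, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = max(M[0, j - 1] + gap_open, Y[0, j - 1] + gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = diag + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # free trailing reference gap: best over all i at j = m
    return max(max(M[i, m], Y[i, m]) for i in range(n + 1))


def shift_left_oracle(chrom_seq: str, pos0: int, ref: str, alt: str):
    """Left-normalization oracle: enumerate every equivalent placement of
    an InDel by literal string application and return the leftmost
    anchored representation."""
    # apply the event, then slide a window to find all placements giving
    # the same resulting sequence
    applied = chrom_seq[:pos0] + alt + chrom_seq[pos0 + len(ref) :]
    if len(ref) == len(alt):
        return pos0, ref, alt
    best = (pos0, ref, alt)
    length = abs(len(ref) - len(alt))
    is_del = len(ref) > len(alt)
    for p in range(pos0 + 1):
        if is_del:
            cand_ref = chrom_seq[p : p + 1 + length]
            cand_alt = chrom_seq[p]
            if len(cand_ref) < 1 + length:
                continue
            res = chrom_seq[:p] + cand_alt + chrom_seq[p + len(cand_ref) :]
        else:
            ins = applied[p + 1 : p + 1 + length]
            cand_ref = chrom_seq[p]
            cand_alt = chrom_seq[p] + ins
            res = chrom_seq[:p] + cand_alt + chrom_seq[p + 1 :]
        if res == applied:
            best = (p, cand_ref, cand_alt)
            break  # leftmost
    return best


def matmul_identity_scan(oligo_seqs: list[str], genome: Genome, min_identity: float = 0.80):
    """Independent exhaustive both-strands identity scan for many oligos.

    One-hot encodes genome windows and oligos and accumulates match counts
    with four dense matmuls per oligo batch -- a completely different
    route from the bit-packed scanner. Returns the per-oligo count of
    genome locations with gap-free identity >= min_identity.
    """
    if not oligo_seqs:
        return []
    L = len(oligo_seqs[0])
    assert all(len(s) == L for s in oligo_seqs)
    spacer = "N" * L
    concat = spacer.join(seq for _, seq in genome)
    arr = np.frombuffer(concat.encode(), dtype=np.uint8)
    M = len(arr) - L + 1
    win = np.lib.stride_tricks.sliding_window_view(arr, L)
    # windows containing N (spacers) are not real positions; chromosome-
    # internal N windows are excluded identically by both implementations
    valid = ~(win == ord("N")).any(axis=1)
    W = [(win == ord(b)).astype(np.float32) for b in "ACGT"]
    min_matches = int(np.ceil(min_identity * L - 1e-9))

    counts_out = np.zeros(len(oligo_seqs), dtype=np.int64)
    B = 64
    for lo in range(0, len(oligo_seqs), B):
        batch = oligo_seqs[lo : lo + B]
        cols = [s for s in batch] + [reverse_complement(s) for s in batch]
        O = np.frombuffer("".join(cols).encode(), dtype=np.uint8).reshape(-1, L)
        acc = np.zeros((M, len(cols)), dtype=np.float32)
        for b, Wb in zip("ACGT", W):
            Ob = (O == ord(b)).astype(np.float32)
            acc += Wb @ Ob.T
        nb = len(batch)
        best = np.maximum(acc[:, :nb], acc[:, nb:])
        hit = (best >= min_matches - 0.5) & valid[:, None]
        counts_out[lo : lo + nb] = hit.sum(axis=0)
    return counts_out.tolist()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(777)
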