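"""De novo assembly of short reads and read-back mapping.

The assembler is a plain de Bruijn unitig builder: canonical k-mers occurring
at least ``min_kmer_count`` times form the graph, dead-end branches ("tips")
shorter than 2k are clipped once, and maximal unambiguous paths of length
``min_contig_length`` or more are emitted as contigs. There is no bubble
resolution; tangled regions fragment into shorter contigs.

The mapper assigns each read to at most one contig by exact seed-k-mer lookup
on both strands, verifying candidates by full-length comparison with a
bounded number of substitutions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .synthetic_data import ReadSet

__all__ = ["Contig", "assemble", "map_reads", "MappingResult"]


@dataclass
class Contig:
    contig_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)  # sample -> reads

    def __len__(self) -> int:
        return len(self.sequence)


# --------------------------------------------------------------------------- #
# assembler
# --------------------------------------------------------------------------- #


def _count_canonical_kmers(seqs: list[str], k: int, length: int | None) -> Counter:
    """Canonical k-mer multiset of a read pool.

    Equal-length pools go through the packed vectorised path; ragged pools
    (or reads with non-ACGT symbols) fall back to per-read counting.
    """
    counts: Counter = Counter()
    uniform = [s for s in seqs if len(s) == length] if length else []
    if length and len(uniform) == len(seqs) and length >= k:
        try:
            mat = _seq.encode_reads(seqs, length)
        except ValueError:
            mat = None
        if mat is not None:
            fwd = _seq.rolling_kmer_codes(mat, k)
            rev = _seq.revcomp_kmer_codes(fwd, k)
            canon = np.minimum(fwd, rev).ravel()
            codes, n = np.unique(canon, return_counts=True)
            return Counter({int(c): int(v) for c, v in zip(codes, n)})
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if any(b not in "ACGT" for b in km):
                continue
            counts[_canon_code(km, k)] += 1
    return counts


def _canon_code(km: str, k: int) -> int:
    code = 0
    for b in km:
        code = (code << 2) | "ACGT".index(b)
    rc = 0
    cur = code
    for _ in range(k):
        rc = (rc << 2) | (3 - (cur & 3))
        cur >>= 2
    return min(code, rc)


def _build_unitigs(kmers: set[str], k: int) -> list[str]:
    """Maximal unambiguous paths over a double-stranded k-mer set."""

    def succs(km: str) -> list[str]:
        suf = km[1:]
        return [suf + b for b in "ACGT" if suf + b in kmers]

    def preds(km: str) -> list[str]:
        pre = km[:-1]
        return [b + pre for b in "ACGT" if b + pre in kmers]

    visited: set[str] = set()
    unitigs: set[str] = set()

    def walk(start: str) -> str:
        seq = start
        cur = start
        visited.add(start)
        visited.add(_seq.revcomp(start))
        while True:
            nxt = succs(cur)
            if len(nxt) != 1:
                break
            nxt_km = nxt[0]
            if len(preds(nxt_km)) != 1 or nxt_km in visited:
                break
            seq += nxt_km[-1]
            cur = nxt_km
            visited.add(nxt_km)
            visited.add(_seq.revcomp(nxt_km))
        return seq

    # unitig starts: k-mers whose backward extension is ambiguous or absent
    for km in sorted(kmers):
        if km in visited:
            continue
        p = preds(km)
        if len(p) == 1 and len(succs(p[0])) == 1:
            continue  # interior of some unitig
        unitigs.add(_seq.canonical(walk(km)))

    # leftovers are simple cycles; break each at its smallest k-mer
    for km in sorted(kmers):
        if km not in visited:
            unitigs.add(_seq.canonical(walk(km)))

    return sorted(unitigs)


def _clip_tips(kmers: set[str], k: int) -> set[str]:
    """Remove dead-end unitigs shorter than 2k that hang off a junction."""

    def succs(km: str) -> list[str]:
        suf = km[1:]
        return [suf + b for b in "ACGT" if suf + b in kmers]

    def preds(km: str) -> list[str]:
        pre = km[:-1]
        return [b + pre for b in "ACGT" if b + pre in kmers]

    unitigs = _build_unitigs(kmers, k)
    drop: set[str] = set()
    for u in unitigs:
        if len(u) >= 2 * k:
            continue
        for seq in (u, _seq.revcomp(u)):
            first, last = seq[:k], seq[-k:]
            dead_start = len(preds(first)) == 0
            attached_end = len(succs(last)) >= 1
            if dead_start and attached_end:
                for i in range(len(seq) - k + 1):
                    km = seq[i : i + k]
                    drop.add(km)
                    drop.add(_seq.revcomp(km))
                break
    return kmers - drop


def assemble(
    reads: ReadSet | list[str],
    k: int = 25,
    min_kmer_count: int = 2,
    min_contig_length: int = 200,
) -> list[Contig]:
    """Assemble a pooled read set into unitig contigs.

    Contig ids are deterministic: contigs sorted by (canonical) sequence and
    indexed. The emitted strand is the lexicographically smaller of a
    unitig's two orientations, so output is independent of read input order.
    """
    if isinstance(reads, ReadSet):
        seqs = [seq for (_, seq, _) in reads.iter_pooled()]
        read_length: int | None = reads.read_length
    else:
        seqs = list(reads)
        read_length = len(seqs[0]) if seqs and len({len(s) for s in seqs}) == 1 else None
    if k % 2 == 0 or k < 15:
        raise ValueError("k must be odd and >= 15")
    if seqs and read_length is not None and k >= read_length:
        raise ValueError("k must be smaller than the read length")
    if not seqs:
        return []
    if any(len(s) < k for s in seqs):
        raise ValueError("k must be smaller than every read length")

    counts = _count_canonical_kmers(seqs, k, read_length)
    surviving = {code for code, c in counts.items() if c >= min_kmer_count}
    if not surviving:
        return []

    kmers: set[str] = set()
    for code in surviving:
        km = _seq.kmer_code_to_str(code, k)
        kmers.add(km)
        kmers.add(_seq.revcomp(km))

    kmers = _clip_tips(kmers, k)
    unitigs = [u for u in _build_unitigs(kmers, k) if len(u) >= min_contig_length]
    width = max(5, len(str(len(unitigs))))
    return [Contig(f"contig_{i + 1:0{width}d}", u) for i, u in enumerate(unitigs)]


# --------------------------------------------------------------------------- #
# mapper
# --------------------------------------------------------------------------- #


@dataclass
class MappingResult:
    counts: pd.DataFrame  # contigs x samples
    mapped: dict[str, int]  # sample -> mapped reads
    unmapped: dict[str, int]  # sample -> unmapped reads


def _mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_reads(
    reads: ReadSet,
    contigs: list[Contig],
    seed_kmer: int = 25,
    max_mismatch: int = 3,
) -> MappingResult:
    """Assign each read to at most one contig (fewest mismatches wins).

    Candidates come from exact seed-k-mer lookup on both read strands; the
    winning placement is verified full-length with at most ``max_mismatch``
    substitutions. Ties break to the lexicographically smallest contig_id.
    """
    if seed_kmer > reads.read_length:
        raise ValueError("seed_kmer must not exceed the read length")

    index: dict[str, list[tuple[int, int]]] = {}
    for ci, contig in enumerate(contigs):
        s = contig.sequence
        for pos in range(len(s) - seed_kmer + 1):
            index.setdefault(s[pos : pos + seed_kmer], []).append((ci, pos))

    samples = reads.samples
    counts = np.zeros((len(contigs), len(samples)), dtype=np.int64)
    mapped: dict[str, int] = {}
    unmapped: dict[str, int] = {}
    rl = reads.read_length
    probe_offsets = sorted({o for o in range(0, rl - seed_kmer + 1, seed_kmer)} | {rl - seed_kmer})

    for s_idx, sample in enumerate(samples):
        n_mapped = 0
        for _, seq, _ in reads.reads_by_sample[sample]:
            best: tuple[int, str, int] | None = None  # (mm, contig_id, ci)
            for oriented in (seq, _seq.revcomp(seq)):
                seen_placements: set[tuple[int, int]] = set()
                for off in probe_offsets:
                    seed = oriented[off : off + seed_kmer]
                    for ci, pos in index.get(seed, ()):
                        start = pos - off
                        if start < 0 or start + rl > len(contigs[ci].sequence):
                            continue
                        if (ci, start) in seen_placements:
                            continue
                        seen_placements.add((ci, start))
                        window = contigs[ci].sequence[start : start + rl]
                        mm = _mismatches(oriented, window, max_mismatch)
                        if mm > max_mismatch:
                            continue
                        cand = (mm, contigs[ci].contig_id, ci)
                        if best is None or cand[:2] < best[:2]:
                            best = cand
            if best is None:
                continue
            counts[best[2], s_idx] += 1
            n_mapped += 1
        mapped[sample] = n_mapped
        unmapped[sample] = len(reads.reads_by_sample[sample]) - n_mapped

    df = pd.DataFrame(counts, index=[c.contig_id for c in contigs], columns=samples)
    for contig in contigs:
        contig.counts = {s: int(df.loc[contig.contig_id, s]) for s in samples}
    return MappingResult(counts=df, mapped=mapped, unmapped=unmapped)
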