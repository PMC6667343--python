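"""ORF prediction, peptide clustering, and translated protein search.

Six-frame translation yields at most one peptide per frame per parent (the
longest stop-free stretch); short reads instead contribute their single best
peptide. Peptides are greedily clustered at an identity threshold, and
cluster representatives are aligned to the reference database with local
affine-gap Smith-Waterman (BLOSUM62 by default). Raw scores are converted to
bit scores and Karlin-Altschul E-values:

    bits = (lambda * S - ln K) / ln 2        E = K * m * n * exp(-lambda * S)

with fixed gapped-BLOSUM62 constants. Because both workflows are compared at
matched thresholds, absolute E-value calibration cancels out.

The alignment DP itself runs on Bio.Align.PairwiseAligner (C implementation);
scoring conversion, thresholds, the k-mer prefilter and all hit bookkeeping
live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _seq
from .synthetic_data import ReferenceDB

__all__ = [
    "Peptide",
    "AlignmentHit",
    "AlignerParams",
    "Threshold",
    "six_frame_orfs",
    "read_orfs",
    "bulk_read_orfs",
    "cluster_peptides",
    "PeptideCluster",
    "sw_align",
    "karlin_altschul_evalue",
    "bit_score",
    "search",
]

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Peptide:
    peptide_id: str
    parent_id: str
    frame: int
    start: int  # 0-based half-open nt coordinates on the parent
    end: int
    sequence: str


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    aln_length: int
    identity: float
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 0  # 1-based, BLAST tabular convention
    qend: int = 0
    sstart: int = 0
    send: int = 0


@dataclass(frozen=True)
class AlignerParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    K: float = 0.041
    lam: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


@dataclass(frozen=True)
class Threshold:
    """Confidence cut-off: either (max E-value AND min alignment length) or
    a minimum bit score."""

    mode: str  # "evalue" | "bitscore"
    max_evalue: float = math.inf
    min_aln_length: int = 0
    min_bitscore: float = 0.0
    label: str = ""
    category: str = ""

    @classmethod
    def evalue(cls, max_evalue: float, min_aln_length: int = 15, category: str = "") -> "Threshold":
        return cls(
            mode="evalue",
            max_evalue=max_evalue,
            min_aln_length=min_aln_length,
            label=f"{max_evalue:.0E}",
            category=category,
        )

    @classmethod
    def bitscore(cls, min_bitscore: float, category: str = "") -> "Threshold":
        return cls(
            mode="bitscore",
            min_bitscore=min_bitscore,
            label=f"BTS {min_bitscore:g}",
            category=category,
        )

    def passes(self, hit: AlignmentHit) -> bool:
        if self.mode == "evalue":
            return hit.e_value <= self.max_evalue and hit.aln_length >= self.min_aln_length
        if self.mode == "bitscore":
            return hit.bit_score >= self.min_bitscore
        raise ValueError(f"unknown threshold mode {self.mode!r}")


# --------------------------------------------------------------------------- #
# ORF prediction
# --------------------------------------------------------------------------- #


def _translate_frame(seq: str, offset: int) -> str:
    aas = []
    table = _seq.CODON_TABLE
    for i in range(offset, len(seq) - 2, 3):
        aas.append(table.get(seq[i : i + 3], "X"))
    return "".join(aas)


def _longest_stop_free(aa: str) -> tuple[int, int]:
    """(start, length) of the leftmost longest stop-free stretch."""
    best_start, best_len = 0, 0
    start = 0
    for i, ch in enumerate(aa + "*"):
        if ch == "*":
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i + 1
    return best_start, best_len


def _frame_peptide(parent_id: str, seq: str, frame: int, min_aa: int) -> Peptide | None:
    L = len(seq)
    offset = abs(frame) - 1
    src = seq if frame > 0 else _seq.revcomp(seq)
    aa = _translate_frame(src, offset)
    a, m = _longest_stop_free(aa)
    if m < min_aa:
        return None
    s = offset + 3 * a
    e = s + 3 * m
    if frame < 0:
        s, e = L - e, L - s
    return Peptide(
        peptide_id=f"{parent_id}|{frame:+d}",
        parent_id=parent_id,
        frame=frame,
        start=s,
        end=e,
        sequence=aa[a : a + m],
    )


def six_frame_orfs(parent_id: str, sequence: str, min_aa: int = 30) -> list[Peptide]:
    """Longest stop-free peptide per frame (up to six per parent).

    Codons containing non-ACGT symbols translate to X, which is allowed
    inside ORFs; only stop codons break a stretch.
    """
    peptides = []
    for frame in FRAMES:
        p = _frame_peptide(parent_id, sequence, frame, min_aa)
        if p is not None:
            peptides.append(p)
    return peptides


def read_orfs(parent_id: str, sequence: str, min_aa: int = 20) -> list[Peptide]:
    """Single longest peptide over all six frames (at most one per read).

    Equal-length stretches resolve by frame order +1, +2, +3, -1, -2, -3.
    """
    best: Peptide | None = None
    for frame in FRAMES:
        p = _frame_peptide(parent_id, sequence, frame, min_aa=1)
        if p is not None and (best is None or len(p.sequence) > len(best.sequence)):
            best = p
    if best is None or len(best.sequence) < min_aa:
        return []
    return [best]


def bulk_read_orfs(
    ids: list[str], seqs: list[str], read_length: int, min_aa: int = 20
) -> list[Peptide]:
    """Vectorised ``read_orfs`` over an equal-length read pool.

    Only reads over {A,C,G,T} take the fast path; others fall back to the
    scalar routine. Results are identical to calling read_orfs per read.
    """
    clean_idx, dirty_idx = [], []
    for i, s in enumerate(seqs):
        (clean_idx if set(s) <= set("ACGT") else dirty_idx).append(i)
    out: list[Peptide | None] = [None] * len(seqs)
    for i in dirty_idx:
        hits = read_orfs(ids[i], seqs[i], min_aa)
        out[i] = hits[0] if hits else None
    if clean_idx:
        mat = _seq.encode_reads([seqs[i] for i in clean_idx], read_length)
        n = len(clean_idx)
        rc = (3 - mat)[:, ::-1]
        stop_code = ord("*")
        frame_aas: list[np.ndarray] = []
        frame_best: list[tuple[np.ndarray, np.ndarray]] = []
        for frame in FRAMES:
            src = mat if frame > 0 else rc
            off = abs(frame) - 1
            m = (read_length - off) // 3
            cod = (
                16 * src[:, off : off + 3 * m : 3].astype(np.int16)
                + 4 * src[:, off + 1 : off + 1 + 3 * m : 3]
                + src[:, off + 2 : off + 2 + 3 * m : 3]
            )
            aa = _seq.CODON_AA_CODES[cod]  # (n, m) ascii codes
            stops = aa == stop_code
            cur = np.zeros(n, dtype=np.int32)
            best = np.zeros(n, dtype=np.int32)
            best_end = np.zeros(n, dtype=np.int32)
            for j in range(m):
                cur = np.where(stops[:, j], 0, cur + 1)
                upd = cur > best
                best[upd] = cur[upd]
                best_end[upd] = j
            frame_aas.append(aa)
            frame_best.append((best, best_end))
        lengths = np.stack([b for b, _ in frame_best], axis=1)  # (n, 6)
        winner = np.argmax(lengths, axis=1)  # first max -> frame order
        for row, i in enumerate(clean_idx):
            f_idx = int(winner[row])
            blen = int(lengths[row, f_idx])
            if blen < min_aa:
                continue
            frame = FRAMES[f_idx]
            aa = frame_aas[f_idx]
            end_aa = int(frame_best[f_idx][1][row]) + 1
            start_aa = end_aa - blen
            seq_aa = aa[row, start_aa:end_aa].tobytes().decode()
            off = abs(frame) - 1
            s = off + 3 * start_aa
            e = s + 3 * blen
            if frame < 0:
                s, e = read_length - e, read_length - s
            out[i] = Peptide(
                peptide_id=f"{ids[i]}|{frame:+d}",
                parent_id=ids[i],
                frame=frame,
                start=s,
                end=e,
                sequence=seq_aa,
            )
    return [p for p in out if p is not None]


# --------------------------------------------------------------------------- #
# clustering
# --------------------------------------------------------------------------- #


@dataclass
class PeptideCluster:
    representative: Peptide
    members: list[Peptide]

    @property
    def size(self) -> int:
        return len(self.members)


def _ungapped_identity(short: str, long_: str, diagonals: set[int]) -> float:
    """Best matches/len(short) over the candidate diagonals (offset of short
    inside long)."""
    best = 0
    for d in diagonals:
        lo = max(0, -d)
        hi = min(len(short), len(long_) - d)
        if hi - lo <= best:
            continue
        matches = sum(1 for i in range(lo, hi) if short[i] == long_[i + d])
        best = max(best, matches)
    return best / len(short) if short else 0.0


def cluster_peptides(
    peptides: list[Peptide],
    identity_threshold: float = 0.95,
    word_size: int = 8,
) -> list[PeptideCluster]:
    """Greedy incremental clustering by decreasing length.

    Each peptide joins the first existing cluster whose representative it
    matches at >= identity_threshold (ungapped, word-seeded, identity over
    the shorter sequence), otherwise it founds a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must lie in (0, 1]")

    by_seq: dict[str, list[Peptide]] = {}
    for p in peptides:
        by_seq.setdefault(p.sequence, []).append(p)
    order = sorted(by_seq, key=lambda s: (-len(s), s))

    clusters: list[PeptideCluster] = []
    word_index: dict[str, list[int]] = {}  # word -> cluster indices
    rep_words_cache: list[dict[str, list[int]]] = []  # per cluster

    def min_shared_words(m: int) -> int:
        # a >= thr identity match of length m tolerates floor((1-thr)*m)
        # mismatches; each destroys at most word_size words, so any true
        # member still shares this many words with its representative
        e = int((1.0 - identity_threshold) * m)
        return max(1, int(math.ceil(identity_threshold * m)) - (word_size - 1) - word_size * e)

    for seq in order:
        assigned = None
        if len(seq) < word_size:
            candidates = list(range(len(clusters)))
        else:
            shared: dict[int, int] = {}
            for i in range(len(seq) - word_size + 1):
                for ci in word_index.get(seq[i : i + word_size], ()):
                    shared[ci] = shared.get(ci, 0) + 1
            need = min_shared_words(len(seq))
            candidates = sorted(ci for ci, c in shared.items() if c >= need)
        for ci in candidates:
            rep = clusters[ci].representative.sequence
            if len(seq) < word_size:
                diags = set(range(-len(seq) + 1, len(rep)))
            else:
                diags = set()
                rep_words = rep_words_cache[ci]
                for i in range(len(seq) - word_size + 1):
                    for j in rep_words.get(seq[i : i + word_size], ()):
                        diags.add(j - i)
            if not diags:
                continue
            if _ungapped_identity(seq, rep, diags) >= identity_threshold:
                assigned = ci
                break
        if assigned is None:
            rep_pep = by_seq[seq][0]
            clusters.append(PeptideCluster(representative=rep_pep, members=[]))
            assigned = len(clusters) - 1
            words: dict[str, list[int]] = {}
            for i in range(len(seq) - word_size + 1):
                w = seq[i : i + word_size]
                words.setdefault(w, []).append(i)
                word_index.setdefault(w, []).append(assigned)
            rep_words_cache.append(words)
        clusters[assigned].members.extend(by_seq[seq])
    return clusters


# --------------------------------------------------------------------------- #
# alignment
# --------------------------------------------------------------------------- #


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    # unknown residues score at the matrix minimum, never contributing to hits
    floor = float(np.min(mat))
    for ch in ("X", "B", "Z"):
        if ch in mat.alphabet:
            mat[ch, :] = floor
            mat[:, ch] = floor
    return mat


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # BLAST convention: a length-g gap costs gap_open + g * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float, params: AlignerParams) -> float:
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def karlin_altschul_evalue(raw_score: float, search_space: float, params: AlignerParams) -> float:
    """E = K * m * n * exp(-lambda * S): decreasing in S, linear in m * n."""
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    if search_space <= 0:
        raise ValueError("search_space must be positive")
    return params.K * search_space * math.exp(-params.lam * raw_score)


def _traceback_stats(alignment) -> tuple[int, int, int, int, tuple[int, int, int, int]]:
    """(aln_length, matches, mismatches, gap_opens, 1-based q/s coords).

    Biopython calls the first sequence passed to align() the "target"; here
    that is our query peptide and the "query" is our subject protein.
    """
    t = str(alignment.target)
    q = str(alignment.query)
    tb, qb = alignment.aligned  # blocks on (our query, our subject)
    aln_length = matches = mismatches = gap_opens = 0
    prev_te = prev_qe = None
    for (ts, te), (qs, qe) in zip(tb, qb):
        if prev_te is not None:
            dt = ts - prev_te
            dq = qs - prev_qe
            aln_length += dt + dq
            gap_opens += (1 if dt else 0) + (1 if dq else 0)
        for i in range(te - ts):
            aln_length += 1
            if t[ts + i] == q[qs + i]:
                matches += 1
            else:
                mismatches += 1
        prev_te, prev_qe = te, qe
    coords = (int(tb[0][0]) + 1, int(tb[-1][1]), int(qb[0][0]) + 1, int(qb[-1][1]))
    return aln_length, matches, mismatches, gap_opens, coords


def sw_align(
    query: str,
    subject: str,
    params: AlignerParams = AlignerParams(),
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: float | None = None,
) -> AlignmentHit | None:
    """Optimal local affine-gap alignment of a peptide against a protein.

    Returns None when the optimal raw score is zero (no positive-scoring
    local alignment exists).
    """
    if not query or not subject:
        raise ValueError("empty sequences cannot be aligned")
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    raw = aligner.score(query, subject)
    if raw <= 0:
        return None
    if search_space is None:
        search_space = len(query) * len(subject)
    alignment = aligner.align(query, subject)[0]
    aln_length, matches, mismatches, gap_opens, coords = _traceback_stats(alignment)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(round(raw)),
        bit_score=bit_score(raw, params),
        e_value=karlin_altschul_evalue(raw, search_space, params),
        aln_length=aln_length,
        identity=matches / aln_length if aln_length else 0.0,
        mismatches=mismatches,
        gap_opens=gap_opens,
        qstart=coords[0],
        qend=coords[1],
        sstart=coords[2],
        send=coords[3],
    )


# --------------------------------------------------------------------------- #
# database search
# --------------------------------------------------------------------------- #

_PREFILTER_WORD = 4


def _subject_word_index(db: ReferenceDB) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, entry in enumerate(db.entries):
        p = entry.protein
        for j in range(len(p) - _PREFILTER_WORD + 1):
            index.setdefault(p[j : j + _PREFILTER_WORD], set()).add(i)
    return index


def search(
    queries: list[Peptide],
    db: ReferenceDB,
    threshold: Threshold | None = None,
    params: AlignerParams = AlignerParams(),
    prefilter: bool = True,
    compute_stats: bool = True,
) -> list[AlignmentHit]:
    """Align every query against the database and keep hits passing the
    threshold (pass ``threshold=None`` to keep every positive-scoring hit).

    With ``prefilter=True`` only query/subject pairs sharing an exact 4-mer
    are aligned; hits strong enough to matter at the default thresholds
    always share one on this problem scale.

    ``compute_stats=False`` skips the traceback (alignment length, identity
    and coordinates stay zero) for bit-score-only pipelines where the hit
    set is filtered purely on scores; ``fill_hit_stats`` restores them.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    if compute_stats is False and threshold is not None and threshold.mode == "evalue":
        raise ValueError("E-value/length thresholds require compute_stats=True")
    total_residues = db.total_residues
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    word_index = _subject_word_index(db) if prefilter else None

    hits: list[AlignmentHit] = []
    for pep in queries:
        q = pep.sequence
        if word_index is not None:
            cand: set[int] = set()
            for j in range(len(q) - _PREFILTER_WORD + 1):
                cand |= word_index.get(q[j : j + _PREFILTER_WORD], set())
            candidates = sorted(cand)
        else:
            candidates = range(len(db.entries))
        m_n = len(q) * total_residues
        for i in candidates:
            entry = db.entries[i]
            raw = aligner.score(q, entry.protein)
            if raw <= 0:
                continue
            bits = bit_score(raw, params)
            ev = karlin_altschul_evalue(raw, m_n, params)
            if threshold is not None:
                if threshold.mode == "bitscore" and bits < threshold.min_bitscore:
                    continue
                if threshold.mode == "evalue" and ev > threshold.max_evalue:
                    continue
            if compute_stats:
                alignment = aligner.align(q, entry.protein)[0]
                aln_length, matches, mismatches, gap_opens, coords = _traceback_stats(alignment)
            else:
                aln_length = matches = mismatches = gap_opens = 0
                coords = (0, 0, 0, 0)
            hit = AlignmentHit(
                query_id=pep.peptide_id,
                subject_id=entry.subject_id,
                raw_score=int(round(raw)),
                bit_score=bits,
                e_value=ev,
                aln_length=aln_length,
                identity=matches / aln_length if aln_length else 0.0,
                mismatches=mismatches,
                gap_opens=gap_opens,
                qstart=coords[0],
                qend=coords[1],
                sstart=coords[2],
                send=coords[3],
            )
            if threshold is None or not compute_stats or threshold.passes(hit):
                hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, -h.bit_score, h.subject_id))
    return hits


def fill_hit_stats(
    hits: list[AlignmentHit],
    sequences_by_query: dict[str, str],
    db: ReferenceDB,
    params: AlignerParams = AlignerParams(),
) -> list[AlignmentHit]:
    """Compute traceback statistics for hits produced with
    ``compute_stats=False`` (in place; returns the list for convenience)."""
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    for h in hits:
        if h.aln_length:
            continue
        q = sequences_by_query[h.query_id]
        alignment = aligner.align(q, db.entry(h.subject_id).protein)[0]
        aln_length, matches, mismatches, gap_opens, coords = _traceback_stats(alignment)
        h.aln_length = aln_length
        h.identity = matches / aln_length if aln_length else 0.0
        h.mismatches = mismatches
        h.gap_opens = gap_opens
        h.qstart, h.qend, h.sstart, h.send = coords
    return hits


def refilter_hits(
    hits: list[AlignmentHit],
    threshold: Threshold,
    db: ReferenceDB | None = None,
    full_db_residues: int | None = None,
) -> list[AlignmentHit]:
    """Re-apply a threshold to stored un-thresholded hits.

    When ``db`` is a cropped database, hits to removed subjects are dropped
    and E-values rescaled to the smaller search space (E is linear in the
    database length), which is exactly equivalent to re-running the search.
    """
    out = []
    scale = 1.0
    keep_subjects = None
    if db is not None:
        keep_subjects = {e.subject_id for e in db.entries}
        if full_db_residues:
            scale = db.total_residues / full_db_residues
    for h in hits:
        if keep_subjects is not None and h.subject_id not in keep_subjects:
            continue
        h2 = replace(h, e_value=h.e_value * scale) if scale != 1.0 else h
        if threshold.passes(h2):
            out.append(h2)
    out.sort(key=lambda h: (h.query_id, -h.bit_score, h.subject_id))
    return out
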