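"""ORF prediction, clustering and Smith-Waterman search, including the
exhaustive local-alignment oracle on short peptides."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given
from hypothesis import strategies as st

from mtx_arena import _seq
from mtx_arena.homology import (
    AlignerParams,
    Threshold,
    bit_score,
    bulk_read_orfs,
    cluster_peptides,
    karlin_altschul_evalue,
    read_orfs,
    search,
    six_frame_orfs,
    sw_align,
)
from mtx_arena.synthetic_data import generate_catalog

AA = _seq.AMINO_ACIDS
_B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(q: str, s: str, gap_open=11, gap_extend=1) -> float:
    """Exhaustive enumeration of all local alignments via index matchings.

    Every local alignment corresponds to a strictly increasing matching of
    query positions to subject positions; skipped positions between matched
    pairs form affine gaps (simultaneous skips on both sides count as two
    separate gaps). No dynamic programming involved.
    """
    best = 0.0
    n, m = len(q), len(s)
    for k in range(1, min(n, m) + 1):
        for qi in itertools.combinations(range(n), k):
            for si in itertools.combinations(range(m), k):
                score = sum(_B62[q[a], s[b]] for a, b in zip(qi, si))
                for arr in (qi, si):
                    for x, y in zip(arr, arr[1:]):
                        g = y - x - 1
                        if g:
                            score -= gap_open + g * gap_extend
                best = max(best, score)
    return best


class TestSixFrameOrfs:
    def test_hand_translation(self):
        peps = six_frame_orfs("p", "ATGAAATAA", min_aa=2)
        plus1 = [p for p in peps if p.frame == 1]
        assert len(plus1) == 1
        assert plus1[0].sequence == "MK"
        assert (plus1[0].start, plus1[0].end) == (0, 6)

    def test_revcomp_symmetry(self, rng):
        seq = _seq.decode(rng.integers(0, 4, size=300).astype(np.uint8))
        fwd = {p.frame: p.sequence for p in six_frame_orfs("a", seq, min_aa=5)}
        rev = {p.frame: p.sequence for p in six_frame_orfs("b", _seq.revcomp(seq), min_aa=5)}
        for f in (1, 2, 3):
            assert fwd.get(f) == rev.get(-f)
            assert fwd.get(-f) == rev.get(f)

    def test_min_aa_threshold_empties(self):
        assert six_frame_orfs("p", "ATGAAATAA", min_aa=5) == []

    def test_coordinates_map_back_to_parent(self, rng):
        seq = _seq.decode(rng.integers(0, 4, size=240).astype(np.uint8))
        for p in six_frame_orfs("x", seq, min_aa=5):
            sub = seq[p.start : p.end]
            if p.frame < 0:
                sub = _seq.revcomp(sub)
            assert _seq.translate(sub) == p.sequence

    def test_n_translates_to_x_inside_orf(self):
        peps = six_frame_orfs("p", "ATGANAAAAATG", min_aa=3)
        plus1 = [p for p in peps if p.frame == 1][0]
        assert "X" in plus1.sequence


class TestReadOrfs:
    def test_read_inside_cds_matches_protein(self, small_catalog_db):
        catalog, _ = small_catalog_db
        gene = catalog.genes[0]
        read = gene.cds[:99]
        peps = read_orfs("r", read, min_aa=20)
        assert len(peps) == 1
        assert peps[0].sequence == gene.protein[:33]

    def test_no_stretch_above_min(self):
        # find (by independent Biopython translation) a read whose longest
        # stop-free stretch is < 20 aa in every frame, then assert emptiness
        from Bio.Seq import Seq

        rng = np.random.default_rng(99)
        seq = None
        for _ in range(500):
            cand = _seq.decode(rng.integers(0, 4, size=100).astype(np.uint8))
            longest = 0
            for src in (cand, _seq.revcomp(cand)):
                for off in range(3):
                    codons = src[off : off + 3 * ((100 - off) // 3)]
                    aa = str(Seq(codons).translate())
                    longest = max(longest, max(len(x) for x in aa.split("*")))
            if longest < 20:
                seq = cand
                break
        assert seq is not None, "no all-frames-blocked read found"
        assert read_orfs("r", seq, min_aa=20) == []

    def test_bulk_matches_scalar(self, rng):
        seqs = [_seq.decode(rng.integers(0, 4, size=100).astype(np.uint8)) for _ in range(300)]
        ids = [f"r{i}" for i in range(300)]
        bulk = {p.parent_id: p for p in bulk_read_orfs(ids, seqs, 100, min_aa=20)}
        for rid, s in zip(ids, seqs):
            scalar = read_orfs(rid, s, min_aa=20)
            if scalar:
                p, b = scalar[0], bulk[rid]
                assert (p.frame, p.start, p.end, p.sequence) == (b.frame, b.start, b.end, b.sequence)
            else:
                assert rid not in bulk


class TestClusterPeptides:
    def _pep(self, i, seq):
        from mtx_arena.homology import Peptide

        return Peptide(f"p{i}", f"parent{i}", 1, 0, 3 * len(seq), seq)

    def test_identical_peptides_merge(self, rng):
        seq = "".join(AA[i] for i in rng.integers(0, 20, size=40))
        clusters = cluster_peptides([self._pep(0, seq), self._pep(1, seq)], 0.95)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_threshold_one_keeps_distinct_apart(self, rng):
        seqs = {"".join(AA[i] for i in rng.integers(0, 20, size=30)) for _ in range(10)}
        peps = [self._pep(i, s) for i, s in enumerate(sorted(seqs))]
        clusters = cluster_peptides(peps, 1.0)
        assert len(clusters) == len(seqs)

    def test_ninety_percent_identity_split_at_095(self, rng):
        base = list("".join(AA[i] for i in rng.integers(0, 20, size=100)))
        mutant = list(base)
        for pos in rng.choice(100, size=10, replace=False):
            mutant[pos] = AA[(AA.index(mutant[pos]) + 1) % 20]
        clusters = cluster_peptides(
            [self._pep(0, "".join(base)), self._pep(1, "".join(mutant))], 0.95
        )
        assert len(clusters) == 2  # identity 0.90 < 0.95

    def test_small_substitution_joins_cluster(self, rng):
        base = list("".join(AA[i] for i in rng.integers(0, 20, size=100)))
        mutant = list(base)
        mutant[50] = AA[(AA.index(mutant[50]) + 1) % 20]
        clusters = cluster_peptides(
            [self._pep(0, "".join(base)), self._pep(1, "".join(mutant))], 0.95
        )
        assert len(clusters) == 1 and clusters[0].size == 2


class TestSwAlign:
    def test_hand_blosum_sum(self):
        hit = sw_align("MKV", "MKV")
        assert hit.raw_score == 14  # 5 + 5 + 4 on the BLOSUM62 diagonal
        assert hit.identity == 1.0 and hit.aln_length == 3

    def test_self_alignment_full_identity(self, rng):
        seq = "".join(AA[i] for i in rng.integers(0, 20, size=30))
        hit = sw_align(seq, seq)
        assert hit.identity == 1.0
        assert hit.aln_length == len(seq)

    def test_score_symmetry(self, rng):
        for _ in range(20):
            a = "".join(AA[i] for i in rng.integers(0, 20, size=12))
            b = "".join(AA[i] for i in rng.integers(0, 20, size=15))
            ha = sw_align(a, b)
            hb = sw_align(b, a)
            sa = ha.raw_score if ha else 0
            sb = hb.raw_score if hb else 0
            assert sa == sb

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            sw_align("", "MKV")

    def test_exhaustive_oracle_small_pairs(self, rng):
        # spot-check here; the full 1,000-pair sweep runs in the acceptance suite
        for _ in range(50):
            la, lb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = "".join(AA[i] for i in rng.integers(0, 20, size=la))
            b = "".join(AA[i] for i in rng.integers(0, 20, size=lb))
            hit = sw_align(a, b)
            dp = hit.raw_score if hit else 0
            assert dp == brute_force_local_score(a, b)


class TestEvalue:
    def test_zero_score_limit(self):
        p = AlignerParams()
        assert karlin_altschul_evalue(0, 1e6, p) == pytest.approx(p.K * 1e6)

    def test_linear_in_search_space(self):
        p = AlignerParams()
        assert karlin_altschul_evalue(30, 2e6, p) == pytest.approx(
            2 * karlin_altschul_evalue(30, 1e6, p)
        )

    def test_direct_evaluation(self):
        # S=14, m*n=1e6, K=0.041, lambda=0.267 -> 0.041e6 * exp(-3.738)
        e = karlin_altschul_evalue(14, 1e6, AlignerParams())
        assert e == pytest.approx(975.868, abs=0.01)

    def test_bit_score_monotone(self):
        p = AlignerParams()
        bits = [bit_score(s, p) for s in range(0, 200, 10)]
        assert all(a < b for a, b in zip(bits, bits[1:]))

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=10**9))
    def test_evalue_decreasing_in_score(self, s, mn):
        p = AlignerParams()
        assert karlin_altschul_evalue(s + 1, mn, p) < karlin_altschul_evalue(s, mn, p)


class TestSearch:
    @pytest.fixture(scope="class")
    def catalog_db_queries(self):
        catalog, db = generate_catalog(20, 10, 4, 2, seed=13)
        queries = []
        for g in catalog.genes[:8]:
            queries.extend(six_frame_orfs(g.gene_id, g.cds, min_aa=30))
        return catalog, db, queries

    def test_evalue_threshold_respected(self, catalog_db_queries):
        _, db, queries = catalog_db_queries
        hits = search(queries, db, Threshold.evalue(1e-5, 15))
        assert hits
        for h in hits:
            assert h.e_value <= 1e-5 and h.aln_length >= 15

    def test_bitscore_threshold_respected(self, catalog_db_queries):
        _, db, queries = catalog_db_queries
        hits = search(queries, db, Threshold.bitscore(50))
        assert hits
        assert all(h.bit_score >= 50 for h in hits)

    def test_stricter_threshold_nested(self, catalog_db_queries):
        _, db, queries = catalog_db_queries
        loose = {(h.query_id, h.subject_id) for h in search(queries, db, Threshold.evalue(1e-3, 10))}
        strict = {(h.query_id, h.subject_id) for h in search(queries, db, Threshold.evalue(1e-8, 10))}
        assert strict <= loose

    def test_prefilter_lossless_at_default_thresholds(self, catalog_db_queries):
        _, db, queries = catalog_db_queries
        for thr in (Threshold.evalue(1e-5, 15), Threshold.bitscore(50)):
            with_pf = {(h.query_id, h.subject_id) for h in search(queries, db, thr, prefilter=True)}
            without = {(h.query_id, h.subject_id) for h in search(queries, db, thr, prefilter=False)}
            assert with_pf == without

    def test_output_ordering(self, catalog_db_queries):
        _, db, queries = catalog_db_queries
        hits = search(queries, db, Threshold.evalue(1e-3, 10))
        key = [(h.query_id, -h.bit_score, h.subject_id) for h in hits]
        assert key == sorted(key)
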