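"""Generator contracts: catalog/database invariants, regulation bookkeeping,
read conservation and the substitution error model."""

import numpy as np
import pytest

from mtx_arena import _seq
from mtx_arena.synthetic_data import (
    ExpressionDesign,
    design_expression,
    generate_catalog,
    illumina_error_profile,
    make_ncrna_refs,
    round_half_up,
    simulate_reads,
    spike_ncrna,
)


class TestGenerateCatalog:
    def test_counts_forced_by_parameters(self):
        catalog, db = generate_catalog(200, 100, 25, 10, decoys_per_ortholog=1, seed=0)
        assert len(catalog) == 200
        assert len(db) == 200  # 100 canonical refs + 100 decoys
        assert sum(db.decoy_flags.values()) == 100

    def test_catalog_invariants(self, small_catalog_db):
        catalog, db = small_catalog_db
        ids = set()
        for g in catalog.genes:
            assert g.gene_id not in ids
            ids.add(g.gene_id)
            assert len(g.cds) % 3 == 0 and len(g.cds) >= 150
            assert _seq.translate(g.cds) == g.protein
            assert "*" not in g.protein
            assert g.true_ortholog in db.hierarchy

    def test_reference_db_invariants(self, small_catalog_db):
        catalog, db = small_catalog_db
        for e in db.entries:
            assert e.ortholog in db.hierarchy
        # at least one non-decoy entry per catalog ortholog
        non_decoy = {e.ortholog for e in db.entries if not db.decoy_flags[e.subject_id]}
        assert {g.true_ortholog for g in catalog.genes} <= non_decoy

    def test_canonical_ref_is_exact_member_translation(self, small_catalog_db):
        catalog, db = small_catalog_db
        member_proteins = {}
        for g in catalog.genes:
            member_proteins.setdefault(g.true_ortholog, []).append(g.protein)
        for e in db.entries:
            if not db.decoy_flags[e.subject_id] and e.ortholog in member_proteins:
                assert e.protein in member_proteins[e.ortholog]

    def test_decoy_divergence_binomial(self):
        # 0.70 identity on a 100-aa protein: ~30 +/- 3 binomial sd differences
        catalog, db = generate_catalog(
            10, 5, 2, 1, decoys_per_ortholog=1, decoy_identity=0.70,
            protein_len_range=(100, 100), seed=3,
        )
        refs = [e.protein for e in db.entries if not db.decoy_flags[e.subject_id]]
        sd3 = 3 * np.sqrt(100 * 0.3 * 0.7)
        for e in db.entries:
            if db.decoy_flags[e.subject_id]:
                d = min(_seq.hamming(e.protein, r) for r in refs if len(r) == len(e.protein))
                assert abs(d - 30) <= sd3

    def test_decoy_lands_in_same_subsystem_different_ortholog(self):
        catalog, db = generate_catalog(20, 10, 4, 2, decoys_per_ortholog=1, seed=5)
        refs = {e.ortholog: e.protein for e in db.entries if not db.decoy_flags[e.subject_id]}
        for e in db.entries:
            if not db.decoy_flags[e.subject_id]:
                continue
            # identify the decoy's source as the closest same-length ref
            sources = [
                og for og, p in refs.items()
                if len(p) == len(e.protein)
                and _seq.hamming(p, e.protein) / len(p) < 0.45
            ]
            assert sources, "decoy has no plausible source reference"
            src = min(sources, key=lambda og: _seq.hamming(refs[og], e.protein))
            assert src != e.ortholog
            assert db.subsystem_of(src) == db.subsystem_of(e.ortholog)

    def test_background_entries_have_no_genes(self):
        catalog, db = generate_catalog(20, 10, 5, 2, background_per_family=2, seed=1)
        catalog_ogs = {g.true_ortholog for g in catalog.genes}
        all_ogs = {e.ortholog for e in db.entries}
        assert len(all_ogs - catalog_ogs) == 10  # 5 families x 2

    def test_determinism(self):
        a = generate_catalog(30, 15, 5, 2, seed=42)
        b = generate_catalog(30, 15, 5, 2, seed=42)
        assert [(g.gene_id, g.cds) for g in a[0].genes] == [
            (g.gene_id, g.cds) for g in b[0].genes
        ]
        assert [(e.subject_id, e.protein) for e in a[1].entries] == [
            (e.subject_id, e.protein) for e in b[1].entries
        ]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=5, n_orthologs=10, n_families=2, n_subsystems=1),
            dict(n_genes=10, n_orthologs=5, n_families=2, n_subsystems=3),
            dict(n_genes=10, n_orthologs=5, n_families=2, n_subsystems=1, decoy_identity=1.5),
            dict(n_genes=10, n_orthologs=5, n_families=2, n_subsystems=1, decoy_identity=0.0),
        ],
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            generate_catalog(**kwargs)


class TestDesignExpression:
    def test_exact_knockout_and_regulated_counts(self, small_catalog_db):
        catalog, _ = small_catalog_db
        design = ExpressionDesign(n_samples=10, frac_knockout=0.05, frac_regulated=0.10, seed=1)
        # 20 genes: 1 knockout, 2 regulated -> 1 up, 1 down
        tc = design_expression(catalog, design)
        labels = list(tc.labels.values())
        assert labels.count("knockout") == round_half_up(0.05 * 20) == 1
        assert labels.count("up") == 1 and labels.count("down") == 1

    def test_up_down_tie_favors_up(self):
        catalog, _ = generate_catalog(30, 15, 5, 2, seed=2)
        tc = design_expression(
            catalog, ExpressionDesign(n_samples=4, frac_regulated=0.10, frac_knockout=0.0, seed=2)
        )
        labels = list(tc.labels.values())
        assert labels.count("up") == 2 and labels.count("down") == 1  # round(3)/2 ties up

    def test_fold_bounds_and_row_invariants(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=20, seed=3))
        for g, lab in tc.labels.items():
            fold = tc.true_fold[g]
            row = tc.matrix.loc[g]
            if lab == "knockout":
                assert fold == 0.0 and (row == 0).all()
            elif lab == "null":
                assert fold == 1.0
            elif lab == "up":
                assert 1.0 < fold <= 4.0
            else:
                assert 0.25 <= fold < 1.0
        assert len(tc.labels) == len(catalog)

    def test_mean_recovery_null_genes(self):
        catalog, _ = generate_catalog(40, 20, 5, 2, seed=4)
        design = ExpressionDesign(n_samples=100, baseline_mean=50.0, dispersion=0.2, seed=4)
        tc = design_expression(catalog, design)
        null_genes = [g for g, lab in tc.labels.items() if lab == "null"]
        means = tc.matrix.loc[null_genes].mean(axis=1)
        # NB(50, disp 0.2): var = 50 + 0.2*2500 = 550, sd of mean over 100 samples
        sd = np.sqrt(550 / 100)
        assert (np.abs(means - 50.0) <= 3 * sd).mean() > 0.95

    def test_invalid_fractions_error(self, small_catalog_db):
        catalog, _ = small_catalog_db
        with pytest.raises(ValueError):
            design_expression(
                catalog, ExpressionDesign(frac_regulated=0.7, frac_knockout=0.5)
            )


class TestSimulateReads:
    def test_conservation_and_zero_error_exactness(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=4, baseline_mean=8, seed=5))
        reads = simulate_reads(catalog, tc, read_length=100, error_model=None, seed=5)
        for s in tc.sample_ids:
            assert len(reads.reads_by_sample[s]) == int(tc.matrix[s].sum())
        cds_plus_rc = {}
        for rid, seq, qual in reads.iter_pooled():
            assert len(qual) == len(seq) == 100
            gene = rid.split("|")[1]
            if gene not in cds_plus_rc:
                cds = catalog[gene].cds
                cds_plus_rc[gene] = (cds, _seq.revcomp(cds))
            fwd, rev = cds_plus_rc[gene]
            assert seq in fwd or seq in rev

    def test_knockouts_absent_from_reads(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=10, seed=6))
        reads = simulate_reads(catalog, tc, seed=6)
        ko = {g for g, lab in tc.labels.items() if lab == "knockout"}
        seen = {rid.split("|")[1] for rid, _, _ in reads.iter_pooled()}
        assert not (ko & seen)

    def test_uniform_error_rate_recovered(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=4, baseline_mean=30, seed=7))
        rate = 0.01
        reads = simulate_reads(
            catalog, tc, error_model=np.full(100, rate), seed=7
        )
        mismatches = bases = 0
        for rid, seq, _ in reads.iter_pooled():
            gene = rid.split("|")[1]
            cds = catalog[gene].cds
            best = min(
                _seq.hamming(seq, win)
                for src in (cds, _seq.revcomp(cds))
                for win in (src[i : i + 100] for i in range(len(src) - 99))
            )
            mismatches += best
            bases += 100
        observed = mismatches / bases
        sd = np.sqrt(rate * (1 - rate) / bases)
        assert abs(observed - rate) <= 3 * sd

    def test_quality_string_encodes_error_model(self):
        profile = illumina_error_profile(100, 0.005)
        from mtx_arena.synthetic_data import _quality_string

        qual = _quality_string(profile)
        assert len(qual) == 100
        decoded = 10 ** (-(np.array([ord(c) - 33 for c in qual])) / 10)
        assert np.all(np.abs(np.log10(decoded) - np.log10(profile)) < 0.06)

    def test_read_length_longer_than_shortest_cds_refused(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=4, seed=8))
        with pytest.raises(ValueError):
            simulate_reads(catalog, tc, read_length=catalog.min_cds_length + 1)

    def test_determinism(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=4, seed=9))
        r1 = simulate_reads(catalog, tc, seed=9)
        r2 = simulate_reads(catalog, tc, seed=9)
        assert r1.reads_by_sample == r2.reads_by_sample


class TestSpikeNcrna:
    def test_identity_at_zero_fraction(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=2, seed=10))
        reads = simulate_reads(catalog, tc, seed=10)
        assert spike_ncrna(reads, [], 0.0) is reads

    def test_spike_fraction_arithmetic(self):
        # 900 genuine reads at fraction 0.10 -> 100 spiked appended
        from mtx_arena.synthetic_data import ReadSet

        reads = ReadSet(
            reads_by_sample={"S1": [(f"S1|g1|{i}", "A" * 50, "I" * 50) for i in range(900)]},
            read_length=50,
        )
        refs = make_ncrna_refs(2, 200, seed=0)
        out = spike_ncrna(reads, refs, 0.10, seed=0)
        assert len(out.reads_by_sample["S1"]) == 1000
        assert len(out.spiked_ids) == 100
        genuine_ids = {r[0] for r in reads.reads_by_sample["S1"]}
        assert not (out.spiked_ids & genuine_ids)

    def test_empty_refs_with_positive_fraction(self, small_catalog_db):
        catalog, _ = small_catalog_db
        tc = design_expression(catalog, ExpressionDesign(n_samples=2, seed=11))
        reads = simulate_reads(catalog, tc, seed=11)
        with pytest.raises(ValueError):
            spike_ncrna(reads, [], 0.1)
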