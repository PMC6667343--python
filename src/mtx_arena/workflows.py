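"""End-to-end workflows and the full benchmark orchestration.

Two annotation routes over the same simulated community:

* assembly-based: assemble reads -> map reads back -> abundance + ncRNA
  filters -> six-frame contig ORFs -> translated search with an
  E-value + alignment-length threshold -> shared annotation stages;
* assembly-free: per-read ORFs -> greedy peptide clustering -> translated
  search of cluster representatives with a bit-score threshold -> the same
  shared annotation stages, with cluster counts distributed back to the
  member reads' samples.

Both store their full un-thresholded hit set, so the 15-point threshold
sweep and segmented cross-validation re-filter in place (score of a pair
never depends on other database entries; E-values rescale linearly with
database size), which is exactly equivalent to re-running the alignment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, assembly, diffexpr, evaluation, fileio, homology
from . import synthetic_data as sd

__all__ = [
    "BenchmarkConfig",
    "WorkflowResult",
    "BenchmarkReport",
    "simulate_community",
    "run_assembly_based",
    "run_assembly_free",
    "run_benchmark",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass
class BenchmarkConfig:
    """Every stage's parameters, serialisable to a flat YAML file."""

    # community simulation
    n_genes: int = 200
    n_orthologs: int = 100
    n_families: int = 25
    n_subsystems: int = 10
    decoys_per_ortholog: int = 1
    decoy_identity: float = 0.70
    background_per_family: int = 2  # reference-only orthologs per family
    protein_len_min: int = 50
    protein_len_max: int = 100
    n_samples: int = 20
    frac_regulated: float = 0.10
    max_fold: float = 4.0
    frac_knockout: float = 0.05
    dispersion: float = 0.2
    coverage: float = 20.0
    read_length: int = 100
    error_rate: float = 0.005
    ncrna_fraction: float = 0.05
    n_ncrna: int = 3
    ncrna_length: int = 600
    # assembler / mapper (scaled to the pooled depth of this design)
    k: int = 25
    min_kmer_count: int = 8
    min_contig_length: int = 150
    seed_kmer: int = 25
    max_mismatch: int = 3
    # contig filters
    abundance_rate: float = 0.01
    ncrna_kmer: int = 15
    ncrna_containment: float = 0.5
    # ORF prediction / clustering
    contig_min_aa: int = 30
    read_min_aa: int = 20
    cluster_identity: float = 0.95
    # search thresholds
    min_aln_length: int = 15
    default_evalue: float = 1e-5
    default_bitscore: float = 50.0
    # evaluation / DE
    n_segcv_subsystems: int = 3
    de_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "BenchmarkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_STAGES = ("catalog", "design", "reads", "spike", "segcv")


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into recorded per-stage seeds (all < 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


# --------------------------------------------------------------------------- #
# simulation bundle
# --------------------------------------------------------------------------- #


@dataclass
class Community:
    catalog: sd.GeneCatalog
    db: sd.ReferenceDB
    truecounts: sd.TrueCounts
    reads: sd.ReadSet
    ncrna_refs: list[str]
    seeds: dict[str, int]

    @property
    def truth_orthologs(self) -> set[str]:
        expressed = self.truecounts.matrix.sum(axis=1) > 0
        return {
            self.catalog[g].true_ortholog
            for g in self.truecounts.matrix.index[expressed]
        }

    def truth_labels(self, level: str) -> set[str]:
        ogs = self.truth_orthologs
        if level == "ortholog":
            return ogs
        if level == "family":
            return {self.db.family_of(og) for og in ogs}
        if level == "subsystem":
            return {self.db.subsystem_of(og) for og in ogs}
        raise ValueError(f"unknown level {level!r}")


def simulate_community(config: BenchmarkConfig) -> Community:
    """Generate catalog, reference database, true counts and reads."""
    seeds = stage_seeds(config.seed)
    catalog, db = sd.generate_catalog(
        n_genes=config.n_genes,
        n_orthologs=config.n_orthologs,
        n_families=config.n_families,
        n_subsystems=config.n_subsystems,
        decoys_per_ortholog=config.decoys_per_ortholog,
        decoy_identity=config.decoy_identity,
        seed=seeds["catalog"],
        protein_len_range=(config.protein_len_min, config.protein_len_max),
        background_per_family=config.background_per_family,
    )
    design = sd.ExpressionDesign(
        n_samples=config.n_samples,
        frac_regulated=config.frac_regulated,
        max_fold=config.max_fold,
        frac_knockout=config.frac_knockout,
        dispersion=config.dispersion,
        seed=seeds["design"],
    )
    # a gene's expected count per sample follows the coverage target
    baselines = {
        g.gene_id: config.coverage * len(g.cds) / config.read_length
        for g in catalog.genes
    }
    truecounts = sd.design_expression(catalog, design, baseline_means=baselines)
    profile = sd.illumina_error_profile(config.read_length, config.error_rate)
    reads = sd.simulate_reads(
        catalog, truecounts, config.read_length, profile, seed=seeds["reads"]
    )
    ncrna_refs = sd.make_ncrna_refs(config.n_ncrna, config.ncrna_length, seed=seeds["spike"])
    if config.ncrna_fraction > 0:
        reads = sd.spike_ncrna(reads, ncrna_refs, config.ncrna_fraction, seed=seeds["spike"])
    return Community(catalog, db, truecounts, reads, ncrna_refs, seeds)


# --------------------------------------------------------------------------- #
# workflow results
# --------------------------------------------------------------------------- #


@dataclass
class WorkflowResult:
    """A workflow's stored state: feature-level hits plus source counts.

    Hits are keyed by feature id (contig or cluster), un-thresholded, so any
    confidence threshold and any cropped database can be applied after the
    fact without re-aligning.
    """

    name: str
    mode: str  # threshold mode: "evalue" | "bitscore"
    default_threshold: homology.Threshold
    hits: list[homology.AlignmentHit]
    source_counts: annotation.CountTable
    db: sd.ReferenceDB
    full_db_residues: int
    logs: dict = field(default_factory=dict)

    def hits_at(
        self, threshold: homology.Threshold, db: sd.ReferenceDB | None = None
    ) -> list[homology.AlignmentHit]:
        return homology.refilter_hits(
            self.hits, threshold, db=db, full_db_residues=self.full_db_residues
        )

    def assignment_at(
        self, threshold: homology.Threshold | None = None, db: sd.ReferenceDB | None = None
    ) -> dict[str, annotation.Assignment]:
        thr = threshold or self.default_threshold
        return annotation.best_hit_assign(self.hits_at(thr, db), db or self.db)

    def labels_at(
        self, threshold: homology.Threshold | None = None, db: sd.ReferenceDB | None = None,
        level: str = "ortholog",
    ) -> set[str]:
        use_db = db or self.db
        ogs = {a.ortholog for a in self.assignment_at(threshold, db).values()}
        if level == "ortholog":
            return ogs
        if level == "family":
            return {use_db.family_of(og) for og in ogs}
        if level == "subsystem":
            return {use_db.subsystem_of(og) for og in ogs}
        raise ValueError(f"unknown level {level!r}")

    def counts_at(
        self, threshold: homology.Threshold | None = None, level: str = "ortholog",
        db: sd.ReferenceDB | None = None,
    ) -> annotation.CountTable:
        assign = self.assignment_at(threshold, db)
        table, unassigned = annotation.build_feature_counts(assign, self.source_counts)
        self.logs.setdefault("unassigned", {})[
            (threshold or self.default_threshold).label
        ] = unassigned
        if level == "ortholog":
            return table
        return annotation.collapse(table, db or self.db, level)


# --------------------------------------------------------------------------- #
# the two workflows
# --------------------------------------------------------------------------- #


def run_assembly_based(
    config: BenchmarkConfig,
    reads: sd.ReadSet,
    db: sd.ReferenceDB,
    ncrna_refs: list[str] | None = None,
    outdir: str | Path | None = None,
) -> WorkflowResult:
    """assemble -> map -> abundance filter -> ncRNA filter -> contig ORFs ->
    translated search (E-value + alignment-length threshold) -> annotation."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    contigs = assembly.assemble(
        reads, k=config.k, min_kmer_count=config.min_kmer_count,
        min_contig_length=config.min_contig_length,
    )
    timings["assemble"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mapping = assembly.map_reads(
        reads, contigs, seed_kmer=config.seed_kmer, max_mismatch=config.max_mismatch
    )
    timings["map"] = time.perf_counter() - t0

    table = annotation.CountTable(mapping.counts, level="contig")
    table, ab_log = annotation.abundance_filter(table, config.abundance_rate)
    kept_ids = set(table.df.index)
    contigs = [c for c in contigs if c.contig_id in kept_ids]
    contigs, ncrna_removed = annotation.ncrna_filter(
        contigs, ncrna_refs or [], kmer=config.ncrna_kmer,
        containment_min=config.ncrna_containment,
    )
    kept_ids = {c.contig_id for c in contigs}
    table = annotation.CountTable(
        table.df.loc[[i for i in table.df.index if i in kept_ids]], level="contig"
    )

    t0 = time.perf_counter()
    peptides: list[homology.Peptide] = []
    for c in contigs:
        peptides.extend(homology.six_frame_orfs(c.contig_id, c.sequence, config.contig_min_aa))
    # stored hits cover every threshold of the sweep grid (loosest 1e-3, with
    # a 10x margin so cropped-database E-value rescaling cannot lose hits)
    storage_thr = homology.Threshold.evalue(
        10.0 * evaluation.default_grid("evalue").loosest.max_evalue, min_aln_length=0
    )
    hits = homology.search(peptides, db, threshold=storage_thr, prefilter=True)
    for h in hits:
        h.query_id = h.query_id.rsplit("|", 1)[0]  # peptide -> parent contig
    timings["orfs+search"] = time.perf_counter() - t0

    result = WorkflowResult(
        name="assembly_based",
        mode="evalue",
        default_threshold=homology.Threshold.evalue(
            config.default_evalue, config.min_aln_length
        ),
        hits=hits,
        source_counts=table,
        db=db,
        full_db_residues=db.total_residues,
        logs={
            "timings": timings,
            "n_contigs": len(contigs),
            "abundance_removed": ab_log.removed,
            "ncrna_removed": ncrna_removed,
            "mapped": mapping.mapped,
            "unmapped": mapping.unmapped,
        },
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fileio.write_fasta(out / "contigs.fasta", ((c.contig_id, c.sequence) for c in contigs))
        fileio.write_counts(out / "contig_counts.tsv", table)
        fileio.write_hits(out / "assembly_based_hits.tsv", hits)
        pd.DataFrame(
            {"sample": list(mapping.mapped), "mapped": list(mapping.mapped.values()),
             "unmapped": list(mapping.unmapped.values())}
        ).to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
    return result


def run_assembly_free(
    config: BenchmarkConfig,
    reads: sd.ReadSet,
    db: sd.ReferenceDB,
    outdir: str | Path | None = None,
) -> WorkflowResult:
    """per-read ORFs -> greedy clustering -> search of representatives
    (bit-score threshold) -> the same shared annotation stages."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    ids, seqs = [], []
    for rid, seq, _ in reads.iter_pooled():
        ids.append(rid)
        seqs.append(seq)
    peptides = homology.bulk_read_orfs(ids, seqs, reads.read_length, config.read_min_aa)
    timings["read_orfs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clusters = homology.cluster_peptides(peptides, config.cluster_identity)
    timings["cluster"] = time.perf_counter() - t0

    width = max(6, len(str(len(clusters))))
    samples = reads.samples
    sample_pos = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(clusters), len(samples)), dtype=np.int64)
    cluster_ids = []
    reps = []
    for i, cl in enumerate(clusters):
        cid = f"cluster_{i + 1:0{width}d}"
        cluster_ids.append(cid)
        reps.append(dataclasses.replace(cl.representative, peptide_id=cid))
        for member in cl.members:
            sample = member.parent_id.split("|", 1)[0]
            counts[i, sample_pos[sample]] += 1
    table = annotation.CountTable(
        pd.DataFrame(counts, index=cluster_ids, columns=samples), level="contig"
    )

    t0 = time.perf_counter()
    storage_thr = homology.Threshold.bitscore(
        evaluation.default_grid("bitscore").loosest.min_bitscore
    )
    # bit-score filtering needs no traceback; stats are filled in on demand
    # for the hits that get written to disk
    hits = homology.search(reps, db, threshold=storage_thr, prefilter=True, compute_stats=False)
    timings["search"] = time.perf_counter() - t0

    result = WorkflowResult(
        name="assembly_free",
        mode="bitscore",
        default_threshold=homology.Threshold.bitscore(config.default_bitscore),
        hits=hits,
        source_counts=table,
        db=db,
        full_db_residues=db.total_residues,
        logs={"timings": timings, "n_peptides": len(peptides), "n_clusters": len(clusters)},
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fileio.write_fasta(out / "cluster_reps.fasta", ((r.peptide_id, r.sequence) for r in reps))
        fileio.write_counts(out / "cluster_counts.tsv", table)
        written = result.hits_at(result.default_threshold)
        homology.fill_hit_stats(written, {r.peptide_id: r.sequence for r in reps}, db)
        fileio.write_hits(out / "assembly_free_hits.tsv", written)
    return result


# --------------------------------------------------------------------------- #
# full benchmark
# --------------------------------------------------------------------------- #


def _truth_de_labels(
    community: Community, alpha: float
) -> tuple[set[str], set[str]]:
    """Ground-truth DE at ortholog level: the same engine run on the true
    gene-level counts aggregated to orthologs (the full-length-gene route)."""
    mat = community.truecounts.matrix
    mapping = pd.Series({g: community.catalog[g].true_ortholog for g in mat.index})
    og_counts = mat.groupby(mapping).sum().sort_index()
    og_counts = og_counts.loc[og_counts.sum(axis=1) > 0]
    results = diffexpr.nb_test(og_counts, community.truecounts.groups, alpha=alpha)
    return diffexpr.call_de(results, alpha)


@dataclass
class BenchmarkReport:
    config: BenchmarkConfig
    truth_orthologs: int
    sweeps: dict[str, list[dict]]
    best: dict[str, dict]
    default: dict[str, dict]
    segcv: dict[str, dict[str, dict]]
    recall_drop: dict[str, float]
    de: dict[str, dict[str, dict]]
    runtime_s: float

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "truth_orthologs": self.truth_orthologs,
            "sweeps": self.sweeps,
            "best": self.best,
            "default": self.default,
            "segcv": self.segcv,
            "recall_drop": self.recall_drop,
            "de": self.de,
            "runtime_s": self.runtime_s,
        }

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for wf, entries in self.sweeps.items():
            for e in entries:
                rows.append({"workflow": wf, **e, "best": e["threshold"] == self.best[wf]["threshold"]})
        return pd.DataFrame(rows)


def _report_dict(threshold: homology.Threshold, rep: evaluation.MetricsReport) -> dict:
    return {
        "threshold": threshold.label,
        "category": threshold.category,
        "tp": rep.confusion.tp,
        "fp": rep.confusion.fp,
        "fn": rep.confusion.fn,
        "precision": rep.precision,
        "recall": rep.recall,
        "f_score": rep.f_score,
        "fdr_percent": rep.fdr_percent,
    }


def _metrics_dict(rep: evaluation.MetricsReport) -> dict:
    return {
        "tp": rep.confusion.tp,
        "fp": rep.confusion.fp,
        "fn": rep.confusion.fn,
        "precision": rep.precision,
        "recall": rep.recall,
        "f_score": rep.f_score,
        "fdr_percent": rep.fdr_percent,
    }


def run_benchmark(
    config: BenchmarkConfig, outdir: str | Path | None = None
) -> BenchmarkReport:
    """Simulate one community, run both workflows, sweep thresholds, run
    segmented cross-validation and DE evaluation; one seed, fully
    reproducible."""
    t_start = time.perf_counter()
    community = simulate_community(config)
    truth = community.truth_orthologs

    workflows = {
        "assembly_based": run_assembly_based(
            config, community.reads, community.db, community.ncrna_refs,
            outdir=Path(outdir) / "assembly_based" if outdir else None,
        ),
        "assembly_free": run_assembly_free(
            config, community.reads, community.db,
            outdir=Path(outdir) / "assembly_free" if outdir else None,
        ),
    }

    sweeps: dict[str, list[dict]] = {}
    best: dict[str, dict] = {}
    best_thresholds: dict[str, homology.Threshold] = {}
    default: dict[str, dict] = {}
    for name, wf in workflows.items():
        grid = evaluation.default_grid(wf.mode, config.min_aln_length)
        reports, best_thr, best_rep = evaluation.threshold_sweep(
            lambda thr, wf=wf: wf.labels_at(thr), grid, truth
        )
        sweeps[name] = [_report_dict(t, r) for t, r in reports]
        best[name] = _report_dict(best_thr, best_rep)
        best_thresholds[name] = best_thr
        default_rep = evaluation.metrics(
            evaluation.confusion(wf.labels_at(), truth)
        )
        default[name] = _report_dict(wf.default_threshold, default_rep)

    # segmented cross-validation at each workflow's F-optimal threshold
    rng = np.random.default_rng(community.seeds["segcv"])
    subsystems = community.db.subsystems
    n_remove = min(config.n_segcv_subsystems, len(subsystems) - 1)
    removed = [subsystems[i] for i in sorted(rng.choice(len(subsystems), n_remove, replace=False))]
    annotators = {
        name: (lambda cropped, wf=wf, thr=best_thresholds[name]: wf.labels_at(thr, db=cropped))
        for name, wf in workflows.items()
    }
    segcv_raw = evaluation.segmented_cross_validation(
        community.db, removed, annotators, truth
    )
    segcv = {
        ss: {name: _metrics_dict(rep) for name, rep in per_wf.items()}
        for ss, per_wf in segcv_raw.items()
    }
    # degradation due to removal: recall on the restricted truth with the
    # cropped database, against the same restricted truth with the full
    # database (same denominator, so missing labels unrelated to the removal
    # do not masquerade as degradation)
    recall_drop: dict[str, float] = {}
    for name, wf in workflows.items():
        thr = best_thresholds[name]
        full_labels = wf.labels_at(thr)
        drops = []
        for ss in segcv:
            truth_r = truth - evaluation.labels_in_subsystem(community.db, ss, "ortholog")
            baseline = evaluation.metrics(
                evaluation.confusion(full_labels, truth_r)
            ).recall
            drops.append(baseline - segcv[ss][name]["recall"])
        recall_drop[name] = float(np.mean(drops)) if drops else 0.0

    # differential expression at the F-optimal threshold, ortholog level
    truth_up, truth_down = _truth_de_labels(community, config.de_alpha)
    de: dict[str, dict[str, dict]] = {}
    for name, wf in workflows.items():
        table = wf.counts_at(best_thresholds[name], level="ortholog")
        results = diffexpr.nb_test(table, community.truecounts.groups, alpha=config.de_alpha)
        up, down = diffexpr.call_de(results, config.de_alpha)
        evald = evaluation.evaluate_de(up, down, truth_up, truth_down)
        de[name] = {
            "up": _metrics_dict(evald["up"]),
            "down": _metrics_dict(evald["down"]),
            "n_up": len(up),
            "n_down": len(down),
        }

    report = BenchmarkReport(
        config=config,
        truth_orthologs=len(truth),
        sweeps=sweeps,
        best=best,
        default=default,
        segcv=segcv,
        recall_drop=recall_drop,
        de=de,
        runtime_s=time.perf_counter() - t_start,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")
        fileio.write_catalog(out / "simulation", community.catalog, community.db)
        fileio.write_truth(out / "simulation" / "truth.tsv", community.truecounts)
        community.truecounts.matrix.rename_axis("feature_id").to_csv(
            out / "simulation" / "true_counts.tsv", sep="\t"
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        report.summary_table().to_csv(out / "sweep_summary.tsv", sep="\t", index=False)
    return report
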