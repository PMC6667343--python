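"""Readers and writers for the benchmark's on-disk formats.

FASTA/FASTQ go through Biopython; tables are TSV via pandas. Hit files use
the 12-column BLAST tabular layout (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import CountTable
from .homology import AlignmentHit
from .synthetic_data import GeneCatalog, ReadSet, ReferenceDB, TrueCounts

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_counts",
    "read_counts",
    "write_hits",
    "read_hits",
    "write_hierarchy",
    "write_truth",
    "write_catalog",
]


def write_fasta(path: str | Path, records) -> None:
    """records: iterable of (id, sequence)."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(path: str | Path, reads: list[tuple[str, str, str]]) -> None:
    """reads: (read_id, sequence, phred33 quality string)."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(33 + q) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_readset(outdir: str | Path, reads: ReadSet, prefix: str = "reads") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, lst in reads.reads_by_sample.items():
        write_fastq(outdir / f"{prefix}_{sample}.fastq", lst)


def write_counts(path: str | Path, table: CountTable) -> None:
    df = table.df.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"level": table.level}) + "\n")


def read_counts(path: str | Path, level: str | None = None) -> CountTable:
    if level is None:
        sidecar = Path(str(path) + ".json")
        level = json.loads(sidecar.read_text())["level"] if sidecar.exists() else "ortholog"
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(df, level=level)


HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits(path: str | Path, hits: list[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100.0 * h.identity:.2f}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.e_value:.3e}\t{h.bit_score:.1f}\n"
            )


def read_hits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_hierarchy(path: str | Path, db: ReferenceDB) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tortholog\tfamily\tsubsystem\tis_decoy\n")
        for e in db.entries:
            fam, ss = db.hierarchy[e.ortholog]
            fh.write(
                f"{e.subject_id}\t{e.ortholog}\t{fam}\t{ss}\t"
                f"{int(db.decoy_flags[e.subject_id])}\n"
            )


def write_truth(path: str | Path, counts: TrueCounts) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\ttrue_fold\n")
        for g in counts.matrix.index:
            fh.write(f"{g}\t{counts.labels[g]}\t{counts.true_fold[g]:.6g}\n")


def write_catalog(outdir: str | Path, catalog: GeneCatalog, db: ReferenceDB) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "catalog_cds.fasta", ((g.gene_id, g.cds) for g in catalog.genes))
    write_fasta(outdir / "catalog_protein.fasta", ((g.gene_id, g.protein) for g in catalog.genes))
    write_fasta(outdir / "reference_db.fasta", ((e.subject_id, e.protein) for e in db.entries))
    write_hierarchy(outdir / "hierarchy.tsv", db)
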