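"""Filtering, best-hit assignment, hierarchy collapsing, count tables.

These stages are shared verbatim by the assembly-based and assembly-free
workflows: the same code assigns features (contigs or read-peptide clusters)
to orthologs via their best database hit, builds ortholog-level count tables,
and collapses them up the hierarchy to families and subsystems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import _seq
from .homology import AlignmentHit
from .synthetic_data import ReferenceDB

__all__ = [
    "CountTable",
    "Assignment",
    "abundance_filter",
    "ncrna_filter",
    "best_hit_assign",
    "build_feature_counts",
    "collapse",
]

logger = logging.getLogger(__name__)

LEVELS = ("contig", "ortholog", "family", "subsystem")


@dataclass
class CountTable:
    """Features x samples non-negative integer matrix at a hierarchy level."""

    df: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if (self.df.to_numpy() < 0).any():
            raise ValueError("count tables must be non-negative")
        if self.df.index.has_duplicates:
            raise ValueError("feature ids must be unique")

    @property
    def features(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def total(self) -> int:
        return int(self.df.to_numpy().sum())


@dataclass
class Assignment:
    """Per-feature best-hit annotation (at most one subject per feature)."""

    subject_id: str
    ortholog: str
    bit_score: float
    e_value: float


@dataclass
class FilterLog:
    threshold: float = 0.0
    removed: list[str] = field(default_factory=list)


def abundance_filter(
    contig_counts: CountTable, rate: float
) -> tuple[CountTable, FilterLog]:
    """Drop contigs whose total count falls below rate x the smallest
    sample's depth.

    The threshold is ``rate * min(column sums)``; contigs with total across
    samples strictly below it are removed (keep-if-equal). ``rate=0``
    bypasses the filter entirely.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if contig_counts.level != "contig":
        raise ValueError("abundance filter operates on contig-level tables")
    log = FilterLog()
    if rate == 0:
        return contig_counts, log
    if contig_counts.df.empty:
        logger.warning("abundance_filter: empty table, returning unchanged")
        return contig_counts, log
    threshold = rate * float(contig_counts.df.sum(axis=0).min())
    totals = contig_counts.df.sum(axis=1)
    keep = totals >= threshold
    log.threshold = threshold
    log.removed = list(contig_counts.df.index[~keep])
    if log.removed:
        logger.info(
            "abundance_filter: removed %d contigs below threshold %.3f",
            len(log.removed),
            threshold,
        )
    return CountTable(contig_counts.df.loc[keep].copy(), level="contig"), log


def ncrna_filter(
    contigs: list,
    ncrna_refs: list[str],
    kmer: int = 15,
    containment_min: float = 0.5,
) -> tuple[list, list[str]]:
    """Remove contigs whose canonical k-mers are largely contained in the
    ncRNA reference set (a sequence-level stand-in for structure-aware
    ncRNA screening). Returns (kept contigs, removed contig ids).
    """
    if not 0 < containment_min <= 1:
        raise ValueError("containment_min must lie in (0, 1]")
    if not ncrna_refs:
        return list(contigs), []
    ref_kmers: set[str] = set()
    for ref in ncrna_refs:
        for i in range(len(ref) - kmer + 1):
            ref_kmers.add(_seq.canonical(ref[i : i + kmer]))
    kept, removed = [], []
    for contig in contigs:
        s = contig.sequence
        n = len(s) - kmer + 1
        if n <= 0:
            kept.append(contig)
            continue
        contained = sum(
            1 for i in range(n) if _seq.canonical(s[i : i + kmer]) in ref_kmers
        )
        if contained / n >= containment_min:
            removed.append(contig.contig_id)
        else:
            kept.append(contig)
    return kept, removed


def best_hit_assign(
    hits: list[AlignmentHit], db: ReferenceDB
) -> dict[str, Assignment]:
    """Keep the best hit per query: highest bit score, then lowest E-value,
    then lexicographically smallest subject_id. The assignment inherits the
    subject's ortholog from the database hierarchy.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        a = (-h.bit_score, h.e_value, h.subject_id)
        b = (-cur.bit_score, cur.e_value, cur.subject_id)
        if a < b:
            best[h.query_id] = h
    out: dict[str, Assignment] = {}
    for qid, h in best.items():
        entry = db.entry(h.subject_id)  # KeyError on corrupt reference
        if entry.ortholog not in db.hierarchy:
            raise KeyError(f"subject {h.subject_id} maps to unknown ortholog")
        out[qid] = Assignment(
            subject_id=h.subject_id,
            ortholog=entry.ortholog,
            bit_score=h.bit_score,
            e_value=h.e_value,
        )
    return out


def build_feature_counts(
    assignment: dict[str, Assignment],
    source_counts: CountTable,
) -> tuple[CountTable, list[str]]:
    """Sum each source feature's per-sample counts into its assigned ortholog.

    Works for both workflows: sources are contigs (assembly path) or peptide
    clusters whose per-sample member counts were tabulated beforehand
    (assembly-free path). Unassigned features are dropped and returned for
    the log — their mass is never redistributed, so FDR accounting stays
    honest.
    """
    unknown = [f for f in assignment if f not in source_counts.df.index]
    if unknown:
        raise KeyError(f"assigned features missing from source table: {unknown[:5]}")
    rows = []
    unassigned = []
    for feat in source_counts.df.index:
        if feat in assignment:
            rows.append((assignment[feat].ortholog, feat))
        else:
            unassigned.append(feat)
    if not rows:
        empty = pd.DataFrame(
            0, index=pd.Index([], dtype=object), columns=source_counts.df.columns
        )
        return CountTable(empty, level="ortholog"), unassigned
    mapping = pd.Series({feat: og for og, feat in rows})
    sub = source_counts.df.loc[mapping.index]
    grouped = sub.groupby(mapping).sum().sort_index()
    if unassigned:
        logger.info("build_feature_counts: %d features unassigned", len(unassigned))
    return CountTable(grouped, level="ortholog"), unassigned


def collapse(table: CountTable, db: ReferenceDB, to_level: str) -> CountTable:
    """Sum ortholog counts into families or subsystems (total preserved)."""
    if table.level != "ortholog":
        raise ValueError("collapse starts from an ortholog-level table")
    if to_level not in ("family", "subsystem"):
        raise ValueError("to_level must be 'family' or 'subsystem'")
    idx = 0 if to_level == "family" else 1
    try:
        mapping = pd.Series({og: db.hierarchy[og][idx] for og in table.df.index})
    except KeyError as e:
        raise KeyError(f"ortholog missing from hierarchy: {e}") from e
    grouped = table.df.groupby(mapping).sum().sort_index()
    return CountTable(grouped, level=to_level)
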