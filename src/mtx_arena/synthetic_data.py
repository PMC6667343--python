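"""Synthetic community transcriptomes with known functional ground truth.

The generator emulates a small gut-community expression experiment: a catalog
of protein-coding genes, each belonging to an ortholog group that nests in a
gene family and a functional subsystem; a reference protein database over the
same hierarchy (one canonical protein per ortholog plus deliberately mutated
decoy homologs); a two-group expression design with up/down-regulated and
knocked-out genes; and per-sample short reads with a position-dependent
Illumina-like substitution error model.

Sequence realism, chosen once:

* reference proteins of sibling orthologs in a family descend from a common
  family ancestor (~0.78 pairwise identity by default), so short peptides can
  best-hit the wrong ortholog of the right family — the homology-driven
  false-positive channel that annotation benchmarks care about;
* the second (and further) member genes of an ortholog are diverged copies of
  the canonical reference (~0.75 identity by default — the strain-versus-
  database gap: a reference database carries the deposited strain's gene
  exactly, here member one, while other community strains carry diverged
  copies), back-translated independently at the nucleotide level;
* decoys are point-mutated copies of reference proteins at a controlled
  identity, filed under a *different* ortholog of the same subsystem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import _seq

__all__ = [
    "Gene",
    "GeneCatalog",
    "RefEntry",
    "ReferenceDB",
    "ExpressionDesign",
    "TrueCounts",
    "ReadSet",
    "generate_catalog",
    "design_expression",
    "simulate_reads",
    "spike_ncrna",
    "make_ncrna_refs",
    "illumina_error_profile",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Gene:
    gene_id: str
    cds: str
    protein: str
    true_ortholog: str


@dataclass
class GeneCatalog:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids must be unique")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def min_cds_length(self) -> int:
        return min(len(g.cds) for g in self.genes)


@dataclass(frozen=True)
class RefEntry:
    subject_id: str
    protein: str
    ortholog: str


@dataclass
class ReferenceDB:
    entries: list[RefEntry]
    hierarchy: dict[str, tuple[str, str]]  # ortholog -> (family, subsystem)
    decoy_flags: dict[str, bool]

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_ids must be unique")
        for e in self.entries:
            if e.ortholog not in self.hierarchy:
                raise ValueError(f"ortholog {e.ortholog} missing from hierarchy")
        self._by_id = {e.subject_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, subject_id: str) -> RefEntry:
        return self._by_id[subject_id]

    @property
    def total_residues(self) -> int:
        return sum(len(e.protein) for e in self.entries)

    def family_of(self, ortholog: str) -> str:
        return self.hierarchy[ortholog][0]

    def subsystem_of(self, ortholog: str) -> str:
        return self.hierarchy[ortholog][1]

    @property
    def subsystems(self) -> list[str]:
        return sorted({s for (_, s) in self.hierarchy.values()})

    def cropped(self, remove_subsystems: set[str] | list[str]) -> "ReferenceDB":
        """Database with every entry of the named subsystems removed."""
        removed = set(remove_subsystems)
        unknown = removed - set(self.subsystems)
        if unknown:
            raise ValueError(f"unknown subsystems: {sorted(unknown)}")
        keep = [e for e in self.entries if self.subsystem_of(e.ortholog) not in removed]
        if not keep:
            raise ValueError("cropping removed every reference entry")
        return ReferenceDB(
            entries=keep,
            hierarchy=dict(self.hierarchy),
            decoy_flags={e.subject_id: self.decoy_flags[e.subject_id] for e in keep},
        )


@dataclass
class ExpressionDesign:
    """Two-group design: group B is the condition, A the reference."""

    n_samples: int = 100
    group_of: dict[str, str] | None = None
    frac_regulated: float = 0.10
    max_fold: float = 4.0
    frac_knockout: float = 0.05
    baseline_mean: float = 50.0
    dispersion: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if not 0 <= self.frac_regulated + self.frac_knockout <= 1:
            raise ValueError("frac_regulated + frac_knockout must lie in [0, 1]")
        if self.max_fold <= 1:
            raise ValueError("max_fold must exceed 1")
        if self.group_of is not None:
            groups = set(self.group_of.values())
            if groups != {"A", "B"}:
                raise ValueError("groups must be exactly {'A', 'B'}")

    def sample_ids(self) -> list[str]:
        if self.group_of is not None:
            return sorted(self.group_of)
        width = len(str(self.n_samples))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_samples)]

    def groups(self) -> dict[str, str]:
        if self.group_of is not None:
            return dict(self.group_of)
        ids = self.sample_ids()
        half = self.n_samples // 2
        return {s: ("A" if i < half else "B") for i, s in enumerate(ids)}


@dataclass
class TrueCounts:
    matrix: pd.DataFrame  # genes x samples, int
    labels: dict[str, str]  # gene -> up/down/null/knockout
    true_fold: dict[str, float]  # gene -> group-B mean over group-A mean
    groups: dict[str, str]  # sample -> A/B

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ReadSet:
    reads_by_sample: dict[str, list[tuple[str, str, str]]]  # (id, seq, qual)
    read_length: int
    spiked_ids: set[str] = field(default_factory=set)
    quality_string: str = ""

    @property
    def samples(self) -> list[str]:
        return list(self.reads_by_sample)

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads_by_sample.values())

    def iter_pooled(self):
        for sample in self.reads_by_sample:
            yield from self.reads_by_sample[sample]


# --------------------------------------------------------------------------- #
# catalog + reference database
# --------------------------------------------------------------------------- #

_CODONS_OF_AA: dict[str, list[str]] = {}
for _codon, _aa in _seq.CODON_TABLE.items():
    if _aa != "*":
        _CODONS_OF_AA.setdefault(_aa, []).append(_codon)
for _lst in _CODONS_OF_AA.values():
    _lst.sort()


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(_seq.AMINO_ACIDS), size=length)
    return "".join(_seq.AMINO_ACIDS[i] for i in idx)


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    """Per-position Bernoulli substitution to a different residue."""
    out = list(protein)
    hits = np.nonzero(rng.random(len(protein)) < rate)[0]
    for i in hits:
        choices = _seq.AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_OF_AA[aa]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def generate_catalog(
    n_genes: int,
    n_orthologs: int,
    n_families: int,
    n_subsystems: int,
    decoys_per_ortholog: int = 1,
    decoy_identity: float = 0.70,
    seed: int = 0,
    protein_len_range: tuple[int, int] = (50, 100),
    family_divergence: float = 0.12,
    member_divergence: float = 0.25,
    background_per_family: int = 0,
) -> tuple[GeneCatalog, ReferenceDB]:
    """Generate a gene catalog and its companion reference database.

    Each ortholog's canonical reference protein is the exact translation of
    its first member gene; decoys are point-mutated copies of reference
    proteins (expected identity ``decoy_identity``) filed under a different
    ortholog of the same subsystem.

    ``background_per_family`` adds that many extra orthologs per family to
    the reference database only (no catalog genes): homologous database
    entries that are absent from the community, as any real reference
    database contains. They are the natural sink for homology-driven
    false-positive annotations.
    """
    if not (n_genes >= n_orthologs >= n_families >= n_subsystems >= 1):
        raise ValueError("require n_genes >= n_orthologs >= n_families >= n_subsystems >= 1")
    if not 0 < decoy_identity < 1:
        raise ValueError("decoy_identity must lie strictly between 0 and 1")
    if decoys_per_ortholog < 0:
        raise ValueError("decoys_per_ortholog must be non-negative")
    lo, hi = protein_len_range
    if lo * 3 < 150:
        raise ValueError("protein_len_range floor must keep CDS length >= 150 nt")

    rng = np.random.default_rng(seed)
    n_background = n_families * background_per_family
    n_total_og = n_orthologs + n_background
    gw = len(str(n_genes))
    ow = len(str(n_total_og))
    fw = len(str(n_families))
    sw = len(str(n_subsystems))
    ortholog_ids = [f"OG{i + 1:0{ow}d}" for i in range(n_total_og)]
    catalog_ogs = ortholog_ids[:n_orthologs]
    family_ids = [f"F{i + 1:0{fw}d}" for i in range(n_families)]
    subsystem_ids = [f"SS{i + 1:0{sw}d}" for i in range(n_subsystems)]

    hierarchy = {
        ortholog_ids[i]: (family_ids[i % n_families], subsystem_ids[(i % n_families) % n_subsystems])
        for i in range(n_total_og)
    }

    # family ancestors, then per-ortholog reference proteins
    family_len = {f: int(rng.integers(lo, hi + 1)) for f in family_ids}
    family_ancestor = {f: _random_protein(rng, family_len[f]) for f in family_ids}
    ref_protein: dict[str, str] = {}
    for og in ortholog_ids:
        fam, _ = hierarchy[og]
        ref_protein[og] = _mutate_protein(rng, family_ancestor[fam], family_divergence)

    # genes: round-robin over catalog orthologs; member 0 sources the ref
    genes: list[Gene] = []
    for i in range(n_genes):
        og = catalog_ogs[i % n_orthologs]
        member = i // n_orthologs
        protein = ref_protein[og] if member == 0 else _mutate_protein(rng, ref_protein[og], member_divergence)
        cds = _back_translate(rng, protein)
        genes.append(Gene(f"g{i + 1:0{gw}d}", cds, protein, og))
    catalog = GeneCatalog(genes)

    entries = [RefEntry(f"REF_{og}", ref_protein[og], og) for og in ortholog_ids]
    decoy_flags = {e.subject_id: False for e in entries}

    by_subsystem: dict[str, list[str]] = {}
    for og in ortholog_ids:
        by_subsystem.setdefault(hierarchy[og][1], []).append(og)
    n_dec = 0
    for og in ortholog_ids:
        siblings = by_subsystem[hierarchy[og][1]]
        pos = siblings.index(og)
        for d in range(decoys_per_ortholog):
            if len(siblings) > 1:
                target = siblings[(pos + 1 + d) % len(siblings)]
                if target == og:
                    target = siblings[(pos + 1) % len(siblings)]
            else:
                # degenerate hierarchy: no sibling ortholog available; fall
                # back to any other ortholog so the decoy is still mislabeled
                target = ortholog_ids[(ortholog_ids.index(og) + 1) % n_orthologs]
                if target == og:
                    continue
            n_dec += 1
            decoy = _mutate_protein(rng, ref_protein[og], 1.0 - decoy_identity)
            sid = f"DEC{n_dec:05d}"
            entries.append(RefEntry(sid, decoy, target))
            decoy_flags[sid] = True

    db = ReferenceDB(entries=entries, hierarchy=hierarchy, decoy_flags=decoy_flags)
    return catalog, db


# --------------------------------------------------------------------------- #
# expression design
# --------------------------------------------------------------------------- #


def design_expression(
    catalog: GeneCatalog,
    design: ExpressionDesign,
    baseline_means: dict[str, float] | None = None,
) -> TrueCounts:
    """Draw a true count matrix under the two-group regulation scheme.

    Exactly ``round(frac_knockout * n)`` genes are knocked out (all-zero rows)
    and ``round(frac_regulated * n)`` regulated, split evenly up/down with the
    tie going to up. log2 fold magnitudes are uniform on
    [0.5, log2(max_fold)], so effects stay non-zero and bounded by max_fold.
    Counts are negative binomial with the given dispersion; group-B means are
    scaled by the gene's true fold.
    """
    design.validate()
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(design.seed)
    gene_ids = catalog.gene_ids
    n = len(gene_ids)

    n_ko = round_half_up(design.frac_knockout * n)
    n_reg = round_half_up(design.frac_regulated * n)
    if n_ko + n_reg > n:
        raise ValueError("knockout and regulated sets exceed the catalog")
    n_up = (n_reg + 1) // 2  # ties favor up
    n_down = n_reg - n_up

    perm = rng.permutation(n)
    ko_idx = perm[:n_ko]
    up_idx = perm[n_ko : n_ko + n_up]
    down_idx = perm[n_ko + n_up : n_ko + n_reg]

    labels = {g: "null" for g in gene_ids}
    true_fold = {g: 1.0 for g in gene_ids}
    for i in ko_idx:
        labels[gene_ids[i]] = "knockout"
        true_fold[gene_ids[i]] = 0.0
    max_l2 = math.log2(design.max_fold)
    for i in up_idx:
        labels[gene_ids[i]] = "up"
        true_fold[gene_ids[i]] = 2.0 ** rng.uniform(0.5, max_l2)
    for i in down_idx:
        labels[gene_ids[i]] = "down"
        true_fold[gene_ids[i]] = 2.0 ** -rng.uniform(0.5, max_l2)

    samples = design.sample_ids()
    groups = design.groups()
    group_arr = np.array([groups[s] for s in samples])
    is_b = group_arr == "B"
    if not is_b.any() or is_b.all():
        raise ValueError("both groups must be non-empty")

    if baseline_means is None:
        base = np.full(n, float(design.baseline_mean))
    else:
        base = np.array([float(baseline_means[g]) for g in gene_ids])
    base[[labels[g] == "knockout" for g in gene_ids]] = 0.0  # zero in BOTH groups
    fold = np.array([true_fold[g] for g in gene_ids])
    mean = np.where(is_b[None, :], base[:, None] * fold[:, None], base[:, None])

    if design.dispersion > 0:
        r = 1.0 / design.dispersion
        p = r / (r + np.maximum(mean, 1e-12))
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)
    counts[mean == 0] = 0

    matrix = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=samples)
    return TrueCounts(matrix=matrix, labels=labels, true_fold=true_fold, groups=groups)


# --------------------------------------------------------------------------- #
# read simulation
# --------------------------------------------------------------------------- #


def illumina_error_profile(read_length: int, mean_rate: float = 0.005) -> np.ndarray:
    """Linear 5'->3' substitution-rate ramp with the requested mean rate."""
    if mean_rate < 0:
        raise ValueError("mean_rate must be non-negative")
    ramp = np.linspace(0.4, 1.6, read_length)
    return mean_rate * ramp


def _quality_string(probs: np.ndarray) -> str:
    q = np.full(probs.shape, 40, dtype=int)
    pos = probs > 0
    q[pos] = np.clip(np.rint(-10.0 * np.log10(probs[pos])), 2, 40).astype(int)
    return "".join(chr(33 + v) for v in q)


def simulate_reads(
    catalog: GeneCatalog,
    counts: TrueCounts,
    read_length: int = 100,
    error_model: np.ndarray | None = None,
    seed: int = 0,
) -> ReadSet:
    """Emit exactly counts[g, s] single-end reads per gene and sample.

    Start positions are uniform over the valid range, strands uniform, and
    substitutions applied per position with the error model's probability.
    Phred+33 qualities encode the model's per-position error probability.
    Read ids encode ``sample|gene|index`` so every read is truth-traceable.
    """
    if read_length > catalog.min_cds_length:
        raise ValueError(
            f"read_length {read_length} exceeds the shortest CDS ({catalog.min_cds_length} nt)"
        )
    if error_model is None:
        probs = np.zeros(read_length)
    else:
        probs = np.asarray(error_model, dtype=float)
        if probs.shape != (read_length,):
            raise ValueError("error_model must have one probability per read position")
    qual = _quality_string(probs)

    rng = np.random.default_rng(seed)
    samples = counts.sample_ids
    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {s: [] for s in samples}
    mat = counts.matrix

    for gene in catalog.genes:
        row = mat.loc[gene.gene_id].to_numpy()
        total = int(row.sum())
        if total == 0:
            continue
        arr = _seq.encode(gene.cds)
        windows = sliding_window_view(arr, read_length)
        starts = rng.integers(0, len(gene.cds) - read_length + 1, size=total)
        strands = rng.integers(0, 2, size=total)
        block = windows[starts].copy()
        rc = strands == 1
        if rc.any():
            block[rc] = 3 - block[rc][:, ::-1]
        emask = rng.random((total, read_length)) < probs[None, :]
        n_err = int(emask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            block[emask] = (block[emask] + shift) % 4
        ascii_block = _seq._ASCII_OF[block].tobytes()
        pos = 0
        for s_idx, sample in enumerate(samples):
            c = int(row[s_idx])
            lst = reads_by_sample[sample]
            for k in range(c):
                i = pos + k
                seq = ascii_block[i * read_length : (i + 1) * read_length].decode()
                lst.append((f"{sample}|{gene.gene_id}|{k}", seq, qual))
            pos += c

    return ReadSet(
        reads_by_sample=reads_by_sample,
        read_length=read_length,
        quality_string=qual,
    )


def make_ncrna_refs(n: int, length: int, seed: int = 0) -> list[str]:
    """Random nucleotide references standing in for non-coding RNA sequences."""
    rng = np.random.default_rng(seed)
    return [_seq.decode(rng.integers(0, 4, size=length).astype(np.uint8)) for _ in range(n)]


def spike_ncrna(
    reads: ReadSet,
    ncrna_set: list[str],
    fraction: float,
    seed: int = 0,
) -> ReadSet:
    """Append ncRNA-derived reads so they form ``fraction`` of each sample."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0:
        return reads
    if not ncrna_set:
        raise ValueError("ncrna_set is empty but fraction > 0")
    for ref in ncrna_set:
        if len(ref) < reads.read_length:
            raise ValueError("every ncRNA reference must be at least read_length long")

    rng = np.random.default_rng(seed)
    qual = reads.quality_string or "I" * reads.read_length
    new_by_sample: dict[str, list[tuple[str, str, str]]] = {}
    spiked = set(reads.spiked_ids)
    for sample, lst in reads.reads_by_sample.items():
        genuine = len(lst)
        n_spike = round_half_up(fraction * genuine / (1.0 - fraction))
        out = list(lst)
        for j in range(n_spike):
            ref = ncrna_set[int(rng.integers(0, len(ncrna_set)))]
            start = int(rng.integers(0, len(ref) - reads.read_length + 1))
            rid = f"{sample}|nc|{j}"
            out.append((rid, ref[start : start + reads.read_length], qual))
            spiked.add(rid)
        new_by_sample[sample] = out
    return ReadSet(
        reads_by_sample=new_by_sample,
        read_length=reads.read_length,
        spiked_ids=spiked,
        quality_string=reads.quality_string,
    )
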