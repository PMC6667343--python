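# mtx-arena

A desk-scale benchmarking arena for a recurring design decision in
metatranscriptomics: annotate short RNA-seq reads **after assembling them
into contigs** (assembly-based) or **align the reads directly** to a protein
reference (assembly-free)? The package simulates community transcriptomes
with exact functional and differential-expression ground truth, runs both
annotation workflows end to end with self-contained stand-ins for every
pipeline stage, and scores them with the standard precision/recall
framework. It is aimed at microbial-ecology bioinformaticians who want a
controlled, fully reproducible way to see *why* and *when* the two routes
disagree.

## What it computes

A simulated community provides genes with known ortholog → family →
subsystem annotations and a two-group expression design (10% of genes
regulated ≤ 4-fold, 5% knocked out, negative-binomial counts, ~20×
coverage, Illumina-like substitution errors). Both workflows recover a set
of functional labels, which are scored against the truly expressed set:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F = 2PR / (P + R)                 FDR% = 100 · FP / (TP + FP)

Alignments use local affine-gap Smith–Waterman (BLOSUM62) with bit scores
`(λS − ln K)/ln 2` and Karlin–Altschul E-values `K·m·n·e^(−λS)`. Each
workflow is swept over 15 confidence thresholds (5 low / 5 medium / 5
high), reported at its F-optimal threshold, stress-tested by removing one
functional subsystem from the reference at a time (segmented
cross-validation), and compared on negative-binomial differential
expression (Wald test, Benjamini–Hochberg) against DE computed from the
true counts. See `docs/methods.md` for the full model.

## Worked example

```bash
mtx-arena run-benchmark --outdir out --seed 1
```

prints, after about a minute:

```
assembly_based: best F=0.9899 at 1E-17 (precision 1.0000, recall 0.9800, FDR 0.00%)
assembly_free: best F=0.9849 at BTS 60 (precision 0.9899, recall 0.9800, FDR 1.01%)
report -> out/report.json
```

Reading this: at its own F-optimal threshold each workflow recovers ~98 of
the 100 expressed ortholog groups, but the assembly-based route does so
with zero false labels even at its most stringent E-value threshold, while
the assembly-free route's best operating point (bit score 60) keeps one
false ortholog — a short read peptide whose best hit is a homolog of the
right family but the wrong ortholog. Collapsing the count tables to the
subsystem level removes exactly this class of error. `out/report.json`
holds the full 15-threshold sweep, the segmented cross-validation rounds
and the DE comparison; intermediate FASTA/TSV artifacts for both workflows
are persisted next to it.

The library is usable piecemeal — `generate_catalog`, `assemble`,
`six_frame_orfs`, `search`, `nb_test`, `threshold_sweep`, etc. are plain
functions over plain containers (pandas tables, dataclasses); the CLI
subcommands (`simulate`, `run-workflow`, `de`, `run-benchmark`) are thin
wrappers over them.

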