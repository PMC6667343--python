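# Methods

`mtx-arena` is a self-contained, desk-scale benchmark for the central design
question of metatranscriptome annotation: should short reads be assembled
into contigs before translated alignment to a protein reference
("assembly-based"), or aligned directly ("assembly-free")? Everything — the
community, the reference database, both workflows, and the scoring — is
generated and executed in-repo so the comparison has exact ground truth.

## The simulated community

The generator produces a catalog of protein-coding genes embedded in a
three-tier functional hierarchy (ortholog group → gene family → functional
subsystem) together with a protein reference database over the same
hierarchy.

Sequence model (amino-acid level, back-translated to CDS with uniformly
random synonymous codons):

* Each **family** draws an ancestor protein of uniform random length
  (default 50–100 aa, so CDS ≥ 150 nt).
* Each **ortholog** in the family mutates the ancestor at rate 0.12 per
  site, giving sibling reference proteins ~0.78 pairwise identity —
  homologs close enough to confuse a 33-aa read peptide, far enough apart
  that a full-length contig ORF is never confused.
* Each ortholog's **canonical reference protein** is the exact translation
  of its first member gene: that strain is "in the database". Further
  member genes mutate the reference at rate 0.25 — the strain-versus-
  database gap. Real reference databases contain a community gene exactly
  only when that strain was deposited; other community strains diverge
  substantially, and this divergence is what makes short-read annotation
  hard. (An earlier draft used 0.08 here; that leaves a clean score gap
  between true and homologous hits, the assembly-free route becomes
  error-free at every threshold, and the decoy entries below can never win
  a best-hit contest — an unrealistically easy regime.)
* **Decoys**: per ortholog, a point-mutated copy of its reference protein
  (default expected identity 0.70, per-site Bernoulli so the Hamming
  distance is binomial) filed under a *different* ortholog of the same
  subsystem. A decoy that wins a best-hit contest produces an
  ortholog-level false positive that collapsing to subsystem level
  converts back into a true positive.
* **Background orthologs** (benchmark default: 2 per family) are reference
  entries with no catalog genes. Without them every database label would be
  truly expressed and a false-positive label would be structurally
  impossible; real databases are always supersets of the community.

Expression design: samples split into groups A (reference) and B
(condition); 10% of genes regulated, split evenly up/down (tie to up), with
|log2 fold| uniform on [0.5, 2] (i.e. 1.41–4-fold — nonzero and bounded);
5% of genes knocked out (all-zero rows in both groups, absent from reads);
counts negative binomial with dispersion 0.2, group-B means scaled by the
gene's true fold. Per-gene baseline means follow the coverage target:
`coverage × CDS length / read length`. Selections are random but recorded.

Reads: single-end, 100 nt, substitution-only errors from a position-indexed
profile (linear 5'→3' ramp, mean 0.5% in the benchmark), Phred+33 qualities
encoding the model's per-position error probability, strand and start
uniform, read ids encoding `sample|gene|index` for truth tracking. An
optional ncRNA spike appends reads drawn from random non-coding references
to a fixed fraction of each sample (benchmark default 5%) as substrate for
the ncRNA contig filter. Paired-end reads and indel errors are out of
scope.

What the generator does **not** emulate: rRNA carry-over, GC/positional
coverage bias, chimeric fragments, uneven taxon abundances, multi-label
(multi-inheritance) orthologs, and real database noise. Passing benchmarks
here show the *relative* behavior of the two routes under controlled
homology structure, not absolute performance on environmental data.

## The two workflows

**Assembly-based**: de Bruijn unitig assembly over canonical k-mers
(k = 25; k-mers below a count floor dropped; tips shorter than 2k clipped;
no bubble resolution — tangles fragment, which is accepted and visible as
slightly sub-unit recall) → reads mapped back by exact seed-k-mer lookup
with ≤ 3 substitutions, ties to the smallest contig id → abundance filter
(contigs with total count below `rate × smallest sample depth` removed;
rate 0 bypasses) → ncRNA filter (canonical k-mer containment ≥ 0.5 against
the ncRNA references; a sequence-level stand-in for structure-aware
screening) → six-frame ORFs (longest stop-free stretch per frame, ≥ 30 aa)
→ translated search thresholded on **E-value ≤ 1e-5 AND alignment length
≥ 15 aa** by default.

**Assembly-free**: per-read ORF (single longest stop-free translation
across six frames, ≥ 20 aa) → greedy length-sorted clustering at 0.95
ungapped identity (word-seeded, identity over the shorter sequence; a
shared-word count bound prunes candidates losslessly) → translated search
of cluster representatives thresholded on **bit score ≥ 50** by default →
cluster counts distributed back to member reads' samples.

Both routes then share one annotation code path: best hit per feature
(highest bit score, then lowest E-value, then smallest subject id), count
tables at ortholog level, and exact-sum collapsing to family/subsystem.
Unassigned mass is logged, never redistributed.

Alignment is local affine-gap Smith–Waterman with BLOSUM62 (gap open 11,
extend 1; the DP runs on Biopython's C PairwiseAligner; unknown residues
score the matrix minimum). Raw scores convert to bit scores and E-values
with fixed gapped-BLOSUM62 Karlin–Altschul constants (K = 0.041,
λ = 0.267); because both workflows are compared at matched thresholds,
absolute E-value calibration cancels. A shared-4-mer prefilter limits
aligned pairs; its losslessness at the default thresholds is asserted by a
test. Searches store every hit above the loosest sweep threshold (with a
10× E-value margin), so the 15-point sweep and segmented cross-validation
re-filter stored hits instead of re-aligning — exactly equivalent, since a
pair's score is independent of the rest of the database and E-values are
linear in database size.

## Evaluation

Label-set confusion by default (the annotation unit is the recovered
ortholog/family/subsystem set): TP = recovered ∧ expressed, FP = recovered
∧ not expressed, FN = expressed ∧ never recovered; precision, recall,
harmonic-mean F, FDR% = 100·FP/(TP+FP). A feature-resolved mode exists for
diagnostics.

The threshold grid has 15 entries, 5 per category: E-value mode 1e-3…1e-7
(low), 1e-8…1e-12 (medium), 1e-13…1e-17 (high); bit-score mode
40/50/60/70/80, 85/90/95/100/105, 110/120/130/140/150. The best threshold
maximizes F; ties go to the more stringent entry.

Segmented cross-validation removes one functional subsystem's reference
entries at a time (benchmark default: 3 seeded picks), re-annotates both
workflows at their F-optimal thresholds, and restricts truth to the
surviving labels. The **recall drop** is measured against the same
restricted truth with the full database, so labels missed for unrelated
reasons do not masquerade as removal-induced degradation.

Differential expression: median-of-ratios size factors; per-feature moment
dispersion on normalized counts pooled within groups (floor 1e-8); Wald
test on log2(B/A) with a delta-method standard error under σ² = μ + αμ²;
BH adjustment; calls at adjusted p ≤ 0.05. All-zero features (knockouts)
are never tested; features zero in exactly one group get a 0.5 pseudo-count
for the displayed fold change only and are flagged. There is no dispersion
shrinkage or outlier moderation — the benchmark's claims concern
annotation, not DE machinery. Ground-truth DE labels come from the same
engine run on the true gene counts aggregated to orthologs, mirroring a
full-length-gene analysis. Note the normalization assumes most features are
null; grossly one-sided regulation would bias size factors.

## Benchmark conditions and problem sizes

The default configuration is 200 genes over 100 orthologs (25 families, 10
subsystems, 2 background orthologs per family, 1 decoy per ortholog at
0.70 identity), 20 samples at 20× coverage (~185k reads), error rate 0.5%,
5% ncRNA spike, five seeds. One seed runs in about a minute on one CPU.
`min_kmer_count` is raised to 8 for this design: pooled per-gene depth is
~400×, so a specific erroneous base at a site recurs ~Poisson(0.67) times
and P(≥8) ≈ 1e-6, while true k-mers sit at hundreds-fold — the floor kills
error k-mers without touching signal. Module-level defaults keep
conventional stand-in values (min_kmer_count 2, min_contig_length 200).

## Numerical and tie-break conventions

Round-half-up for gene-set sizes; up/down tie favors up; knockout and
regulated sets disjoint. Contigs emitted as the lexicographically smaller
of the two strands, sorted, then indexed — assembly output is independent
of read order. Clustering processes unique sequences by (length
descending, sequence); a peptide joins the first matching cluster.
Best-F ties go stringent. All randomness flows from one seed expanded into
recorded per-stage seeds (catalog, design, reads, spike, segmented-CV
choice), so any stage can be reproduced in isolation.

## Known limitations

* The assembler fragments at repeat/bubble tangles instead of resolving
  them; recall of the assembly-based route is occasionally one or two
  orthologs short for purely assembly-graph reasons.
* E-values are calibrated by fixed constants, not fitted to the score
  distribution; only relative comparisons across workflows are meaningful.
* The greedy clusterer's identity is ungapped; indel variants would split
  clusters (the simulator emits no indels).
* Sub-minute scale means single-label FP/FN events move FDR by about one
  percentage point; directional claims are therefore evaluated as
  seed-majority votes, not point estimates.
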