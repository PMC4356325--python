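# Methods

## The analysis this package implements

`methexp` reimplements, as a tested pipeline, an integrated genome-wide
DNA-methylation / RNA-expression analysis for cervical cancer. The study
design it models is small and paired: four patients — two with invasive
cervical cancer, two with pre-invasive lesions (CIN III / CIS) — each
contributing a normal and a tumor biopsy, profiled on a two-channel
450K-style CpG methylation array and a ~47,000-probe single-channel
expression array. Because n = 2 per group, the analysis deliberately avoids
inferential statistics for selection and instead uses hard effect-size
thresholds plus a per-patient reproducibility requirement.

### Methylation arm

For probe *i* and sample *j*, with methylated intensity *M*, unmethylated
intensity *U* and per-sample background *b* (the mean of that sample's
negative-control probes):

β = max(M − b, 0) / (max(M − b, 0) + max(U − b, 0)) ∈ [0, 1]

A zero denominator (both channels at or below background) is reported as
β = 0 with a flag. No stabilizing offset is added to the denominator by
default (the formula above has none); an optional `offset` argument exposes
the convention used by some array workflows.

Detection p is the empirical rank of the probe's total intensity (M + U)
against the sample's negative controls: p = (#{controls ≥ signal} + 1) /
(#controls + 1). The exact detection-p definition used by vendor software
is proprietary; this add-one rank estimate is monotone in signal and is the
definition tested here. Probes with p < 0.05 in at least 50 % of samples
are kept (the keep-fraction boundary is inclusive and is applied
identically to both platforms), then β is quantile-normalized across
arrays.

Differential methylation per disease group is Δ = mean β(tumor) − mean
β(normal) over that group's columns; a locus is hypermethylated when
Δ ≥ 0.2, hypomethylated when Δ ≤ −0.2. The boundary is inclusive: the
candidate table contains loci printed at exactly 0.20.

### Expression arm

Probes pass the same detection filter, are log2-transformed and
quantile-normalized. Fold change is computed on **linear-scale** group
means of the normalized data and reported signed: FC = r if r ≥ 1 else
−1/r, so |FC| ≥ 1 always. Differential expression is |FC| ≥ 2, again
inclusive. An equal-variance two-sample t-test (Welch by flag) and
Benjamini–Hochberg q-values are computed for completeness, but with two
patients per group they do not participate in selection — the selection
rule is purely threshold-based, and the logs record this.

### Integration

Within each disease group independently:

1. join differentially-methylated loci to differentially-expressed probes
   by gene symbol (genes lacking either data type are dropped and logged);
2. keep only sign-opposed pairs — hypermethylated + downregulated
   ("down_by_hyper") or hypomethylated + upregulated ("up_by_hypo").
   With two samples per condition a correlation coefficient is
   meaningless, so "negative correlation" is implemented as this sign
   opposition of threshold calls, not as a continuous statistic;
3. require per-patient consistency: each patient of the group must
   individually show |Δβ| ≥ 0.1 and |FC| ≥ 1.5 with the signs of the
   group-level call. These per-patient minima are deliberately permissive
   relative to the group thresholds — they operationalize "no change in
   one of two individuals" without double-imposing the group cutoffs —
   and are config knobs;
4. report one record per gene carrying all qualifying loci; the Δ shown is
   the locus with maximal |Δ|. Records are ordered group, category, |Δ|
   descending, then symbol.

The selection report tallies genes per (group × category); on the packaged
19-gene table the partition is 9/4/5/1 with 28 loci.

### Clustering

The heatmap-style view clusters the per-patient Δβ and log2 FC matrices of
the selected genes (one column per patient): array (column) mean centering
— gene-wise centering is *not* applied — Pearson "correlation (centered)"
dissimilarity d = 1 − r, and unweighted average linkage (UPGMA). UPGMA is
implemented directly because the merge tie-break is part of the contract
(ties go to the lexicographically smallest pair of cluster ids, ids in
creation order); it is cross-checked against `scipy.cluster.hierarchy` on
tie-free instances and against a definitional brute-force oracle for ≤ 6
leaves. Output is written as Cluster-3.0 `.cdt`/`.gtr`/`.atr` files
loadable in TreeView, plus a JSON dendrogram.

### Validation arm

* **2^−ΔΔCt**: relative expression from qPCR threshold cycles, anchored to
  an explicitly named reference (housekeeping) gene and a baseline
  condition. The schema *requires* the reference label because the
  underlying experiment does not fix one; guessing would hide an analysis
  choice. The statistic is invariant under adding a constant to all four
  Ct values.
* **Bisulfite conversion**: every cytosine becomes thymine except
  cytosines at explicitly listed methylated CpG positions; listing a
  non-CpG position is an error.
* **MSP matching**: exact string match of the sense primer and the reverse
  complement of the antisense primer on the converted top strand (bottom
  strand is not modeled). Product size is counted inclusively from sense
  start to antisense end, the convention in which MSP product sizes are
  reported. Multiple compatible amplicons are all reported and flagged.
* **Dose response**: fold-vs-baseline across the decitabine series (0, 5,
  10, 20 µM) with a non-decreasing verdict and an optional per-step dip
  tolerance.

## The synthetic-data generator

No raw arrays are distributed with the analysis this package models, so
every stage is driven by a generator that emulates the study conditions:

* 2 + 2 patients, paired normal/tumor columns (8 arrays);
* planted per-gene effects: a methylation difference `delta_beta` applied
  to the tumor columns of the gene's group (normal baseline defaults to
  0.5 − Δ/2 so both values sit inside [0, 1]) and an expression `log2_fc`
  applied the same way on the log2 scale;
* intensities M = scale·β + background, U = scale·(1 − β) + background,
  with negative controls drawn from the same background distribution —
  exactly what the β computation subtracts back out;
* noise: truncated Gaussian on β (default SD 0.02) and Gaussian on log2
  expression (default SD 0.1); effects are applied identically in both
  patients of a group (per-patient heterogeneity is not modeled — the
  consistency filter passes by construction on planted genes);
* default probe counts emulate the platforms (10,000 CpG decoys for
  routine use, 47,000 expression probes); tests use much smaller matrices.

### The deterministic 19-gene fixture

`fixture_from_table1(decoys, seed)` plants the packaged candidate table
verbatim: each gene's printed Δ and signed FC, the first nine genes
carrying two CpG loci each (28 loci over 19 genes). Two design choices
make the fixture exact rather than approximate:

* **Zero noise by default.** Several genes sit exactly on the inclusive
  thresholds (Δ = 0.20, |FC| = 2.06); any noise would turn their selection
  into a coin flip. With zero β-noise and zero background spread the
  pipeline recovers every planted value to machine precision.
* **Mirror probes.** Quantile normalization would otherwise perturb the
  planted values. Every effect probe is paired with a mirror probe holding
  the same two values with tumor/normal swapped (and the complementary
  baseline), so all eight columns are permutations of one another and
  quantile normalization is an exact fixed point. Mirror probes belong to
  synthetic "complement" genes (`CMETH_*`, `CEXPR_*`) whose other data
  type is flat, so the sign-opposition step discards them; decoy genes
  come in mirror pairs (`DEC*`) with |Δ| < 0.15 and |FC| < 1.7, clear of
  the thresholds on both sides so the decoy rejection is deterministic.

What passing on this fixture shows: the thresholding, pairing, consistency
and reporting logic is exact, including boundary behavior. What it does
not show: robustness to probe-level noise, batch effects, Infinium I/II
chemistry, annotation ambiguity or real biological heterogeneity — those
are exercised separately (noisy-recovery property tests) or are out of
scope.

## Packaged reference tables

* `integrated_genes.tsv` — the 19 candidate genes with Δ, signed FC and
  the CCDB/CCDB-novelty and GENT-direction annotations. The concordance
  report counts a gene novel when absent from CCDB (15 of 19) and
  direction-concordant when the GENT direction matches the sign of the
  fold change here, ignoring the "highly" qualifier (16 of 19);
  "not changed" and "absent" never concord. Genes described as moderately
  downregulated map to direction "down".
* `msp_primers.tsv` — MSP primer pairs and expected product sizes for
  CAMK2N1 (185/186 bp), ALDH1A3 (134/135 bp), PPP1R3C (153/153 bp).
* `functional_clusters.tsv` — static functional-annotation clusters of the
  19 genes; reference data only, never recomputed (it derives from an
  external annotation service).

Live database queries are intentionally replaced by these packaged
snapshots: the web resources are version-unstable and their recomputation
is out of scope.

## Numerical conventions and degenerate inputs

* Quantile normalization resolves ties by assigning the mean of the
  reference values at the tied ranks; a single-column matrix is returned
  unchanged. Idempotence holds exactly on tie-free data.
* β is clamped to [0, 1]; channels below background clamp to 0.
* Fold change requires strictly positive group means; signed FC of equal
  means is +1 by convention.
* t-test on zero-variance-in-both-groups rows: p = 1 if means agree, else 0.
* UPGMA requires a symmetric zero-diagonal matrix; merge heights are
  non-decreasing (average linkage is reducible).
* Zero-variance rows/columns cannot be clustered with correlation
  distance; the pipeline skips the clustering stage for degenerate
  matrices rather than failing the run.
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed reproduces every matrix bit-for-bit, and pipeline reruns with the
  same config are byte-identical (outputs carry a hash of the analysis
  config, excluding the output path).

## Problem sizes

The default acceptance-style run uses the 19-gene fixture plus 1,000 decoy
genes (~1,100 CpG probes, ~1,060 expression probes, 8 arrays) and
completes in about a second; the free simulator scales to full platform
sizes (~485k CpG / 47k expression probes) in a few seconds. These sizes
were chosen to keep the deterministic fixture exhaustive while remaining
trivially fast.

## Known limitations

* No IDAT decoding, Infinium I/II correction, dye bias or batch handling.
* The detection-p definition is a stand-in for a proprietary one.
* MSP matching is exact (no mismatch tolerance) and top-strand only;
  primer *design* is out of scope.
* With n = 2 per group the t-test/BH machinery is reported but cannot
  meaningfully rank genes; selection rests entirely on effect sizes.
* The mapping of multiple loci per gene in the packaged table is a fixture
  convention (first nine genes carry two loci); the true per-gene locus
  counts are not published.
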