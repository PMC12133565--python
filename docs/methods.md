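# Methods

`tadlink` implements an integrative analysis of chromatin accessibility
(ATAC-seq) and gene expression (RNA-seq) for a two-group, replicated
study design, with long-range regulatory assignment constrained by
topologically associating domains (TADs). This note documents the models
and procedures, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Coordinate and interval conventions

All internal coordinates are 0-based half-open `[start, end)`. BED-family
formats are native; GTF (1-based inclusive) is converted at the parse
boundary and converted back on write, so printed GTF coordinates round
trip exactly. The TSS is the first transcribed base (`start` on `+`,
`end − 1` on `−`).

Interval merging requires at least one shared base: half-open adjacency
(`[0,10)` next to `[10,20)`) does **not** merge. This convention
propagates to consensus building and Venn classification, whose counting
unit is a merged region of the relevant union — a shared region is
counted once however many input peaks cover it.

TAD partitions are consumed, never called: overlapping input TADs are
repaired by truncation at the midpoint of the overlap (each repair is
logged), because public TAD calls can overlap while the downstream
search assumes a disjoint partition.

## Consensus peaks and Venn classification

A group's consensus is the merged union of all replicates' peaks,
retaining regions overlapped by peaks from at least `min_samples`
(default 2) distinct replicates. Support is counted at the region level:
a replicate supports a region if any of its peaks overlaps it. The
shared/unique classification of two groups labels each merged region of
the A∪B union by which group's consensus it overlaps. Both operations
are validated against per-base painting oracles in the test suite (with
runs split at unbridged junctions, honoring the adjacency convention).

## Normalization

Size factors use the median-of-ratios estimator: for features positive
in every sample, the median over features of `count / geometric mean`,
rescaled so the factors' geometric mean is 1. Two variance-stabilizing
transforms are provided:

- `log2p1`: `y = log2(x/s + 1)` — simple, monotone, zero-preserving;
- `asinh_nb` (default): `y = (2/√α̂)·asinh(√(α̂·x/s))`, the classical
  negative-binomial stabilizer, with a common moment-based dispersion
  `α̂` estimated from the matrix. Its variance is approximately constant
  for means above ~1/α̂; a test verifies that replicate SDs vary by
  < 3× across mean deciles on NB simulations.

## Differential testing

The NB moment/Wald test works on size-factor-normalized counts. Per
feature: group means `μ_A, μ_B`; `LFC = log2((μ_B + c)/(μ_A + c))` with
pseudocount `c = 0.5` so zero groups stay finite; delta-method standard
error from `Var(μ̂_g) = (μ_g + α_i μ_g²)/n_g`; two-sided normal p on
`z = LFC/se`; Benjamini–Hochberg adjustment; calls at adjusted p < 0.05
and |LFC| ≥ 1 (both configurable).

The dispersion `α_i` is the element that required a real design
decision. A pure per-feature moment estimate at n = 4 per group is
strongly anti-conservative (measured type-I ≈ 0.10 at nominal 0.05),
while a plain across-feature mean is destroyed by a minority of features
carrying strong latent biological covariation (their huge variance
inflates the common value and silences every call). The implementation
uses

    α_i = max(per-feature moment estimate, robust common estimate)

where the per-feature estimate solves `E[v] = μ + αμ²` with a
small-sample bias correction of the `μ²` denominator
(`E[μ̂²] = μ² + Var(μ̂)`), and the common estimate is a Huber M-location
of the per-feature values. The per-feature floor protects highly
variable features from being called on noise; the robust common floor
stabilizes the tiny-n estimates. Measured on seeded simulations: type-I
error 0.037–0.051 across seeds at dispersion 0.4 (4 vs 4), power ≈ 0.99
for planted |LFC| = 2 at mean 100 and dispersion 0.1, and ≥ 0.9 recovery
of planted differential genes in full synthetic datasets that also
contain planted latent links.

BH adjustment is implemented directly (step-up, `q_(i) = min_{j≥i}
p_(j)·m/j`, capped at 1) and is checked exactly against an independent
brute-force implementation and against `statsmodels` in the tests. Note
that BH is *not* idempotent in general — `BH(0.1, 0.9) = (0.2, 0.9)` but
`BH(0.2, 0.9) = (0.4, 0.9)` — so the suite asserts the true properties
(dominance, order preservation, constant fixed points) instead.

## TAD-constrained linking

Peaks are anchored at their midpoint (the summit is optional where
present; the midpoint always exists), genes at their TSS. An element
belongs to the unique TAD whose half-open interval contains its anchor;
elements outside every TAD are excluded from pairing and counted. Within
each TAD, every peak × gene pair is tested: Pearson r across all pooled
samples of both groups on VST values, two-sided p from
`t = r√(n−2)/√(1−r²)` with n−2 df. Zero-variance vectors make a pair
untestable (dropped with a reason code); |r| = 1 is reported
deterministically as p = 0 with a flag rather than numerical noise.

Significance defaults to raw p < 0.05 — matching the convention of
reporting "significant correlations (p < 0.05)" without multiplicity
correction in this kind of analysis — with a config switch to BH. The
pooled-sample design means group differences legitimately produce
correlations (a peak and gene that both shift between genotypes are
correlated across the pooled samples); in full synthetic datasets the
significant fraction therefore exceeds the nominal α even though purely
null pairs reject at ≈ 0.05 (verified by a dedicated null benchmark).

The correlation p-threshold used when intersecting linked genes with
differential calls is an explicit parameter (`corr_p_threshold`,
default 0.05) rather than a constant, because source analyses of this
design have reported both 0.05 and 0.5 in different places; the default
follows the conventional 0.05.

## Motif enrichment

A JASPAR-format count matrix becomes a probability matrix after adding a
background-split pseudocount (`cell_b += 4·pc·background_b` per column,
default pc = 0.8, so a uniform background adds 0.8 per cell) and
column-normalizing; scores are log2-odds in bits against a 0-order
background.

The scan threshold is derived from the exact distribution of the score
of a random background L-mer, computed by dynamic programming over
per-column score distributions discretized to 0.01-bit bins: the
threshold is the smallest binned score whose tail probability is ≤ the
target (default 1e-4). Because each column's score is rounded, an exact
window score can drift from its binned sum by up to L·bin/2; the
returned threshold subtracts that drift so the scan keeps every window
the DP tail counted. DP tails match exhaustive L-mer enumeration exactly
for L ≤ 6 in the tests.

Both strands are scanned (reverse strand via reverse complement);
windows containing N are skipped. Enrichment is sequence-level
presence/absence: one-sided hypergeometric upper-tail p of `k_target`
hit-bearing sequences among `n_target` draws from the pooled
target+background universe — exact, discrete, and therefore mildly
conservative under the null (verified: null rejection ≈ nominal for
moderately sized designs). The GC-matched background sampler draws
length-matched genomic windows accepted when their GC is within ±0.05 of
a sampled target's GC, rejecting windows that overlap target regions;
it is seeded and reproducible.

The packaged `nfat_ap1_synthetic` matrix is a synthetic composite
NFAT:AP1-like PWM (GGAAA + 3-bp spacer + TGACTCA) constructed in-package
as a scanning fixture; any JASPAR-format matrix can be supplied instead.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 2
genotype groups × 4 biological replicates. Defaults (chosen once, for
desk scale — the full pipeline runs in seconds): 2 chromosomes × 1 Mb at
GC 0.42, 20 TADs tiling the chromosomes disjointly, 300 genes with TSSs
inside TADs, 1000 non-overlapping peaks (~400 bp, 40% promoter-proximal),
NB counts with means log-uniform in [50, 500] and dispersion 0.1 (a
typical between-biological-replicate value for inbred-mouse tumor
counts), per-sample library depth factors log-uniform in [0.7, 1.4],
30% group-unique peaks (near-silent, mean × 0.02, in the other group),
10% differential genes at LFC 2, 1% of eligible within-TAD pairs planted
as links at target |r| = 0.9 with 20% negative, and replicate peak
boundary jitter of ±10 bp.

Planted correlation uses a shared log-normal latent factor: each linked
pair draws per-sample `z_j ~ N(0,1)` and multiplies both NB means by
`exp(±b·z − b²/2)` (negated exponent on the peak for negative links),
which keeps counts marginally NB-like. The factor scale is calibrated
per entity from the target correlation and the approximate log-scale NB
noise (`Var(log X) ≈ 1/μ + α`): `b² = r/(1−r)·v_noise`, which makes the
expected VST-scale Pearson r of the pair ≈ r_target. The calibration is
itself under test (mean empirical r within 0.1 of target over ≥ 100
links), as are planted-LFC consistency, consensus recovery at small
jitter, and byte-level determinism of every emitted file under a fixed
seed.

What the generator does **not** emulate: read-level data (no FASTQ/BAM,
no Tn5 insertion bias or fragment-length structure), GC- or
mappability-dependent coverage bias, correlated peak co-accessibility
beyond the planted pairs, distance-dependence of peak–gene contacts
within TADs, and Hi-C contact matrices (TADs are generated as a
partition directly). Passing tests therefore demonstrate correctness of
the algebra, the statistics and the calibrations under an idealized NB
world, not robustness to alignment artifacts or real chromatin-biology
confounders.

A focused benchmark generator (`generate_link_benchmark`) emits paired
peak/gene count matrices with a configurable number of planted links and
exactly-null pairs (no group effects), used for the parameter-recovery
and calibration studies: with 200 planted links (|r| = 0.9, 20%
negative) and 2000 null pairs at 4+4 samples, measured recall is
0.91–0.95 at α = 0.05, sign accuracy 1.0, and null false-positive rate
≈ 0.05 (0.037–0.062 across seeds — a single 2000-pair run fluctuates by
±0.01 around the nominal level).

## Pipeline and determinism

The pipeline executes parse → consensus/Venn → normalize → differential
→ annotate → TAD-link → summarize → (optional) motif enrichment from a
single YAML config whose keys mirror the module parameters (α_de = 0.05,
lfc_min = 1, α_corr = 0.05 defaults). Every stage writes its table
(BED/TSV/JSON) so each report count is recomputable from files; a stage
failure aborts with the stage name, keeping partial outputs. Reruns with
the same config and seed are byte-identical; wall-clock timestamps are
confined to `run_log.txt`.

Annotation classifies each peak by its anchor with precedence promoter >
TTS > exon > intron > intergenic; the promoter window is
transcription-oriented (default −1000/+100 bp around the TSS, Homer-like),
the TTS window ±100 bp; ties between equidistant genes break to the
lexicographically smaller gene id.

## Known limitations

- The differential test uses a normal reference for the Wald statistic;
  at n = 4 per group its calibration rests on the moderated dispersion
  (measured, not proven) and degrades below ~10 counts per feature.
- No dispersion trend fitting or LFC shrinkage — features at very low
  means are noisier than a DESeq2-class analysis would leave them.
- Pearson correlation on 8 pooled samples has limited resolution
  (|r| ≳ 0.71 for p < 0.05); the pipeline reports what the data support
  at that n rather than attempting hierarchical pooling.
- The t-based correlation p is a continuous approximation to a discrete
  permutation null; at n ≤ 6 the pointwise gap can reach ~0.1–0.27, and
  only the expected gap stays below 0.05.
- The motif background model is 0-order; CpG-poor/rich composition
  beyond GC fraction is not matched.
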