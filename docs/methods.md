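# Methods

`dosagenet` analyzes expression responses to halved gene dose in
*Drosophila* deficiency heterozygotes (Df/+): flies carrying one deleted
and one intact copy of a chromosomal segment, so every gene inside the
segment is at one dose while the rest of the genome stays at two. The
package covers four stages — dose confirmation from DNA-seq coverage,
five-class dosage-compensation calling, sex-specific mutual-information
(MI) network inference, and propagation of dose perturbations into the
two-dose genome — plus a synthetic-data generator that plants ground
truth for every stage.

## Coordinates and containers

Genomic intervals are 1-based inclusive at every public surface (matching
deficiency breakpoint tables); internal arithmetic is 0-based half-open,
with `containers.to_internal`/`to_external` as the only crossing points.
A gene is *one-dose* in a line when its interval overlaps the deletion by
at least 1 bp (removed in full or in part). Expression lives in an
`ExpressionMatrix` (log2 values; gene, control-probe and spike-in rows;
line/sex/replicate sample metadata); coverage in binned `CoverageTrack`s.

## Coverage statistics

Region abundance is reads per million mapped (RPM), with partial bins
pro-rated linearly by overlap fraction (reads treated as uniform within a
bin; default bin 1 kb — at a few-fold sequencing depth per-base estimates
are noisy and 1 kb bins average ~100+ reads). Dose is reported as the
wild-type/deficiency RPM fold difference; 2.0 means the segment is at
half dose. The novel-deletion scan slides a window (default 5 bins) and
merges maximal runs whose Df/WT RPM ratio is ≤ 0.66 — the log-space
midpoint between dose 1 (ratio 0.5) and dose 2 (ratio 1.0). Resolution is
window-limited: deletions much shorter than the window dilute below
threshold, so a ~5 kb deletion at 1 kb bins sits at the detection edge.
Known selectively endoreplicated loci (e.g. chorion clusters in females)
can be masked via an interval list; no mask is applied by default. RPM
fold differences computed per sex library, since coverage is simulated
and summarized per library.

## Replicate QC, detection, references

Within each (line, sex) group, replicates are dropped worst-first while
any sample's median pairwise Spearman correlation with its partners is
below 0.8 (boundary retained); removing the offender first keeps one
corrupt hybridization from disqualifying its intact partners. Detection
uses the control probes: per sample, threshold = mean + 2 SD of
control-probe intensity; a gene is detected in a line when its
replicate-mean expression strictly exceeds the replicate-mean threshold,
and a per-sex mask requires detection in **all** lines of that sex. Two
references are used: the *parental* reference (per-gene median over the
parental line's replicates, for one-dose compensation calls) and the
*composite* reference (per-gene median over all Df/+ samples of that sex,
for per-line differential expression — the median across 21 lines is
insensitive to any single line's deviation).

## Moderated t-test

Per-gene tests use an empirical-Bayes moderated one-sample t on
replicate log-ratios to the reference. With per-gene residual variance
s_g² on d_g df and a scaled-inverse-chi-square prior (s0², d0), the
posterior variance is s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g) and
t = (LFC − null)/ (s̃/√n) has d0 + d_g df. The prior is fit by moment
matching on log s_g²: E[log s_g²] and Var[log s_g²] involve digamma and
trigamma terms of d_g/2 and d0/2; equating observed moments gives d0 via
a Newton inversion of the trigamma function and s0² in closed form. A
degenerate ensemble (no excess spread in log variances) falls back to
d0 = ∞, i.e. a pooled variance and a normal reference distribution;
zero variances are floored at 1e-10 × the median variance. Tests are
two-sided throughout; BH (Benjamini-Hochberg) adjustment is applied
within each (sex, test family) — e.g. per line for per-line differential
expression. Missing values are rejected at ingest rather than imputed.
The simulated-null suite checks type-I error ≈ α and p-value uniformity
at 10,000 genes.

## Compensation classifier

Against the two-fold-reduction null (null LFC = −1): genes whose null is
not rejected (q ≥ 0.05) are **non-compensated**; rejected genes below −1
are **anti-compensated**. The remaining rejected genes (LFC > −1) are
stratified by a bootstrap band: their LFC values are resampled with
replacement (n_boot = 1000 draws), a normal-theory 2.5%/97.5% interval
(bootstrap mean ± 1.96 SD) is computed, and the bootstrap mean is
subtracted so the interval is centered at "no change" vs the reference;
inside the band = **fully**, above = **over-**, below = **partially
compensated**. Boundary ties go to "full"; a rejected gene at exactly −1
(possible only through pathological rounding) defensively goes to "non".
Fewer than 10 step-2 genes → all are called "partial" with a warning
(conservative). The bootstrap is per sex, over gene-level LFCs (the band
describes the spread of fold changes in the step-2 group, not replicate
noise).

*Behavioral note.* Because the band is ±1.96 SD of the step-2 group's own
distribution, it covers ~95% of that group by construction: when the
group is a broad mixture (many genuinely partially compensated genes),
most of it lands in "full" and the partial/over calls thin out. On
synthetic data with a planted 0.05/0.40/0.30/0.20/0.05
anti/non/partial/full/over mixture at 500 one-dose genes, 3 replicates
and 0.25 log2 noise, overall planted-class recovery is ≈ 0.55–0.58 with
partial→full the dominant confusion; step-1 classes (anti, non) and full
recover well. No alternative reading of the centered normal-theory band
does better (a bootstrap-SE-of-the-mean band of ±~0.04 instead
misclassifies most fully compensated genes). The rule is kept as
specified; the recovery ceiling is an inherent property of a
self-referential 95% band and is exercised, not hidden, by the
acceptance suite.

## Resampling and distribution analyses

One-dose LFC distributions are compared with size-matched *contiguous*
blocks of two-dose genes in genome order (physically linked genes
co-express, so scattered sampling would understate the null's
variance); a draw picks a uniformly random valid start among runs of
eligible genes, 2,000 draws by default. Shape tests: Jarque-Bera
(n/6·(S² + K²/4) against χ²(2)) for normality of one-dose LFCs, and a
two-sample Kolmogorov-Smirnov test against the resampled two-dose
values; the mean fold reduction is reported as 2^(−mean LFC).
Variance-in-both-states comparisons bootstrap the gene set and report
notched-boxplot summaries (median, 1.57·IQR/√n notches, quartiles) of
the variance of fold differences. Compensation-vs-expression-level uses
Spearman correlation plus a binned MA-style trend; between-sex
concordance is a per-bias-group Spearman ρ of compensation ratios
(groups under 5 genes report NA). Cross-deficiency consistency, for
genes uncovered by ≥ 2 deletions, is a moderated one-way F (between-line
mean square over the shrunken pooled residual variance) with BH within
the family.

## MI networks

Per sex, each gene's profile is z-scored over all lines and replicates
(zero-variance genes excluded with a warning). Pairwise MI uses the
Gaussian-kernel plug-in estimator with bandwidth h = 0.3 on the z scale
(diagonal bandwidth in the bivariate term): MI = mean over samples of
log[f̂_XY/(f̂_X·f̂_Y)]; kernel normalization constants cancel in the
ratio, and the estimator is exactly symmetric. Edge significance uses a
*pooled* permutation null — MI of independently permuted profile pairs at
the same n and h — because after standardization the null distribution
depends only on n and h, and per-pair permutation across O(G²) pairs at
α = 0.005 is intractable; p = (1 + #{null ≥ obs})/(1 + n_perm), which
requires n_perm ≥ 2/α. Edges with p < 0.005 form a simple graph; genes
without edges stay as isolated nodes so one-dose genes remain queryable.

Topology: average local clustering, mean degree 2|E|/|V|, density, and a
power-law exponent fit by least squares on the log-log degree-frequency
distribution (degree ≥ 1) — matching common network-analysis tooling; an
MLE fit is deliberately not substituted since the slope is descriptive
here. The null model is a degree-preserving double-edge swap ((a,b),(c,d)
→ (a,d),(c,b), rejecting self-loops and already-existing edges), with
n_swaps_factor·|E| attempted swaps per randomization; the degree multiset
is preserved exactly, and a graph admitting no legal swap (K3, complete
graphs) is returned unchanged with a warning. Empirical p-values use the
add-one rule. Per-bias-group subnetwork clustering is compared against
randomizations of the *full* network with memberships fixed.

*Estimator floor.* At n ≈ 40–70 samples the pooled null of the h = 0.3
kernel MI has mean ≈ 0.28 nats and a 99.5th percentile ≈ 0.40, so only
pair correlations ≳ 0.65 clear α = 0.005. A hub shares its variance
across its neighbors (Σ corr² ≤ 1 over edges at a node), so hub edges
cannot all be that strong: recall of a planted scale-free network is
necessarily partial and concentrated on low-degree pairs, and the test
suite asserts exactly that (low-degree recall plus false edges at the α
expectation) rather than a blanket recall figure. At n = 500 the same
estimator reproduces the bivariate-Gaussian closed form
−½ln(1−ρ²) within ±0.05–0.1 nats (smoothing and resubstitution biases
largely cancel at h = 0.3).

## Propagation

Per-line differential expression is the one-versus-everyone scheme: each
line's replicates against the composite reference, moderated t with
null 0, BH within the line, sign recorded. First-degree neighbors of a
one-dose gene exclude one-dose genes of the same line; on the X
chromosome in males genes count as two-dose (the male X is dosage
compensated). Per compensation class, the probability that a neighbor
changes and the positive-direction proportion among changed neighbors
are tested against pooled global rates by a 1-df chi-square
(goodness-of-fit against the global expectation), falling back to an
exact binomial when an expected cell is below 5. The global change
denominator is network nodes two-dose in each line (the null neighbors
come from those); the all-measured-genes denominator is reported
alongside. Pooling uses union-with-multiplicity by default — each
(one-dose gene → neighbor) pair counts once, a neighbor shared by two
hubs of a class counts twice — with a `mode="unique"` switch.

Complex coherence, per (complex, line, sex) cell: universe = measured
two-dose genes of that line and sex; enrichment p = upper-tail
hypergeometric of the changed-member count; direction p = two-sided
binomial of the positive count among changed members at the sex's global
positive rate; joint p = their product (the pure enrichment p is
reported alongside, since "coherent co-change" is usually quoted as the
hypergeometric alone), flagged at joint p < 0.01. Complexes are selected
once per sex (≥ 10 members among that sex's measured genes), so the
retained complexes enumerate a complete complex × line matrix — with the
default 23 synthetic complexes and 21 lines, 966 cells over both sexes.

## Synthetic data generator

The generator emulates the study design: a parental line (`w1118`) plus
21 Df/+ lines on one chromosome arm, two sexes, three biological
replicates per (line, sex), gene-level log2 expression with 50 control
probes and 96 spike-ins (three 32-spike subsets at design ratios 1:1,
1.5:1, 1:1.5 between the Df and parental mixes, baselines spanning a
2^20 dynamic range), and Poisson DNA-seq tracks with half depth over
deletions. One master seed drives deterministic per-component child
streams (`numpy` SeedSequence spawning), so outputs are byte-identical
under a fixed seed.

Planted structure, with defaults and rationale:

- **Deletions**: `genes_per_df` contiguous genes per line (default 2 at
  the default 500-gene genome, making the one-dose union ≈ 5–8% of genes,
  the study's genome-wide proportion); two line pairs deliberately
  overlap so one-dose genes recur in multiple deficiencies; breakpoints
  jitter into intergenic space so the one-dose set is exact.
- **Compensation classes**: per-gene labels from the mixture
  (0.05, 0.40, 0.30, 0.20, 0.05) over (anti, non, partial, full, over);
  true log2 responses drawn uniformly from per-class ranges
  anti (−1.9, −1.3), non (−1.0, −0.95), partial (−0.65, −0.35),
  full (±0.06), over (0.35, 0.65) — the class structure is published
  only qualitatively, so the ranges are config, chosen to respect the
  ordering anti < −1 < non ≤ partial < full ≈ 0 < over.
- **Sex effects**: 20%/20%/60% female-/male-/non-biased genes, ±0.75
  log2 offset per sex for biased genes; per-sex deviations of the dose
  response with SD 0.25 for biased genes vs 0.05 for unbiased ones, so
  between-sex compensation concordance is higher for unbiased genes.
- **Network**: a simple scale-free graph (configuration model on a
  power-law degree sequence, exponent 2.5, degrees capped at 20 so
  per-edge correlation does not vanish at the largest hubs).
- **Co-expression**: per-edge latent factors weighted 0.12, drawn per
  (line, sex) — line-level biological covariation that the MI stage can
  see while replicate-level variance (what the moderated t uses) stays
  at `noise_sd`. The weight is anchored to the per-line
  differential-expression rate: 0.12 yields ≈ 8% of detected genes
  changed per line, the order observed in real Df/+ panels; a
  `coexpression_per="sample"` mode draws factors per sample for tests
  that isolate network inference.
- **Propagation**: first-degree neighbors of a one-dose gene shift in
  that line by a per-class amount — anti −0.9, non −0.6, partial +0.6,
  full +0.6, over +0.7 log2. The sign pattern (down for anti/non, up for
  compensated classes, anti largest) is planted directly because a pure
  "shift with the hub's expression change" rule cannot produce upward
  neighbor skew for partially compensated hubs, which is the empirical
  signature being emulated; magnitudes are set to be detectable at 3
  replicates and 0.25 noise.
- **Noise**: iid Gaussian, 0.25 log2 per replicate — array-scale
  measurement plus biological replicate noise on the log scale, keeping
  the moderated-t assumptions testable.
- **Complexes**: 23 membership lists of 12–20 genes, a third drawn from
  planted-network neighborhoods (their members co-change through shared
  factors), the rest random — a synthetic stand-in for a curated
  co-purification complex catalog.

What the generator does **not** emulate: probe-level microarray signal
and RMA summarization, spatial/batch artifacts, read-level sequencing
(FASTQ/alignment), X-chromosome compensation machinery, endoreplicating
tissues, and indirect (multi-hop) propagation. Passing tests therefore
demonstrate that the statistics recover the *planted* generative
structure at these noise levels and sample sizes — not that real Df/+
data satisfy the generator's assumptions.

## Problem sizes

The test and acceptance runs use scaled-down genomes chosen so every
stage has adequate counts: 120–500 genes for pipeline tests, 1,100 genes
/ ~500 one-dose genes for classifier recovery, 500 genes × 21 lines ×
2 sexes × 3 replicates for the end-to-end propagation run (per-class
neighbor counts of ~10–250), 10,000 genes for t-test calibration, and
2,016 pairs at n = 66 for edge-null calibration. The full suite runs in
a few minutes on one CPU.

## Known limitations

- The step-2 band's self-referential construction limits partial/over
  recall (see the classifier note above).
- Kernel-MI edge recall at array-scale sample sizes is confined to
  strongly coupled, low-degree pairs; inferred networks confound direct
  and indirect (same-line co-deviation) relationships — no DPI/ARACNe
  style pruning is applied.
- The pooled MI null assumes exchangeable z-scored profiles; replicate
  structure within lines makes it mildly optimistic for line-level
  covariation.
- Real-data ingest expects RMA-summarized (or otherwise gene-level) log2
  matrices; no normalization is performed beyond the documented steps.
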