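# Methods

`methylflux` implements the desk side of a study design used to dissect how an
m6A writer/reader axis shapes the primed-to-naive transition (PNT) of
pluripotent stem cells: MeRIP-seq peak calling, actinomycin-D (ActD) chase
half-life estimation anchored to ERCC spike-ins, time-course expression
dynamics, over-representation analysis, and m6A ELISA quantification. This
note records the models, defaults, numerical choices, and what the synthetic
data does and does not emulate.

## MeRIP-seq peak calling

Input is paired IP/input per-nucleotide coverage over transcripts
(bedGraph, 0-based half-open, transcript-relative coordinates, strand fixed
"+"). Each transcript is scanned with a **100-nt window advanced in 50-nt
steps**; a terminal truncated window is kept only if it is at least one step
(50 nt) long, since sub-step fragments estimate fold from too few positions.

Windows are normalized to RPKM using the per-base convention of coverage-track
tools: `rpkm = mean_depth * 1e9 / library_total`, under which a track of
uniform depth 1 from a one-million-read library scores 1000. Enrichment is

    fold = (ip_rpkm + alpha) / (input_rpkm + alpha),      alpha = 0.5 RPKM

The symmetric pseudocount bounds the fold and avoids division by zero on
uncovered windows. A window is *enriched* when `fold >= 4` (inclusive — a
window at exactly fourfold is called) **and** its raw IP+input coverage,
summed per-nt depth over the window, reaches `min_window_reads = 10`
read-equivalents; the gate suppresses spurious large folds supported by one
or two reads. Enriched windows on a transcript that overlap or are book-ended
merge into final peaks ("adjacent" means gap <= 0; consecutive enriched
windows overlap by construction at 50-nt stepping). A peak's score is its
maximum member-window fold. Per-transcript peak-coverage summaries
(`transcript_peak_coverage`) are computed over the **union** of peak
intervals, so they are invariant to how a region is split into adjacent
peaks.

Whether enrichment should be computed on raw reads or RPKM is an assumption:
RPKM-based windows are used, matching how the coverage tracks are generated.
Genome-coordinate (spliced) calling, statistical peak significance and
replicate reconciliation are out of scope.

## mRNA decay kinetics

After transcription shutoff, first-order decay gives
`N(t) = N(0) exp(-k t)`, hence `t1/2 = ln2 / k`. Per gene, `ln(count + 0.5)`
is regressed on time (default t = 0, 4, 8 h) by ordinary least squares;
replicate samples at a timepoint are averaged after normalization. The +0.5
pseudocount handles zero counts at late timepoints and is the dominant error
term on otherwise exact series (a noise-free 1000/500/250 series fits
t1/2 = 4.004 h rather than 4). Positive slopes are clipped to k = 0: under
ActD apparent synthesis is noise, and k = 0 maps to an infinite half-life.
All-zero genes are reported as missing (NaN) rather than dropped.

Because the cellular mRNA pool decays while ERCC spike-ins (added per unit
RNA) do not, library-size normalization must be anchored to the spikes.
`spike_in_size_factors` divides each sample by
`spike_total / geometric_mean(spike totals)`, so factors have geometric mean
1 and normalization is idempotent. Optionally, an RUV-style factor removal
strips residual sample-level structure: the top *k* left singular vectors of
the gene-centered spike-in submatrix are the unwanted factors, and their
least-squares contribution is subtracted from every gene column (computed on
`ln(normalized + 0.5)`; fits then run on the adjusted log values). For a
fixed orthonormal factor basis this is an exact projection. When factors are
**re-estimated** from already-adjusted data, idempotence holds only if the
control structure was (numerically) rank <= k — with noisy controls a second
pass would peel a further noise direction; numerically-zero singular
directions are therefore gated out, and `estimate_unwanted_factors` is
exposed for callers who want the fixed-basis projection semantics.

Stabilization between conditions ("inhibited degradation") is a declared
stand-in, as the source analyses do not state their criterion: a gene is
stabilized when both fits are trustworthy (`r2 >= 0.5`, or k = 0 — a flat
profile carries no decay signal to doubt), the control decays (k_ctrl > 0),
the treatment decays more slowly, and the half-life ratio
treatment/control >= 1.5. Both cuts are configurable and logged.

A note on when spike anchoring matters: a *symmetric* distortion such as
(1, 2, 1) across t = (0, 4, 8) h inflates residuals but leaves the OLS
log-slope of a flat gene unbiased; a *monotone* distortion — for example a
per-timepoint halving (1, 0.5, 0.25), the signature of equalized sequencing
depth over a decaying pool — masquerades exactly as decay with k = ln2/4 per
halving interval. The suite asserts both: flat genes fit |k| < 0.02/h after
spike normalization under either distortion, and fit k ≈ ln2/4 without it
under the monotone one.

## Time-course expression dynamics

Filtering keeps genes with **row sum > 1** (literally: total count >= 2).
Size factors are median-of-ratios: for genes nonzero in all samples, the
median of `count / gene geometric mean` per sample. Differential expression
is a deliberately simple, fully documented stand-in for negative-binomial GLM
machinery: `log2fc = log2((meanB + 1)/(meanA + 1))` on normalized counts,
two-sided Welch tests on `log2(norm + 1)` (flagged low-power at n = 2
replicates), Benjamini-Hochberg adjustment. The variance-stabilizing
transform for PCA and clustering is `log2(norm + 1)`.

Two DEG threshold rules coexist because both are in use for different
readouts, and callers must pick one explicitly:

* `log2fc` mode: up iff `log2fc >= 1`, down iff `<= -1` (inclusive);
* `fc_p` mode: up iff `fold > 1.5` and `p < 0.05` (both strict; fold exactly
  1.5 is not significant), down symmetric at `fold < 1/1.5`.

`overlap_sets` enumerates every region of the Venn partition of 2–4 named
gene sets and returns the common intersection. `pca_trajectory` uses the 500
most variable genes of the log-transformed matrix, gene-centered SVD, and a
fixed sign convention (each component's largest-magnitude loading is
positive) so coordinates are reproducible.

Clustering follows the Mfuzz recipe: per-gene standardized profiles (mean 0,
sd 1 across timepoints; zero-variance genes must be pre-filtered, and
`standardize_profiles` drops them with a warning) partitioned by **fuzzy
c-means** with fuzzifier m = 2 (configurable; the conventional soft-clustering
default) and c = 9 clusters by default. Updates are the standard alternating
minimization — memberships `u_ij ∝ d_ij^(-2/(m-1))`, centroids the
`u^m`-weighted means — iterated until the objective `Σ u^m d²` changes by
less than 1e-6 or 500 iterations. Memberships are seed-initialized, rows sum
to 1, the recorded objective sequence is non-increasing, hard labels are the
argmax with ties to the lowest cluster index, and a gene sitting exactly on
centroids splits its membership uniformly over them.

## Over-representation analysis

For query size n from universe N with a term annotating K genes, the overlap
k is tested against the hypergeometric upper tail `P(X >= k)` (scipy's
`hypergeom.sf(k-1, N, K, n)`), BH-adjusted across tested terms. The universe
should be the expression-filtered gene set, not the genome. Terms are
intersected with the universe and gated to sizes 3–2000 to avoid degenerate
tests; query genes outside the universe are dropped with a logged count.
This is a generic ORA; it is not expected to reproduce any specific
annotation service term-for-term.

## m6A ELISA

A linear standard curve `OD = slope * ng + intercept` is fitted to the kit's
positive-control series (0.02–0.4 ng/well); the quoted standard range implies
a linear working range, so no 4PL fit is attempted. Sample amounts are
`(OD - intercept)/slope`, floored at zero with a below-detection flag
(background subtraction is not specified by the kit protocol as quoted; an
optional blank can be subtracted upstream), and
`m6A% = amount / input_ng * 100` with 200 ng immobilized mRNA as default
input. Inverting the fitted curve recovers simulated amounts exactly.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions and write sidecar truth tables so
downstream scoring never reaches into generator internals.

* **Time-course counts** — gene-by-sample negative-binomial counts (variance
  `mu + phi mu²`, default dispersion 0.1; Poisson at 0) with planted temporal
  patterns over days 3/5/7 (72/120/168 h), two conditions, two replicates,
  mean library 1e6. The nine built-in templates come in mirrored pairs plus a
  flat shape, so the balanced set keeps expected library size equal to the
  target depth at every timepoint while a single per-condition scale
  preserves each gene's temporal shape.
* **ActD chase** — expected gene counts `baseline * 2^(-t/t1/2) * distortion`,
  spike-ins `spike_def * distortion` (constant per unit RNA), Poisson
  sampling, t = 0/4/8 h, baseline 1000, half-life grid {1,2,4,8,16} h in the
  recovery setting. Ten ERCC rows at expected count 1000 by default.
* **MeRIP coverage** — per-nt Poisson input at background depth 30; IP
  multiplied by the planted enrichment (5x, 150-nt intervals in the fidelity
  setting) inside truth intervals. Both tracks carry the same nominal library
  total (the expected background mass over all simulated transcripts),
  mimicking depth-matched libraries in which the simulated transcripts are a
  negligible slice of a genome-wide library; recording realized sums instead
  would deflate local folds by the planted enrichment mass. One IP/input pair
  by default (replicate structure for MeRIP is not specified upstream).

Not emulated: read-level artifacts (fragment length, GC bias, duplicates),
spliced genome coordinates, batch structure beyond a rank-1 sample effect,
overdispersion in the decay counts, and biological coupling between the three
assays. Passing tests therefore demonstrate correctness of the *procedures*
under their stated statistical models, not robustness to every artifact of
real libraries.

## Problem sizes and determinism

The shipped checks run at desk scale by choice: 300 transcripts x 2 kb for
peak fidelity, 1000 genes for half-life recovery, 100–360 genes for
clustering — sizes at which every property is already stable across seeds.
Every stochastic step takes an explicit seed (`numpy.random.default_rng`),
and rerunning any CLI stage with the same config and seed writes
byte-identical tables (fixed float formatting, no timestamps in outputs).

## Known limitations

* The Welch-test DEG stand-in is underpowered at n = 2; it is meant for
  threshold-rule analysis, not discovery-grade inference.
* The stabilization criterion (ratio >= 1.5, r2 >= 0.5) is a declared default
  where the upstream analyses leave the rule unstated.
* Three-timepoint OLS cannot distinguish non-exponential decay; r2 is
  reported but has little power at three points.
* ORA ignores gene-set topology (no DAG propagation or semantic collapsing).
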