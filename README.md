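# methylflux

Analysis pipeline for studies of m6A-driven mRNA turnover during pluripotent
cell-state transitions. Given gene-by-sample count matrices, paired MeRIP-seq
IP/input coverage, and actinomycin-D (ActD) chase time courses with ERCC
spike-ins, `methylflux` provides:

* **MeRIP-seq peak calling** — sliding 100-nt windows at 50-nt steps over
  transcript coverage; a window is enriched when the pseudocount-stabilized
  IP/input RPKM ratio is >= 4 and carries enough raw coverage; adjacent
  enriched windows merge into peaks, with per-transcript peak-coverage
  summaries.
* **mRNA half-life estimation** — first-order decay
  `N(t) = N(0) e^(-kt)`, `t1/2 = ln2/k`, fitted by OLS on
  `ln(count + 0.5)` over t = 0/4/8 h after ERCC spike-in size-factor
  normalization and optional RUV-style factor removal, plus
  control-vs-treatment stabilization calls.
* **Time-course expression dynamics** — low-expression filtering,
  median-of-ratios normalization, DEG classification under both common
  threshold rules (|log2FC| >= 1; FC > 1.5 & p < 0.05), Venn overlaps, PCA
  trajectories, and Mfuzz-style fuzzy c-means clustering of standardized
  temporal profiles.
* **Over-representation analysis** — hypergeometric upper-tail tests of gene
  lists against GMT collections with Benjamini-Hochberg correction.
* **m6A ELISA quantification** — linear standard curve and
  `m6A% = (m6A amount / input mRNA) x 100`.
* **A ground-truthed synthetic-data generator** for all three assay types, so
  every stage is testable without sequencing data.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate MeRIP coverage with one planted 5x-enriched 150-nt interval per
transcript and call peaks:

```bash
methylflux simulate merip --out-prefix m --n-transcripts 3 \
    --transcript-length 1000 --seed 1
methylflux callpeaks --ip m.ip.bedgraph --input m.input.bedgraph \
    --lengths m.lengths.tsv --out peaks.bed
```

Truth (`m.truth.bed`) versus calls (`peaks.bed`):

```
tx0000  402  552  truth_1  500  +
tx0001  435  585  truth_2  500  +
tx0002  642  792  truth_3  500  +

tx0000  400  550  peak_1   493  +
tx0001  450  600  peak_2   500  +
tx0002  650  800  peak_3   491  +
```

Each planted interval is recovered with both boundaries within one 50-nt
step; the BED score is 100x the best window fold (capped at 1000), so 493
means a 4.93-fold IP/input enrichment against the planted 5x.

Simulate an ActD chase (half-lives 2 h and 8 h, baseline 1000, ERCC spike-ins)
and fit decay:

```bash
methylflux simulate decay --out-prefix d --genes-per-stratum 3 \
    --half-lives 2,8 --seed 1
methylflux decay --counts d.counts.tsv --out-prefix f --ruv-k 0
head -4 f.fits.tsv
```

```
gene       k         half_life  r2        n_points
hl2_g0000  0.328209  2.11191    0.997318  3
hl2_g0001  0.353669  1.95988    0.999312  3
hl2_g0002  0.357354  1.93966    0.999874  3
```

`k` is the decay constant in 1/h and `half_life = ln2/k` in hours: genes
simulated with a 2 h half-life fit between 1.94 and 2.11 h from three Poisson
timepoints.

The same operations are available as a library:

```python
import methylflux as mf

cm, truth = mf.simulate_decay_experiment(
    [mf.DecayTruth(f"g{i}", half_life=4.0, baseline=1000) for i in range(200)],
    seed=1,
)
fits = mf.decay_pipeline(cm, ruv_k=0)      # spike factors -> OLS decay fits
```

Other stages: `methylflux deg --mode fc_p`, `methylflux cluster --c 9`,
`methylflux ora --gmt sets.gmt`, `methylflux elisa --input-ng 200`. Every
subcommand accepts `--seed`, `--config config.yaml` and `--log-level`, with
flag > file > default precedence; rerunning a stage with the same config and
seed writes byte-identical outputs.

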