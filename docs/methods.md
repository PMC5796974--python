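# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Interval algebra

Coordinates are 0-based half-open (BED convention); strand is ignored, as
peak files in this workflow are unstranded. Merging fuses overlapping and
book-ended intervals (gap ≥ 1 bp afterwards), preserving the covered-base
set. The Venn partition of two cistromes is computed on the merged union of
both sets: each union interval is *common* if it overlaps ≥ 1 bp of both
inputs (the BEDtools default threshold), otherwise unique to whichever side
it came from. Counting on merged-union intervals is the one convention that
makes the triple well-defined and symmetric under swapping the inputs.

Remodeling between a pre- and post-treatment cistrome: a pre site is
*retained* iff it overlaps ≥ 1 bp of any post site; post sites overlapping
no pre site are *gained*; percent inhibition is
`100 · (1 − (n_retained + n_gained) / n_pre)`. Negative values mean net
expansion; equal loss and gain give 0% (pure redistribution). The measure
is count-based, not signal-weighted — a signal-weighted variant would need
per-site intensities that this stage deliberately does not require — and it
is undefined (reported as null) for an empty pre set.

## Motif enrichment

A PWM is a 4 × L count matrix with a pseudocount (default 0.5 per cell)
and log2-odds scores against a uniform 0.25 background — appropriate for
the uniform-composition synthetic genomes; the background is configurable
for biased genomes. Both strands are scanned; a window containing N never
scores; hits are reported as 0-based forward-strand starts. The hit
threshold is a fraction (default 0.8) of the motif's maximum attainable
score, which is scale-free across motifs of different lengths and
information content.

Enrichment treats each interval as motif-positive iff it contains ≥ 1 hit
and compares foreground against an explicitly supplied background interval
set by an upper-tail hypergeometric: drawing `n_fg` intervals from the
pooled population, `p = P(X ≥ n_fg_hit)`. Note that feeding the same set as
foreground and background does not give p = 1 (duplicated draws concentrate
X near its mean, so p ≈ 0.5–0.7); only the all-hit and no-hit boundaries
are degenerate.

## Count-matrix machinery

Features are the merged union of peak sets; reads are single positions
counted into the half-open feature that contains them (features are
disjoint after merging, so each read lands at most once). RPKM is
`x · 10⁹ / (L · N)`. Quantile normalization maps each column onto the
reference distribution of row means of the column-sorted matrix; tied
values within a column receive the mean of the reference values their tied
ranks span (the behaviour of limma's `normalizeQuantiles`). With ties
present the columns therefore do not share an exactly identical multiset —
the idealised multiset identity holds exactly only for tie-free columns.

Samples are compared by Pearson correlation over all features (a top-N
variance filter is available but off by default); zero-variance samples
yield flagged undefined entries rather than silent zeros. Clustering is
agglomerative with average linkage on `d = 1 − r`; samples are sorted
lexicographically before linkage so that equal-distance merges break ties
deterministically by label, making results invariant to input column order.

## Differential expression

The default statistic is a moderated t on `log2(x + 1)`: per-gene pooled
variances `s²_g` (df = nₐ + n_b − 2) are shrunk toward the across-gene mean
variance `s²₀` with a fixed prior weight d₀ = 10,
`s²* = (d₀ s²₀ + df · s²_g) / (d₀ + df)`, and the statistic is referred to
t with df + d₀ degrees of freedom. At the 3–4 replicates per group typical
of these designs, an unmoderated Welch t has ~6 degrees of freedom, so its
attainable p-values (~10⁻³) sit at the BH rejection boundary whenever true
effects are ~10% of genes; variance moderation is the standard remedy and
restores near-complete recovery of 4-fold effects at q ≤ 0.05 while
remaining clean on null data. The unmoderated `welch_t` is provided through
the pluggable `stat_fn` hook for sensitivity analyses. Fold changes are
mean differences on the log2(x + 1) scale; BH adjustment runs across all
tested genes; genes with zero variance in both groups report p = 1.

The repression comparison labels each shared regulated gene by which
condition affects it more strongly: among repressed genes (joint direction
negative) condition A is stronger iff `lfc_A < lfc_B − δ`, symmetric for
induced genes, with ties inside the δ band (default 0.25 log2 units — the
smallest margin that makes the asymmetry computable without crediting
replicate noise). Signatures are the top-N genes by |statistic| with
deterministic tie-breaks (|lfc|, then gene id), each gene carrying the sign
of its fold change; top-|statistic| was chosen as the extraction rule
because it is the quantity the contrast actually ranks — the alternative
(cluster loadings) is not well-defined for a two-group contrast.

## Interactome

Spectral counts (MS/MS spectra per protein per run) proxy abundance.
Background filtering retains a protein iff
`max(avgA, avgB) ≥ fold_min · mean IgG` and `≥ count_min` (defaults 2.0 and
2), an explicit stand-in for the common "enriched over IgG" rule; removed
proteins are labelled, never dropped. The spectral index
`SI = (avgA − avgB)/(avgA + avgB)` is bounded in [−1, 1], antisymmetric
under bait swap and invariant to count rescaling; ±1 means bait-exclusive
recovery. Classification thresholds at |SI| ≥ 0.33 (A- or B-preferential,
else shared) — one-third is the conventional "twice as much in one bait"
point: SI = 1/3 ⟺ avgA = 2·avgB. With two replicates per bait no
variance-based test is meaningful, so the module reports point estimates
only. Upstream identification confidence is modelled as a boolean pass flag
per protein; failing rows never reach the index.

## Survival

Patients are scored by the signed mean z-score of the signature genes
(each gene z-scored across patients, multiplied by its +1/−1 direction,
averaged; zero-variance genes excluded with a warning). The cohort is cut
at the 25th/75th score percentiles (linear-interpolation quantiles);
patients strictly above/below form the high/low groups and the middle half
is excluded, reading "upper and lower quartiles" literally as a two-group
comparison. Kaplan–Meier uses the product-limit estimator with events
processed before censorings at tied times; the log-rank test accumulates
observed minus expected deaths in one group under the hypergeometric model
at each distinct event time (tied events pooled), with
`χ² = (ΣO − ΣE)²/ΣV` on 1 df. Both are implemented from first principles —
they are the analytical core of this stage — and are cross-checked against
an independent survival library in the test suite.

## Synthetic data

One global seed drives everything; per-stage child seeds derive
deterministically from it by stage index, so a fixed seed gives
byte-identical outputs. Counts are negative binomial parameterized by
(mean m, dispersion d) with variance `m + d·m²` via gamma–Poisson mixing;
d = 0.1 is a typical bulk RNA/ChIP overdispersion. Defaults per generator:

- **Genome** — uniform-random A/C/G/T chromosomes; no GC bias or
  mappability structure.
- **Cistromes** — fixed-width sites (200 bp) placed ≥ 2× width apart on a
  slot grid, so planted Venn triples and retained/lost/gained counts are
  recovered *exactly*, making overlap recovery a sharp test. Demo scale
  (50/100/75 sites, 500 remodeling sites at retained fraction 0.3) keeps
  runs in seconds while exercising every code path.
- **Reads** — single-position reads: negative-binomial counts per true site
  (demo mean 50) over a uniform background (0.05 reads/kb); per-track
  totals are recorded as library sizes. No fragments, pairing or sequence
  content — the counting step only needs positions.
- **Expression** — log-normal baseline means (median 100, log-sd 1) with
  condition-specific log2 effects; the two-group design (2000 genes, 200
  regulated at |lfc| = 2, 4 samples/group) is the clustering benchmark, and
  the vehicle/isoform-A/isoform-B design (500 regulated genes, strong
  effect −2.5 vs weak −1.0, A stronger with probability 0.8) plants the
  repression asymmetry.
- **Spectral tables** — Poisson counts: preferential proteins at
  `mean_count` (30) in their bait and `igg_mean` (1) elsewhere; shared in
  both baits; background-only everywhere at `igg_mean`; IgG runs always at
  `igg_mean`; two replicates per bait.
- **Cohorts** — per-patient score s ~ N(0,1); signature-gene expression
  scales linearly with s (relative amplitude 0.2) plus per-gene noise
  controlled by a `noise_sd` multiplier (default 1.0, i.e. per-gene noise
  equal in magnitude to the signal term — exposed as a knob because real
  tumor heterogeneity is not identifiable from the published analyses);
  event times are exponential with hazard `h₀·exp(β·s)` and censoring
  exponential at `censor_rate` (defaults 0.1 and 0.04 give ~30% censoring).

What passing tests show — and do not. Recovery at zero or planted noise
demonstrates the *operations* are correct and calibrated; it does not show
that real cistromes (variable peak widths, clustered binding), real
transcriptomes (correlated genes, batch effects), real proteomes (shared
peptides, protein inference) or real cohorts (non-proportional hazards,
informative censoring) would behave as cleanly. The simulator deliberately
omits those complications.

## Numerical and degenerate-input conventions

Quantile cuts use linear interpolation between order statistics; boundary-
equal scores go to the excluded middle. All-identical scores, empty pre
cistromes, zero library sizes, zero-variance correlation inputs and absent
IgG runs raise explicit errors or flagged records rather than silent
coercions. P-values are floored at the smallest positive double rather than
reported as 0. The pipeline writes per-stage wall-clock to a separate
timings file so the run manifest (config hash, seed, file digests) is
byte-identical across reruns.

## Known limitations

The motif stage is an intentionally simplified scanner/enrichment pair, not
a replacement for dedicated motif tools; its numbers are not comparable to
figure-level motif analyses produced by unstated tools. The DE engine is a
two-group location test on transformed values, not a count GLM; it is the
feed for the downstream comparisons, not a DESeq substitute for production
DE calling. Problem sizes in the demo config and acceptance script (10²–10³
sites, 2×10³ genes, 300–400 proteins/patients, ≤400 replicates per
calibration) were chosen so a full verification pass completes in seconds
on one core while keeping every statistical check well-powered.
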