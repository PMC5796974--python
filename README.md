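# hormonesig

Integrative downstream analysis of hormone-receptor genomics: how a second
nuclear receptor (for example the two progesterone-receptor isoforms PRA and
PRB, or a PR ligand class) reprograms estrogen-receptor signaling. The
package implements the full analytical chain a study of this kind needs
**after** alignment, peak calling and protein identification:

- **Cistrome comparison** — BED interval algebra: merge, the symmetric Venn
  partition of two binding-site sets counted on the merged union, and
  quantification of binding-site remodeling (retained / lost / gained sites,
  percent inhibition) between a pre- and post-treatment cistrome.
- **Motif enrichment** — PWM log-odds scanning of interval sequences on both
  strands and upper-tail hypergeometric enrichment of foreground vs
  background interval sets.
- **Matrix machinery** — union-of-peaks features, read counting, RPKM
  (`x · 10⁹ / (L · N)` for feature length `L` bp and library size `N`),
  quantile normalization, sample–sample Pearson correlation and average-
  linkage hierarchical clustering on distance `1 − r`.
- **Differential expression** — a moderated t on `log2(x + 1)` with BH
  adjustment, comparison of which condition represses each shared target
  more strongly, and top-N gene-signature extraction.
- **Interactome comparison** — two-bait spectral-count processing with IgG
  background filtering and the spectral index
  `SI = (avgA − avgB) / (avgA + avgB) ∈ [−1, 1]`, classifying each protein
  as A-preferential, B-preferential, shared, or filtered.
- **Survival stratification** — signed mean z-score signature scoring,
  upper-vs-lower-quartile patient stratification, Kaplan–Meier product-limit
  curves `S(t) = Π (1 − dᵢ/nᵢ)` and a from-scratch two-group log-rank test
  `χ² = (ΣO − ΣE)² / ΣV`.
- **Synthetic data** — generators for every input above with planted ground
  truth (exact Venn triples, planted percent inhibition, group structure,
  repression asymmetry, protein preference classes, a score→hazard link),
  so each stage can be tested for exact or statistical recovery.

Public studies in this area often deposit no raw accessions, so the
simulator is a first-class component: it defines the conditions under which
the pipeline's claims are verified.

## Worked example

Run the full demo pipeline (simulate → cistrome → motif → cluster → DE →
interactome → survival) twice from one seed:

```sh
hormonesig all --seed 1 --outdir demo
```

Selected outputs from `demo/` (seed 1):

```text
overlap_summary.json      {"n_common": 50, "n_unique_a": 100, "n_unique_b": 75}
remodeling_summary.json   {"n_pre": 500, "n_retained": 150, "n_lost": 350,
                           "n_gained": 0, "percent_inhibition": 70.0}
repression_comparison.json {"n_a_stronger": 388, "n_b_stronger": 115, "n_tied": 3}
survival_report.json      {"log_rank": {"chi2": 95.449, "df": 1,
                           "p_value": 1.52e-22}, "n_high": 75, "n_low": 75}
motif_enrichment.json     {"n_fg_hit": 98, "n_fg": 150, "n_bg_hit": 2,
                           "n_bg": 200, "neg_log10_p": 44.44}
```

Reading these: the two simulated cistromes share exactly the 50 planted
common sites beside 100 and 75 unique ones; the remodeled binding-site set
retains 150 of 500 sites with no gains, i.e. 70% inhibition; isoform A is
the stronger repressor for 388 of the shared regulated genes versus 115 for
isoform B (planted asymmetry 0.8); the signature-high patient quartile has
far worse survival than the signature-low quartile (log-rank χ² = 95.4,
p ≈ 10⁻²²), matching the planted positive log hazard ratio; and the motif
planted into binding sites is strongly enriched over matched background
intervals. `run_manifest.json` records SHA-256 digests of every artifact
and is byte-identical across reruns of the same config and seed.

The same operations are available as a library:

```python
from hormonesig.intervals import read_bed, intersect
summary = intersect(read_bed("a.bed"), read_bed("b.bed"))
print(summary.n_common, summary.n_unique_a, summary.n_unique_b)
```

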