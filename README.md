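# panelcnv

Read-depth CNV surveillance for targeted gene-panel sequencing.

Clinical gene panels capture only the protein-coding exons (±50 bp) of the
genes they test, so the breakpoints of copy-number variants — which usually
fall deep in introns or outside the genes entirely — are never sequenced.
The only CNV signal available is *read depth*: a heterozygous deletion halves
the expected number of deduplicated reads over the affected exons, a
duplication raises it by half, and a 4-copy event doubles it. `panelcnv`
implements a complete surveillance workflow over per-exon read-count matrices
of the kind produced by diagnostic panel services (the motivating application
is inherited retinal dystrophy testing, where such a workflow raises the
diagnostic yield of a first-tier test by several percent):

* **Coverage QC** — counts-per-million normalization, insufficient-coverage
  flags (< 50 deduplicated reads), cohort-wide consistently-poor exons, and
  the per-exon intersample coefficient of variation (CV) across the selected
  reference samples, the main covariate of calling accuracy.
* **Caller A: aggregated-reference beta-binomial HMM.** For test sample $t$
  with count $x_e$ at exon $e$ and an aggregated reference count $r_e$
  (element-wise sum over reference samples ranked by correlation of
  normalized coverage), the emission is
  $x_e \mid n_e \sim \mathrm{BetaBin}(n_e,\, p_c,\, \varphi)$ with
  $n_e = x_e + r_e$, expected test fraction
  $p_c = \tfrac{c}{2}\,\omega / (\tfrac{c}{2}\,\omega + 1)$,
  $\omega$ the test/reference odds, copy-number states $c \in \{1,2,3\}$,
  and a per-sample maximum-likelihood overdispersion $\varphi$ ($\varphi = 0$
  is exactly binomial). A three-state Markov chain along the panel (CNV entry
  probability $10^{-4}$ per exon) is decoded by Viterbi; each call carries a
  log₁₀ Bayes factor against the all-normal path.
* **Caller B: control-matched ratio/z-score engine** — an independent
  statistic (ratio to the mean of the k = 10 best-matching controls, z
  against the control-ratio spread) filling the "second algorithm" role.
* **Three-stage consensus filter** — (1) events must be called against each
  of **three disjoint reference sets** of 30 samples matched on gender and
  enrichment kit (span = intersection); (2) corroborated by ≥ 1 other
  algorithm (same type, ≥ 1 shared exon); (3) pass a codified inspection:
  ratio consistency across the span, reference-set variability, cohort-wide
  recurrence of the signal, and continuity of abnormal exons.
* **Interpretation** — copy number/zygosity from the read ratio (bins at
  0.15/0.75/1.25/1.75 around the expected CN/2 ratios), HGVS-style
  uncertain-breakpoint cDNA names such as `c.(100+1_101-1)_(250+1_251-1)del`,
  carrier counts against external (WGS-style) call sets using a ≥ 50 %
  one-directional overlap rule, positive predictive value and per-individual
  diagnostic yield.
* **Synthetic cohorts** — a seeded generator of panel cohorts (negative-
  binomial counts with log-normal exon baselines, per-sample size factors and
  per-exon dispersion heterogeneity; spiked CNVs from single-exon to
  multi-gene scale with CN ∈ {0,1,3,4}) plus external-style call sets, so
  every stage is testable against ground truth.

## Worked example

Simulate a 120-sample cohort with 20 spiked CNVs, run the full pipeline, and
summarise the reporting arithmetic:

```bash
python analysis/03_call_and_filter.py
python analysis/05_interpret_and_report.py
```

prints

```
null cohort funnel: 78 candidates -> 35 (triple) -> 9 (cross-algorithm) -> 4 (inspection)
spiked cohort: sensitivity 0.90 overall, 0.93 for het deletions; mean het-del ratio 0.527
PPV of the filter chain: 79% (44/56); expanded set 65.2% (45/69)
diagnostic yield: 4.5% of 550; incidental confirmed CNVs: 3.3%; any confirmed CNV: 7.8%
confirmed events: 33 deletions, 11 duplications
```

The null-cohort funnel shows what the three filters are for: on 200 samples
with *no* real CNVs the caller still proposes 78 candidate events (about one
per 2–3 samples — the false-positive burden of read-depth calling on capture
data), and the filter chain removes 95 % of them. On the spiked cohort,
heterozygous deletions are recovered with 93 % sensitivity at an observed
ratio of ≈ 0.5, and recovered 4-copy duplications are assigned CN 4. The
PPV and yield figures are arithmetic over the packaged confirmation-outcome
table (`src/panelcnv/data/confirmed_events.tsv`): 44 of the 56
filter-selected events were wet-lab confirmed (79 %), and confirmed CNVs
contribute to a molecular diagnosis in 4.5 % of 550 referred individuals.

The same workflow is scriptable through the CLI
(`panelcnv simulate|qc|call|filter|run|report --config cfg.yaml --out DIR`).

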