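# Methods

## Data model and coordinate conventions

The pipeline's sole sequencing-derived input is a matrix of deduplicated read
counts, exons × samples, one matrix per enrichment-kit version (panel
versions are disjoint exon sets and are never mixed). Exons carry gene,
transcript and within-transcript ordinal annotations; internal coordinates
are 0-based half-open (BED), every human-facing report is 1-based inclusive.
Counts are exon-level; where a metric is defined at nucleotide resolution in
clinical practice (coverage sufficiency), the exon count stands proxy for the
exon's minimum per-base depth — a documented granularity limit of this input
format.

## Caller A: aggregated-reference beta-binomial HMM

**Reference aggregation.** Candidate reference samples are ranked by Pearson
correlation of counts-per-million coverage with the test sample. Prefix sets
of the ranking are scored with a precision proxy — the sample variance of the
per-exon fraction x_e/(x_e + r_e) under the aggregated (summed) reference —
and the best prefix is kept, resolving ties toward more samples, capped at 30.
The proxy directly measures how tightly the observed test fraction
concentrates, which is what the emission model sees; published callers in
this family use an expected-power heuristic whose exact form is not public,
so this operationalisation is the package's own. A pool containing a single
candidate is used but flagged (solitary reference); downstream accounting
excludes that sample's exon cells from CV analysis.

**Emission.** With n_e = x_e + r_e and test/reference odds ω estimated from
column totals, the expected test fraction under copy number c is
p_c = (c/2)ω / ((c/2)ω + 1). The emission is beta-binomial with mean p_c and
intraclass correlation φ, parameterised a = p(1/φ − 1), b = (1−p)(1/φ − 1);
the φ → 0 branch calls the binomial pmf directly, so φ = 0 is *exactly*
binomial (oracle-tested to 1e-9). φ is fitted per (sample, reference) pair by
bounded maximum likelihood on log φ over non-CNV exons: the fit runs twice,
first over all exons, then excluding any decoded CNV spans, because a real
multi-exon event otherwise inflates φ and suppresses its own Bayes factor.
A single-exon panel cannot self-calibrate ω (the totals are the observation);
callers may supply the expected fraction explicitly.

**Chain and decoding.** States CN {1, 2, 3}; per-exon CNV entry probability
10⁻⁴ (a prior of roughly one event per 10⁴ exons, making single-exon events
callable at depth ≥ 500 with φ ≤ 0.01), exit probability 0.5 (expected event
length two exons — panel CNV spans are short), no direct del↔dup transition.
Chromosome boundaries reset the chain to its initial distribution, so calls
never span chromosomes. Viterbi decoding; maximal runs of non-normal states
become calls. Confidence is the log₁₀ likelihood ratio of the decoded path
*isolated to the call's span* (normal elsewhere) against the all-normal path,
which equals the plain path ratio when a chromosome carries one call and is
well-defined when it carries several. CN 0 and CN 4 are deliberately not
decoding states: the read ratio, not the path, is the zygosity evidence, so
extreme copy numbers are assigned afterwards from the ratio. A decoded CNV
whose mean span ratio contradicts its side (a del run with ratio ≥ 1) is
discarded as noise.

## Caller B: control-matched ratio/z-score

Per exon, the test's counts-per-million value is divided by the mean of its
k = 10 best-matching controls (smallest total absolute normalized
difference). z is the ratio's deviation from 1 over the spread (ddof = 1) of
the control ratios around their own mean. An exon is abnormal iff the ratio
leaves [0.75, 1.25] *and* |z| ≥ 3; maximal same-side runs merge into calls
with peak |z| as confidence. Degenerate guards: zero control spread with
ratio exactly 1 is normal; a zero control mean is treated as uninformative.
The two callers share no statistical machinery, which is the point of the
cross-algorithm filter.

## Consensus filtering

Stage 1 (triple reference sets): per test sample, three *disjoint* reference
sets of exactly 30 samples matched on gender and panel version are drawn
uniformly without replacement; an insufficient matched pool is a hard error
(sets are never silently shrunk). The draw is seeded by the global seed plus
a CRC32 hash of the sample id, so one sample's sets are independent of which
other samples are analysed. An event survives only if all three runs call it
with the same type and ≥ 1 shared exon — unanimity, not majority — and the
surviving span is the *intersection* of the three spans (the conservative
choice; pairwise overlap with the seeding call guarantees non-emptiness).
Merged ratio and confidence are the medians of the three.

Stage 2 (cross-algorithm): ≥ 1 independent call list must contain a call of
the same type sharing ≥ 1 exon. The ≥ 1-shared-exon rule in both stages is
the interval-intersection default (≥ 1 bp) expressed at the panel's calling
resolution.

Stage 3 (codified inspection) computes four features an analyst would read
off a ratio plot, with config-exposed thresholds:

| feature | definition | default threshold |
|---|---|---|
| ratio consistency | SD (ddof = 1) of per-exon test/reference ratios in the span | ≤ 0.15 |
| reference variability | max per-exon CV (%) over the selected reference samples | ≤ 15 % |
| cohort recurrence | fraction of other samples whose mean span ratio leaves [0.75, 1.25] | ≤ 0.10 |
| continuity | longest same-side abnormal run / span length | ≥ 1.0 |

The verdict is pass iff all four hold; raw features are retained for manual
review. These thresholds operationalise an inherently subjective visual step;
they are an automation of its criteria, not a reconstruction of any
particular analyst's judgement.

## QC metrics and accounting

Normalization is counts-per-million (any positive constant gives identical
CVs by scale invariance, so the constant is cosmetic). Insufficiency is a
strict `count < 50`. "Consistently poor" is flagged in ≥ 90 % of cohort
samples — the fraction is a design choice, config-exposed. The intersample CV
uses the sample (n − 1) standard deviation (material at reference-set size
30); a constant set reports exactly 0 (guarding the ~1e-14 round-off of
floating-point means), a zero-mean exon reports NaN and routes to exclusion,
and a one-sample set raises a solitary-reference signal counted separately.
The accounting identity excluded_solitary + excluded_poor + analysed = total
is enforced, never assumed.

Spike-in accuracy: each replicate thins one (sample, exon) cell binomially to
copy number 1 (or the requested CN; CN = 2 is the null spike whose
"detection" rate is the caller's per-replicate false-positive rate), re-calls
the sample against the remaining cohort, and scores a detection when a call
of the spiked type covers the spiked exon, stratified by the exon's
intersample CV over the rest of the cohort.

## Interpretation

Ratio → copy-number bins: [0, 0.15) → CN 0, [0.15, 0.75) → CN 1,
[0.75, 1.25) → CN 2, [1.25, 1.75) → CN 3, ≥ 1.75 → CN 4, symmetric around
the expected CN/2 ratios (0, 0.5, 1, 1.5, 2) and config-exposed; the bins
partition [0, ∞). A call whose type contradicts its ratio bin raises an
inconsistency (the pipeline keeps the decoded CN and marks zygosity
unresolved rather than dropping a surviving event).

HGVS-style names use the uncertain-breakpoint convention — exon-level calling
never knows breakpoints: whole-transcript events are `c.(?_-1)_(*1_?)del|dup`;
internal events flank the span with the last cDNA position of the preceding
exon and the first of the following exon, `c.(a+1_b-1)_(c+1_d-1)`. Multi-gene
events emit one name per implicated transcript. The emitted grammar is
round-trip parseable (oracle-tested). cDNA maps are built from captured-exon
lengths; with real annotation they would come from the transcript's CDS.

Frequency annotation counts a cohort sample as a carrier iff any of its
same-type calls covers ≥ 50 % of the *panel event's* length (one-directional,
base pairs — whether such comparisons should use exon counts instead is
ambiguous in clinical practice; base pairs are assumed). PPV is
100 × confirmed/tested with decimal half-up rounding at the requested printed
precision (78.571 → 79; 65.217 → 65.2); raw values are always retained.
Cohort yields de-duplicate individuals, with diagnosis-contributing events
taking precedence. ACMG classifications are carried as input labels only:
the evidence they require lives outside this data model.

## Synthetic cohorts: what they emulate, and what they do not

count(e, s) ~ NB(mean = λ_e · f_s · CN/2, Var = m + α_e m²) with

| parameter | default | rationale |
|---|---|---|
| exon baseline median | 1579 reads | production panel service scale |
| exon baseline log-sd | 0.91 | gives mean ≈ 2389 with a long right tail |
| sample size-factor log-sd | 0.15 | typical library-size spread |
| mean dispersion α | 0.0025 | reference-set CV ≈ 5–6 % at this depth |
| exon dispersion log-sd | 1.5 | capture efficiency varies strongly by target |
| CN = 0 dropout floor | 0.01 | residual mis-mapping/contamination signal |
| spike placement depth | λ ≥ 500 | events are placed on callable exons |

Per-exon dispersion heterogeneity is essential, not cosmetic: with a uniform
α the fitted beta-binomial absorbs the overdispersion completely and the
caller produces *no* false candidates, which contradicts how read-depth
calling behaves on real capture data (on the order of one candidate per three
samples before filtering). With the default log-sd of 1.5 the 200-sample null
cohort yields ≈ 0.4 candidates per sample, the scale observed in production.

Deliberately not modelled: GC-bias curves, per-base coverage shape, chrX
dosage (gender is matching metadata only), relatedness, batch drift within a
panel version, and read-level artefacts. Passing tests therefore demonstrate
the statistical machinery under realistic count noise — not robustness to
alignment or capture artefacts, which only real data can show.

The accuracy-curve cohort uses three dispersion strata (α = 5e-4, 3e-3,
2.5e-2) chosen to land in distinct intersample-CV bins (≈ 3.5 %, 6 %, 16 %)
at panel-typical depth, so the accuracy-vs-CV relationship is identifiable;
the top stratum is kept mild enough that it does not poison the globally
fitted φ for clean exons.

## Problem sizes and numerical choices

Monte-Carlo sizes are chosen for stable estimates at desk scale: the
recovery cohort is 120 samples × 300 exons with 20 spiked events (binomial
SE on a 0.93 sensitivity at n = 15 het deletions ≈ 0.06); the null cohort is
200 samples; the accuracy curve uses 500 replicates (per-bin SE ≤ 3 %);
Viterbi-vs-enumeration equivalence is checked on 1000 random instances of up
to 8 exons (3⁸ paths each). The dispersion MLE is bounded on
log φ ∈ [log 1e-8, log 0.5] with an explicit φ = 0 comparison, so the
binomial limit is reachable exactly. Monotone funnel behaviour, reference-set
invariants and ratio-bin partition are property-tested over random instances.

## Known limitations

* Caller A is a reconstruction of the aggregated-reference beta-binomial HMM
  family at documented-behaviour level; numeric equality with any specific
  published implementation is a non-goal, and "standard parameters" of such
  tools are declared in this package's config rather than asserted
  equivalent.
* The funnel's absolute counts depend on the synthetic noise model; only
  their ordering and ratios are meaningful for comparison with production
  figures.
* Confirmation outcomes (and hence PPV/yield) are inputs: the wet-lab assays
  they summarise are outside the package's scope.
* Duplications are recovered less reliably than deletions (the ratio signal
  is 1.5× against 0.5×), mirroring the known read-depth asymmetry; the
  4-copy assignment is only evaluated on recovered events.
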