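# Methods

## Scope and data model

The package post-processes *segmented* tumor copy-number profiles; it does
not segment read depth itself (that is the job of an upstream caller whose
`.cns`-style output is the input contract here). Internally every interval
is 0-based half-open; SEG-dialect files on disk are 1-based inclusive, and
the two conversions are exact inverses. The chromosome universe defaults to
the 22 GRCh37 autosomes; sex chromosomes are excluded from every
percent-of-genome denominator because allele-dosage conventions differ
there and the GI parameters are meant to be comparable across a mixed-sex
panel design. Chromosome sizes ship as a configurable two-column table, not
a hard-coded build.

## Copy-number events

Per segment, the observed ratio is modeled as a two-component mixture of
tumor (fraction *p*, copy number *n_t*) and diploid normal:
`r = p·n_t/2 + (1 − p)`. Inverting gives the purity-adjusted copy number,
clamped at zero. Purity is an input (however it was estimated upstream);
at *p* = 1 the adjustment reduces to `2·2^log2`.

Calling order is fixed and matters:

1. **Significance filter** — segments with a present p-value above 0.001
   are dropped. Segments *without* a p-value pass: absence of an upstream
   statistic should not silently delete data.
2. **Classification** — gain at adjusted CN ≥ 2.5, loss at ≤ 1.5
   (half-integer midpoints between diploid and a single-copy change;
   configurable).
3. **Merge** — adjacent same-state events separated by at most the merge
   gap (default 0, i.e. touching) fuse, with length-weighted CN and BAF.
4. **Artifact filter** — events shorter than 1 Mb are removed. Merging
   precedes this filter deliberately: sub-megabase fragments of one
   biological event are segmentation artifacts, and filtering first would
   delete real events piecewise.

The BAF "borderline" filter removes events whose mean BAF lies strictly
inside the open interval (0.3, 0.7): such events look allelically balanced
and are demoted to a separate, filtered parameter tier. The bounds are
exclusive so that a BAF of exactly 0.3 still counts as imbalanced. Events
lacking a BAF are kept (exempt, not dropped).

## LOH

Constitutively heterozygous positions come from a small panel of normals
(default 5): a SNP enters the mask when no control genotype is missing and
at least 3 of 5 controls are heterozygous (a majority rule buffering
per-control genotyping noise). LOH is evaluated on the copy-number
segmentation's own intervals — the simplest construction consistent with
the input provenance — and chromosome spans not covered by any segment are
tiled at 10 Mb so copy-neutral LOH in segment-free regions stays
detectable.

Per interval, tumor BAFs at masked SNPs are **folded** onto the upper half
(0.5 + |b − 0.5|) before the median is taken. Folding is essential: which
allele an imbalance favors is arbitrary per SNP, so in a real LOH tract
half the BAFs sit near 0 and half near 1, and a raw median would hover
uninformatively near 0.5. The interval is called LOH when it holds at
least 10 informative SNPs and the folded median exceeds the upper band
bound (0.7); for a one-sided shift this is equivalent to "median BAF
outside the open (0.3, 0.7) band". The median (not the mean) is used for
robustness to the minority of tumor-homozygous sites inside the mask.
Adjacent called intervals merge and the same 1 Mb artifact filter applies.
Long-LOH features use *strict* span thresholds (>10 Mb, >15 Mb), so the
15 Mb tier is a subset of the 10 Mb tier by construction.

Purity limits the method: a pure-LOH tract diluted to purity 0.4 has
expected BAF 0.625 and is invisible to the band — this is a property of
the band definition, not a bug, and is pinned by a test.

## GI parameter vector

25 named, non-negative parameters per sample: count / mean length / summed
length / percent of autosomal genome for all events; the same four on the
BAF-filtered tier; count/length/percent for gains and for BAF-filtered
gains; count/length/percent for losses; LOH length and percent; and
count/length/percent for LOH >15 Mb and >10 Mb. Which three of the loss
statistics belonged to the original 24-parameter panel is ambiguous in the
source material, so all are emitted under stable column names. Mean event
length is defined as 0 when there are no events, keeping vectors total and
sortable. Percentages use the configured genome's autosomal length — not a
covered/callable length — so identical event sets score identically across
samples.

Cohort categorization: median scheme labels low/high with ties at the cut
going low; the quartile scheme uses linear interpolation between order
statistics (the convention is configuration because group membership near
a cut depends on it). Constant parameters degenerate to a single bin with
a logged warning.

## Mutational HRD

A variant qualifies at coverage ≥ 100× and VAF strictly above 5% when it is
P/LP, or a VUS with an upstream pathogenic-prediction flag, or a VUS with
*both* SIFT and PolyPhen pathogenic. HRD is any qualifying variant in the
configured HRR gene set — the 35-gene panel minus TP53, the MMR genes
(MLH1/MSH2/MSH6/PMS2), the CN-only targets CCNE1/EMSY, and PTEN. The set is
configuration, not code, and is echoed in reports. Gene-level CN calls use
the length-weighted mean adjusted CN over a gene's BED interval
(amplified ≥ 5, deleted ≤ 1), with a "no data" flag when nothing overlaps.

## Clinical statistics

ORR groups CR/PR against SD/PD; CBR adds SD lasting strictly more than
6 months to the positive side (exactly 6 months is negative); LTR is PFS at
least twice the cohort's median PFS, inclusive at the boundary, with the
option to pin the median (e.g. 4.54 months) instead of re-estimating it.
NE (not evaluable) patients stay in intention-to-treat denominators for
rates but drop out of two-group comparisons.

Rates carry exact Clopper–Pearson 95% CIs (beta-quantile construction, via
`scipy.stats.binomtest`). Two-group comparisons use the Wilcoxon rank-sum
test: the exact null distribution for tie-free samples with combined
n ≤ 12, otherwise the normal approximation with tie and continuity
corrections (`scipy.stats.mannwhitneyu` supplies both branches; an
independent full-enumeration oracle checks the exact branch in the tests).
Full enumeration shows the two branches differ by at most 0.0155 in
two-sided p at n1 = n2 = 6, which bounds the approximation error a user
inherits near the switch point. Effect sizes are Cohen's *d* with the
(n1−1, n2−1)-weighted pooled SD; a zero pooled SD yields a missing value
with a warning, not a crash.

Survival uses the Kaplan–Meier product-limit estimate (lifelines). The
median is read off the curve as the earliest time survival reaches 0.5 or
below, with a Greenwood-based (log-log) CI; the two-group log-rank test is
the standard 1-df chi-square with hypergeometric variance.

The association scan crosses every GI parameter with every grouping,
reporting group sizes, medians, the rank-sum statistic and raw p, Cohen's
*d* and its direction, plus Benjamini–Hochberg adjusted p in a separate
column — adjusted values are reported alongside, never instead of, the raw
ones. Pairs with fewer than 2 samples in either group, or constant values,
are skipped with a log entry.

## Synthetic cohorts

The generator emulates the pipeline's input shapes on a 1/10-scale
autosomal genome (~288 Mb) with one SNP per 20 kb (~14,400 sites, a tenth
of a full-size ~147k backbone) — small enough that a 200-patient cohort
simulates and scores in seconds on one core, large enough that every
segment holds ample informative SNPs. Per patient: a latent instability
level θ ~ Uniform(0,1); event count ~ Poisson(2 + 18·θ); event lengths
log-normal (median 8 Mb, σ_log 0.8, capped at 40 Mb); event types gain
0.4 / loss 0.4 / copy-neutral LOH 0.2 with allele copies (2,1), (1,0),
(2,0); purity ~ Uniform(0.3, 0.9). Events are placed uniformly without
overlap (rejection sampling with a 100 kb minimum gap; unplaceable events
are skipped and the realized list is the recorded truth; genuinely
impossible requests raise). Log2 ratios and segment/SNP BAFs follow the
same two-component mixture the caller inverts — making recovery tests
self-consistent — with Gaussian noise (sd 0.05 on log2, 0.03 on BAF) and
random mirroring of het BAFs.

The control panel is cohort-level: one backbone genotyped once (het
probability 0.4 per control per SNP), shared by all tumors. Tumors are
heterozygous at constitutively-het sites with probability 0.9 — the
backbone stands in for a design enriched for high-heterozygosity markers —
which leaves a 10% homozygous minority the folded-median statistic must
(and does) tolerate.

Clinical links: with z the standardized engineered event count,
P(response) = expit(−2.2 + 1.0·z); PFS is exponential with log hazard
log(1/4.5) − 0.5·z and uniform censoring on (0, 24) months; OS is
exponential with a 15-month median at z = 0 and a weaker link (0.3);
6.8% of patients are relabeled NE. HRR-variant probability is logistic in
θ (expit(−2.5 + 2θ), ≈17% mid-range), with decoy variants that fail the
coverage/VAF gates or the two-predictor VUS rule so the filters are
actually exercised. Effect sizes are set so group differences are
detectable at n ≈ 40–60 without being trivial.

What the generator does **not** emulate: subclonal heterogeneity (one
purity per sample), GC/wave artifacts in log2, linkage between SNPs,
germline CNVs, panel-specific capture bias, and correlated missingness.
Passing recovery and calibration tests therefore shows the pipeline is
internally consistent and correctly calibrated under its own generative
assumptions — not that it is robust to every artifact of real FFPE panel
data.

## Validation suite and problem sizes

* Oracle equivalence: GI vectors against a per-basepair brute-force tally
  (100 random event sets on ≤1 Mb toy genomes); the exact rank-sum branch
  against full enumeration of every tie-free configuration with combined
  n ≤ 8; Clopper–Pearson bounds against direct beta quantiles.
* Parameter recovery: at the reference conditions (n = 200), the Spearman
  correlation between θ and the recovered event count must exceed 0.6;
  at purity 1 with zero noise, called spans and copy numbers equal the
  engineered ones exactly.
* Null calibration: with the response and PFS links switched off
  (β1 = γ1 = 0), raw scan p values over 200 replicate cohorts of n = 50
  pass a Kolmogorov–Smirnov uniformity test at α = 0.01. These replicates
  run with the SNP layer disabled, so the calibration statement covers the
  copy-number-derived parameters; LOH columns are constant zero there and
  are skipped as degenerate.
* Monotonicity: the >15 Mb LOH tier is nested in the >10 Mb tier on 1,000
  random LOH sets; BAF filtering never increases any parameter.

## Known limitations

* The LOH band is purity-blind: below ≈0.55 purity a full LOH tract falls
  inside (0.3, 0.7) and is missed. A purity-aware band is deliberately out
  of scope because the reference procedure uses a fixed band.
* LOH inherits the CN segmentation's breakpoints (plus 10 Mb tiles);
  an imbalance confined to part of one long segment dilutes the median and
  can be missed.
* Whether "event count" should be counted pre- or post-merge is exposed via
  the `merge` flag rather than decided; defaults merge.
* Allele-specific copy number (major/minor counts) is not inferred; the
  pipeline reports allelic imbalance, not its copy-number mechanism.
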