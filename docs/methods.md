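# Methods

## Metrics

**VAF.** For dPCR, `VAF = 100 · FAM/(FAM + VIC)` where FAM and VIC are the
mutant and wild-type copy concentrations (copies/µL); undefined when both
are zero (no template). For NGS, `VAF = 100 · mutant/total` molecules.
VAF is carried in percent everywhere, including inside the R-score: with
the conventional cohort medians (MAPD 0.28, VAF 1.87%) the percent
convention places the median R-score at −0.82, inside the cutoff range
(−1.25 … 0.25) over which the score is interpreted; the fraction
convention would place it at +1.18, outside that range.

**MAPD.** Per-amplicon log2 ratios are
`x_i = log2((count_i + pseudocount) / baseline)`. The baseline defaults to
the per-sample median of the pseudocounted counts — vendor pipelines use a
proprietary reference baseline, so the per-sample median is this package's
explicit, reproducible choice; a user-supplied per-amplicon baseline
vector (e.g. from a panel of normals) is accepted. The pseudocount
(default 0.5) keeps ratios finite at zero-coverage amplicons rather than
dropping markers. MAPD is the median of `|x_{i+1} − x_i|` over adjacent
pairs, where adjacency holds only between consecutive amplicons on the
same chromosome in coordinate order (genomic adjacency cannot span a
chromosome boundary); the even-count median is the mean of the two central
values. Coordinates are 0-based internally. For iid `N(0, σ²)` log2
ratios the adjacent difference is `N(0, 2σ²)`, so MAPD converges to
`√2 · Φ⁻¹(0.75) · σ ≈ 0.9539 σ`; this closed form anchors both the
generator calibration and a convergence test (5% tolerance at 10,000
amplicons). The review flag triggers on MAPD strictly greater than 0.5
(a run at exactly the threshold passes).

**R-score.** `log10(MAPD / VAF%)`, base 10 throughout (the companion
log-scale constants −0.301 = log10(0.5), 0.272 = log10(1.87) are base-10
values). Undefined — recorded as missing, never imputed — when VAF or
MAPD is non-positive, i.e. for non-detections and degenerate runs.

## Concordance analysis

All agreement statistics run on *paired records*: one per
reference-positive call, concordant iff a detected comparison-platform
call matches on sample and variant. Matching levels: `exact_variant`,
`variant_class`, or the default `auto` — class-level for exon 19 deletions
(a dPCR deletion assay detects the class, not one specific allele), exact
otherwise. Duplicate calls on one platform are an error listing the
duplicates. No negative agreement is computed: every record is
reference-positive by construction.

Each record's R-score is `log10(MAPD / reference VAF)`, using the
comparison run's per-sample MAPD and the *reference* platform's VAF. The
reference VAF is used deliberately: discordant records have no comparison
VAF, yet the concordant-vs-discordant comparisons and the cutoff sweep
require every record to be scored on the same footing, and the two
platforms' VAFs are strongly rank-correlated, making the reference VAF a
faithful proxy. The comparison VAF is carried separately on the record for
the cross-platform correlation. When two NGS platforms are compared, the
MAPD/R-bearing platform is the reference call set by default (its detected
variants carry the scores being evaluated); the direction is a flag.

**PPA** = `100 · c/(c+d)` with a two-sided Clopper–Pearson (default) or
Wald interval via statsmodels. Exact intervals are the default because
small per-quadrant and per-class counts are routine; point estimates, not
CI bounds, are the comparable surface across software.

**Quadrant analysis** splits records by `log10(reference VAF)` and
`log10(MAPD)` at either the data's log-medians (`data_median` mode) or the
technical cuts −0.301/−0.301 (VAF 0.5%, MAPD 0.5). Boundary values go to
the low side (≤). Records missing MAPD are excluded and counted; quadrant
counts partition the eligible set.

**Cutoff sweep.** For each cutoff *t* in the grid (default −1.25, −1,
−0.75, −0.5, −0.25, 0, 0.25), PPA over records with `r_score ≤ t`
(inclusive on the low side). Undefined-R records are excluded and counted;
empty subsets yield an undefined PPA dropped from the correlation. The
cutoff–PPA association is summarized by the signed Spearman rank
correlation with its p-value, undefined (reported as such) when fewer
than three cutoffs have a defined PPA or the PPAs are constant.

**Group tests.** Concordant vs discordant values of VAF, MAPD and R-score
are compared with the two-sided Mann–Whitney U test: exact enumeration for
untied samples with both n ≤ 20, otherwise the tie-corrected normal
approximation with midranks and no continuity correction (so identical
groups give p = 1 exactly). Rank tests are invariant under monotone
transforms, so testing raw or log VAFs is equivalent. No multiple-testing
correction is applied; p-values are reported raw. Cross-platform VAF
agreement is the Spearman correlation over pairs detected by both
platforms (incomplete pairs excluded and counted; ≥ 3 required).

## Synthetic cohorts

The generator emulates a paired-platform EGFR liquid-biopsy series. Per
sample: one driver mutation with class probabilities ex19del 0.553, L858R
0.365, L861Q 0.035, G719A 0.023, S768I 0.012, ex20ins 0.012, plus a T790M
resistance mutation with probability 0.61; driver and T790M VAFs are drawn
independently (no within-sample coupling is modelled) from
`log10-Normal(log10 1.87, 0.55²)` percent. Each comparison-platform run
draws a noise level `σ ~ Gamma(shape 4, scale 0.0799)` — calibrated
through the MAPD ≈ 0.9539σ closed form so the realized median MAPD is
≈ 0.28, with shape 4 spreading run quality over a realistic 0.1–0.6
range — and generates `n_amplicons = 500` counts
`round(1000 · 2^x), x ~ N(0, σ²)` on one synthetic chromosome. MAPD is
then *recomputed from the generated coverage*, not copied from σ, so the
pipeline is exercised end to end.

Detection by the MAPD-bearing platform is Bernoulli with
`P(detect) = 1/(1 + exp(a + b·R))`, `R = log10(realized MAPD / true VAF)`,
defaults a = 0.85, b = 2.0 — a single-index logistic, the simplest model
under which miss probability rises jointly with low VAF and high run
noise; it is a simulation assumption, not a mechanistic claim. The
defaults were fixed once by Monte-Carlo grid search so that overall PPA
≈ 0.66 at large n. Observed VAFs are
`true VAF · 10^N(0, 0.27²)`, floored at the 0.1% limit of detection
(sub-LOD truths are either missed or reported at ≥ LOD); the noise sd 0.27
puts the cross-platform Spearman correlation near 0.89. A second
comparison platform carries its own VAF noise but no MAPD (UMI-based
pipelines do not report one); its detection is logistic in log10(VAF)
(`expit(2.2 + 2.0·log10 VAF)`), the minimal model giving VAF-driven
concordance between the two NGS platforms.

What the generator does *not* emulate: read-level error profiles, UMI
family structure, real panel geometry (multi-chromosome amplicon maps,
GC-dependent coverage waves), inter-assay dPCR variability, or
false-positive comparison calls (all records are reference-positive).
Passing pipeline tests therefore demonstrate internal statistical
correctness under the stated model, not performance on any particular
instrument.

## Numerical and design conventions

* Medians: mean of the two central values at even counts.
* Boundary conventions: MAPD flag triggers on `>` threshold; quadrant and
  sweep comparisons are inclusive (`≤`) on the low side.
* Missing data are always excluded-and-counted, never silently dropped or
  imputed; every reported percentage carries its numerator and
  denominator.
* Reports render percentages to 2 decimals; underlying values are kept at
  full precision. Report JSON is deterministic given the inputs except for
  the provenance timestamp; the config hash covers all analysis
  parameters.
* VCF ingestion (4.2) takes AF as a fraction and converts to percent,
  falling back on AO/DP.
* Test problem sizes: distributional checks use a 450-sample cohort
  (~720 matched records) and, for calibration targets, a 2000-sample
  cohort; closed-form MAPD recovery uses 10,000 amplicons. These sizes put
  Monte-Carlo error well inside the asserted tolerances while keeping the
  suite quick.

## Limitations

* The per-sample-median baseline will not reproduce vendor MAPD values
  bit-for-bit (their baselines are proprietary); MAPD is comparable within
  a pipeline, not across pipelines.
* The logistic detection model and the independence of driver and T790M
  VAFs are simplifying assumptions.
* The concordance correlation coefficient is not implemented; Spearman is
  the supported correlation.
* Analyses are per-mutation (each mutation measurement treated as an
  independent record); within-patient correlation is not modelled.
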