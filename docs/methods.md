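# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer needs to know.

## ddPCR quantification and CDR15

Each well is modelled as N independent droplets receiving template by a
Poisson process; a droplet is positive with probability 1 - exp(-lambda).
The maximum-likelihood inversion `copies = -ln(1 - k/N) * N` is exact under
this model and strictly increasing in k; a fully positive well (k = N) has
unbounded concentration and is treated as an error, never clipped.
Concentration pools the summed well copies over the plasma volume the
reaction represents (default 2 ml split into 2 wells of 15,000 accepted
droplets of 0.85 nl — platform-typical values; droplet volume is carried on
the data model but cancels out of concentration ratios).

CDR15 = EOT copies/ml over baseline copies/ml per mutation. Where several
mutations are tracked, the combination rule is a weighted mean with weights
proportional to baseline copies/ml. This choice (the assay literature says
only "a weighted mean") weights by information content and is algebraically
identical to the pooled ratio sum(EOT)/sum(baseline); it is asserted as an
invariant in the tests and is configurable in spirit — any other weighting
would be a one-line change in `ctdna.cdr15`.

Evaluability conditions only on baseline depth (>= 4 positive droplets,
default); EOT is never thresholded, so complete suppression legitimately
yields CDR15 = 0. Suppression is strict: CDR15 < 0.25. The reference-assay
mass conversion uses 3.3 pg per haploid genome copy.

## Bisulfite methylation calling

Only the forward-converted top strand is modelled; reads are assumed
merged and primer-trimmed upstream. Alignment is global with affine gaps
(match +1, mismatch -1, gap open -2, extend -0.5) over an asymmetric
substitution matrix in which read T opposite reference C scores as a match,
because conversion is expected, not an error. Identity is matching columns
(including T/C) over the reference length.

Performance shortcut: for an equal-length read whose gapless identity is
>= 0.95, the gapless comparison is returned without running the dynamic
program. Under the default scoring this is exact — a mismatch costs 2
relative to a match while avoiding it needs at least two gap openings
(cost 4) plus lost matches — and the full aligner still handles every read
with indels or heavier damage.

QC cascade, in order, with the first failure recorded: identity < 0.90;
more than 1 non-bisulfite mismatch; any unconverted non-CpG cytosine
(default tolerance 0 — the strictest reading, since the assay description
gives no cutoff; configurable); any non-excluded CpG column that is neither
C nor T. The ">1 mismatch" rule deliberately counts non-bisulfite
mismatches only — counting C->T conversions would fail every converted
read.

A read is methylated when its methylated CpG fraction strictly exceeds
0.90 (9/10 sites is *not* methylated). Excluded CpG sites (e.g. the two
RAD51C sites found constitutively methylated) leave both numerator and
denominator; their identities are an input, not inferred. Sample-level
positivity — methylated-read fraction >= 0.10 with >= 100 passed reads —
is this package's own operating point; the assay literature reports
per-tumour verdicts without stating one. Coordinates are 0-based
half-open; a CpG site is identified by its C position.

## IHC scoring

Ki67 response is a relative fall >= 50% between baseline and EOT. The
descriptions in circulation state both ">= 50%" and "> 50%"; >= is the
default here and `strict=True` switches the boundary. Cleaved PARP needs
>= 500 assessable invasive tumour cells, otherwise "insufficient invasive
tumour". RAD51/geminin counts pool across fields *before* division
(ratio of sums), making scores invariant to field partitioning; with two
blinded scorers the reported score is the mean of per-scorer pooled scores
and validity (>= 300 tumour cells, >= 30 GMNN+ cells per scorer) must hold
for every scorer — no reconciliation rule exists in the assay description,
so the package takes the conservative reading. An invalid sample is never
classified; a valid score < 20% (strict) calls functional HR deficiency.

## Genomic features and HRDetect-style score

Signature exposures are refit by nonnegative least squares against a fixed
catalog; NNLS recovers exact mixtures to machine precision and stays within
10% on 5,000-mutation Poisson-noise mixtures (tested against a grid-search
oracle). The HRD-LOH index counts LOH segments (minor CN 0, major CN >= 1)
longer than 15 Mb that do not span a whole chromosome; adjacent equal-CN
segments merge first so the index ignores segmentation granularity.
Chromosome lengths ship as a GRCh37 table.

The score is logistic over six features, each transformed
log(x + offset) with offset 1 (the offset guards log(0) and is
configurable) and standardised by per-feature (mean, sd). The engine is
weight-agnostic; coefficients load from JSON. The bundled default model is
**synthetic-calibrated**: means/sds are derived analytically from the
generator's class medians (so the two latent classes sit near z = +/-1)
with positive weights and zero intercept. It is not a published coefficient
set and is labelled accordingly; supply real coefficients via
`HrdetectModel.from_json` for any non-synthetic use. Classification is
strict: score > 0.70, and the composite genomic-instability HRD score,
accepted as an input when present, is positive above 42.

## Exact statistics and the two-stage design

Fisher's two-sided p uses the small-p-values convention (sum of all
hypergeometric outcomes no more probable than the observed table), which
reproduces the association p-values this pipeline is checked against
(0.037, 0.031, 5.797e-4); the doubling convention is available behind a
flag. Clopper-Pearson bounds are beta quantiles. Mann-Whitney and Wilcoxon
use full enumeration up to 10 per group / 15 nonzero pairs (tie-free) and
continuity-corrected normal approximations with tie corrections beyond;
the switchover points are arguments.

`simon_search` enumerates all (n1, r1, n, r) up to n_max with exact
binomial error rates, vectorised over (x1, r); minimax picks the smallest
n, ties broken by smallest expected size under p0. The reference design
this package targets — stage 1 of 41, total 73, activity at >= 14
responses, for p0 = 0.10, p1 = 0.25, power 0.90 — is the exact minimax
optimum at one-sided alpha 0.016, and that is the package's default search
level for it. Two points a maintainer should know, both established by
exhaustive search: (i) at one-sided alpha 0.008 no 73-patient design is
feasible (the minimax total is 82), so a "two-sided 1.6%" label on this
design cannot be taken literally — its exact one-sided type-I error is
0.0124 (two-sided 2.5%); (ii) at alpha 0.016 the strict minimax tie-break
prefers interim futility at <= 4/41 (expected size 53.5) over the widely
quoted <= 3/41 (expected size 60.1); both satisfy the error constraints,
and `simon_oc` evaluates either exactly.

## Synthetic cohort generator

A latent Bernoulli HR-deficiency status (default prevalence 0.69, the
reported TNBC prevalence this pipeline models) drives every stream.
Mechanism is sampled conditionally on deficiency (defaults: BRCA1/2
germline 0.40, BRCA1 methylation 0.20, PALB2 0.05, RAD51C methylation
0.08, none 0.27 — leaving ~73% of deficient tumours with a detectable
mechanism). Baseline ctDNA is log-normal (log10 mean 1.5, sd 1.0
copies/ml — free parameters; no public per-patient concentration
distribution exists for this setting, so these are documented choices
producing mostly-evaluable patients with a realistic non-evaluable tail).
True CDR is Beta(1, 6) for deficient (mode 0, mean 0.14) and Beta(6, 2)
for proficient tumours, reproducing the reported direction of separation.
RAD51 EOT scores are normal around 8% (deficient) and 45% (proficient),
sd 5, with baseline scores near 5% for everyone (little DNA damage before
treatment); Ki67 response is Bernoulli(0.12) independent of deficiency,
mirroring the reported dissociation between Ki67 response and HR status.

Methylation-mechanism patients draw a methylated-template fraction uniform
on [0.3, 0.8]; everyone else carries a 1% background. Reads default to 400
per sample per amplicon — a deliberate scale-down from the tens of
thousands a sequencing run produces, chosen to keep full-cohort analyses
fast while leaving binomial standard errors around 2 percentage points.
Amplicon references are fixed synthetic sequences (random inserts flanked
by the real printed primer sequences) with >= 10 CpGs; the signature
catalog is likewise a fixed synthetic Dirichlet draw with the real shape
(12 substitution x 96 channels, 6 rearrangement x 32).

Copy-number segments are constructed so their HRD-LOH index equals the
latent feature value (Poisson mean 18 deficient / 3 proficient, capped at
34 placements), with sub-threshold and whole-chromosome LOH decoys that
must not count. Error models are per-base independent substitutions
(conversion failure 0.002, sequencing 0.002); no indels, no paired-end
structure, no tumour-purity modelling beyond the scalar methylated/ctDNA
fractions, no droplet fluorescence — those belong to upstream wet-lab and
image analysis. Consequently, passing tests demonstrate correctness of the
quantification, calling, scoring and inference rules under idealised noise,
not robustness to alignment artefacts, purity variation or assay failure
modes in real data.

All randomness descends from one root seed through named per-patient,
per-assay substreams (`default_rng([seed, patient, stream])`), so cohorts
are bit-reproducible and assays are independently perturbable.

## Problem sizes

End-to-end checks run a 200-patient cohort (about 10 s); distributional
checks use n = 1000 for prevalence, 2000 reads for methylation fractions,
10^4 draws for interval coverage and 10^5 replicates for design-operating-
characteristic Monte Carlo, each with 3-standard-error bands. The design
search is exact and takes a few seconds to n = 100.
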