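# riokit

Biomarker-analysis pipeline for pre-surgical ("window of opportunity")
PARP-inhibitor trials in triple negative breast cancer (TNBC), built around
the readouts such trials use to detect homologous-recombination (HR) DNA
repair deficiency and early drug activity:

* **ctDNA dynamics** — droplet digital PCR (ddPCR) quantification of
  patient-specific tumour mutations in plasma, and the day-15 circulating
  DNA ratio (CDR15) as an early activity marker;
* **promoter methylation** — per-read methylation calling from merged
  bisulfite amplicon reads over the BRCA1 and RAD51C promoters;
* **IHC scoring** — Ki67 response, cleaved-PARP (apoptosis), and the
  RAD51/geminin focus assay as a functional HR readout;
* **HR-deficiency genomics** — mutational-signature exposure refitting
  (NNLS), the HRD-LOH index from allele-specific copy-number segments, and
  an HRDetect-style weighted logistic score;
* **exact trial statistics** — two-sided Fisher's exact test, Clopper-
  Pearson intervals, exact Mann-Whitney / Wilcoxon tests, and exhaustive
  Simon two-stage design search with exact operating characteristics.

A seeded synthetic-cohort generator (`riokit.synth`) ties everything
together: a latent per-patient HR-deficiency status drives every raw data
stream, so the full pipeline is testable end to end without access to any
patient-level data.

## The statistics at the core

**ddPCR quantification.** A well partitions template into N droplets; with
k positive droplets the copy estimate is Poisson inversion
`copies = -ln(1 - k/N) * N`. Concentrations pool wells and divide by the
plasma volume represented. **CDR15** is EOT copies/ml over baseline
copies/ml; with several tracked mutations, a baseline-copies-weighted mean
(algebraically the pooled ratio). Only mutations with >= 4 positive
baseline droplets are evaluable; CDR15 < 0.25 (strict) is suppression.

**Methylation calling.** Reads align to the unconverted amplicon with
conversion-aware scoring (read T opposite reference C matches). QC requires
>= 90% identity, <= 1 non-bisulfite mismatch, complete conversion at
non-CpG cytosines, and every CpG column C or T. A read is methylated when
strictly more than 90% of its non-excluded CpG sites retain C.

**RAD51 score.** Per scorer, counts pool across five 40x fields:
`proliferation = 100 * GMNN+ / tumour cells`,
`RAD51 score = 100 * RAD51+ / GMNN+` (cells with >= 5 foci). Validity needs
>= 300 tumour cells and >= 30 GMNN+ cells; a valid score < 20% indicates
functional HR deficiency.

**HRDetect-style score.** logistic(intercept + sum of weights * z) over six
log-transformed, standardised features (substitution signatures 3 and 8,
rearrangement signatures 3 and 5, microhomology-deletion proportion,
HRD-LOH index); positive above 0.70.

**Simon two-stage design.** Stop for futility if <= r1 responses in n1;
declare activity if total responses > r of n. `simon_search` scans all
(n1, r1, n, r) for exact binomial type-I error and power, returning the
minimax (or optimal) design; `simon_oc` evaluates any design exactly.

## Worked example

```python
from riokit import pipeline, stats
from riokit.synth import CohortConfig, generate_cohort

design = stats.simon_search(0.10, 0.25, alpha_one_sided=0.016, beta=0.10)
lo, hi = stats.clopper_pearson(3, 25)

cohort = generate_cohort(CohortConfig(n_patients=50, seed=1))
report = pipeline.associations(pipeline.records_frame(pipeline.assemble(cohort)))
```

prints (via the formatting in `python -m riokit.cli` or your own):

```
design: stage1 n1=41 (futility <= 4), total n=73, activity >= 14; power 0.9005, one-sided alpha 0.0124
Ki67 response 3/25 = 12.0% (95% CI 2.5-31.2%)
Fisher p = 5.80e-04
HRDetect-positive: 38/50 = 76%
HRDetect class x mechanism detected: table [[29, 9], [0, 12]], Fisher p = 2.42e-06
CDR15 by HRDetect class: U = 23, p = 3.39e-06
RAD51 score baseline->EOT: Wilcoxon p = 1.46e-05 (n = 50)
```

Reading the numbers: the design search recovers a 41/73 minimax trial with
exact power 90.05%; 3 responders of 25 gives the exact 2.5-31.2% interval;
in the 50-patient synthetic cohort, every patient with a detectable HR
mechanism (germline annotation or measured promoter methylation) falls in
the HRDetect-positive class, ctDNA suppression concentrates in
HRDetect-positive patients, and RAD51 scores rise on treatment as
drug-induced DNA damage recruits RAD51 foci in repair-proficient tumours.

There is also a CLI: `riokit simulate | ctdna | methyl | ihc | hrdetect |
stats | design | run` (see `riokit --help`).

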