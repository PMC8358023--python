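# Methods

## The filtering model

The pipeline treats a targeted-panel variant list from plasma as a
mixture of four sources — tumor-derived somatic mutations, germline
variants, clonal hematopoiesis (CH), and sequencing/PCR noise — and
separates them with matched controls rather than statistical error
models:

* **Functional-class selection.** Only missense, stop-gain, stop-loss,
  in-frame deletion and frameshift calls proceed; everything else
  (synonymous, intronic, UTR) is dropped first. This is a panel-design
  assumption: the genes are chosen so that functional coding hits are
  the informative events.
* **Material-specific detection thresholds.** cfDNA calls need VAF ≥ 1%
  and ≥ 10 variant reads; tissue calls need VAF ≥ 10% and ≥ 10 variant
  reads. Boundaries are inclusive, and the VAF comparison is done on raw
  read counts (`100·alt ≥ pct·depth`) to avoid float rounding exactly at
  the boundary. Calls ingested from report-style tables without read
  counts waive the read-count criterion with a logged warning.
* **Germline subtraction.** A patient's PBMC calls at VAF ≥ 20% are
  germline (heterozygous ≈ 50%, homozygous ≈ 100%) and are removed from
  that patient's cfDNA and tissue results. The 20% boundary is a single
  comparator: a PBMC call is germline iff VAF ≥ 20% and a blacklist
  candidate iff VAF < 20% — never both, never neither. A patient with no
  PBMC sample skips subtraction with a warning rather than failing.
* **Cohort blacklist.** All sub-20% PBMC calls pooled over the cohort
  form a blacklist applied to every sample, on the rationale that
  alleles visible in blood cells at low VAF are CH or recurrent
  artifacts, not tumor signal. Singleton entries are admitted by
  default; `blacklist_min_recurrence` restricts to keys seen in ≥ k
  distinct PBMC samples, and `blacklist_scope="patient"` restricts the
  subtraction to the contributing patient for sensitivity analyses.
* **Order and logging.** The cascade order is class → thresholds →
  germline → blacklist → manual exclusions; a call matching several
  rules is logged under the first. The manual-exclusion hook represents
  interactive alignment review and is a no-op unless keys are supplied.
  The cascade is idempotent on its own output, and every input call
  receives exactly one disposition.

UMI deduplication, when read records are available, groups reads by
exact `(umi, chrom, start, strand)` and takes the strict-majority allele
of each family as its consensus; tied families are discarded from both
depth and variant counts. Exact-match grouping (no edit-distance
merging) keeps the operation deterministic; with ~10-base random
barcodes and position in the key, barcode collisions are negligible at
panel depths. VCF input is treated as already deduplicated.

## Burden tracking and downstream analyses

The per-sample burden summary is the **average VAF**: the unweighted
arithmetic mean VAF (percent) of the finalized somatic calls at that
timepoint. The denominator is the set detected *at that timepoint*, not
a baseline-tracked set, so complete molecular response maps to 0 rather
than being undefined; averaging (instead of tracking the top clone)
deliberately dampens clonal switching under combined cytotoxic/targeted
therapy. **Clearance** is average VAF strictly below 1% at the first
response evaluation; a patient without a first-evaluation sample is
`unknown` and excluded from clearance-stratified comparisons.

**Concordance** matches finalized tissue calls against the plasma
somatic set by exact variant key (a positional chrom+pos mode exists for
indel-representation drift). Unmatched tissue variants are *rescued*
when present in the post-class, pre-threshold plasma calls with VAF > 0
— quantifying sensitivity lost to the 1% cutoff rather than to absent
signal; the symmetric check runs for plasma-only variants against
unfiltered tissue calls. **Emergent** mutations are finalized
progression-sample calls absent from all earlier plasma somatic sets
and from the tissue somatic set (screening against every earlier
timepoint, not baseline alone).

Statistics use standard machinery: Kaplan–Meier curves and two-sided
log-rank tests (lifelines), with median survival as the earliest time
at survival ≤ 0.5 (undefined when never reached); Pearson/Spearman
correlation and Fisher/chi-square association (scipy), selecting
Fisher's exact test when any expected cell is below 5 and the
continuity-corrected chi-square otherwise, with both p-values carried
in the result. The Mann–Whitney U test enumerates all group assignments
for combined n ≤ 16 (exact even under ties, which scipy's exact mode
refuses) and uses the tie-corrected normal approximation above. No
multiplicity correction is applied; p-values are reported raw, and all
tests are two-sided.

`binomial_power` computes the exact power of the two-sided exact
binomial test: the rejection region is every outcome whose
minimum-likelihood two-sided p-value under the null is ≤ α, and power
is the alternative's probability mass on that region. Note the exact
test's power is *not* monotone in n — the rejection boundary shifts
discretely, producing a sawtooth of small (< 0.05) local dips — so the
tests assert the coarse-scale rise rather than pointwise monotonicity.
For detection-sensitivity designs quoted on a full cohort with partial
marker prevalence, `evaluable_n(total, prevalence)` gives the evaluable
subset (e.g. 40% prevalence of 78 → n = 31, where power for
0.70 → 0.90 at α = 0.05 is 0.807).

## The synthetic cohort generator

`simulate_cohort` produces the complete input set (per-sample calls,
sample sheet, clinical table) plus a ground-truth JSON. Defaults are
the study-shaped conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 93 | cohort size (≤ 512, the position-stratification stride) |
| `depth_mean` | 2000× | Poisson mean of per-locus deduplicated depth |
| `dropout` | 0.097 | fraction of patients shedding essentially no ctDNA |
| `somatic_extra_mean` | 1.74 | baseline somatic count = 1 + Poisson(·) → mean 2.74 |
| `vaf_scale_median` | 0.149 | per-patient shedding scale (lognormal median) |
| `shedding_coef` | 0.70 | coupling of log shedding scale to log tumor size |
| `patient_sigma`, `variant_sigma` | 0.6, 0.5 | lognormal spreads (patient, variant) |
| `germline_het`/`hom` | 3 / 1 | germline variants per patient, VAF ~ N(0.50, 0.02) / ≈ 1.0 |
| `ch_mean`, `ch_vaf_range` | 0.35, 1–15% | CH variants per patient, shared PBMC+plasma |
| `response_probs` | PR .75 / SD .207 / PD .043 | RECIST best-response mix |
| `clearance_by_response` | PR .82 / SD .55 / PD .10 | P(cleared) given response |
| `pfs_median_cleared` / `not_cleared` | 11.9 / 5.5 mo | exponential PFS medians |
| `pd_sample_rate`, `tissue_rate` | 0.58, 0.71 | progression-draw / tissue availability |
| `emergent_mean` | 1.15 | emergent mutations per shedding patient at PD |

Read support is sampled `Binomial(Poisson(depth), true VAF)` per call;
alleles with < 3 supporting reads are not emitted (a caller's reporting
floor). Tumor size is lognormal (median 35 mm) and drives the shedding
scale through `shedding_coef`, producing a baseline burden–size Pearson
r ≈ 0.6 at defaults (r ≈ 0 when the coefficient is 0). `vaf_scale_median`
was calibrated once so the cohort mean of baseline average VAF is
≈ 23%. Concordance structure comes from two per-variant mechanisms:
~10% of somatic variants are nearly absent from tissue (plasma-only),
and a zero-inflated set of tissue-enriched variants sheds at 0.2–0.3%
plasma VAF (detectable as sub-threshold rescue but never passing the
cutoff). Each patient draws from `default_rng([seed, index])`, so
patient i is byte-identical regardless of cohort size; panel positions
are stratified by patient index modulo 512 within per-gene intervals,
guaranteeing cross-patient key uniqueness without coordination (small
genes fall back to a gene with free capacity). Recurrent resistance
alleles at fixed real coordinates are drawn for a quarter of emergent
mutations so hotspot/pathogenicity annotation is exercised end to end.

**Detection margins.** So that planted truth is recoverable exactly at
2000× depth, the generator keeps true VAFs away from the decision
boundaries: baseline VAFs of shedding patients avoid the 0.4–2.5% band,
non-shedders are capped at 0.4% at every timepoint, cleared patients'
residual disease sits at 0.02–0.2% while persistent disease stays at
≥ 2.5%, noise stays ≤ 0.3%, and emergent VAFs start at ≥ 1.5%. Binomial
sampling still produces realistic borderline behavior for the
sub-threshold populations; the margins only exclude coin-flip
detectability of the *planted* categories, which would otherwise make
"recovered exactly" ill-posed.

**What passing tests do and do not show.** The generator has
single-nucleotide/indel keys with uniform random alleles, no
position-specific error spectra, no tri-nucleotide context, no CNVs or
structural variants, per-variant independent sampling (no overlapping
reads), and clean exponential PFS. Recovery results on it demonstrate
the pipeline's logic (partitioning, thresholds, bookkeeping,
statistics) — not robustness to alignment artifacts, FFPE deamination
damage, panel dropout or real clonal dynamics.

## Numerical and design choices

* VAF is a fraction in [0, 1] internally; every user-facing threshold is
  percent and converted at the configuration boundary.
* Coordinates are 1-based inclusive; chromosome labels compare as exact
  strings with an optional "chr"-stripping normalization; indels use the
  VCF left-anchored convention, and anchorless `-` alleles are rejected
  (left-anchoring would require a reference genome).
* The flat table dialect's printed `VAF (%)` is overridden by
  `alt/depth` whenever read counts are present (counts are
  authoritative; the percent is display precision).
* Empty inputs are defined, not errors: empty blacklist pool → empty
  blacklist; empty somatic set → average VAF 0; fully censored survival
  group → valid curve with undefined median.
* Report JSON is written with sorted keys; reruns with the same config
  and seed are byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on generated
cohorts: 93 patients for the study-scale run, 200 patients for exact
recovery and the 20-seed correlation check, 500 for the cohort-shape
check, and 200 replicates for log-rank power at hazard ratio 3 — sizes
at which the targeted quantities are stable while the full suite stays
interactive.

## Limitations

* Hotspot and pathogenicity annotation are offline snapshots bundled
  with the package, covering the panel's recurrent alleles only; they
  are not a substitute for a live database query on novel variants.
* The blacklist admits singleton PBMC observations by default, which is
  aggressive against noise but can, in principle, swallow a true tumor
  allele that independently arose as CH in another patient; the
  recurrence and scope switches exist for that analysis.
* Dedup implements single-strand consensus only (no duplex), without
  per-base quality weighting.
* The power computation covers the one-sample binomial design; no
  survival-endpoint power tools are included.
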