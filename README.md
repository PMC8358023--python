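# ctdna-pipeline

Somatic variant filtering and longitudinal analysis for targeted
circulating-tumor-DNA (ctDNA) panel sequencing, aimed at translational
oncology groups who monitor treatment response from serial plasma draws
alongside matched tumor tissue and PBMC (peripheral blood mononuclear
cell) controls.

Plasma cell-free DNA carries a small tumor-derived fraction, so a
targeted-panel variant list from plasma mixes true tumor mutations with
germline variants, clonal-hematopoiesis (CH) alleles and sequencing
noise. This package implements the standard matched-control cascade for
separating them, plus the downstream burden-tracking and outcome
statistics:

1. **UMI deduplication** (optional, read-record level): reads sharing a
   molecular barcode and alignment key collapse to one consensus
   observation per source molecule; families with no strict-majority
   allele are discarded. Depth and VAF (variant allele frequency,
   `alt reads / total reads`) are recomputed on families.
2. **Filter cascade** per sample:
   * keep possibly-functional classes only (missense, stop-gain,
     stop-loss, in-frame deletion, frameshift);
   * cfDNA: keep calls with VAF ≥ 1% **and** ≥ 10 variant reads;
     tissue: VAF ≥ 10% **and** ≥ 10 variant reads (boundaries inclusive);
   * subtract the patient's germline set — PBMC calls with VAF ≥ 20%
     (heterozygous ≈ 50%, homozygous ≈ 100%);
   * subtract a cohort-wide **blacklist** — every PBMC call below 20%
     VAF pooled across all patients (recurrent noise and CH).
3. **Longitudinal tracking**: per patient per timepoint, the *average
   VAF* (unweighted mean VAF of detected somatic mutations, in percent;
   0 when nothing is detected). Patients whose average VAF falls
   strictly below 1% at the first response evaluation are classified
   *cleared*.
4. **Tissue–plasma concordance** by exact variant key, with
   sub-threshold *rescue*: unmatched tissue variants are searched for in
   the unfiltered plasma calls below the 1% cutoff (and vice versa for
   plasma-only variants in tissue).
5. **Emergent resistance mutations**: finalized plasma calls at
   progression absent from every earlier plasma somatic set and from
   the tissue somatic set, annotated against bundled RAS/RAF/MEK hotspot
   and pathogenicity tables.
6. **Cohort statistics**: Kaplan–Meier / log-rank progression-free
   survival (PFS) comparisons (clearance groups, RAS-hotspot carriers),
   Pearson/Spearman burden–size correlations, Mann–Whitney and
   chi-square/Fisher detection associations, per-gene frequency tables,
   and the exact two-sided binomial power computation used for
   enrollment sizing.

A fully seeded **synthetic cohort generator** emulates the statistical
structure such a study observes (germline ~50/100% VAF, low-VAF CH
shared by plasma and PBMC, binomial read sampling at ~2000× depth,
response-linked VAF trajectories, clearance-linked exponential PFS) and
emits the exact file formats the pipeline reads plus a ground-truth
JSON, so the whole analysis is testable end to end without any external
data.

## Worked example

```python
from ctdna import RunConfig, run_pipeline

report = run_pipeline(RunConfig(out_dir="demo", seed=1, n_patients=93))

freq = report["frequency_baseline"]
print(f"mutation-positive patients: {100 * freq['fraction_positive']:.1f}%")
print(f"mean mutations per positive patient: {freq['mean_mutations_per_positive']:.2f}")

conc = report["concordance"]
print(f"tissue variants matched in plasma: {conc['matched_pct']}%")
print(f"unmatched tissue variants rescued below cutoff: {conc['rescued_pct_of_unmatched']}%")

surv = report["stats"]["pfs_by_clearance"]
print(f"median PFS cleared vs not: {surv['cleared']['median_pfs_months']} "
      f"vs {surv['not_cleared']['median_pfs_months']} months "
      f"(log-rank p = {surv['logrank']['p']:.2g})")
```

prints

```
mutation-positive patients: 91.4%
mean mutations per positive patient: 2.47
tissue variants matched in plasma: 70.3%
unmatched tissue variants rescued below cutoff: 81.5%
median PFS cleared vs not: 10.28 vs 5.39 months (log-rank p = 0.00079)
```

i.e. with no input directory the run simulates a 93-patient cohort
(seeded, reproducible), filters every sample, and summarizes baseline
mutation burden, tissue concordance and the survival split between
patients whose plasma burden cleared below 1% at first evaluation and
those whose did not — the cleared group progressing roughly half a year
later.

The same stages are exposed on the command line:

```bash
ctdna simulate --n-patients 93 --seed 1 --out cohort/
ctdna blacklist --cohort cohort/ --out blacklist.tsv
ctdna filter --cohort cohort/ --sample P001_cf_baseline --blacklist blacklist.tsv --out somatic.tsv
ctdna run --seed 1 --out demo/
ctdna power --p0 0.7 --p1 0.9 --n-total 78 --prevalence 0.4
```

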