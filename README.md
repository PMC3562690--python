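# lfquant

Label-free quantitative LC-MS/MS proteomics by peptide ion **peak area**:
post-identification retention-time alignment, extracted-ion-chromatogram
(XIC) quantitation, peptide qualification filtering, and normalization-free
protein roll-up with CV/QC reporting and differential statistics — plus a
synthetic LC-MS experiment simulator with full ground truth, so every stage
is testable without instrument data.

## The problem

In bottom-up label-free quantitation, a protein's abundance is measured from
the chromatographic peak areas of its peptides across many injections. Three
things make this hard in practice, especially on low-resolution instruments:

1. **Alignment.** A peptide's LC retention time drifts by roughly 3 min
   between injections, and under dynamic exclusion its MS/MS scans fire off
   the elution apex (from ~0.5 min before to >1.5 min after). Where should
   the XIC be extracted in injections where the peptide was never
   identified?
2. **Peptide qualification.** Not every identified peptide can quantify its
   protein: identification frequency is heavily skewed (in a typical
   35-injection experiment a quarter of peptides are seen in just one
   injection), elution patterns vary from perfectly reproducible single
   peaks to indistinct multi-modal smears, technical-replicate CVs range
   from ~10% to >60% for equally abundant peptides, and peptides of one
   protein can show mutually contradictory fold changes (PTMs, sharing,
   carry-over, misidentification).
3. **Normalization.** Global/linear/local/quantile rescaling all rest on
   assumptions (equal response, global carry-over, similar abundance
   distributions) that fail for complex peptide mixtures. This pipeline
   applies **no normalization at all**; instead, batch validity is
   established from QC injections, and accuracy comes from eliminating
   unquantifiable peptides before roll-up.

## Method

For each peptide *p* (sequence + modification + charge):

1. **Consensus RT** — collect all MS/MS scan times
   {t₁…t_n} of *p* across injections. If max−min ≤ 3 min they form one
   cluster; otherwise the sorted times are split at gaps > 1 min
   (1-D single-linkage). The retention time is the weighted mean
   RT_p = Σwᵢtᵢ / Σwᵢ over the largest-weight cluster (weights uniform, or
   the identification confidences). Because only identical peptide IDs are
   ever pooled, this is a three-dimensional (m/z, RT, MS/MS identity)
   alignment with thousands of landmarks.
2. **Quantitation** — in *every* injection (identified there or not) the XIC
   at the peptide's median precursor m/z (±0.5 Da low-res / ±10 ppm
   high-res) is extracted in RT_p ± 3 min; the elution peak nearest RT_p is
   detected and its raw trace integrated by the trapezoid rule:
   A_{p,j} = ∫ I(t) dt.
3. **Qualification** — four filters with a full audit trail:
   identification frequency (≥ 50% of injections), retention time
   (bulk-signal elution within 1.5 min of RT_p in ≥ 75% of injections),
   technical-replicate CV (≤ 30%), and intra-protein correlation (median
   Pearson r ≥ 0.5 against sibling peptides, greedy worst-offender
   removal). All thresholds are configuration, not dogma.
4. **Roll-up & statistics** — protein abundance = Σ of its qualified,
   non-shared peptide areas per injection. Precision is reported as CV
   distributions (bins ≤15 / 15–20 / 20–30 / 30–50 / >50%), QC injections
   are checked against the bioanalytical acceptance bounds (CV ≤ 25%,
   ≤ 30% at LLOQ), and group differences use Welch's t on log₂ abundances
   with Benjamini–Hochberg q-values.

## Worked example

```bash
cat > cfg.yaml <<'YAML'
seed: 1
simulate:
  n_proteins: 10
  peptides_per_protein: [2, 3]
  groups:
    control: {n_samples: 5}
    treated: {n_samples: 5, fold_change: 2.0, n_changed: 5}
YAML
lfq all --config cfg.yaml --out demo_out --seed 1
```

This simulates ten proteins (five truly changed 2-fold in `treated`), twelve
injections (10 experimental + 2 QC), runs every stage, and writes
`consensus_rt.tsv`, `peptide_matrix.tsv`, `filtered_matrix.tsv` +
`filter_report.tsv`, `protein_matrix.tsv`, `cv_report.tsv`,
`qc_result.json`, `diff_table.tsv` and a `manifest.json`. With the config
above the run prints/records:

- 24 aligned peptides, of which 12 are retained by the filters (the
  simulation deliberately injects badly eluting and rarely identified
  peptides);
- QC verdict `pass` with mean protein CV 7.4% (control), 10.4% (treated),
  6.4% (QC pool);
- a differential table whose top rows look like

  ```
  protein_id  log2fc     p      q   significant
  PROT0001     0.902  0.000  0.000  True
  PROT0002     0.114  0.271  0.434  False
  PROT0003     1.019  0.000  0.000  True
  ```

  i.e. the truly changed proteins come out near log₂FC = 1 at q < 0.05 and
  the null proteins near 0.

Every stage is also available as its own subcommand (`lfq simulate`,
`align`, `quantify`, `filter`, `rollup`, `report`, `compare`) over the same
tab-delimited files, and as plain library functions
(`lfquant.alignment.align_events`, `lfquant.quantify.build_peptide_matrix`,
…).

## What is deliberately *not* here

Spectral counting, peptide identification (database search), global /
linear / local regression / quantile / spike-in normalization, 2-D
chromatogram warping, base-peak-chromatogram alignment, and
linear-regression RT models — each either rejected on methodological
grounds (see `docs/methods.md`) or out of scope (identification happens
upstream; this package consumes a PSM table).
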