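# Methods

This note documents the models, parameter choices and numerical decisions
behind `lfquant`, and what the synthetic-data studies do and do not
demonstrate.

## Units and conventions

All times are minutes, all m/z values Da, all abundances arbitrary detector
units. "CV" is always 100·sd/mean with the sample (ddof = 1) standard
deviation. Confidence scores are probabilities in [0, 1], larger is better;
mapping search-engine scores onto this scale is the caller's job.

## Consensus retention time

All MS/MS scan times of one peptide key are pooled across injections. The
alignment never pools different peptides (identity is part of the key), so
it is immune to the classic image-warping failure of aligning dissimilar
features.

- **Clustering trigger** (`range_threshold`, default 3.0 min): no clustering
  below this spread, reflecting the typical injection-to-injection
  retention drift of LC peptide separations. A single cluster then holds
  everything.
- **Gap splitting** (`gap`, default 1.0 min): above the trigger, sorted
  times are cut at every inter-observation gap > 1 min. For sorted points
  this produces the minimum number of clusters such that no intra-cluster
  gap exceeds the parameter (verified against exhaustive enumeration in the
  test suite). It is deterministic and invariant to input order; ties in
  time are ordered by run id.
- **Weighted mean** (`weighting`): the retention time is the weighted mean
  scan time of the cluster with the largest total weight (tie → earlier
  mean). Weights are uniform by default; weighting by identification
  confidence is available because the literature leaves the weight choice
  open. Minority clusters are reported via `n_clusters` and
  `selected_cluster_fraction` but not quantified separately — downstream
  XIC extraction needs exactly one anchor per peptide.

## XIC quantitation

- **m/z tolerance**: ±0.5 Da in `low_res` mode — covering the ~0.3–0.9 Da
  precursor m/z spread ion traps show for the same peptide across
  injections — and ±10 ppm in `high_res` mode. The per-peptide target m/z
  is the median of its event precursor m/z values (robust to stray
  outliers).
- **RT window**: ±3.0 min around the consensus RT, matching the drift
  magnitude that motivates alignment in the first place.
- **Peak detection**: local maxima of the 3-point moving-average-smoothed
  trace; the apex is the maximum nearest the consensus RT (not the highest
  one — co-eluting interference should not hijack the peak), and
  boundaries walk outward on the *raw* trace until intensity falls below
  max(1% of apex, noise floor) or a local minimum. Integration is
  trapezoidal on the raw trace: smoothing is for apex finding only, since
  it biases areas. `PeakBounds.top_time` additionally records where the
  window's global intensity maximum lies; see the retention-time filter.
- **Missingness**: a cell with no point above the noise floor stays
  missing. No imputation anywhere.
- Extraction is attempted in **every** injection, identified there or not:
  absence of an identification is an acquisition artifact (dynamic
  exclusion, precursor competition), not evidence of absence.

## Qualification filters

Executed frequency → retention time → CV → correlation, with every failed
reason recorded per peptide. Defaults (`FilterConfig`): identification in
≥ 50% of experimental injections; bulk-signal elution within 1.5 min of the
consensus RT in ≥ 75% of injections; per-sample technical-replicate CV
≤ 30% (the LLOQ-style acceptance bound); median sibling correlation ≥ 0.5
for proteins with ≥ 3 quantifiable peptides. No universal cutoffs exist for
any of these; all are configuration.

Two design choices deserve explanation:

- **The RT filter judges `top_time`, not the integrated apex.** The
  quantification apex is *chosen* as the local maximum nearest the
  consensus RT, so its deviation is biased toward zero by construction and
  would let erratically eluting peptides pass. The filter instead asks
  where the bulk of the signal eluted (the window's global maximum) and
  counts injections with no detectable peak as discordant — elution at the
  consensus time could not be confirmed there.
- **Correlation uses greedy worst-offender elimination.** With a one-shot
  median, a single anti-correlated peptide among three drags a concordant
  sibling's median r down and removes it too; recomputing after removing
  the worst offender isolates the actual discordant peptide. Pairs need
  ≥ 3 common non-missing injections; flat (zero-variance) profiles
  contribute no information; shared peptides and small proteins are not
  judged.

The CV filter pools only same-sample injections (technical replicates or
the QC pool): between-group differences are signal, not noise, which is
precisely the assumption failure that makes quantile normalization unsafe.

## Roll-up, reports and statistics — and why no normalization

Protein abundance is the **sum** of its qualified, non-shared peptide areas
per injection (a mean is available; sum is the common convention and
preserves scale equivariance). Shared peptides stay in the peptide matrix
but never enter roll-up.

No stage rescales intensities: multiplying one run's intensities by c
changes exactly that run's column by c, and the test suite asserts this
end-to-end. Rather than normalize, the pipeline (a) filters unquantifiable
peptides — on the simulated experiments this alone cuts the mean protein CV
from ~40% to ~10% — and (b) verifies the batch with QC injections against
the CV ≤ 25% acceptance bound (≤ 30% at LLOQ; `min_fraction_pass` of 0.8 by
default, a deliberate choice since no standard fraction exists).

Group comparison: Welch's t on log₂ abundances (≥ 2 non-missing values per
group, otherwise "untested"), Benjamini–Hochberg q-values across tested
proteins, significance at q < α and |log₂FC| ≥ log₂(fc_min). The degenerate
all-identical case returns p = 1 rather than NaN. Reports round percentages
to one decimal and fold ratios to two, matching the conventions of
bioanalytical acceptance tables.

## The simulator

`synthetic_data.simulate_experiment` emulates the acquisition phenomenology
that motivates each pipeline stage, with full ground truth:

- **Elution patterns** (i)–(vi), Gaussian-based because real peak shapes
  are approximately Gaussian at these widths: (i) one consistent peak
  (retention jitter damped to 0.15× the global sd); (ii) one peak with
  injection-specific apex shifts (1.5×); (iii)/(iv) early/late satellites
  carrying a configurable 20% of the area at ±2 min (column overload /
  tight binding); (v) both; (vi) 2–3 low, broad blobs redrawn per injection
  over ±6 min — genuinely indistinct elution. Satellite fractions are not
  literature-derived; they are explicit parameters.
- **Retention drift**: per-injection apex jitter with sd 0.75 min, giving a
  max–min spread on the order of 3 min across ~10 injections.
- **Acquisition**: MS1 cycle 0.05 min over a 30-min gradient; MS/MS
  triggers above an intensity threshold, wins the scan slot with
  probability 0.7 (precursor competition), and is then dynamically excluded
  for 0.5 min — so events land on the leading edge and in the tail, not at
  the apex.
- **Identification probability**: logistic in log₁₀ abundance. Only its
  qualitative consequence matters: a right-skewed identification-frequency
  histogram with a singleton mode, like real multi-injection experiments.
- **Noise**: per peptide-injection multiplicative lognormal area noise
  (`noise_cv`, default 0.10), optional biological sample-to-sample
  variation, m/z jitter with sd 0.15 Da (low-res regime).
- **Corruptions**: optional misidentified singletons (events reassigned to
  a fresh fake key — the frequency filter's target) and shared peptides
  (5% get a second accession — the roll-up exclusion's target).

Everything derives from one seeded generator; identical config + seed gives
bit-identical runs, events, design and truth.

**What the simulator does not model**: isotope/charge envelopes, chimeric
spectra, co-eluting interference at the same m/z (only incidental overlap
occurs), detector saturation, baseline/electronic noise (baseline defaults
to 0), batch drift within a run sequence, and real search-engine score
distributions. Consequently, passing simulation studies demonstrate the
pipeline's internal correctness and its behaviour under the modelled
failure modes — not performance on raw instrument files.

`simulate_protein_matrix` bypasses chromatography entirely (lognormal
protein abundances with multiplicative noise) and backs the
statistics-level studies: power, false-positive count and type-I error of
the group comparison at 1,000 proteins, where full-XIC simulation would add
nothing but runtime.

## Problem sizes in the packaged studies

The packaged studies use: 30 proteins × 2–4 peptides, 2 × 5 injections for
full-pipeline fold-change recovery; 1,000 proteins (50 changed) at n = 5
per group for power/FDR; 1,000 null proteins for type-I error; 20 proteins
with 50% pattern-(vi) peptides, 15% misidentification, 5 × 2 technical
replicates for the filter studies. These sizes give stable statistics at
interactive runtimes; all scale linearly via `SimConfig`.

## Known limitations

- The internal run format and the mzML subset assume centroided MS1 data;
  no profile-mode peak picking.
- Satellite peaks (patterns iii–v) are deliberately *not* added to the main
  peak's area; the quantified quantity is the main-peak area. The
  alternative (integrating all components) would change absolute areas but
  not fold changes, as both groups scale identically.
- One consensus RT per peptide: genuinely bimodal eluters are represented
  by their dominant cluster only (the minority fraction is reported).
- The QC verdict is a summary gate, not an outlier-injection detector.
- `compare_groups` handles exactly two groups per call; multi-group designs
  are compared pairwise by naming the pair.
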