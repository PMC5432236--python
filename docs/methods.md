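# Methods

This note documents the models, parameters and numerical choices behind
`sicquant`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Study model

The supported design is a fixed-effects layout of `G` groups ×
`B` biological replicates (animals) × `T` technical replicates
(injections); the default is 4 × 3 × 4 = 48 runs, with groups named
`control`, `placebo`, `rapamycin` and `incomplete_sf` after the
liver-carcinogenesis study type the pipeline targets (normal liver,
Solt–Farber placebo foci, Solt–Farber rapamycin foci, incomplete
Solt–Farber oval-cell regions). Nothing in the code depends on these
labels except defaults.

## PSM filter chain

Order: deduplication → score filter → target-decoy FDR (configurable via
`filter_order`; this order mirrors the processing narrative the defaults
come from, and the operations commute only partially — dedup before
thresholding guarantees that a spectrum's best match, not an arbitrary one,
is what gets thresholded).

* Deduplication keeps, per `(spectrum_key, peptide_id)`, the maximum score;
  ties break on lowest `run_id`, then input order, making the output a
  deterministic function of the input multiset.
* The score filter is strictly `score > min_score` (default 20): a score of
  exactly 20 is removed.
* The FDR filter finds the *lowest* score cutoff `s` with
  `#decoys(≥ s) / max(1, #targets(≥ s)) ≤ level` (default 1%), i.e. the
  largest admissible retained set, and returns only targets. The estimator
  is the simple decoy/target count ratio; it is deliberately a swappable
  strategy (`filter_by_target_decoy_fdr`) because production search
  engines use richer calibrated scores. Peptides observed only as decoys
  can never reach quantitation.

## SIC quantitation

* **Extraction.** A peptide's m/z is computed from the consensus (median)
  precursor mass and modal charge of its confident PSMs:
  `mz = (M + z·1.00728)/z`. All centroids within ±10 ppm are summed per
  scan; scans with no centroid in window contribute zero. Extraction is
  restricted to ±150 s around the expected retention time — wide relative
  to both peak widths (≤ 80 s) and alignment residuals (~1–2 s).
* **Multipass detection.** Candidate apexes come from
  continuous-wavelet-transform ridge detection (`scipy.signal.
  find_peaks_cwt`, Ricker wavelet) with per-pass scale grids spanning half
  the pass's minimum width up to half the maximum width. Passes run widest
  minimum first ({20, 15, 10, 6, 4, 2} s) so that broad peaks are not
  fragmented by narrow scales; the first pass producing a candidate above
  the S/N gate wins. Among candidates, the apex nearest the expected RT is
  chosen (highest apex when no expectation exists).
* **Noise model.** Baseline and noise are estimated from the lower 80% of
  trace intensities: baseline = median, noise SD = 84.1th-percentile excess
  over baseline. Quantile estimation is used because sparse centroid SICs
  have zero-inflated baselines on which MAD-type estimators collapse to
  zero. The SD is floored at 1/1000 of the trace's dynamic range rather
  than at an absolute count, which makes every derived threshold
  homogeneous in intensity: rescaling a run rescales every area exactly and
  leaves the spike-normalized matrix unchanged to floating-point precision.
  S/N is (apex − baseline)/SD, gated at 10.
* **Peak limits.** From the apex, each side walks outward on the raw trace
  tracking the running minimum; it stops when intensity reaches
  baseline + 0.5·SD, or at a *sustained* rise — two consecutive samples
  exceeding the running minimum by max(3·SD, 2% of apex). The two-sample
  requirement is what makes the slope-sign-flip criterion robust to
  single-sample noise excursions, which otherwise truncate peaks near the
  apex. Total width is capped at 80 s around the apex.
* **Integration.** Trapezoidal area of the segment above the constant
  baseline level (clipped at zero). A constant background was chosen over
  interpolating a line between the descent endpoints: under noise the
  endpoints sit on the peak flanks at ≈ 0.5–1 noise SD, and an
  endpoint-interpolated baseline removes several percent of genuine peak
  area (up to ~10% at S/N near the gate) while the constant background is
  unbiased on flat baselines. Validated against the analytic Gaussian
  area: ≥ 95% of a 500-peak batch within 5% for noise SDs up to
  amplitude/15. At S/N exactly 10 the irreducible stochastic error of a
  trapezoidal integral (noise SD × √width) alone approaches the 5% band
  for narrow peaks, so "moderate noise" is operationalized as S/N ≥ 15 in
  that validation batch.
* **Fallback.** When no candidate clears the gate, a fixed ±40 s region
  (half the maximum width) around the SIC maximum is integrated without
  baseline subtraction, mirroring the simple pre-defined-region
  integration used as a rescue path in this methodology.
* **Noise floor.** Any raw area below 1000 intensity·s is flagged
  `below_noise` and treated as missing, uniformly for detected, fallback
  and backfilled areas (the floor is applied to raw, pre-normalization
  areas since it represents a spectral-noise-level area).

## Retention-time alignment and backfill

The reference run is the one with the most confident identifications.
For each other run, anchor pairs (reference RT, run RT) are the per-peptide
median observed RTs of shared identifications; the mapping is a lowess fit
(`frac` = 0.3, 2 robustness iterations) post-processed by isotonic
regression plus an ε-ramp to strict monotonicity, linearly extrapolated
beyond the anchor range, and inverted by coordinate exchange. Runs with
fewer than 20 anchors fall back to the identity warp with a warning. On
synthetic warps (shift ≤ 20 s, linear ≤ 1%, quadratic ≤ 60 s amplitude,
100 anchors with 1 s observation noise) a constant 30 s shift is recovered
within ±2 s everywhere and the median residual under a 60 s quadratic warp
is ≈ 1 s (requirement: < 5 s).

Backfill (match-between-runs): a peptide missing its MS/MS identification
in a run is quantified at the expected RT obtained by mapping each peer
apex into reference coordinates through its own warp's inverse, taking the
median, and mapping out through the target run's warp. Detection then
proceeds exactly as for identified peptides (expected-RT-guided multipass,
then fallback), and the provenance is recorded as `backfill`. Peptides
quantified in no run at all are absent from the matrix. Because backfilled
areas pass the same 1000 noise floor, truly absent peptides (ground-truth
area 0) are reported above the floor in ≤ 1% of runs at default noise —
backfill repairs dropout without fabricating signal.

## Normalization

Each run's areas are divided by the spiked standard's area in that run
(phosphorylated angiotensin II, DRVpYIHPF, monoisotopic 1125.50084 Da,
charge 2 by default). A run whose spike is missing or below the noise
floor has no valid normalization basis and aborts the pipeline by default,
naming the run.

## Replicate statistics

* Technical replicates are averaged (arithmetic mean of available values)
  into one column per biological sample; a cell is missing only when all
  technical replicates are missing.
* COV = sample SD (n−1) / mean on normalized, untransformed areas (a COV
  of log values is not a COV); undefined when n < 2 or mean ≤ 0, and such
  cases are excluded rather than imputed. Both levels are reported:
  technical-within-biological and biological-within-group.
* Detection overlap: exact region counts of the Venn partition over
  per-biological-replicate (or per-group) MS/MS-detection sets, plus
  "detected in ≥ k of n" tallies; region counts sum to the union size by
  construction.
* PCA runs on log2 abundances (abundances are multiplicative), centered
  per peptide, unscaled — matching the convention of R's `prcomp` with
  default arguments on log data. Missing cells are imputed with half the
  peptide's minimum observed value (configurable: `drop` removes
  incomplete rows). Scores are U·S from the SVD of the samples × peptides
  matrix; variance fractions are singular values squared over their total.

## Differential abundance

Per peptide, a one-way fixed-effects ANOVA on log2 biological-replicate
means; peptides without at least two groups having two or more values are
skipped with a recorded reason, and no imputation is done. Pairwise
contrasts use the pooled residual variance from the same fit
(`t = Δmean / √(s²(1/n₁ + 1/n₂))`), so contrast and omnibus inference are
consistent. Contrast labels read `X_vs_Y` = X relative to Y
(log2 FC = mean(X) − mean(Y)).

Variance moderation (default on) shrinks per-peptide residual variances
toward a pooled prior via the scaled inverse-chi-square hierarchical model:
prior df `d₀` and prior variance `s₀²` are moment-matched on the log scale
(trigamma inversion by Newton iteration), posterior variances are
`(d₀s₀² + df·s²)/(d₀ + df)`, and test df become `df + d₀` (normal/χ²
limits when `d₀ = ∞`, i.e. when observed variances are homogeneous). Plain
ANOVA (`moderated=False`) is the mode with exactly nominal finite-sample
calibration and is what the null simulations use; it agrees with
`scipy.stats.f_oneway` to relative 1e-9 in tests.

Adjustment is Benjamini–Hochberg step-up applied within each contrast
across peptides (Holm available); significance is strictly q < 0.05. The
pathway-input export lists proteins with ≥ 2 significant peptides per
contrast.

## Reporting

Heat-map values are per-peptide ratios of each biological sample's mean to
the mean of the control-group samples; peptides with missing or
non-positive control means are excluded with reasons. Only proteins with
≥ 5 quantified peptides are displayed. Rendering clamps colors to
[0.2, 5.0] on a log scale with white at 1.0; stored tables are never
clamped.

"Consistent over-abundance" — the marker rule — is not quantified in the
methodology this pipeline reproduces, so it is an explicit, configurable
decision: a protein qualifies when the median of its peptide ratios
exceeds 1.5 in *every* biological replicate of at least one target group
(threshold, replicate fraction and summary statistic configurable). At a
planted 3× effect with default noise this rule recovers planted markers
with sensitivity and specificity 1.0 on 212-protein studies; the margin
degrades as the effect approaches 1×.

## Synthetic-data generator

What it emulates: the 48-run design; peptides grouped into proteins with
per-group abundance multipliers (differential proteins split into
up-regulated, marker-like, and down-regulated, drug-metabolism-like, in
the two focal groups); multiplicative log-normal noise with separate
biological (log-SD 0.30) and technical (log-SD 0.48) components, tuned so
measured technical-within-biological COVs land in the 0.4–0.5 band; a
per-run global intensity scale (log-SD 0.15); per-run monotone quadratic
RT warps (shift ≤ 20 s, slope ≤ 1%, quadratic ≤ 30 s, total ≲ 60 s);
Gaussian chromatographic peaks (σ 3–6 s, optional exponential tailing) on
a 1 s scan grid; ppm-scale mass errors (2 ppm systematic per peptide-run,
0.5 ppm per centroid); Bernoulli MS/MS dropout (default 20%); duplicate
PSMs; decoy PSMs with scores from a null distribution (Normal(18, 6))
shifted below targets (Normal(35, 8), both truncated at 0 — only the
ordering matters); and a spike peptide present and identified in every
run. Base areas are log-normal around 4·10⁴ intensity·s with a 5·10³
floor, about 40× the noise floor.

What it does **not** emulate: isotope envelopes and charge-state overlap,
profile-mode peak shapes, chimeric/interfering peaks in the SIC window,
FFPE chemical artifacts, intensity-dependent (heteroscedastic) detector
noise, correlated peptide noise within a protein, and realistic dynamic
range (full-scale studies of this kind identify thousands of peptides over
≥ 4 orders of magnitude; desk-scale defaults use hundreds over ~2). Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical structure, not performance on any particular instrument's
data.

Problem sizes in tests and in `scripts/acceptance.py` (default study of
60 proteins × 5 peptides × 48 runs; 10 000-peptide null simulations;
212-protein marker studies; 500-peak area batches) are the package's
validation scale, chosen so the whole suite runs on a laptop CPU in a few
minutes.

## Other decisions and limitations

* Peptide species are keyed by `peptide_id` (sequence + modifications);
  when PSMs of one peptide appear at several charge states the modal
  charge defines the extraction m/z. Charge-state-resolved quantitation
  would key on (peptide, z); the abundance matrix interface would be
  unchanged.
* The analysis runs on biological-replicate means per the explicit
  averaging convention; a run-level mode exists
  (`anova_per_peptide` accepts any column design) but is not the default.
* Config round-trips losslessly through YAML; all stage outputs are TSV
  with schemas in `sicquant.io.SCHEMAS`, and a MANIFEST with SHA-256
  checksums supports byte-level reproducibility checks (same config + seed
  ⇒ identical checksums).
* mzML support is a compatibility layer (centroid MS1 only, 32/64-bit,
  zlib or plain, seconds or minutes): the writer emits minimal documents
  that Bioconductor's mzR parses identically (cross-checked in tests);
  profile-mode input is rejected with instructions to centroid first.
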