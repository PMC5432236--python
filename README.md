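# sicquant

Label-free LC-MS/MS peptide quantitation by selected-ion-chromatogram (SIC)
peak areas, with differential-abundance analysis — the kind of pipeline used
to compare proteomes of laser-capture-microdissected tissue regions (for
example preneoplastic liver foci against normal liver) across a
groups × biological-replicates × technical-replicates design.

It is written for proteomics analysts who have centroided MS1 data plus a
peptide-spectrum-match (PSM) table from a database search, and for method
developers who want a fully synthetic, ground-truthed test bed for
label-free quantitation machinery.

## What it computes

Starting from PSMs and centroided runs (or from its own simulator):

1. **PSM filtering** — duplicate matches of one spectrum collapse to the
   highest-scoring record; matches with score ≤ 20 are removed (strict
   boundary); the remainder is thresholded at the most permissive score
   cutoff *s* with estimated FDR
   `#decoys(score ≥ s) / #targets(score ≥ s) ≤ 1%`.
2. **SIC quantitation** — for each confident peptide and run, the SIC at the
   peptide's computed m/z within ±10 ppm is integrated. Peaks are found by
   multiple passes of continuous-wavelet-transform ridge detection over
   progressively narrower minimum widths (20 → 2 s, maximum width 80 s,
   S/N ≥ 10), with peak limits located by descent from the apex on the raw
   trace; when detection fails, a fixed ±40 s window around the SIC maximum
   is integrated instead.
3. **Alignment and backfill** — runs are aligned in retention time by robust
   locally weighted regression on shared identifications (made monotone by
   isotonic post-processing); peptides lacking an MS/MS identification in a
   run are backfilled at the alignment-predicted retention time
   (match-between-runs). A minimum SIC area of 1000 (typical spectral noise
   level) is required of every reported value.
4. **Normalization** — every peak area is divided by the area of the
   exogenously spiked standard peptide (DRVpYIHPF) in the same run.
5. **Statistics** — technical replicates are averaged per biological sample;
   coefficients of variation, detection-overlap (Venn) counts and PCA are
   computed; per peptide, a one-way ANOVA on log2 abundances (optionally
   with empirical-Bayes variance moderation) yields all pairwise group
   contrasts, Benjamini–Hochberg adjusted; significance is q < 0.05
   (strict).
6. **Reporting** — per-peptide ratios of each biological sample to the
   control-group mean (heat-map tables, ≥ 5 quantified peptides per protein
   shown), a candidate-marker panel (proteins consistently over-abundant in
   a target group), and the ≥ 2-significant-peptide protein list used as
   pathway-analysis input.

The synthetic module generates the whole study — 4 groups × 3 biological ×
4 technical replicates = 48 centroided runs, peptides with planted fold
changes, RT drift, ppm mass error, MS/MS dropout, decoys, spike — together
with the ground truth, so every stage can be validated quantitatively.

## Worked example

```python
import sicquant as sq
from sicquant.synthetic import CatalogParams
from sicquant.stats import average_technical_replicates, cov_summary
from sicquant.differential import anova_per_peptide, significant_protein_rollup

runs, psms, truth = sq.generate_study(
    catalog_params=CatalogParams(n_proteins=15), seed=42)
print(f"simulated {len(runs)} runs, {len(psms)} PSMs "
      f"({int(psms.is_decoy.sum())} decoys)")

confident, report = sq.filter_chain(psms, min_score=20.0, fdr_level=0.01)
print(f"confident PSMs: {report.n_retained_targets} of {report.n_input} "
      f"(score cutoff {report.score_cutoff_used:.1f}, "
      f"estimated FDR {report.estimated_fdr_at_cutoff:.4f})")

matrix, quants = sq.quantify_study(runs, confident, sq.StudyDesign())
print(f"abundance matrix: {matrix.values.shape[0]} peptides x "
      f"{matrix.values.shape[1]} runs, "
      f"completeness {100 * matrix.completeness():.1f}%")

cov = cov_summary(matrix, level="technical-within-biological")
print(f"technical COV: mean {cov.mean_cov:.2f}, median {cov.median_cov:.2f}")

bio = average_technical_replicates(matrix)
res, _ = anova_per_peptide(bio)
sig = res[(res.contrast == "placebo_vs_control") & res.significant]
roll = significant_protein_rollup(res, 2, "placebo_vs_control")
print(f"placebo vs control: {len(sig)} significant peptides, "
      f"{len(roll)} proteins with >= 2 significant peptides")
```

prints:

```
simulated 48 runs, 4988 PSMs (1151 decoys)
confident PSMs: 2171 of 4988 (score cutoff 31.1, estimated FDR 0.0097)
abundance matrix: 75 peptides x 48 runs, completeness 100.0%
technical COV: mean 0.43, median 0.42
placebo vs control: 12 significant peptides, 3 proteins with >= 2 significant peptides
```

Reading the numbers: of 4,988 simulated PSMs, 2,171 targets survive the
dedup → score → 1% FDR chain; all 75 catalog peptides are quantified in all
48 runs (MS/MS dropout is repaired by backfill); the technical
coefficient of variation sits in the 0.4–0.5 band the generator emulates;
and the differential stage recovers the proteins whose abundance was
planted 3× higher in the focal-lesion groups.

The same flow is available from the shell:

```bash
sicquant run-all --seed 42 --out out/        # simulate + full analysis
sicquant simulate --seed 1 --out sim/        # runs/, psms.tsv, ground truth
sicquant filter-psms --psms sim/psms.tsv --min-score 20 --fdr 0.01 --out filt/
```

Outputs are tab-separated tables with documented schemas
(`sicquant.io.SCHEMAS`) plus a `MANIFEST.tsv` of per-file checksums; runs
can also be exchanged as minimal centroid-MS1 mzML.

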