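"""End-to-end pipeline driver.

Runs simulate -> filter-psms -> quantify -> stats -> diff -> report, writing
every stage's table, a structured log, and a MANIFEST with per-file
checksums. Deterministic given the seed: the same configuration and seed
yield byte-identical outputs.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff_mod
from . import io as io_mod
from . import reporting, stats, synthetic
from .core import StudyDesign
from .psm import filter_chain
from .quant import AbundanceMatrix, quantify_study

__all__ = ["StageError", "run_pipeline", "matrix_to_table", "table_to_matrix",
           "bio_matrix_to_table", "table_to_bio_matrix", "detection_sets"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def matrix_to_table(matrix: AbundanceMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    vals = matrix.values.copy()
    vals.insert(0, "protein_id", matrix.peptide_protein)
    vals = vals.reset_index().rename(columns={"index": "peptide_id"})
    vals.columns.name = None
    prov = matrix.provenance.reset_index().rename(columns={"index": "peptide_id"})
    prov.columns.name = None
    return vals, prov


def table_to_matrix(vals: pd.DataFrame, prov: pd.DataFrame | None,
                    design: StudyDesign) -> AbundanceMatrix:
    pp = vals.set_index("peptide_id")["protein_id"]
    values = vals.set_index("peptide_id").drop(columns="protein_id")
    if prov is not None:
        provenance = prov.set_index("peptide_id").reindex(values.index).fillna("")
    else:
        provenance = pd.DataFrame("", index=values.index, columns=values.columns)
    return AbundanceMatrix(values, provenance, pp, design)


def bio_matrix_to_table(bio: stats.BioReplicateMatrix) -> pd.DataFrame:
    out = bio.values.copy()
    out.insert(0, "protein_id", bio.peptide_protein)
    out = out.reset_index().rename(columns={"index": "peptide_id"})
    out.columns.name = None
    return out


def table_to_bio_matrix(df: pd.DataFrame, design: StudyDesign) -> stats.BioReplicateMatrix:
    pp = df.set_index("peptide_id")["protein_id"]
    values = df.set_index("peptide_id").drop(columns="protein_id")
    n_tech = values.notna().astype(int)
    return stats.BioReplicateMatrix(values, n_tech, pp, design)


def detection_sets(matrix: AbundanceMatrix, design: StudyDesign,
                   by: str = "bio") -> dict[str, dict[str, set]]:
    """Peptides detected by MS/MS (not backfill), per biological replicate
    of each group, and per group overall."""
    run_tab = design.run_table()
    msms = matrix.provenance.isin(["wavelet", "fallback"]) & matrix.values.notna()
    per_group: dict[str, dict[str, set]] = {}
    group_sets: dict[str, set] = {}
    for g in design.groups:
        per_group[g] = {}
        for b in range(1, design.n_biological + 1):
            runs = run_tab[(run_tab["group"] == g)
                           & (run_tab["biological"] == b)]["run_id"]
            cols = [r for r in runs if r in msms.columns]
            det = set(matrix.values.index[msms[cols].any(axis=1)]) if cols else set()
            per_group[g][design.bio_id(g, b)] = det
        group_sets[g] = set().union(*per_group[g].values())
    per_group["__groups__"] = group_sets
    return per_group


def run_pipeline(config: io_mod.PipelineConfig, out_dir, seed: int = 0,
                 input_dir=None, log_level: str = "INFO") -> dict[str, Path]:
    """Execute the full pipeline into ``out_dir``; returns written paths.

    With ``input_dir`` given, centroid runs and a PSM table are read from it
    instead of being simulated (expects ``runs/`` and ``psms.tsv``).
    Any stage failure aborts with :class:`StageError`; partial outputs stay
    on disk and the MANIFEST notes the incompleteness.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = io_mod.get_logger(log_level)
    written: dict[str, Path] = {}
    design = config.design
    stage = "setup"

    def manifest(status: str):
        rows = []
        for name, p in sorted(written.items()):
            n_rows = (sum(1 for _ in open(p)) - 1) if p.suffix == ".tsv" else -1
            rows.append({"file": p.name, "sha256": io_mod.sha256_of(p),
                         "n_rows": n_rows, "status": status})
        io_mod.write_table(pd.DataFrame(rows, columns=io_mod.SCHEMAS["manifest"]),
                           out / "MANIFEST.tsv", "manifest")

    try:
        # -------------------------------------------------- simulate / load
        stage = "simulate" if input_dir is None else "load"
        t0 = time.perf_counter()
        if input_dir is None:
            runs, psms, truth = synthetic.generate_study(
                design, config.catalog, config.noise, seed)
            written["ground_truth"] = io_mod.write_table(
                truth.truth, out / "ground_truth.tsv", "ground_truth")
            written["truth_runs"] = io_mod.write_table(
                truth.runs, out / "truth_runs.tsv", "truth_runs")
            if config.write_runs:
                io_mod.write_runs(runs, out / "runs")
        else:
            runs = io_mod.read_centroid_runs(Path(input_dir) / "runs")
            psms = io_mod.read_table(Path(input_dir) / "psms.tsv")
        written["psms"] = io_mod.write_table(psms, out / "psms.tsv", "psms")
        io_mod.log_stage(logger, stage, n_runs=len(runs), n_psms=len(psms),
                         wall_s=round(time.perf_counter() - t0, 2))

        # -------------------------------------------------- filter-psms
        stage = "filter-psms"
        t0 = time.perf_counter()
        confident, report = filter_chain(psms, config.min_score,
                                         config.fdr_level, config.filter_order)
        written["confident_psms"] = io_mod.write_table(
            confident, out / "confident_psms.tsv", "psms")
        written["filter_report"] = io_mod.write_table(
            pd.DataFrame([vars(report)]), out / "filter_report.tsv",
            "filter_report")
        io_mod.log_stage(logger, stage, n_in=len(psms), n_out=len(confident),
                         cutoff=report.score_cutoff_used,
                         wall_s=round(time.perf_counter() - t0, 2))

        # -------------------------------------------------- quantify
        stage = "quantify"
        t0 = time.perf_counter()
        matrix, quants = quantify_study(runs, confident, design, config.quant)
        qdf = pd.DataFrame([{
            "peptide_id": q.peptide_id, "run_id": q.run_id,
            "rt_start": q.rt_start, "rt_apex": q.rt_apex, "rt_end": q.rt_end,
            "raw_area": q.raw_area, "normalized_area": q.normalized_area,
            "method": q.method, "below_noise": q.below_noise} for q in quants])
        written["peak_quants"] = io_mod.write_table(
            qdf, out / "peak_quants.tsv", "peak_quants")
        vals, prov = matrix_to_table(matrix)
        written["abundance_matrix"] = io_mod.write_table(
            vals, out / "abundance_matrix.tsv", "abundance_matrix")
        written["provenance_matrix"] = io_mod.write_table(
            prov, out / "provenance_matrix.tsv", "provenance_matrix")
        io_mod.log_stage(logger, stage, n_quants=len(quants),
                         completeness=round(matrix.completeness(), 4),
                         wall_s=round(time.perf_counter() - t0, 2))

        # -------------------------------------------------- stats
        stage = "stats"
        t0 = time.perf_counter()
        bio = stats.average_technical_replicates(matrix, design)
        written["bio_matrix"] = io_mod.write_table(
            bio_matrix_to_table(bio), out / "bio_matrix.tsv", "bio_matrix")
        cov_rows = []
        for level in ("technical-within-biological", "biological-within-group"):
            cs = stats.cov_summary(matrix, design, level)
            per = cs.per_unit.copy()
            per.insert(0, "level", level)
            cov_rows.append(per)
        written["cov_summary"] = io_mod.write_table(
            pd.concat(cov_rows, ignore_index=True)[io_mod.SCHEMAS["cov_summary"]],
            out / "cov_summary.tsv", "cov_summary")
        det = detection_sets(matrix, design)
        venn_rows = []
        for g in design.groups:
            v = stats.detection_overlap(det[g])
            v.insert(0, "scope", g)
            venn_rows.append(v)
        v = stats.detection_overlap(det["__groups__"])
        v.insert(0, "scope", "groups")
        venn_rows.append(v)
        written["venn_counts"] = io_mod.write_table(
            pd.concat(venn_rows, ignore_index=True), out / "venn_counts.tsv",
            "venn_counts")
        scores, var_frac = stats.pca_scores(bio, log2=config.log2,
                                            impute=config.pca_impute)
        pca_rows = [{"sample_id": s, "component": c,
                     "score": scores.loc[s, c], "variance_fraction": var_frac[c]}
                    for s in scores.index for c in scores.columns]
        written["pca_scores"] = io_mod.write_table(
            pd.DataFrame(pca_rows), out / "pca_scores.tsv", "pca_scores")
        io_mod.log_stage(logger, stage, n_peptides=len(bio.values),
                         wall_s=round(time.perf_counter() - t0, 2))

        # -------------------------------------------------- diff
        stage = "diff"
        t0 = time.perf_counter()
        results, skipped = diff_mod.anova_per_peptide(
            bio, design, moderated=config.moderated, log2=config.log2,
            alpha=config.alpha, adjust_method=config.adjust_method)
        written["differential"] = io_mod.write_table(
            results, out / "differential.tsv", "differential")
        rollup = diff_mod.significant_protein_rollup(
            results, config.rollup_min_peptides)
        written["pathway_input"] = io_mod.write_table(
            rollup, out / "pathway_input.tsv", "pathway_input")
        io_mod.log_stage(logger, stage, n_tested=results["peptide_id"].nunique(),
                         n_skipped=len(skipped),
                         n_significant=int(results["significant"].sum()),
                         wall_s=round(time.perf_counter() - t0, 2))

        # -------------------------------------------------- report
        stage = "report"
        t0 = time.perf_counter()
        heat = reporting.ratio_to_control(bio, config.control_group)
        heat5 = reporting.filter_min_peptides(heat, config.heatmap_min_peptides)
        hdf = heat5.ratios.copy()
        hdf.insert(0, "protein_id", heat5.peptide_protein)
        hdf = hdf.reset_index().rename(columns={"index": "peptide_id"})
        hdf.columns.name = None
        written["heatmap_ratios"] = io_mod.write_table(
            hdf, out / "heatmap_ratios.tsv", "heatmap_ratios")
        panel = reporting.extract_marker_panel(
            heat5, config.target_groups,
            reporting.MarkerRule(threshold=config.marker_threshold))
        written["marker_panel"] = io_mod.write_table(
            panel, out / "marker_panel.tsv", "marker_panel")
        if config.render_heatmap and len(heat5.ratios):
            reporting.render_heatmap(heat5, out / "heatmap.png")
        io_mod.log_stage(logger, stage, n_heatmap_peptides=len(heat5.ratios),
                         n_markers=len(panel),
                         wall_s=round(time.perf_counter() - t0, 2))
    except Exception as e:
        manifest(f"incomplete:failed_at={stage}")
        raise StageError(stage, e) from e

    manifest("complete")
    written["MANIFEST"] = out / "MANIFEST.tsv"
    return written
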