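"""Ratio-to-control heat maps and candidate-marker extraction.

Each biological sample's technical-replicate mean abundance is expressed as
a ratio to the mean of the control-group samples, peptide by peptide.
Display clamps the color ramp to [0.2, 5.0] with white at 1.0 but never
alters the stored ratios. Proteins shown must have at least 5 quantified
peptides; candidate markers are proteins whose peptide-level median ratio
exceeds a threshold in every biological replicate of at least one target
group ("consistent over-abundance").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StudyDesign
from .stats import BioReplicateMatrix

__all__ = [
    "RatioHeatmap",
    "MarkerRule",
    "ratio_to_control",
    "filter_min_peptides",
    "extract_marker_panel",
    "render_heatmap",
]

CLAMP_LO, CLAMP_MID, CLAMP_HI = 0.2, 1.0, 5.0


@dataclass
class RatioHeatmap:
    """Peptide x biological-sample ratios to the control-group mean."""

    ratios: pd.DataFrame            # stored unclamped
    peptide_protein: pd.Series
    control_group: str
    design: StudyDesign
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def group_columns(self, group: str) -> list[str]:
        return [b for b in self.ratios.columns
                if self.design.group_of_bio(b) == group]


@dataclass(frozen=True)
class MarkerRule:
    """Operationalization of "consistent over-abundance".

    A protein qualifies when ``summary`` (median by default) of its peptide
    ratios exceeds ``threshold`` in at least ``min_replicate_fraction`` of
    the biological replicates of at least one target group (all replicates
    by default).
    """

    threshold: float = 1.5
    min_replicate_fraction: float = 1.0
    summary: str = "median"  # median | mean


def ratio_to_control(bio_matrix: BioReplicateMatrix,
                     control_group: str) -> RatioHeatmap:
    """Per-peptide ratio of every biological sample to the control mean.

    Peptides whose control-group mean is missing or non-positive are
    excluded, with the reason recorded.
    """
    design = bio_matrix.design
    if control_group not in design.groups:
        raise ValueError(f"unknown control group {control_group!r}")
    ctrl_cols = bio_matrix.group_columns(control_group)
    ctrl_mean = bio_matrix.values[ctrl_cols].mean(axis=1)
    bad = ctrl_mean.isna() | (ctrl_mean <= 0)
    excluded = pd.DataFrame({
        "peptide_id": bio_matrix.values.index[bad],
        "reason": np.where(ctrl_mean[bad].isna(),
                           "control mean missing", "control mean <= 0")})
    ratios = bio_matrix.values.loc[~bad].div(ctrl_mean[~bad], axis=0)
    return RatioHeatmap(ratios, bio_matrix.peptide_protein.reindex(ratios.index),
                        control_group, design, excluded)


def filter_min_peptides(heatmap: RatioHeatmap,
                        min_peptides: int = 5) -> RatioHeatmap:
    """Keep only proteins with at least ``min_peptides`` quantified peptides."""
    pp = heatmap.peptide_protein
    counts = pp.groupby(pp).size()
    keep_prot = set(counts[counts >= min_peptides].index)
    keep = pp.isin(keep_prot)
    return RatioHeatmap(heatmap.ratios.loc[keep.to_numpy()],
                        pp[keep.to_numpy()], heatmap.control_group,
                        heatmap.design, heatmap.excluded)


def extract_marker_panel(heatmap: RatioHeatmap,
                         target_groups: tuple[str, ...] = ("placebo", "rapamycin"),
                         rule: MarkerRule | None = None,
                         exclude_proteins: set[str] | None = None) -> pd.DataFrame:
    """Proteins consistently over-abundant in at least one target group.

    ``exclude_proteins`` removes panels handled upstream (known markers,
    enzyme families). Returns a table of protein_id, qualifying group(s)
    and the per-group minimum of the per-replicate summary ratios.
    """
    rule = rule or MarkerRule()
    exclude = exclude_proteins or set()
    summarize = {"median": np.median, "mean": np.mean}[rule.summary]
    rows = []
    pp = heatmap.peptide_protein
    for prot, idx in pp.groupby(pp).groups.items():
        if prot in exclude:
            continue
        sub = heatmap.ratios.loc[idx]
        qualifying = []
        stats = {}
        for g in target_groups:
            cols = heatmap.group_columns(g)
            if not cols:
                continue
            per_rep = np.array([summarize(sub[c].dropna().to_numpy())
                                if sub[c].notna().any() else np.nan
                                for c in cols])
            ok = per_rep > rule.threshold
            frac = np.mean(ok) if per_rep.size else 0.0
            stats[g] = float(np.nanmin(per_rep)) if np.all(~np.isnan(per_rep)) else np.nan
            if per_rep.size and not np.any(np.isnan(per_rep)) \
                    and frac >= rule.min_replicate_fraction:
                qualifying.append(g)
        if qualifying:
            row = {"protein_id": prot, "groups": "|".join(qualifying),
                   "n_peptides": len(idx)}
            row.update({f"min_summary_ratio_{g}": stats.get(g, np.nan)
                        for g in target_groups})
            rows.append(row)
    cols = ["protein_id", "groups", "n_peptides"] + [
        f"min_summary_ratio_{g}" for g in target_groups]
    return (pd.DataFrame(rows, columns=cols)
            .sort_values("protein_id").reset_index(drop=True))


def render_heatmap(heatmap: RatioHeatmap, path: str) -> None:
    """Render the ratio matrix as a blue-white-red image, clamped [0.2, 5].

    The color scale is log-linear with white at ratio 1.0; clamping affects
    the rendering only, never the stored ratios.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, LogNorm

    data = heatmap.ratios.clip(lower=CLAMP_LO, upper=CLAMP_HI)
    cmap = LinearSegmentedColormap.from_list("ratio", ["#00008b", "white", "#d40000"])
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * data.shape[1]), max(4, 0.02 * data.shape[0])))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap,
                   norm=LogNorm(vmin=CLAMP_LO, vmax=CLAMP_HI))
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{data.shape[0]} peptides")
    fig.colorbar(im, ax=ax, label="ratio to control mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
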