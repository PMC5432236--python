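"""Replicate reproducibility statistics.

Technical-replicate averaging to biological-sample means, coefficients of
variation at both replicate levels, detection-overlap (Venn) counts, and
principal-component scores of the biological-sample abundance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import StudyDesign
from .quant import AbundanceMatrix

__all__ = [
    "BioReplicateMatrix",
    "CovSummary",
    "average_technical_replicates",
    "compute_cov",
    "cov_summary",
    "detection_overlap",
    "pca_scores",
]


@dataclass
class BioReplicateMatrix:
    """Peptides x biological samples of technical-replicate mean abundances."""

    values: pd.DataFrame          # columns = bio_ids
    n_technical: pd.DataFrame     # how many technical values entered each mean
    peptide_protein: pd.Series
    design: StudyDesign

    def group_columns(self, group: str) -> list[str]:
        return [b for b in self.values.columns
                if self.design.group_of_bio(b) == group]


@dataclass
class CovSummary:
    level: str                    # technical-within-biological | biological-within-group
    per_unit: pd.DataFrame        # peptide_id, unit (bio_id or group), cov
    mean_cov: float
    median_cov: float


def average_technical_replicates(matrix: AbundanceMatrix,
                                 design: StudyDesign | None = None) -> BioReplicateMatrix:
    """Average technical replicates into one column per biological sample.

    Missing technical values are excluded from the mean; a cell is missing
    only when all of its technical replicates are missing.
    """
    design = design or matrix.design
    run_map = design.run_table().set_index("run_id")["bio_id"]
    unknown = [c for c in matrix.values.columns if c not in run_map.index]
    if unknown:
        raise ValueError(f"runs not in design: {unknown}")
    groups = matrix.values.T.groupby(run_map.reindex(matrix.values.columns))
    means = groups.mean().T.reindex(columns=design.bio_ids)
    counts = groups.count().T.reindex(columns=design.bio_ids).fillna(0).astype(int)
    return BioReplicateMatrix(means, counts, matrix.peptide_protein, design)


def compute_cov(values) -> float | None:
    """Coefficient of variation: sample (n-1) SD over mean.

    Returns ``None`` (excluded) when fewer than two values are available or
    the mean is not positive.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 2:
        return None
    m = v.mean()
    if m <= 0:
        return None
    return float(v.std(ddof=1) / m)


def cov_summary(matrix: AbundanceMatrix, design: StudyDesign | None = None,
                level: str = "technical-within-biological") -> CovSummary:
    """Per-peptide COVs at one replicate level, with mean/median summaries.

    ``technical-within-biological``: COV across the technical replicates of
    each biological sample. ``biological-within-group``: COV across each
    group's biological-sample means (technical replicates averaged first).
    """
    design = design or matrix.design
    rows = []
    if level == "technical-within-biological":
        run_map = design.run_table().set_index("run_id")["bio_id"]
        for bio_id in design.bio_ids:
            cols = [r for r in matrix.values.columns if run_map.get(r) == bio_id]
            sub = matrix.values[cols]
            for pid, vals in sub.iterrows():
                c = compute_cov(vals)
                if c is not None:
                    rows.append({"peptide_id": pid, "unit": bio_id, "cov": c})
    elif level == "biological-within-group":
        bio = average_technical_replicates(matrix, design)
        for g in design.groups:
            sub = bio.values[bio.group_columns(g)]
            for pid, vals in sub.iterrows():
                c = compute_cov(vals)
                if c is not None:
                    rows.append({"peptide_id": pid, "unit": g, "cov": c})
    else:
        raise ValueError(f"unknown COV level {level!r}")
    per = pd.DataFrame(rows, columns=["peptide_id", "unit", "cov"])
    covs = per["cov"].to_numpy()
    return CovSummary(level, per,
                      float(covs.mean()) if covs.size else np.nan,
                      float(np.median(covs)) if covs.size else np.nan)


def detection_overlap(sets: dict[str, set]) -> pd.DataFrame:
    """Counts for every region of the Venn partition plus >=k-of-n tallies.

    ``sets`` maps a sample/group label to its detected identifier set.
    Returns a tidy table: one row per non-trivial subset with the count of
    identifiers detected in exactly that subset (``region``) and in at least
    that subset (``containing``), plus ``at_least_k`` rows.
    """
    labels = list(sets.keys())
    universe = set().union(*sets.values()) if sets else set()
    membership = {e: frozenset(l for l in labels if e in sets[l]) for e in universe}
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            fs = frozenset(combo)
            exact = sum(1 for m in membership.values() if m == fs)
            containing = sum(1 for m in membership.values() if fs <= m)
            rows.append({"kind": "region", "subset": "&".join(combo),
                         "n_sets": r, "count": exact, "containing": containing})
    counts = pd.Series([len(m) for m in membership.values()], dtype=int)
    for k in range(1, len(labels) + 1):
        rows.append({"kind": "at_least_k", "subset": f">={k}", "n_sets": k,
                     "count": int((counts >= k).sum()) if len(counts) else 0,
                     "containing": np.nan})
    return pd.DataFrame(rows)


def pca_scores(bio_matrix: BioReplicateMatrix, log2: bool = True,
               impute: str = "half_min", scale: bool = False):
    """Principal components of biological samples over peptide abundances.

    Abundances are log2-transformed (data are multiplicative) and centered
    per peptide; scaling to unit variance is off by default. Missing cells
    are imputed with half the peptide's minimum observed value
    (``impute='half_min'``) or the incomplete peptide rows are dropped
    (``impute='drop'``). Returns ``(scores, variance_fractions)`` where
    ``scores`` is a samples x components DataFrame.
    """
    X = bio_matrix.values.copy()
    if impute == "half_min":
        X = X.apply(lambda row: row.fillna(0.5 * row.min()), axis=1)
        X = X.dropna(axis=0, how="any")  # rows that were all-missing
    elif impute == "drop":
        X = X.dropna(axis=0, how="any")
    else:
        raise ValueError(f"unknown imputation {impute!r}")
    if X.shape[1] < 2 or X.shape[0] < 1:
        raise ValueError("PCA needs at least two samples and one peptide")
    M = np.log2(X.to_numpy(dtype=float).T) if log2 else X.to_numpy(dtype=float).T
    M = M - M.mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant peptide rows cannot be scaled")
        M = M / sd
    if not np.any(M != 0):
        raise ValueError("matrix is constant; PCA is degenerate")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    n_comp = min(M.shape[0] - 1, M.shape[1]) or 1
    U, S = U[:, :n_comp], S[:n_comp]
    scores = pd.DataFrame(U * S, index=X.columns,
                          columns=[f"PC{i + 1}" for i in range(n_comp)])
    total = float(np.sum(np.linalg.svd(M, compute_uv=False) ** 2))
    var_frac = pd.Series(S ** 2 / total, index=scores.columns)
    return scores, var_frac
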