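"""Per-peptide differential abundance across groups.

One-way fixed-effects ANOVA on log2-transformed biological-replicate means,
with all pairwise group contrasts from the same fit, Benjamini-Hochberg
(or Holm) adjustment per contrast, volcano tables, and the
>=2-significant-peptide protein roll-up used as pathway-analysis input.

Variance estimation is optionally moderated by empirical-Bayes shrinkage of
the per-peptide residual variances toward a pooled prior (the scaled
inverse-chi-square hierarchical model used by moderated linear-model
frameworks); plain ANOVA is selectable and is the mode with exactly nominal
finite-sample behavior.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .core import StudyDesign
from .stats import BioReplicateMatrix

__all__ = [
    "anova_per_peptide",
    "adjust_pvalues",
    "volcano_table",
    "significant_protein_rollup",
    "squeeze_variances",
]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: np.ndarray):
    """Empirical-Bayes shrinkage of sample variances.

    Fits a scaled inverse-chi-square prior (prior df ``d0``, prior variance
    ``s0_2``) to the observed variances by moment-matching on the log scale,
    then returns the posterior variances ``(d0*s0_2 + df*s2) / (d0 + df)``
    together with ``(d0, s0_2)``. ``d0 = inf`` means complete shrinkage to
    the common prior.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.nanmean(s2[ok])) if ok.any() else np.nan
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(polygamma(1, df[ok] / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        post[~ok & (df <= 0)] = np.nan
    return post, float(d0), s0_2


def anova_per_peptide(bio_matrix: BioReplicateMatrix,
                      design: StudyDesign | None = None,
                      moderated: bool = True, log2: bool = True,
                      alpha: float = 0.05, adjust_method: str = "bh"):
    """Omnibus one-way ANOVA and all pairwise contrasts, per peptide.

    Analysis runs on log2 biological-replicate means; peptides are analyzed
    on their available replicates (no imputation) and skipped — with a
    recorded reason — unless at least two groups have at least two
    non-missing values. Returns ``(results, skipped)``: a tidy DataFrame
    with one row per peptide x contrast (omnibus F/p repeated per row) and
    a table of skipped peptides.
    """
    design = design or bio_matrix.design
    X = bio_matrix.values
    Y = np.log2(X.to_numpy(dtype=float)) if log2 else X.to_numpy(dtype=float)
    groups = list(design.groups)
    gmask = {g: np.array([design.group_of_bio(b) == g for b in X.columns])
             for g in groups}

    n_g = np.stack([np.sum(~np.isnan(Y[:, gmask[g]]), axis=1) for g in groups], axis=1)
    sum_g = np.stack([np.nansum(Y[:, gmask[g]], axis=1) for g in groups], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_g = np.where(n_g > 0, sum_g / np.maximum(n_g, 1), np.nan)
    usable = (n_g >= 2).sum(axis=1) >= 2

    k_eff = (n_g >= 1).sum(axis=1)
    N = n_g.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(np.where(n_g > 0, n_g * mean_g, 0.0), axis=1) / N
        ssb = np.nansum(np.where(n_g > 0, n_g * (mean_g - grand[:, None]) ** 2, 0.0),
                        axis=1)
        ssw = np.zeros(Y.shape[0])
        for j, g in enumerate(groups):
            sub = Y[:, gmask[g]]
            ssw += np.nansum((sub - mean_g[:, j][:, None]) ** 2, axis=1)
    df1 = (k_eff - 1).astype(float)
    df2 = (N - k_eff).astype(float)
    s2 = np.where(df2 > 0, ssw / np.maximum(df2, 1), np.nan)

    if moderated:
        sel = usable & (df2 > 0)
        post, d0, s0_2 = squeeze_variances(s2[sel], df2[sel])
        s2_post = s2.copy()
        s2_post[sel] = post
        df_total = df2 + (d0 if np.isfinite(d0) else 0.0)
        if np.isinf(d0):
            df_total = np.full_like(df2, np.inf)
    else:
        s2_post = s2
        df_total = df2.astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        msb = np.where(df1 > 0, ssb / np.maximum(df1, 1), np.nan)
        f_stat = msb / s2_post
    # degenerate cases: no between-group signal -> p = 1; zero residual
    # variance with signal -> p = 0
    p_omni = np.full(Y.shape[0], np.nan)
    for i in range(Y.shape[0]):
        if not usable[i]:
            continue
        if ssb[i] <= 0:
            f_stat[i], p_omni[i] = 0.0, 1.0
        elif not np.isfinite(s2_post[i]) or s2_post[i] <= 0:
            f_stat[i], p_omni[i] = np.inf, 0.0
        else:
            dfd = df_total[i]
            p_omni[i] = (sps.chi2.sf(f_stat[i] * df1[i], df1[i])
                         if np.isinf(dfd)
                         else sps.f.sf(f_stat[i], df1[i], dfd))

    peptides = X.index
    pp = bio_matrix.peptide_protein
    skipped = pd.DataFrame(
        [{"peptide_id": peptides[i],
          "reason": "fewer than 2 groups with >= 2 replicates"}
         for i in np.flatnonzero(~usable)])

    rows = []
    # contrast "X_vs_Y" is X relative to Y: log2_fc = mean(X) - mean(Y)
    for b_idx, a_idx in combinations(range(len(groups)), 2):
        ga, gb = groups[a_idx], groups[b_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = mean_g[:, a_idx] - mean_g[:, b_idx]
            se = np.sqrt(s2_post * (1.0 / n_g[:, a_idx] + 1.0 / n_g[:, b_idx]))
            t = diff / se
        for i in np.flatnonzero(usable):
            if n_g[i, a_idx] < 1 or n_g[i, b_idx] < 1:
                p_raw = np.nan
            elif diff[i] == 0:
                p_raw = 1.0
            elif not np.isfinite(se[i]) or se[i] == 0:
                p_raw = 0.0
            else:
                dfd = df_total[i]
                p_raw = (2.0 * sps.norm.sf(abs(t[i])) if np.isinf(dfd)
                         else 2.0 * sps.t.sf(abs(t[i]), dfd))
            rows.append({
                "peptide_id": peptides[i],
                "protein_id": pp.get(peptides[i], ""),
                "f_stat": f_stat[i], "p_omnibus": p_omni[i],
                "contrast": f"{ga}_vs_{gb}",
                "log2_fc": diff[i] if log2 else np.nan,
                "mean_num": mean_g[i, a_idx], "mean_den": mean_g[i, b_idx],
                "p_raw": p_raw})
    results = pd.DataFrame(rows)
    if len(results):
        results["p_adj"] = np.nan
        for c, sub in results.groupby("contrast"):
            results.loc[sub.index, "p_adj"] = adjust_pvalues(
                sub["p_raw"].to_numpy(), adjust_method)
        results["significant"] = results["p_adj"] < alpha
    else:
        results = pd.DataFrame(columns=["peptide_id", "protein_id", "f_stat",
                                        "p_omnibus", "contrast", "log2_fc",
                                        "mean_num", "mean_den", "p_raw",
                                        "p_adj", "significant"])
    return results, skipped


def adjust_pvalues(p_raw, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up or Holm).

    NaN entries are passed through untouched; all finite p must lie in [0, 1].
    """
    p = np.asarray(p_raw, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        sm_method = {"bh": "fdr_bh", "holm": "holm"}.get(method)
        if sm_method is None:
            raise ValueError(f"unknown adjustment method {method!r}")
        out[ok] = multipletests(p[ok], method=sm_method)[1]
    return out


def volcano_table(results: pd.DataFrame, contrast: str,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Volcano-plot rows for one contrast: log2 FC, -log10 q, significance.

    A peptide is flagged only when its adjusted p is strictly below alpha.
    """
    sub = results[results["contrast"] == contrast]
    if len(sub) == 0:
        raise ValueError(f"contrast {contrast!r} not present in results")
    with np.errstate(divide="ignore"):
        neg_log_q = -np.log10(sub["p_adj"].to_numpy(dtype=float))
    return pd.DataFrame({
        "peptide_id": sub["peptide_id"].to_numpy(),
        "protein_id": sub["protein_id"].to_numpy(),
        "log2_fc": sub["log2_fc"].to_numpy(),
        "neg_log10_q": neg_log_q,
        "significant": sub["p_adj"].to_numpy() < alpha,
    })


def significant_protein_rollup(results: pd.DataFrame, min_peptides: int = 2,
                               contrast: str | None = None) -> pd.DataFrame:
    """Proteins with >= ``min_peptides`` significant peptides, per contrast.

    This roll-up is the pathway-analysis input list. Returns a table with
    protein_id, contrast and n_significant_peptides.
    """
    sub = results[results["significant"].fillna(False)]
    if contrast is not None:
        sub = sub[sub["contrast"] == contrast]
    if len(sub) == 0:
        return pd.DataFrame(columns=["protein_id", "contrast",
                                     "n_significant_peptides"])
    counts = (sub.groupby(["contrast", "protein_id"])["peptide_id"]
              .nunique().reset_index(name="n_significant_peptides"))
    out = counts[counts["n_significant_peptides"] >= min_peptides]
    return (out[["protein_id", "contrast", "n_significant_peptides"]]
            .sort_values(["contrast", "protein_id"]).reset_index(drop=True))
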