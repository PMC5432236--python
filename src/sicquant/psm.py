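"""PSM filter chain: deduplication, score filter, target-decoy FDR.

Reduces a raw peptide-spectrum-match table to the confident unique set used
for quantitation: duplicate matches to one spectrum are collapsed to the
highest-scoring record, low-scoring matches (score <= ``min_score``, strict
boundary) are removed, and the remainder is thresholded at a target-decoy
estimated false discovery rate. Decoy records inform the FDR estimate but
never reach quantitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "deduplicate_psms",
    "filter_by_min_score",
    "filter_by_target_decoy_fdr",
    "filter_chain",
]

PSM_COLUMNS = ["run_id", "spectrum_key", "peptide_id", "charge",
               "precursor_mass", "observed_rt", "score", "is_decoy",
               "protein_id"]


@dataclass
class FilterReport:
    n_input: int
    n_after_dedup: int
    n_after_score_filter: int
    score_cutoff_used: float
    estimated_fdr_at_cutoff: float
    n_retained_targets: int


def deduplicate_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate matches of one spectrum to one peptide.

    For each (spectrum_key, peptide_id) pair only the highest-scoring record
    survives; ties break deterministically on lowest run_id, then original
    input order.
    """
    if len(psms) == 0:
        return psms.copy()
    df = psms.reset_index(drop=True)
    df["_ord"] = np.arange(len(df))
    # best = max score; ties -> min run_id -> min input position
    df = df.sort_values(["spectrum_key", "peptide_id", "score", "run_id", "_ord"],
                        ascending=[True, True, False, True, True], kind="stable")
    df = df.drop_duplicates(["spectrum_key", "peptide_id"], keep="first")
    df = df.sort_values("_ord").drop(columns="_ord").reset_index(drop=True)
    return df


def filter_by_min_score(psms: pd.DataFrame, min_score: float = 20.0) -> pd.DataFrame:
    """Keep records with score strictly greater than ``min_score``."""
    if len(psms) == 0:
        return psms.copy()
    return psms[psms["score"] > min_score].reset_index(drop=True)


def _fdr_cutoff(scores: np.ndarray, is_decoy: np.ndarray, fdr_level: float):
    """Lowest score cutoff s with #decoys(>=s) / max(1, #targets(>=s)) <= level.

    Candidate cutoffs are the observed scores; returns (cutoff, fdr_at_cutoff).
    If no candidate satisfies the level, returns (inf, 0.0) (empty set).
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = is_decoy[order].astype(int)
    cum_d = np.cumsum(d)
    cum_t = np.cumsum(1 - d)
    # at cutoff = s[i], everything with score >= s[i] is retained; for tied
    # scores only the last index of the tie gives the full retained set
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    fdr = cum_d / np.maximum(1, cum_t)
    ok = np.flatnonzero(last_of_tie & (fdr <= fdr_level))
    if ok.size == 0:
        return np.inf, 0.0
    i = ok[-1]  # lowest admissible cutoff -> largest retained set
    return s[i], fdr[i]


def filter_by_target_decoy_fdr(psms: pd.DataFrame, fdr_level: float = 0.01):
    """Threshold at the most permissive score cutoff meeting the FDR level.

    Returns ``(targets, FilterReport)``; decoys are never returned. The FDR
    estimate at a cutoff s is #decoys(score >= s) / max(1, #targets(score >= s)).
    """
    if not 0.0 < fdr_level <= 1.0:
        raise ValueError(f"fdr_level must be in (0, 1], got {fdr_level}")
    n_in = len(psms)
    if n_in == 0 or not (~psms["is_decoy"]).any():
        report = FilterReport(n_in, n_in, n_in, np.inf, 0.0, 0)
        return psms.iloc[0:0].copy(), report
    scores = psms["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("PSM scores must be finite")
    decoy = psms["is_decoy"].to_numpy(dtype=bool)
    cutoff, fdr = _fdr_cutoff(scores, decoy, fdr_level)
    keep = (~decoy) & (scores >= cutoff)
    report = FilterReport(n_in, n_in, n_in, float(cutoff), float(fdr),
                          int(keep.sum()))
    return psms[keep].reset_index(drop=True), report


def filter_chain(psms: pd.DataFrame, min_score: float = 20.0,
                 fdr_level: float = 0.01,
                 order: tuple[str, ...] = ("dedup", "score", "fdr")):
    """Run the full dedup -> score -> FDR chain (order configurable).

    Returns ``(confident_targets, FilterReport)`` with stage counts filled in.
    """
    n_input = len(psms)
    out = psms
    n_dedup = n_score = n_input
    cutoff, fdr, n_ret = np.inf, 0.0, n_input
    for stage in order:
        if stage == "dedup":
            out = deduplicate_psms(out)
            n_dedup = len(out)
        elif stage == "score":
            out = filter_by_min_score(out, min_score)
            n_score = len(out)
        elif stage == "fdr":
            out, rep = filter_by_target_decoy_fdr(out, fdr_level)
            cutoff, fdr, n_ret = rep.score_cutoff_used, rep.estimated_fdr_at_cutoff, rep.n_retained_targets
        else:
            raise ValueError(f"unknown filter stage {stage!r}")
    report = FilterReport(n_input, n_dedup, n_score, cutoff, fdr,
                          len(out))
    return out.reset_index(drop=True), report
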