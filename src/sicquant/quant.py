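"""Selected-ion-chromatogram quantitation.

Turns confident peptide identifications plus centroided MS1 runs into a
normalized peptide x run abundance matrix:

1. SIC extraction — all centroid intensity within a 10 ppm window of the
   peptide's computed m/z, summed per scan.
2. Multipass peak detection — continuous-wavelet-transform ridge candidates
   over successive passes of progressively narrower minimum peak width
   (widest first), an S/N >= 10 gate, and peak limits found by descent from
   the apex on the raw (non-transformed) intensities.
3. Fallback integration of a fixed +/-40 s region around the SIC maximum
   when wavelet detection finds nothing.
4. Retention-time alignment — robust locally weighted regression of anchor
   pairs from shared identifications, made monotone by isotonic
   post-processing.
5. Match-between-runs backfill — quantifying a peptide in runs lacking its
   MS/MS identification at the alignment-predicted retention time.
6. Noise floor (minimum SIC peak area 1000) and normalization of every area
   to the spiked standard's peak area in the same run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks_cwt
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import CentroidRun, PeakQuant, StudyDesign, mass_to_mz

__all__ = [
    "SICTrace",
    "RTWarp",
    "AbundanceMatrix",
    "QuantParams",
    "extract_sic",
    "detect_peak_multipass",
    "fallback_integrate",
    "align_retention_times",
    "backfill_missing",
    "normalize_to_spike",
    "build_abundance_matrix",
    "quantify_study",
]


@dataclass(frozen=True)
class QuantParams:
    """Tunables of the quantitation chain (all RTs and widths in seconds)."""

    ppm_window: float = 10.0
    min_widths: tuple[float, ...] = (20.0, 15.0, 10.0, 6.0, 4.0, 2.0)
    max_width: float = 80.0
    snr_threshold: float = 10.0
    noise_floor: float = 1000.0          # minimum raw SIC peak area
    fallback_halfwidth: float = 40.0     # half the maximum peak width
    sic_halfwindow: float = 150.0        # extraction window around expected RT
    min_anchors: int = 20
    lowess_frac: float = 0.3
    spike_peptide_id: str = "DRVpYIHPF"


@dataclass
class SICTrace:
    """Selected ion chromatogram: summed in-window intensity per scan."""

    run_id: str
    target_mz: float
    ppm_window: float
    rts: np.ndarray
    intensity: np.ndarray
    peptide_id: str = ""

    def __len__(self) -> int:
        return self.rts.size


def extract_sic(run: CentroidRun, target_mz: float, ppm_window: float = 10.0,
                rt_range: tuple[float, float] | None = None,
                peptide_id: str = "") -> SICTrace:
    """Extract the SIC at ``target_mz`` within ``ppm_window`` (half-width, ppm).

    Every in-window centroid of a scan is summed into one trace point; scans
    with no in-window centroid contribute intensity 0. ``rt_range`` restricts
    the trace to a retention-time window (the full run by default).
    """
    if target_mz <= 0:
        raise ValueError(f"target_mz must be > 0, got {target_mz}")
    tol = target_mz * ppm_window * 1e-6
    lo = np.searchsorted(run.mz, target_mz - tol, side="left")
    hi = np.searchsorted(run.mz, target_mz + tol, side="right")
    if rt_range is None:
        s0, s1 = 0, run.n_scans
    else:
        s0 = int(np.searchsorted(run.scan_rts, rt_range[0], side="left"))
        s1 = int(np.searchsorted(run.scan_rts, rt_range[1], side="right"))
    rts = run.scan_rts[s0:s1]
    y = np.zeros(rts.size)
    if hi > lo and rts.size:
        idx = run.scan_index[lo:hi]
        w = run.intensity[lo:hi]
        keep = (idx >= s0) & (idx < s1)
        if keep.any():
            y = np.bincount(idx[keep] - s0, weights=w[keep],
                            minlength=rts.size)[: rts.size].astype(float)
    return SICTrace(run.run_id, target_mz, ppm_window, rts, y, peptide_id)


def _trace_noise(y: np.ndarray) -> tuple[float, float]:
    """Baseline level and noise SD of a trace.

    Estimated from the lower 80% of intensities (the peak occupies a
    minority of scans): baseline = median, noise SD = 84.1th-percentile
    excess over the baseline. Quantile-based so it survives the
    zero-clipped baselines typical of sparse centroid data, where the MAD
    collapses to zero. The SD is floored at 1/1000 of the trace's dynamic
    range — every threshold derived from it is then homogeneous of degree
    one in intensity, so quantitation is invariant to rescaling a run —
    which caps signal-to-noise at 1000 on clean traces.
    """
    if y.size == 0:
        return 0.0, 0.0
    v = np.sort(y)[: max(1, int(0.8 * y.size))]
    bg = float(np.median(v))
    spread = float(np.max(y)) - bg
    sd = max(float(np.quantile(v, 0.841)) - bg, 1e-3 * spread)
    return bg, sd


def _descend_limits(y: np.ndarray, apex: int, bg: float,
                    noise: float) -> tuple[int, int]:
    """Peak limits by descent from the apex on the raw intensities.

    Each side walks outward tracking the running minimum; it stops once the
    signal reaches the baseline noise level, or at a sustained rise (two
    consecutive samples above the running minimum by more than the noise
    tolerance — a slope sign flip, noise-robustly), returning the running
    minimum as the limit.
    """
    rise_tol = max(3.0 * noise, 0.02 * y[apex])
    stop_level = bg + 0.5 * noise

    def walk(d: int) -> int:
        i = apex
        best = apex
        while 0 <= i + d < y.size:
            j = i + d
            if y[j] < y[best]:
                best = j
            if y[j] <= stop_level:
                return j
            if y[j] > y[best] + rise_tol:
                k = j + d
                if not (0 <= k < y.size) or y[k] > y[best] + rise_tol:
                    break
            i = j
        return best

    return walk(-1), walk(+1)


def _integrate(rts: np.ndarray, y: np.ndarray, left: int, right: int,
               baseline: float = 0.0) -> float:
    """Trapezoidal area between limits above a constant baseline level."""
    if right <= left:
        return 0.0
    seg_y = np.clip(y[left: right + 1] - baseline, 0.0, None)
    return float(np.trapezoid(seg_y, rts[left: right + 1]))


def detect_peak_multipass(trace: SICTrace, expected_rt: float | None = None,
                          params: QuantParams | None = None) -> PeakQuant | None:
    """Multipass CWT peak detection on a SIC.

    Passes run widest-minimum-width first; the first pass yielding at least
    one candidate above the S/N threshold wins. Among the winning pass's
    candidates, the apex nearest ``expected_rt`` is chosen (highest apex if
    no expectation). Returns ``None`` when no peak clears the gate.
    """
    p = params or QuantParams()
    y, rts = trace.intensity, trace.rts
    if y.size < 5 or not np.any(y > 0):
        return None
    dt = float(np.median(np.diff(rts)))
    bg, noise = _trace_noise(y)
    if noise <= 0:  # flat trace
        return None
    for min_w in p.min_widths:
        w_lo = max(1.0, 0.5 * min_w / dt)
        w_hi = max(w_lo + 1.0, 0.5 * p.max_width / dt)
        widths = np.unique(np.round(np.geomspace(w_lo, w_hi, 6)).astype(int))
        widths = widths[widths < y.size // 2]
        if widths.size == 0:
            continue
        try:
            idx = find_peaks_cwt(y, widths, min_snr=1.0)
        except Exception:
            continue
        candidates = []
        half = max(1, int(round(0.5 * min_w / dt)))
        for i in np.atleast_1d(idx):
            lo = max(0, int(i) - half)
            hi = min(y.size, int(i) + half + 1)
            apex = lo + int(np.argmax(y[lo:hi]))
            if (y[apex] - bg) / noise >= p.snr_threshold:
                candidates.append(apex)
        if not candidates:
            continue
        candidates = sorted(set(candidates))
        if expected_rt is not None:
            apex = min(candidates, key=lambda i: abs(rts[i] - expected_rt))
        else:
            apex = max(candidates, key=lambda i: y[i])
        left, right = _descend_limits(y, apex, bg, noise)
        # enforce the maximum peak width around the apex
        max_half = int(np.floor(0.5 * p.max_width / dt))
        left = max(left, apex - max_half)
        right = min(right, apex + max_half)
        area = _integrate(rts, y, left, right, baseline=bg)
        return PeakQuant(trace.peptide_id, trace.run_id,
                         float(rts[left]), float(rts[apex]), float(rts[right]),
                         area, "wavelet",
                         below_noise=area < p.noise_floor)
    return None


def fallback_integrate(trace: SICTrace, window_halfwidth: float = 40.0,
                       noise_floor: float = 1000.0) -> PeakQuant | None:
    """Integrate a fixed region around the SIC's maximum-intensity point.

    Used when wavelet detection fails; integrates the raw trace (no baseline
    model) over +/- ``window_halfwidth`` seconds of the maximum.
    """
    if len(trace) == 0:
        return None
    y, rts = trace.intensity, trace.rts
    apex = int(np.argmax(y))
    left = int(np.searchsorted(rts, rts[apex] - window_halfwidth, side="left"))
    right = int(np.searchsorted(rts, rts[apex] + window_halfwidth, side="right")) - 1
    area = _integrate(rts, y, left, right, baseline=0.0)
    return PeakQuant(trace.peptide_id, trace.run_id,
                     float(rts[left]), float(rts[apex]), float(rts[right]),
                     area, "fallback", below_noise=area < noise_floor)


# ---------------------------------------------------------------------------
# Retention-time alignment
# ---------------------------------------------------------------------------

@dataclass
class RTWarp:
    """Monotone mapping reference-run RT -> this run's RT, with inverse."""

    run_id: str
    reference_run_id: str
    knots_ref: np.ndarray
    knots_run: np.ndarray
    anchor_count: int
    median_residual: float

    @classmethod
    def identity(cls, run_id: str, reference_run_id: str,
                 rt_range=(0.0, 1e4)) -> "RTWarp":
        x = np.asarray(rt_range, dtype=float)
        return cls(run_id, reference_run_id, x, x.copy(), 0, 0.0)

    def map(self, t):
        """Reference RT -> run RT."""
        return _interp_extrap(t, self.knots_ref, self.knots_run)

    def inverse(self, t):
        """Run RT -> reference RT."""
        return _interp_extrap(t, self.knots_run, self.knots_ref)


def _interp_extrap(t, x, y):
    t = np.asarray(t, dtype=float)
    out = np.interp(t, x, y)
    if x.size >= 2:
        sl = (y[1] - y[0]) / (x[1] - x[0])
        sr = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(t < x[0], y[0] + sl * (t - x[0]), out)
        out = np.where(t > x[-1], y[-1] + sr * (t - x[-1]), out)
    return out if out.ndim else float(out)


def _strictify(y: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Make a non-decreasing sequence strictly increasing."""
    out = y.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def anchor_table(confident_psms: pd.DataFrame) -> pd.DataFrame:
    """Median observed RT per (peptide, run) — the alignment anchors."""
    return (confident_psms.groupby(["peptide_id", "run_id"], sort=True)
            ["observed_rt"].median().unstack("run_id"))


def align_retention_times(runs: list[CentroidRun] | list[str],
                          confident_psms: pd.DataFrame,
                          params: QuantParams | None = None) -> dict[str, RTWarp]:
    """Fit a monotone RT warp for every run against a common reference.

    The reference is the run with the most confidently identified peptides.
    Each other run's warp is a robust lowess fit of (reference RT, run RT)
    anchor pairs from shared peptides, forced monotone by isotonic
    regression. Runs with fewer than ``min_anchors`` shared anchors get an
    identity warp with a warning.
    """
    p = params or QuantParams()
    run_ids = [r.run_id if isinstance(r, CentroidRun) else r for r in runs]
    anchors = anchor_table(confident_psms)
    anchors = anchors.reindex(columns=[r for r in run_ids if r in anchors.columns])
    if anchors.shape[1] == 0:
        raise ValueError("no confident identifications overlap the given runs")
    ref = anchors.notna().sum(axis=0).idxmax()
    warps: dict[str, RTWarp] = {}
    rt_lo = float(np.nanmin(anchors.to_numpy()))
    rt_hi = float(np.nanmax(anchors.to_numpy()))
    for rid in run_ids:
        if rid == ref:
            warps[rid] = RTWarp.identity(rid, ref, (rt_lo, rt_hi))
            continue
        if rid not in anchors.columns:
            warnings.warn(f"run {rid!r} has no anchors; identity warp used")
            warps[rid] = RTWarp.identity(rid, ref, (rt_lo, rt_hi))
            continue
        pair = anchors[[ref, rid]].dropna()
        if len(pair) < p.min_anchors:
            warnings.warn(
                f"run {rid!r}: only {len(pair)} anchors (< {p.min_anchors}); "
                "identity warp used")
            warps[rid] = RTWarp.identity(rid, ref, (rt_lo, rt_hi))
            continue
        x = pair[ref].to_numpy(dtype=float)
        y = pair[rid].to_numpy(dtype=float)
        fit = lowess(y, x, frac=p.lowess_frac, it=2, return_sorted=True)
        xs, ys = fit[:, 0], fit[:, 1]
        xs, uniq = np.unique(xs, return_index=True)
        ys = ys[uniq]
        iso = IsotonicRegression(increasing=True)
        ys = _strictify(iso.fit_transform(xs, ys))
        resid = np.abs(_interp_extrap(x, xs, ys) - y)
        warps[rid] = RTWarp(rid, ref, xs, ys, len(pair),
                            float(np.median(resid)))
    return warps


# ---------------------------------------------------------------------------
# Backfill, normalization, matrix
# ---------------------------------------------------------------------------

def backfill_missing(peptide_id: str, target_mz: float, run: CentroidRun,
                     warps: dict[str, RTWarp], peers: list[PeakQuant],
                     params: QuantParams | None = None) -> PeakQuant | None:
    """Quantify a peptide in a run that lacks its MS/MS identification.

    The expected RT is the warp-mapped median of peer apex RTs (peers mapped
    into reference coordinates through their own warps' inverses, the median
    mapped out through the target run's warp). The SIC is extracted at the
    peptide's computed m/z and quantified by wavelet detection at the
    expected RT, falling back to fixed-window integration.
    """
    p = params or QuantParams()
    peers = [q for q in peers if q.run_id != run.run_id]
    if not peers:
        return None
    ref_rts = [float(warps[q.run_id].inverse(q.rt_apex)) for q in peers
               if q.run_id in warps]
    if not ref_rts:
        return None
    expected_rt = float(warps[run.run_id].map(np.median(ref_rts)))
    trace = extract_sic(run, target_mz, p.ppm_window,
                        rt_range=(expected_rt - p.sic_halfwindow,
                                  expected_rt + p.sic_halfwindow),
                        peptide_id=peptide_id)
    q = detect_peak_multipass(trace, expected_rt, p)
    if q is None:
        q = fallback_integrate(trace, p.fallback_halfwidth, p.noise_floor)
    if q is None:
        return None
    q.method = "backfill"
    return q


def normalize_to_spike(quants: list[PeakQuant], spike_peptide_id: str,
                       noise_floor: float = 1000.0) -> list[PeakQuant]:
    """Divide every raw area by the spiked standard's area in the same run.

    The spike must be quantified above the noise floor in every run; a run
    violating that is a hard error (it has no valid normalization basis).
    """
    spike = {}
    for q in quants:
        if q.peptide_id == spike_peptide_id:
            spike[q.run_id] = q
    by_run: dict[str, list[PeakQuant]] = {}
    for q in quants:
        by_run.setdefault(q.run_id, []).append(q)
    for run_id, qs in by_run.items():
        s = spike.get(run_id)
        if s is None or s.raw_area < noise_floor or s.raw_area <= 0:
            raise ValueError(
                f"run {run_id!r}: spike peptide {spike_peptide_id!r} missing or "
                f"below the noise floor ({None if s is None else s.raw_area}); "
                "run cannot be normalized")
        for q in qs:
            q.normalized_area = q.raw_area / s.raw_area
    return quants


@dataclass
class AbundanceMatrix:
    """Peptides x runs of normalized areas with detection provenance."""

    values: pd.DataFrame      # float, NaN = missing / below noise floor
    provenance: pd.DataFrame  # str: wavelet | fallback | backfill | ''
    peptide_protein: pd.Series  # peptide_id -> protein_id
    design: StudyDesign = field(default_factory=StudyDesign)

    @property
    def peptides(self) -> pd.Index:
        return self.values.index

    @property
    def runs(self) -> pd.Index:
        return self.values.columns

    def completeness(self) -> float:
        return float(self.values.notna().to_numpy().mean())


def build_abundance_matrix(quants: list[PeakQuant],
                           peptide_protein: dict[str, str] | pd.Series,
                           design: StudyDesign) -> AbundanceMatrix:
    """Assemble the peptide x run matrix; below-noise cells become missing."""
    seen = set()
    for q in quants:
        key = (q.peptide_id, q.run_id)
        if key in seen:
            raise ValueError(f"duplicate quantification for {key}")
        seen.add(key)
    rows = [{"peptide_id": q.peptide_id, "run_id": q.run_id,
             "value": np.nan if q.below_noise else (
                 q.normalized_area if q.normalized_area is not None else q.raw_area),
             "method": q.method} for q in quants]
    df = pd.DataFrame(rows)
    run_ids = design.run_ids
    values = (df.pivot(index="peptide_id", columns="run_id", values="value")
              .reindex(columns=run_ids).sort_index())
    prov = (df.pivot(index="peptide_id", columns="run_id", values="method")
            .reindex(columns=run_ids).reindex(values.index).fillna(""))
    pp = pd.Series(dict(peptide_protein), name="protein_id")
    return AbundanceMatrix(values, prov, pp.reindex(values.index), design)


def quantify_study(runs: list[CentroidRun], confident_psms: pd.DataFrame,
                   design: StudyDesign,
                   params: QuantParams | None = None) -> tuple[AbundanceMatrix, list[PeakQuant]]:
    """Full quantitation: SIC areas for every identified peptide in every run.

    Peptides identified by MS/MS in a run are quantified at their observed
    RT; peptides missing in a run but identified elsewhere are backfilled at
    the alignment-predicted RT. Areas are normalized to the spike and
    assembled into the abundance matrix (spike row excluded).
    """
    p = params or QuantParams()
    if len(confident_psms) == 0:
        raise ValueError("no confident PSMs to quantify")
    run_by_id = {r.run_id: r for r in runs}

    pep = (confident_psms.groupby("peptide_id")
           .agg(mass=("precursor_mass", "median"),
                charge=("charge", lambda c: c.mode().iloc[0]),
                protein_id=("protein_id", "first")))
    pep["mz"] = [mass_to_mz(m, int(z)) for m, z in zip(pep["mass"], pep["charge"])]
    anchors = anchor_table(confident_psms)
    warps = align_retention_times(runs, confident_psms, p)

    quants: list[PeakQuant] = []
    peers_by_pep: dict[str, list[PeakQuant]] = {pid: [] for pid in pep.index}
    # pass 1: quantify where MS/MS identified
    for pid, row in pep.iterrows():
        if pid not in anchors.index:
            continue
        obs = anchors.loc[pid].dropna()
        for rid, expected_rt in obs.items():
            run = run_by_id.get(rid)
            if run is None:
                continue
            trace = extract_sic(run, row["mz"], p.ppm_window,
                                rt_range=(expected_rt - p.sic_halfwindow,
                                          expected_rt + p.sic_halfwindow),
                                peptide_id=pid)
            q = detect_peak_multipass(trace, float(expected_rt), p)
            if q is None:
                q = fallback_integrate(trace, p.fallback_halfwidth, p.noise_floor)
            if q is not None:
                quants.append(q)
                peers_by_pep[pid].append(q)
    # pass 2: backfill runs lacking the identification
    identified = {(q.peptide_id, q.run_id) for q in quants}
    for pid, row in pep.iterrows():
        peers = [q for q in peers_by_pep[pid] if not q.below_noise]
        if not peers:
            continue
        for run in runs:
            if (pid, run.run_id) in identified:
                continue
            q = backfill_missing(pid, row["mz"], run, warps, peers, p)
            if q is not None:
                quants.append(q)

    quants = normalize_to_spike(quants, p.spike_peptide_id, p.noise_floor)
    analyte = [q for q in quants if q.peptide_id != p.spike_peptide_id]
    pp = pep["protein_id"]
    matrix = build_abundance_matrix(
        analyte, pp[pp.index != p.spike_peptide_id], design)
    return matrix, quants
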