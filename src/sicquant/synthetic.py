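"""Synthetic LC-MS study generator with ground truth.

Emulates the statistical structure of a laser-capture-microdissection
label-free proteomics study — 4 groups x 3 biological x 4 technical
replicates (48 runs), peptides mapped to proteins, group-level fold changes,
per-run retention-time drift, ppm-scale mass error, MS/MS identification
dropout, decoy PSMs, and a spiked standard peptide present in every run —
so every downstream stage of the pipeline is testable without real data.

Peaks are symmetric Gaussians by default (an exponentially modified
Gaussian tail is available via ``tail_tau``), which keeps the analytic
area oracle exact. Abundance noise is multiplicative log-normal with
separate biological (between-animal) and technical (between-injection)
components; the defaults target a technical-within-biological coefficient
of variation around 0.4-0.5. Retention-time drift is a per-run monotone
quadratic warp of bounded amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erfc

from .core import (
    CentroidRun,
    StudyDesign,
    SPIKE_PEPTIDE_ID,
    SPIKE_PEPTIDE_MASS,
    SPIKE_PEPTIDE_CHARGE,
    mass_to_mz,
)

__all__ = [
    "CatalogParams",
    "NoiseParams",
    "GroundTruth",
    "generate_catalog",
    "generate_study",
    "generate_chromatographic_peak",
    "truth_abundance_matrix",
]


@dataclass(frozen=True)
class CatalogParams:
    """Peptide catalog and identification-process parameters.

    ``fraction_differential`` of proteins carry a fold change in the two
    focal-lesion groups (half up-regulated — marker-like, half down —
    drug-metabolism-enzyme-like). ``msms_dropout_rate`` is the probability
    that a peptide truly present in a run yields no MS/MS identification.
    """

    n_proteins: int = 60
    peptides_per_protein: int = 5
    fraction_differential: float = 0.2
    down_fraction: float = 0.5  # share of differential proteins down-regulated
    fold_change: float = 3.0
    up_groups: tuple[str, ...] = ("placebo", "rapamycin")
    mass_range: tuple[float, float] = (800.0, 2400.0)
    rt_margin: float = 150.0  # keep apexes away from gradient edges, s
    sigma_range: tuple[float, float] = (3.0, 6.0)
    log_area_mean: float = np.log(4e4)
    log_area_sd: float = 0.8
    min_base_area: float = 5e3
    msms_dropout_rate: float = 0.2
    decoy_rate: float = 0.3
    psm_redundancy: float = 0.3  # mean extra duplicate PSMs per identification
    target_score_mean: float = 35.0
    target_score_sd: float = 8.0
    decoy_score_mean: float = 18.0
    decoy_score_sd: float = 6.0

    def __post_init__(self):
        if self.n_proteins < 1 or self.peptides_per_protein < 1:
            raise ValueError("catalog needs at least one protein and one peptide")
        if not 0.0 <= self.msms_dropout_rate <= 1.0:
            raise ValueError(
                f"msms_dropout_rate must be in [0, 1], got {self.msms_dropout_rate}")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise and drift parameters (units: s, ppm, log-SDs)."""

    bio_sigma: float = 0.30       # between-animal log-SD
    tech_sigma: float = 0.48      # between-injection log-SD (COV ~ 0.51)
    run_scale_sigma: float = 0.15  # per-run global intensity scale, log-SD
    spike_tech_sigma: float = 0.05
    warp_shift_max: float = 20.0   # constant RT offset bound, s
    warp_linear_max: float = 0.01  # linear drift slope bound
    warp_quad_max: float = 30.0    # quadratic drift amplitude bound, s
    ppm_error_sd: float = 2.0      # per peptide-in-run systematic mass error
    ppm_jitter_sd: float = 0.5     # per-centroid mass jitter
    baseline_noise_sd: float = 10.0   # additive noise on peak centroids
    noise_centroids_per_scan: float = 1.0
    noise_intensity_scale: float = 20.0
    rt_obs_sd: float = 1.5         # PSM observed-RT error, s
    scan_interval: float = 1.0
    rt_range: tuple[float, float] = (300.0, 3000.0)
    mz_range: tuple[float, float] = (400.0, 1800.0)


@dataclass
class GroundTruth:
    """True abundances, warps and identification mask behind a synthetic study."""

    peptides: pd.DataFrame  # peptide_id, protein_id, mass, charge, base_rt, sigma, base_area, mult_<group>...
    truth: pd.DataFrame     # peptide_id, run_id, true_area, true_apex_rt, identified_by_msms
    runs: pd.DataFrame      # run_id, group, biological, technical, warp coefs, run_scale, spike_true_area
    design: StudyDesign

    def warp_fn(self, run_id: str):
        """True RT warp of a run: chromatographic time -> observed time."""
        row = self.runs.set_index("run_id").loc[run_id]
        a, b, c, tm = row["warp_a"], row["warp_b"], row["warp_c"], row["warp_tmid"]
        return lambda t: t + a + b * (np.asarray(t) - tm) + c * (np.asarray(t) - tm) ** 2


def generate_chromatographic_peak(apex_rt, sigma, area, scan_interval,
                                  baseline_noise_sd=0.0, rt_start=None,
                                  rt_end=None, rng=None, tail_tau=None):
    """Sample a chromatographic elution profile at regular scan times.

    Returns ``(rts, intensities)``. The profile is a Gaussian of the given
    area (intensity*s) and width, optionally exponentially modified with
    time constant ``tail_tau`` (s); either way the analytic area equals
    ``area``. Additive Gaussian baseline noise (SD ``baseline_noise_sd``)
    is applied per sample and clipped at zero.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if scan_interval <= 0:
        raise ValueError(f"scan_interval must be > 0, got {scan_interval}")
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    span = 6.0 * sigma + (4.0 * tail_tau if tail_tau else 0.0)
    lo = apex_rt - 6.0 * sigma if rt_start is None else rt_start
    hi = apex_rt + span if rt_end is None else rt_end
    rts = lo + scan_interval * np.arange(int(np.floor((hi - lo) / scan_interval)) + 1)
    if area == 0:
        y = np.zeros_like(rts)
    elif tail_tau:
        # exponentially modified Gaussian, unit-area parameterization
        t, s, mu = tail_tau, sigma, apex_rt
        z = (s / t) - (rts - mu) / s
        y = area / (2 * t) * np.exp(0.5 * (s / t) ** 2 - (rts - mu) / t) * erfc(z / np.sqrt(2))
    else:
        amp = area / (sigma * np.sqrt(2.0 * np.pi))
        y = amp * np.exp(-0.5 * ((rts - apex_rt) / sigma) ** 2)
    if baseline_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = np.clip(y + rng.normal(0.0, baseline_noise_sd, y.size), 0.0, None)
    return rts, y


def generate_catalog(design: StudyDesign, params: CatalogParams,
                     noise: NoiseParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the peptide catalog: masses, charges, elution, per-group multipliers."""
    n_pep = params.n_proteins * params.peptides_per_protein
    protein_ids = [f"PRT{p + 1:04d}" for p in range(params.n_proteins)
                   for _ in range(params.peptides_per_protein)]
    peptide_ids = [f"PEP{i + 1:05d}" for i in range(n_pep)]
    rt_lo = noise.rt_range[0] + params.rt_margin
    rt_hi = noise.rt_range[1] - params.rt_margin
    cat = pd.DataFrame({
        "peptide_id": peptide_ids,
        "protein_id": protein_ids,
        "mass": rng.uniform(*params.mass_range, n_pep),
        "charge": rng.choice([2, 3], n_pep, p=[0.7, 0.3]),
        "base_rt": rng.uniform(rt_lo, rt_hi, n_pep),
        "sigma": rng.uniform(*params.sigma_range, n_pep),
        "base_area": np.maximum(
            rng.lognormal(params.log_area_mean, params.log_area_sd, n_pep),
            params.min_base_area),
    })
    # per-group abundance multipliers; differential proteins split up/down
    n_diff = int(round(params.fraction_differential * params.n_proteins))
    diff_prot = rng.choice(params.n_proteins, n_diff, replace=False)
    n_down = int(round(params.down_fraction * n_diff))
    up = set(diff_prot[: n_diff - n_down])
    down = set(diff_prot[n_diff - n_down:])
    for g in design.groups:
        mult = np.ones(n_pep)
        if g in params.up_groups:
            for p in range(params.n_proteins):
                if p in up:
                    mult[p * params.peptides_per_protein:
                         (p + 1) * params.peptides_per_protein] = params.fold_change
                elif p in down:
                    mult[p * params.peptides_per_protein:
                         (p + 1) * params.peptides_per_protein] = 1.0 / params.fold_change
        cat[f"mult_{g}"] = mult
    # spiked standard: constant across groups, never dropped
    spike = {"peptide_id": SPIKE_PEPTIDE_ID, "protein_id": "SPIKE",
             "mass": SPIKE_PEPTIDE_MASS, "charge": SPIKE_PEPTIDE_CHARGE,
             "base_rt": 0.5 * (rt_lo + rt_hi), "sigma": 4.0, "base_area": 5e4}
    for g in design.groups:
        spike[f"mult_{g}"] = 1.0
    return pd.concat([cat, pd.DataFrame([spike])], ignore_index=True)


def _draw_warp(noise: NoiseParams, rng: np.random.Generator):
    """Monotone quadratic warp coefficients; total amplitude <= ~60 s."""
    t0, t1 = noise.rt_range
    tm = 0.5 * (t0 + t1)
    half = 0.5 * (t1 - t0)
    a = rng.uniform(-noise.warp_shift_max, noise.warp_shift_max)
    b = rng.uniform(-noise.warp_linear_max, noise.warp_linear_max)
    c = rng.uniform(-noise.warp_quad_max, noise.warp_quad_max) / half ** 2
    # monotone: d/dt = 1 + b + 2c(t - tm) must stay positive over the gradient
    assert 1.0 + b - 2.0 * abs(c) * half > 0
    return a, b, c, tm


def generate_study(design: StudyDesign | None = None,
                   catalog_params: CatalogParams | None = None,
                   noise_params: NoiseParams | None = None,
                   seed: int = 0, catalog: pd.DataFrame | None = None):
    """Generate a full synthetic study.

    Returns ``(runs, psms, truth)``: a list of :class:`CentroidRun`, a PSM
    DataFrame (targets where identified, plus decoys), and the
    :class:`GroundTruth`. Identical seed and parameters give bit-identical
    output. A pre-built ``catalog`` (e.g. one with edited group
    multipliers, including true absences via multiplier 0) may be supplied
    in place of the drawn one.
    """
    design = design or StudyDesign()
    cp = catalog_params or CatalogParams()
    npar = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)

    cat = generate_catalog(design, cp, npar, rng) if catalog is None else catalog
    n_pep = len(cat)
    spike_row = n_pep - 1
    mz = np.array([mass_to_mz(m, z) for m, z in zip(cat["mass"], cat["charge"])])

    run_rows, truth_rows, psm_rows, runs = [], [], [], []
    # biological (between-animal) effects: per peptide x animal, shared by
    # that animal's technical replicates
    bio_eff = {}
    for g in design.groups:
        for b in range(1, design.n_biological + 1):
            e = rng.normal(0.0, npar.bio_sigma, n_pep)
            e[spike_row] = 0.0
            bio_eff[(g, b)] = e

    group_mult = {g: cat[f"mult_{g}"].to_numpy() for g in design.groups}
    scan_rts_template = npar.rt_range[0] + npar.scan_interval * np.arange(
        int(np.floor((npar.rt_range[1] - npar.rt_range[0]) / npar.scan_interval)) + 1)
    n_scans = scan_rts_template.size

    spec_counter = 0
    for run_id, g, b, t in design.iter_runs():
        a, wb, wc, tm = _draw_warp(npar, rng)
        run_scale = float(np.exp(rng.normal(0.0, npar.run_scale_sigma)))
        tech = rng.normal(0.0, npar.tech_sigma, n_pep)
        tech[spike_row] = rng.normal(0.0, npar.spike_tech_sigma)
        true_area = (cat["base_area"].to_numpy() * group_mult[g]
                     * run_scale * np.exp(bio_eff[(g, b)] + tech))
        true_area[group_mult[g] == 0.0] = 0.0
        apex = cat["base_rt"].to_numpy()
        apex = apex + a + wb * (apex - tm) + wc * (apex - tm) ** 2

        identified = rng.random(n_pep) >= cp.msms_dropout_rate
        identified[spike_row] = True
        identified &= true_area > 0

        ppm_off = rng.normal(0.0, npar.ppm_error_sd, n_pep)

        # assemble centroids
        mz_parts, int_parts, idx_parts = [], [], []
        for i in range(n_pep):
            if true_area[i] <= 0:
                continue
            rts, y = generate_chromatographic_peak(
                apex[i], cat["sigma"].iloc[i], true_area[i], npar.scan_interval,
                baseline_noise_sd=npar.baseline_noise_sd, rng=rng)
            # snap to the run's scan grid
            k = np.round((rts - npar.rt_range[0]) / npar.scan_interval).astype(np.int64)
            keep = (k >= 0) & (k < n_scans) & (y > 0)
            k, y = k[keep], y[keep]
            jitter = rng.normal(0.0, npar.ppm_jitter_sd, k.size)
            mz_parts.append(mz[i] * (1.0 + (ppm_off[i] + jitter) * 1e-6))
            int_parts.append(y)
            idx_parts.append(k)
        # background noise centroids at random m/z
        n_noise = rng.poisson(npar.noise_centroids_per_scan * n_scans)
        if n_noise:
            idx_parts.append(rng.integers(0, n_scans, n_noise))
            mz_parts.append(rng.uniform(*npar.mz_range, n_noise))
            int_parts.append(rng.exponential(npar.noise_intensity_scale, n_noise))
        run = CentroidRun(
            run_id, scan_rts_template,
            np.concatenate(mz_parts) if mz_parts else np.empty(0),
            np.concatenate(int_parts) if int_parts else np.empty(0),
            np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=np.int64),
            group=g, biological=b, technical=t)
        runs.append(run)

        run_rows.append({"run_id": run_id, "group": g, "biological": b,
                         "technical": t, "warp_a": a, "warp_b": wb, "warp_c": wc,
                         "warp_tmid": tm, "run_scale": run_scale,
                         "spike_true_area": true_area[spike_row]})
        truth_rows.append(pd.DataFrame({
            "peptide_id": cat["peptide_id"], "run_id": run_id,
            "true_area": true_area, "true_apex_rt": apex,
            "identified_by_msms": identified}))

        # target PSMs (with occasional redundant duplicates of a spectrum)
        for i in np.flatnonzero(identified):
            n_dup = 1 + rng.poisson(cp.psm_redundancy)
            spec_counter += 1
            key = f"{run_id}_s{spec_counter:06d}"
            obs_rt = apex[i] + rng.normal(0.0, npar.rt_obs_sd)
            for _ in range(n_dup):
                psm_rows.append({
                    "run_id": run_id, "spectrum_key": key,
                    "peptide_id": cat["peptide_id"].iloc[i],
                    "charge": int(cat["charge"].iloc[i]),
                    "precursor_mass": cat["mass"].iloc[i] * (1.0 + ppm_off[i] * 1e-6),
                    "observed_rt": obs_rt,
                    "score": max(0.0, rng.normal(cp.target_score_mean,
                                                 cp.target_score_sd)),
                    "is_decoy": False,
                    "protein_id": cat["protein_id"].iloc[i]})

    # decoy PSMs: null score distribution shifted below targets
    n_targets = len(psm_rows)
    n_decoys = int(round(cp.decoy_rate * n_targets))
    run_ids = design.run_ids
    for d in range(n_decoys):
        spec_counter += 1
        rid = run_ids[rng.integers(0, len(run_ids))]
        psm_rows.append({
            "run_id": rid, "spectrum_key": f"{rid}_s{spec_counter:06d}",
            "peptide_id": f"DECOY{d + 1:05d}", "charge": 2,
            "precursor_mass": rng.uniform(*cp.mass_range),
            "observed_rt": rng.uniform(*npar.rt_range),
            "score": max(0.0, rng.normal(cp.decoy_score_mean, cp.decoy_score_sd)),
            "is_decoy": True, "protein_id": "DECOY"})

    psms = pd.DataFrame(psm_rows)
    truth = GroundTruth(peptides=cat,
                        truth=pd.concat(truth_rows, ignore_index=True),
                        runs=pd.DataFrame(run_rows), design=design)
    return runs, psms, truth


def truth_abundance_matrix(truth: GroundTruth):
    """Spike-normalized abundance matrix built from the ground truth itself.

    Models a perfect quantitation stage (true areas, true spike), so the
    statistical machinery downstream of quantitation can be exercised at
    exactly the generator's abundance structure. Cells with true area 0 are
    missing; provenance reflects the identification mask.
    """
    from .quant import AbundanceMatrix

    wide = truth.truth.pivot(index="peptide_id", columns="run_id",
                             values="true_area")
    spike_id = [p for p in wide.index if p == SPIKE_PEPTIDE_ID]
    if not spike_id:
        raise ValueError("ground truth lacks the spike peptide")
    run_ids = truth.design.run_ids
    values = (wide.drop(index=spike_id) / wide.loc[spike_id[0]])[run_ids]
    values = values.where(values > 0)
    ident = (truth.truth.pivot(index="peptide_id", columns="run_id",
                               values="identified_by_msms")
             .drop(index=spike_id)[run_ids])
    prov = pd.DataFrame(np.where(values.isna(), "",
                                 np.where(ident.astype(bool), "wavelet",
                                          "backfill")),
                        index=values.index, columns=values.columns)
    pp = truth.peptides.set_index("peptide_id")["protein_id"].drop(spike_id)
    return AbundanceMatrix(values, prov, pp.reindex(values.index), truth.design)
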