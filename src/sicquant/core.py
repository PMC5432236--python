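"""Shared domain types for the quantitation pipeline.

The pipeline represents one LC-MS acquisition as a :class:`CentroidRun` —
time-ordered centroided MS1 scans — and the experimental layout as a
:class:`StudyDesign` (groups x biological replicates x technical replicates).
Peptide-spectrum matches and abundance matrices travel as pandas DataFrames
with the column schemas documented in :mod:`sicquant.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StudyDesign",
    "CentroidRun",
    "PeakQuant",
    "SPIKE_PEPTIDE_ID",
    "SPIKE_PEPTIDE_MASS",
    "SPIKE_PEPTIDE_CHARGE",
    "PROTON_MASS",
]

# Exogenous spiked standard: phosphorylated angiotensin II (DRVpYIHPF).
# Monoisotopic mass of DRVYIHPF (1045.53451 Da) plus HPO3 (79.96633 Da).
SPIKE_PEPTIDE_ID = "DRVpYIHPF"
SPIKE_PEPTIDE_MASS = 1125.50084
SPIKE_PEPTIDE_CHARGE = 2
PROTON_MASS = 1.00727646688


def mass_to_mz(neutral_mass: float, charge: int) -> float:
    """m/z of a peptide of given neutral monoisotopic mass at a charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class StudyDesign:
    """Experimental layout: groups x biological x technical replicates.

    The default layout of the supported study type is 4 groups x 3 animals
    per group x 4 injections per animal = 48 runs.
    """

    groups: tuple[str, ...] = ("control", "placebo", "rapamycin", "incomplete_sf")
    n_biological: int = 3
    n_technical: int = 4

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("design needs at least one group")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be >= 1")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def n_runs(self) -> int:
        return len(self.groups) * self.n_biological * self.n_technical

    def run_id(self, group: str, biological: int, technical: int) -> str:
        return f"{group}_b{biological}_t{technical}"

    def bio_id(self, group: str, biological: int) -> str:
        return f"{group}_b{biological}"

    def iter_runs(self):
        """Yield (run_id, group, biological, technical), 1-based replicate indices."""
        for group in self.groups:
            for b in range(1, self.n_biological + 1):
                for t in range(1, self.n_technical + 1):
                    yield self.run_id(group, b, t), group, b, t

    @property
    def run_ids(self) -> list[str]:
        return [r[0] for r in self.iter_runs()]

    @property
    def bio_ids(self) -> list[str]:
        return [
            self.bio_id(g, b)
            for g in self.groups
            for b in range(1, self.n_biological + 1)
        ]

    def run_table(self):
        """DataFrame mapping run_id -> (group, biological, technical, bio_id)."""
        import pandas as pd

        rows = [
            {"run_id": r, "group": g, "biological": b, "technical": t,
             "bio_id": self.bio_id(g, b)}
            for r, g, b, t in self.iter_runs()
        ]
        return pd.DataFrame(rows)

    def group_of_bio(self, bio_id: str) -> str:
        for g in self.groups:
            for b in range(1, self.n_biological + 1):
                if self.bio_id(g, b) == bio_id:
                    return g
        raise KeyError(f"unknown biological sample {bio_id!r}")


class CentroidRun:
    """One LC-MS run as time-ordered centroided MS1 scans.

    Internally centroids are held as flat arrays sorted by m/z (``mz``,
    ``intensity``, ``scan_index``) plus the per-scan retention times
    (``scan_rts``, seconds, strictly increasing), which makes narrow-window
    SIC extraction a binary search rather than a scan loop.
    """

    def __init__(self, run_id: str, scan_rts: np.ndarray, mz: np.ndarray,
                 intensity: np.ndarray, scan_index: np.ndarray,
                 group: str = "", biological: int = 0, technical: int = 0,
                 spike_peptide_id: str = SPIKE_PEPTIDE_ID):
        scan_rts = np.asarray(scan_rts, dtype=float)
        if scan_rts.size > 1 and not np.all(np.diff(scan_rts) > 0):
            raise ValueError(f"run {run_id!r}: scan times must be strictly increasing")
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        scan_index = np.asarray(scan_index, dtype=np.int64)
        if not (mz.shape == intensity.shape == scan_index.shape):
            raise ValueError("mz/intensity/scan_index must have equal length")
        order = np.argsort(mz, kind="stable")
        self.run_id = run_id
        self.scan_rts = scan_rts
        self.mz = mz[order]
        self.intensity = intensity[order]
        self.scan_index = scan_index[order]
        self.group = group
        self.biological = biological
        self.technical = technical
        self.spike_peptide_id = spike_peptide_id

    @classmethod
    def from_scans(cls, run_id: str, scans, **meta) -> "CentroidRun":
        """Build from an iterable of (rt, mz_array, intensity_array) triples."""
        rts, mzs, ints, idx = [], [], [], []
        for i, (rt, m, x) in enumerate(scans):
            m = np.asarray(m, dtype=float)
            x = np.asarray(x, dtype=float)
            rts.append(float(rt))
            mzs.append(m)
            ints.append(x)
            idx.append(np.full(m.size, i, dtype=np.int64))
        n = len(rts)
        cat = (lambda a: np.concatenate(a) if a else np.empty(0))
        return cls(run_id, np.asarray(rts), cat(mzs), cat(ints), cat(idx), **meta)

    @property
    def n_scans(self) -> int:
        return self.scan_rts.size

    def iter_scans(self):
        """Yield (rt, mz_array, intensity_array) per scan, m/z-sorted within scan."""
        order = np.argsort(self.scan_index, kind="stable")
        si = self.scan_index[order]
        bounds = np.searchsorted(si, np.arange(self.n_scans + 1))
        for i in range(self.n_scans):
            sel = order[bounds[i]:bounds[i + 1]]
            sub = np.argsort(self.mz[sel], kind="stable")
            yield self.scan_rts[i], self.mz[sel][sub], self.intensity[sel][sub]


@dataclass
class PeakQuant:
    """One quantified peptide-in-run: SIC peak bounds, area and provenance."""

    peptide_id: str
    run_id: str
    rt_start: float
    rt_apex: float
    rt_end: float
    raw_area: float
    method: str  # wavelet | fallback | backfill
    normalized_area: float | None = None
    below_noise: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise ValueError("peak bounds must satisfy rt_start <= rt_apex <= rt_end")
        if self.raw_area < 0:
            raise ValueError("raw_area must be >= 0")
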