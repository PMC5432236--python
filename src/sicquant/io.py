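"""Formats, configuration and logging.

The native interchange format is documented tab-separated tables (schemas
in :data:`SCHEMAS`); centroided runs can also be round-tripped through
minimal mzML (centroid MS1 spectra only) for interoperability with standard
tooling, read back with pyteomics.
"""

from __future__ import annotations

import base64
import hashlib
import logging
import struct
import zlib
from dataclasses import dataclass, field, fields, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CentroidRun, StudyDesign
from .quant import QuantParams
from .synthetic import CatalogParams, NoiseParams

__all__ = [
    "SCHEMAS",
    "PipelineConfig",
    "write_table",
    "read_table",
    "write_centroid_run",
    "read_centroid_run",
    "write_runs",
    "read_centroid_runs",
    "write_mzml",
    "read_mzml",
    "sha256_of",
    "get_logger",
    "log_stage",
]

# Column schemas of every table the pipeline writes. A writer must emit
# exactly these columns (run/sample columns are appended where noted).
SCHEMAS: dict[str, list[str]] = {
    "psms": ["run_id", "spectrum_key", "peptide_id", "charge",
             "precursor_mass", "observed_rt", "score", "is_decoy", "protein_id"],
    "filter_report": ["n_input", "n_after_dedup", "n_after_score_filter",
                      "score_cutoff_used", "estimated_fdr_at_cutoff",
                      "n_retained_targets"],
    "peak_quants": ["peptide_id", "run_id", "rt_start", "rt_apex", "rt_end",
                    "raw_area", "normalized_area", "method", "below_noise"],
    "abundance_matrix": ["peptide_id", "protein_id"],       # + one column per run
    "provenance_matrix": ["peptide_id"],                    # + one column per run
    "bio_matrix": ["peptide_id", "protein_id"],             # + one column per bio sample
    "cov_summary": ["level", "peptide_id", "unit", "cov"],
    "venn_counts": ["scope", "kind", "subset", "n_sets", "count", "containing"],
    "pca_scores": ["sample_id", "component", "score", "variance_fraction"],
    "differential": ["peptide_id", "protein_id", "f_stat", "p_omnibus",
                     "contrast", "log2_fc", "mean_num", "mean_den", "p_raw",
                     "p_adj", "significant"],
    "pathway_input": ["protein_id", "contrast", "n_significant_peptides"],
    "heatmap_ratios": ["peptide_id", "protein_id"],         # + one column per bio sample
    "marker_panel": ["protein_id", "groups", "n_peptides"],  # + per-target-group stats
    "ground_truth": ["peptide_id", "run_id", "true_area", "true_apex_rt",
                     "identified_by_msms"],
    "truth_runs": ["run_id", "group", "biological", "technical", "warp_a",
                   "warp_b", "warp_c", "warp_tmid", "run_scale",
                   "spike_true_area"],
    "run_meta": ["run_id", "group", "biological", "technical"],
    "centroid_run": ["scan", "rt", "mz", "intensity"],
    "manifest": ["file", "sha256", "n_rows", "status"],
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with defaults at the supported values.

    Quantitation defaults (10 ppm window, 2-20 s minimum widths, 80 s
    maximum width, S/N 10, noise-floor area 1000, Mowse-type score > 20,
    1% FDR, alpha 0.05, >= 2 / >= 5 peptide filters, DRVpYIHPF spike) are
    the study parameters this pipeline reproduces; the remaining knobs
    (BH adjustment, log2 scale, warp family, marker rule) are this
    package's documented decisions.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    catalog: CatalogParams = field(default_factory=CatalogParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    quant: QuantParams = field(default_factory=QuantParams)
    min_score: float = 20.0
    fdr_level: float = 0.01
    filter_order: tuple[str, ...] = ("dedup", "score", "fdr")
    moderated: bool = True
    log2: bool = True
    alpha: float = 0.05
    adjust_method: str = "bh"
    pca_impute: str = "half_min"
    control_group: str = "control"
    target_groups: tuple[str, ...] = ("placebo", "rapamycin")
    rollup_min_peptides: int = 2
    heatmap_min_peptides: int = 5
    marker_threshold: float = 1.5
    write_runs: bool = False
    render_heatmap: bool = False

    def to_dict(self) -> dict:
        def conv(v):
            if is_dataclass(v) and not isinstance(v, type):
                return {k: conv(x) for k, x in asdict(v).items()}
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v
        return {f.name: conv(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def tup(x):
            return tuple(x) if isinstance(x, list) else x
        kw = dict(d)
        for key, typ in [("design", StudyDesign), ("catalog", CatalogParams),
                         ("noise", NoiseParams), ("quant", QuantParams)]:
            if key in kw and isinstance(kw[key], dict):
                sub = {k: tup(v) for k, v in kw[key].items()}
                kw[key] = typ(**sub)
        for key in ("filter_order", "target_groups"):
            if key in kw:
                kw[key] = tup(kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Write a TSV; if a schema is named, its fixed columns must lead."""
    path = Path(path)
    if schema is not None:
        want = SCHEMAS[schema]
        got = list(df.columns)[: len(want)]
        if got != want:
            raise ValueError(
                f"{schema} schema expects leading columns {want}, got {got}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_centroid_run(run: CentroidRun, path) -> Path:
    """One row per centroid; a scan without centroids keeps its place on the
    scan grid as a single row with empty m/z and intensity fields."""
    rows = []
    for i, (rt, mzs, ints) in enumerate(run.iter_scans()):
        if mzs.size == 0:
            rows.append((i, rt, np.nan, np.nan))
        for m, x in zip(mzs, ints):
            rows.append((i, rt, m, x))
    df = pd.DataFrame(rows, columns=SCHEMAS["centroid_run"])
    return write_table(df, path, "centroid_run")


def read_centroid_run(path, run_id: str | None = None, **meta) -> CentroidRun:
    """Read one native centroid-run table; scan times must be ordered."""
    path = Path(path)
    df = read_table(path)
    missing = [c for c in SCHEMAS["centroid_run"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    scans = []
    for scan, sub in df.groupby("scan", sort=True):
        rts = sub["rt"].unique()
        if rts.size != 1:
            raise ValueError(f"{path}: scan {scan} has inconsistent retention times")
        sub = sub.dropna(subset=["mz"])
        scans.append((float(rts[0]), sub["mz"].to_numpy(), sub["intensity"].to_numpy()))
    rid = run_id if run_id is not None else path.stem
    try:
        return CentroidRun.from_scans(rid, scans, **meta)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_runs(runs: list[CentroidRun], out_dir) -> Path:
    """Write a directory of native run tables plus run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for r in runs:
        write_centroid_run(r, out / f"{r.run_id}.tsv")
        meta.append({"run_id": r.run_id, "group": r.group,
                     "biological": r.biological, "technical": r.technical})
    write_table(pd.DataFrame(meta, columns=SCHEMAS["run_meta"]),
                out / "run_meta.tsv", "run_meta")
    return out


def read_centroid_runs(path) -> list[CentroidRun]:
    """Read a run directory (native tables + run_meta.tsv, or mzML files)."""
    path = Path(path)
    meta_path = path / "run_meta.tsv"
    meta = {}
    if meta_path.exists():
        for _, row in read_table(meta_path).iterrows():
            meta[row["run_id"]] = dict(group=row["group"],
                                       biological=int(row["biological"]),
                                       technical=int(row["technical"]))
    runs = []
    for f in sorted(path.glob("*.tsv")):
        if f.name == "run_meta.tsv":
            continue
        runs.append(read_centroid_run(f, **meta.get(f.stem, {})))
    for f in sorted(path.glob("*.mzML")):
        runs.append(read_mzml(f, **meta.get(f.stem, {})))
    if not runs:
        raise ValueError(f"no run files found under {path}")
    return runs


# ---------------------------------------------------------------------------
# Minimal mzML (centroid MS1 only)
# ---------------------------------------------------------------------------

def _encode_array(a: np.ndarray) -> str:
    return base64.b64encode(zlib.compress(
        struct.pack(f"<{a.size}d", *np.asarray(a, dtype=float)))).decode()


def write_mzml(run: CentroidRun, path) -> Path:
    """Serialize as minimal mzML: centroided MS1 spectra, 64-bit arrays."""
    path = Path(path)
    spectra = []
    for i, (rt, mzs, ints) in enumerate(run.iter_scans()):
        b_mz = _encode_array(mzs)
        b_int = _encode_array(ints)
        spectra.append(f"""\
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mzs.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitName="second" unitAccession="UO:0000010"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(b_mz)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitName="m/z" unitAccession="MS:1000040"/>
            <binary>{b_mz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(b_int)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitName="number of detector counts" unitAccession="MS:1000131"/>
            <binary>{b_int}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "\n".join(spectra)
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run.run_id}">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run.run_id}">
    <spectrumList count="{run.n_scans}" defaultDataProcessingRef="dp1">
{body}
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(doc)
    return path


def _decode_binary(bda_elem, ns: str) -> np.ndarray:
    accessions = {e.get("accession") for e in bda_elem.findall(f"{ns}cvParam")}
    raw_elem = bda_elem.find(f"{ns}binary")
    raw = base64.b64decode((raw_elem.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, run_id: str | None = None, **meta) -> CentroidRun:
    """Read centroided MS1 spectra from mzML; profile-mode data is rejected.

    Supports 32/64-bit float arrays, optionally zlib-compressed; scan start
    times in seconds or minutes.
    """
    from lxml import etree

    path = Path(path)
    scans = []
    ns = "{http://psi.hupo.org/ms/mzml}"
    for _, spec in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        params = {e.get("accession"): e.get("value")
                  for e in spec.findall(f"{ns}cvParam")}
        ms_level = int(params.get("MS:1000511", "1"))
        if ms_level != 1:
            spec.clear()
            continue
        if "MS:1000128" in params:  # profile spectrum
            raise ValueError(
                f"{path}: spectrum {spec.get('id')!r} is profile-mode; "
                "centroid the data first")
        scan_elem = spec.find(f"{ns}scanList/{ns}scan")
        rt = None
        if scan_elem is not None:
            for cv in scan_elem.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitAccession") == "UO:0000031":  # minute
                        rt *= 60.0
        if rt is None:
            raise ValueError(f"{path}: spectrum {spec.get('id')!r} lacks a "
                             "scan start time")
        arrays = {}
        for bda in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            acc = {e.get("accession") for e in bda.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                arrays["mz"] = _decode_binary(bda, ns)
            elif "MS:1000515" in acc:
                arrays["intensity"] = _decode_binary(bda, ns)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {spec.get('id')!r} lacks "
                             "m/z or intensity arrays")
        scans.append((rt, arrays["mz"], arrays["intensity"]))
        spec.clear()
    rid = run_id if run_id is not None else path.stem
    try:
        return CentroidRun.from_scans(rid, scans, **meta)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# Logging / checksums
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def get_logger(level: str = "INFO") -> logging.Logger:
    logger = logging.getLogger("sicquant")
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level.upper())
    return logger


def log_stage(logger: logging.Logger, stage: str, **kv) -> None:
    """Structured key=value stage log line (machine-checkable)."""
    parts = " ".join(f"{k}={v}" for k, v in kv.items())
    logger.info("stage=%s %s", stage, parts)
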