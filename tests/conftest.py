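"""Shared fixtures: synthetic studies at a few scales.

The full default study (48 runs) and its quantitation are expensive, so
they are session-scoped and shared by every test that needs them.
"""

import numpy as np
import pandas as pd
import pytest

import sicquant as sq
from sicquant.synthetic import CatalogParams, NoiseParams

STUDY_SEED = 101


@pytest.fixture(scope="session")
def default_study():
    """Full default synthetic study: 48 runs, 60 proteins x 5 peptides."""
    return sq.generate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def default_confident(default_study):
    _, psms, _ = default_study
    confident, report = sq.filter_chain(psms)
    return confident, report


@pytest.fixture(scope="session")
def default_quant(default_study, default_confident):
    """Quantitation of the full default study (the expensive fixture)."""
    runs, _, _ = default_study
    confident, _ = default_confident
    matrix, quants = sq.quantify_study(runs, confident, sq.StudyDesign())
    return matrix, quants


@pytest.fixture(scope="session")
def small_study():
    """Two-group, four-run study small enough for per-test quantitation."""
    design = sq.StudyDesign(groups=("a", "b"), n_biological=1, n_technical=2)
    catalog = CatalogParams(n_proteins=12, peptides_per_protein=2,
                            fraction_differential=0.0, msms_dropout_rate=0.0,
                            decoy_rate=0.0, psm_redundancy=0.0)
    runs, psms, truth = sq.generate_study(design, catalog, seed=7)
    return design, runs, psms, truth


def make_psm_frame(rows):
    """PSM DataFrame from (run, spectrum, peptide, score, is_decoy) tuples."""
    return pd.DataFrame([
        {"run_id": r, "spectrum_key": s, "peptide_id": p, "charge": 2,
         "precursor_mass": 1000.0, "observed_rt": 600.0, "score": sc,
         "is_decoy": d, "protein_id": "PROT"}
        for r, s, p, sc, d in rows])
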