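"""SIC extraction, peak detection, alignment, backfill, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sicquant as sq
from sicquant.core import CentroidRun, PeakQuant
from sicquant.quant import (QuantParams, SICTrace, align_retention_times,
                            build_abundance_matrix, detect_peak_multipass,
                            extract_sic, fallback_integrate,
                            normalize_to_spike)
from sicquant.synthetic import generate_chromatographic_peak

from conftest import make_psm_frame


def trace_from_profile(rts, y, mz=1000.0):
    return SICTrace("run", mz, 10.0, np.asarray(rts, float),
                    np.asarray(y, float), "PEP")


class TestExtractSic:
    def make_run(self, scans):
        return CentroidRun.from_scans("r", scans)

    def test_ppm_window_arithmetic(self):
        run = self.make_run([
            (1.0, [1000.0050], [10.0]),   # +5 ppm: inside
            (2.0, [1000.0200], [20.0]),   # +20 ppm: outside
            (3.0, [999.9950, 1000.0], [5.0, 7.0]),  # both inside, summed
        ])
        tr = extract_sic(run, 1000.0, 10.0)
        np.testing.assert_allclose(tr.intensity, [10.0, 0.0, 12.0])

    def test_empty_run(self):
        tr = extract_sic(self.make_run([]), 1000.0)
        assert len(tr) == 0

    def test_rt_range_restricts_trace(self):
        run = self.make_run([(float(t), [1000.0], [1.0]) for t in range(10)])
        tr = extract_sic(run, 1000.0, rt_range=(3.0, 6.0))
        np.testing.assert_array_equal(tr.rts, [3.0, 4.0, 5.0, 6.0])

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            extract_sic(self.make_run([]), -5.0)

    def test_unsorted_scan_times_rejected(self):
        with pytest.raises(ValueError):
            CentroidRun.from_scans("r", [(2.0, [1.0], [1.0]),
                                         (1.0, [1.0], [1.0])])


class TestDetectPeak:
    def test_noiseless_gaussian_area_within_5pct(self):
        rts, y = generate_chromatographic_peak(600.0, 4.0, 10000.0, 1.0,
                                               rt_start=450, rt_end=750)
        q = detect_peak_multipass(trace_from_profile(rts, y))
        assert q is not None
        assert q.method == "wavelet"
        assert abs(q.raw_area - 10000.0) / 10000.0 < 0.05
        assert abs(q.rt_apex - 600.0) < 2.0

    def test_flat_noise_only_trace_rejected(self):
        rng = np.random.default_rng(0)
        rts = np.arange(300.0, 900.0)
        y = np.clip(rng.normal(50.0, 10.0, rts.size), 0, None)
        assert detect_peak_multipass(trace_from_profile(rts, y)) is None

    def test_expected_rt_selects_nearest_of_equal_peaks(self):
        rts = np.arange(200.0, 500.0)
        y = np.zeros_like(rts)
        for apex in (300.0, 400.0):
            y += 1000.0 * np.exp(-0.5 * ((rts - apex) / 4.0) ** 2)
        q = detect_peak_multipass(trace_from_profile(rts, y), expected_rt=395.0)
        assert q is not None
        assert abs(q.rt_apex - 400.0) < 3.0
        q2 = detect_peak_multipass(trace_from_profile(rts, y), expected_rt=310.0)
        assert abs(q2.rt_apex - 300.0) < 3.0

    def test_width_capped_at_maximum(self):
        rts = np.arange(0.0, 1200.0)
        y = 1000.0 * np.exp(-0.5 * ((rts - 600.0) / 60.0) ** 2)  # very broad
        q = detect_peak_multipass(trace_from_profile(rts, y))
        assert q is not None
        assert q.rt_end - q.rt_start <= 80.0 + 1e-9

    def test_empty_trace(self):
        assert detect_peak_multipass(trace_from_profile([], [])) is None


class TestFallback:
    def test_rectangular_pulse_area(self):
        rts = np.arange(500.0, 700.0)
        y = np.where(np.abs(rts - 600.0) <= 10.0, 100.0, 0.0)
        q = fallback_integrate(trace_from_profile(rts, y), 40.0)
        assert q.method == "fallback"
        assert abs(q.raw_area - 2000.0) / 2000.0 < 0.06

    def test_all_zero_trace_below_noise(self):
        rts = np.arange(500.0, 600.0)
        q = fallback_integrate(trace_from_profile(rts, np.zeros(100)), 40.0)
        assert q.raw_area == 0.0
        assert q.below_noise

    def test_gaussian_within_10pct_when_window_covers(self):
        rts, y = generate_chromatographic_peak(600.0, 8.0, 5000.0, 1.0,
                                               rt_start=450, rt_end=750)
        q = fallback_integrate(trace_from_profile(rts, y), 40.0)  # > 3 sigma
        assert abs(q.raw_area - 5000.0) / 5000.0 < 0.10

    def test_empty_trace(self):
        assert fallback_integrate(trace_from_profile([], [])) is None


def shifted_anchor_psms(shift_fn, n=60, seed=0, rt_noise=0.5):
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(400, 2800, n))
    rows = []
    for i, rt in enumerate(base):
        rows.append(("A", f"a{i}", f"P{i}", 40.0, False))
        rows.append(("B", f"b{i}", f"P{i}", 40.0, False))
    psms = make_psm_frame(rows)
    obs = np.empty(2 * n)
    obs[0::2] = base + rng.normal(0, rt_noise, n)
    obs[1::2] = shift_fn(base) + rng.normal(0, rt_noise, n)
    psms["observed_rt"] = obs
    return psms, base


class TestAlignment:
    def test_identical_runs_identity_mapping(self):
        psms, base = shifted_anchor_psms(lambda t: t, rt_noise=0.0)
        warps = align_retention_times(["A", "B"], psms)
        grid = np.linspace(500, 2700, 50)
        np.testing.assert_allclose(warps["B"].map(grid), grid, atol=0.5)
        assert warps["B"].median_residual < 0.1

    def test_constant_shift_recovered(self):
        psms, _ = shifted_anchor_psms(lambda t: t + 30.0, n=100, seed=1)
        warps = align_retention_times(["A", "B"], psms)
        grid = np.linspace(500, 2700, 50)
        shift = warps["B"].map(grid) - grid
        assert np.all(np.abs(shift - 30.0) < 2.0)

    def test_inverse_roundtrip(self):
        psms, _ = shifted_anchor_psms(lambda t: t + 25.0 + 1e-5 * (t - 1600) ** 2,
                                      n=100, seed=2)
        w = align_retention_times(["A", "B"], psms)["B"]
        grid = np.linspace(500, 2700, 40)
        np.testing.assert_allclose(w.inverse(w.map(grid)), grid, atol=0.5)

    def test_too_few_anchors_identity_with_warning(self):
        psms, _ = shifted_anchor_psms(lambda t: t + 30.0, n=5)
        with pytest.warns(UserWarning, match="anchors"):
            warps = align_retention_times(["A", "B"], psms)
        np.testing.assert_allclose(warps["B"].map(1000.0), 1000.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50), st.floats(0, 3))
    def test_warp_strictly_monotone(self, seed, shift, noise_sd):
        rng = np.random.default_rng(seed)
        n = 40
        base = np.sort(rng.uniform(400, 2800, n))
        rows = []
        for i in range(n):
            rows.append(("A", f"a{i}", f"P{i}", 40.0, False))
            rows.append(("B", f"b{i}", f"P{i}", 40.0, False))
        psms = make_psm_frame(rows)
        obs = np.empty(2 * n)
        obs[0::2] = base
        obs[1::2] = base + shift + rng.normal(0, noise_sd, n)
        psms["observed_rt"] = obs
        w = align_retention_times(["A", "B"], psms)["B"]
        grid = np.linspace(300, 3000, 400)
        assert np.all(np.diff(w.map(grid)) > 0)


class TestNormalization:
    def quant(self, pid, rid, area, **kw):
        return PeakQuant(pid, rid, 0.0, 1.0, 2.0, area, "wavelet", **kw)

    def test_simple_division(self):
        qs = [self.quant("A", "r1", 5000.0), self.quant("SPK", "r1", 2500.0)]
        out = normalize_to_spike(qs, "SPK")
        assert out[0].normalized_area == 2.0
        assert out[1].normalized_area == 1.0

    def test_missing_spike_is_hard_error_naming_run(self):
        qs = [self.quant("A", "r7", 5000.0)]
        with pytest.raises(ValueError, match="r7"):
            normalize_to_spike(qs, "SPK")

    def test_below_noise_spike_rejected(self):
        qs = [self.quant("A", "r1", 5000.0),
              self.quant("SPK", "r1", 500.0, below_noise=True)]
        with pytest.raises(ValueError, match="noise floor"):
            normalize_to_spike(qs, "SPK")


class TestAbundanceMatrix:
    def make_quants(self, n_pep, design, below=()):
        qs = []
        for i in range(n_pep):
            for rid in design.run_ids:
                qs.append(PeakQuant(f"P{i}", rid, 0, 1, 2, 5000.0, "wavelet",
                                    normalized_area=2.0,
                                    below_noise=(f"P{i}", rid) in below))
        return qs

    def test_full_matrix_population(self):
        design = sq.StudyDesign()
        m = build_abundance_matrix(self.make_quants(10, design),
                                   {f"P{i}": "PR" for i in range(10)}, design)
        assert m.values.shape == (10, 48)
        assert int(m.values.notna().sum().sum()) == 480

    def test_below_noise_cell_missing(self):
        design = sq.StudyDesign()
        rid = design.run_ids[0]
        m = build_abundance_matrix(
            self.make_quants(10, design, below={("P0", rid)}),
            {f"P{i}": "PR" for i in range(10)}, design)
        assert int(m.values.notna().sum().sum()) == 479
        assert np.isnan(m.values.loc["P0", rid])

    def test_duplicate_quant_rejected(self):
        design = sq.StudyDesign()
        qs = self.make_quants(1, design)
        qs.append(qs[0])
        with pytest.raises(ValueError, match="duplicate"):
            build_abundance_matrix(qs, {"P0": "PR"}, design)


class TestEndToEndQuant:
    def test_areas_track_ground_truth(self, small_study):
        design, runs, psms, truth = small_study
        confident, _ = sq.filter_chain(psms)
        matrix, quants = sq.quantify_study(runs, confident, design)
        tt = truth.truth.set_index(["peptide_id", "run_id"])["true_area"]
        errs = [abs(q.raw_area - tt[(q.peptide_id, q.run_id)])
                / tt[(q.peptide_id, q.run_id)]
                for q in quants if tt[(q.peptide_id, q.run_id)] > 0]
        assert np.median(errs) < 0.05

    def test_backfill_recovers_dropped_identifications(self, default_study,
                                                       default_quant):
        """Cells whose MS/MS identification was dropped but whose signal is
        real are backfilled close to the true area."""
        _, _, truth = default_study
        matrix, quants = default_quant
        tt = truth.truth.set_index(["peptide_id", "run_id"])
        back = [q for q in quants if q.method == "backfill"
                and not q.below_noise]
        assert len(back) > 100
        errs = np.array([abs(q.raw_area - tt.loc[(q.peptide_id, q.run_id),
                                                 "true_area"])
                         / tt.loc[(q.peptide_id, q.run_id), "true_area"]
                         for q in back])
        assert np.median(errs) < 0.10

    def test_provenance_marks_backfilled_cells(self, default_quant):
        matrix, _ = default_quant
        methods = set(np.unique(matrix.provenance.to_numpy()))
        assert "backfill" in methods
        assert methods <= {"wavelet", "fallback", "backfill", ""}
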