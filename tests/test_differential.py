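"""Per-peptide ANOVA, contrasts, multiple-testing adjustment, roll-ups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sicquant as sq
from sicquant.differential import (adjust_pvalues, anova_per_peptide,
                                   significant_protein_rollup,
                                   volcano_table)
from sicquant.stats import BioReplicateMatrix


def bio_matrix(values: pd.DataFrame, design,
               proteins=None) -> BioReplicateMatrix:
    pp = pd.Series(proteins if proteins is not None else "PR",
                   index=values.index)
    return BioReplicateMatrix(values, values.notna().astype(int), pp, design)


@pytest.fixture
def two_group_design():
    return sq.StudyDesign(groups=("g1", "g2"), n_biological=3, n_technical=1)


class TestAnova:
    def test_identical_values_nothing_significant(self, two_group_design):
        vals = pd.DataFrame([[2.0] * 6, [5.0] * 6],
                            index=["P0", "P1"],
                            columns=two_group_design.bio_ids)
        res, _ = anova_per_peptide(bio_matrix(vals, two_group_design),
                                   two_group_design)
        assert not res["significant"].any()
        assert (res["p_raw"] == 1.0).all()

    def test_large_separation_detected(self, two_group_design):
        """Means 1.0 vs 4.0 (log2 FC = 2) with tiny within-group noise."""
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(20):
            g1 = 1.0 * np.exp(rng.normal(0, 0.01, 3))
            g2 = 4.0 * np.exp(rng.normal(0, 0.01, 3))
            rows[f"P{i}"] = np.r_[g1, g2]
        vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=two_group_design.bio_ids)
        res, _ = anova_per_peptide(bio_matrix(vals, two_group_design),
                                   two_group_design, moderated=False)
        assert res["significant"].all()
        assert np.allclose(res["log2_fc"], 2.0, atol=0.1)

    def test_plain_anova_matches_scipy_oracle(self):
        design = sq.StudyDesign(n_biological=3, n_technical=1)
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.lognormal(2, 0.5, (30, 12)),
                            index=[f"P{i}" for i in range(30)],
                            columns=design.bio_ids)
        res, _ = anova_per_peptide(bio_matrix(vals, design), design,
                                   moderated=False)
        omni = res.groupby("peptide_id").first()
        for pid in vals.index:
            y = np.log2(vals.loc[pid].to_numpy())
            f_ref, p_ref = sps.f_oneway(y[0:3], y[3:6], y[6:9], y[9:12])
            assert omni.loc[pid, "f_stat"] == pytest.approx(f_ref, rel=1e-9)
            assert omni.loc[pid, "p_omnibus"] == pytest.approx(p_ref, rel=1e-9)

    def test_peptide_with_insufficient_groups_skipped(self, two_group_design):
        vals = pd.DataFrame(
            [[1.0, np.nan, np.nan, 2.0, np.nan, np.nan],
             [1.0, 1.1, 0.9, 2.0, 2.1, 1.9]],
            index=["Pbad", "Pok"], columns=two_group_design.bio_ids)
        res, skipped = anova_per_peptide(bio_matrix(vals, two_group_design),
                                        two_group_design)
        assert list(skipped["peptide_id"]) == ["Pbad"]
        assert set(res["peptide_id"]) == {"Pok"}

    def test_contrasts_cover_all_group_pairs(self):
        design = sq.StudyDesign(n_biological=3, n_technical=1)
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.lognormal(2, 0.5, (3, 12)),
                            index=["P0", "P1", "P2"], columns=design.bio_ids)
        res, _ = anova_per_peptide(bio_matrix(vals, design), design)
        assert res.groupby("peptide_id")["contrast"].nunique().eq(6).all()

    def test_moderation_shrinks_variance_outliers(self, two_group_design):
        """An outlier tiny-variance peptide that is wildly significant under
        plain ANOVA is tempered by empirical-Bayes moderation."""
        rng = np.random.default_rng(3)
        rows = {f"P{i}": 2.0 ** rng.normal(1.0, 0.5, 6) for i in range(200)}
        rows["Ptiny"] = np.array([1.0, 1.0001, 0.9999, 1.001, 1.0009, 1.0011])
        vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=two_group_design.bio_ids)
        bm = bio_matrix(vals, two_group_design)
        plain, _ = anova_per_peptide(bm, two_group_design, moderated=False)
        mod, _ = anova_per_peptide(bm, two_group_design, moderated=True)
        p_plain = plain.set_index("peptide_id")["p_raw"]["Ptiny"]
        p_mod = mod.set_index("peptide_id")["p_raw"]["Ptiny"]
        assert p_mod > p_plain


class TestAdjustment:
    def test_bh_step_up_hand_calculation(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "bh")
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.2], "bh"), [0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(adjust_pvalues([1.0, 1.0, 1.0], "bh"),
                                   [1.0, 1.0, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 100)
        for method in ("bh", "holm"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [0.5, 2.0]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_pvalues(bad)

    def test_nan_passthrough(self):
        out = adjust_pvalues([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert not np.isnan(out[0])


class TestVolcano:
    def make_results(self, qs):
        return pd.DataFrame({
            "peptide_id": [f"P{i}" for i in range(len(qs))],
            "protein_id": "PR", "f_stat": 1.0, "p_omnibus": 0.5,
            "contrast": "g1_vs_g2", "log2_fc": 0.0,
            "mean_num": 1.0, "mean_den": 1.0,
            "p_raw": qs, "p_adj": qs, "significant": [q < 0.05 for q in qs]})

    def test_q_exactly_alpha_not_flagged(self):
        vt = volcano_table(self.make_results([0.05]), "g1_vs_g2")
        assert not vt["significant"].iloc[0]

    def test_unit_fold_change_is_zero_log2(self, two_group_design):
        vals = pd.DataFrame([[3.0, 3.1, 2.9, 3.0, 3.1, 2.9]], index=["P0"],
                            columns=two_group_design.bio_ids)
        res, _ = anova_per_peptide(bio_matrix(vals, two_group_design),
                                   two_group_design)
        vt = volcano_table(res, "g2_vs_g1")
        assert abs(vt["log2_fc"].iloc[0]) < 0.01

    def test_neg_log10_transform(self):
        vt = volcano_table(self.make_results([0.001]), "g1_vs_g2")
        assert vt["neg_log10_q"].iloc[0] == pytest.approx(3.0)

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            volcano_table(self.make_results([0.5]), "nope_vs_nada")


class TestRollup:
    def make_results(self, sig_counts):
        rows = []
        for prot, n_sig in sig_counts.items():
            for i in range(max(n_sig, 1)):
                rows.append({"peptide_id": f"{prot}_pep{i}",
                             "protein_id": prot, "contrast": "g1_vs_g2",
                             "p_adj": 0.01 if i < n_sig else 0.9,
                             "significant": i < n_sig})
        return pd.DataFrame(rows)

    def test_boundary_at_two_peptides(self):
        res = self.make_results({"A": 1, "B": 2, "C": 3})
        out = significant_protein_rollup(res, min_peptides=2)
        assert list(out["protein_id"]) == ["B", "C"]

    def test_no_significant_peptides_empty(self):
        res = self.make_results({"A": 0, "B": 0})
        assert len(significant_protein_rollup(res, 2)) == 0


class TestPermutation:
    def test_label_permutation_destroys_significance(self):
        """Permuting group labels on a study with real effects leaves only
        false positives (of the order alpha x m or fewer)."""
        design = sq.StudyDesign(n_biological=3, n_technical=1)
        rng = np.random.default_rng(7)
        n_pep = 300
        vals = {}
        for i in range(n_pep):
            base = rng.lognormal(2, 0.3, 12)
            if i < 60:  # real group effect
                base[3:6] *= 3.0
            vals[f"P{i}"] = base
        frame = pd.DataFrame.from_dict(vals, orient="index",
                                       columns=design.bio_ids)
        res, _ = anova_per_peptide(bio_matrix(frame, design), design,
                                   moderated=False)
        n_sig_real = int(res["significant"].sum())
        perm_counts = []
        for _ in range(5):
            cols = rng.permutation(frame.columns)
            perm = frame[cols]
            perm.columns = frame.columns
            pres, _ = anova_per_peptide(bio_matrix(perm, design), design,
                                       moderated=False)
            perm_counts.append(int(pres["significant"].sum()))
        assert n_sig_real > 50
        assert np.median(perm_counts) <= 0.05 * n_pep * 6
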