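import numpy as np
import pandas as pd
import pytest

from smokewas.celltype_profiles import (ProfileClusterer, celltype_association,
                                        classify_profiles,
                                        classify_response_pattern,
                                        cotinine_regression, ddct_fold_change,
                                        predict_wholeblood_delta)
from smokewas.validation import (mixture_conservation, pattern_recovery,
                                 prototype_patterns)

CELL_TYPES = ("CD14", "CD15", "CD19", "CD4T", "CD8T", "CD56")


def _profile(sig_types, alpha=0.05):
    """Profile row with p below alpha exactly for the given cell types."""
    data = {}
    for ct in CELL_TYPES:
        data[f"delta_{ct}"] = -0.2 if ct in sig_types else 0.0
        data[f"p_{ct}"] = alpha / 100 if ct in sig_types else 0.5
    return pd.Series(data)


class TestAssociationProfiles:
    def test_lymphoid_effect_confined_to_lymphoid_columns(self, cell_study):
        truth = cell_study["truth"]
        planted = truth.index[truth.effect_class == "lymphoid"]
        profiles = celltype_association(cell_study["celltype_betas"],
                                        cell_study["sheet"], probes=planted)
        assert (profiles["delta_CD19"].abs() > 0.02).all()
        assert (profiles["delta_CD4T"].abs() > 0.02).all()
        assert (profiles["delta_CD14"].abs() < 0.02).all()
        assert (profiles["delta_CD15"].abs() < 0.02).all()

    def test_missing_probe_names_matrix(self, cell_study):
        with pytest.raises(ValueError, match="CD14"):
            celltype_association({"CD14": cell_study["celltype_betas"]["CD14"]},
                                 cell_study["sheet"], probes=["not_a_probe"])

    def test_mixtures_attenuate_lineage_restricted_effects(self, cell_study):
        """A myeloid-plus-B effect is diluted in whole blood by the T-cell
        weight fraction: |whole-blood delta| < |granulocyte delta|."""
        truth = cell_study["truth"]
        planted = truth.index[truth.effect_class == "myeloid_plus_B"]
        matrices = dict(cell_study["celltype_betas"])
        matrices["whole_blood"] = cell_study["whole_blood"]
        profiles = celltype_association(matrices, cell_study["sheet"],
                                        probes=planted)
        assert (profiles["delta_whole_blood"].abs()
                < profiles["delta_CD15"].abs()).all()


class TestClustering:
    def test_identical_rows_merge_at_zero_distance(self):
        rows = pd.DataFrame({
            "delta_CD14": [0.3, 0.3, -0.5],
            "delta_CD19": [0.1, 0.1, 0.4],
        }, index=pd.Index(["a", "b", "c"], name="probe_id"))
        model = ProfileClusterer(n_clusters=2).fit(rows)
        assert model.linkage_[0, 2] == 0.0  # first merge at distance 0
        assert model.labels_["a"] == model.labels_["b"] != model.labels_["c"]

    def test_row_order_invariance(self, cell_study):
        truth = cell_study["truth"]
        planted = truth.index[truth.effect_class != "null"]
        profiles = celltype_association(cell_study["celltype_betas"],
                                        cell_study["sheet"], probes=planted)
        a = ProfileClusterer(n_clusters=2).fit(profiles)
        shuffled = profiles.sample(frac=1.0, random_state=1)
        b = ProfileClusterer(n_clusters=2).fit(shuffled)
        pd.testing.assert_series_equal(a.labels_, b.labels_)
        assert a.leaves_ == b.leaves_
        assert a.to_newick() == b.to_newick()

    def test_two_class_recovery_by_rand_index(self):
        out = pattern_recovery(n_seeds=5, seed=3)
        assert out["rand_index_mean"] >= 0.95

    def test_single_profile_rejected(self):
        row = pd.DataFrame({"delta_CD14": [0.1]},
                           index=pd.Index(["a"], name="probe_id"))
        with pytest.raises(ValueError, match="at least two"):
            ProfileClusterer().fit(row)

    def test_newick_contains_all_probes(self):
        rows = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)),
                            index=pd.Index(list("abcd"), name="probe_id"),
                            columns=["delta_x", "delta_y", "delta_z"])
        model = ProfileClusterer(n_clusters=2).fit(rows)
        nwk = model.to_newick()
        assert nwk.endswith(";")
        for probe in "abcd":
            assert probe in nwk


class TestPatternClassification:
    @pytest.mark.parametrize("sig,expected", [
        (CELL_TYPES, "pan_cell"),
        (("CD14", "CD15"), "myeloid"),
        (("CD14", "CD15", "CD19"), "myeloid_plus_B"),  # AHRR-like
        (("CD19", "CD4T"), "lymphoid"),                # GPR15-like
        (("CD19", "CD4T", "CD8T", "CD56"), "lymphoid"),
        (("CD4T", "CD8T"), "T_only"),                  # ITGAL-like
        (("CD4T",), "T_only"),
        (("CD14",), "monocyte_only"),                  # MYO1G-like
        ((), "none"),
        (("CD14", "CD4T"), "none"),                    # no rule matches
    ])
    def test_rule_table(self, sig, expected):
        assert classify_response_pattern(_profile(sig)) == expected

    def test_noiseless_prototypes_recover_planted_labels(self):
        out = prototype_patterns(seed=1)
        assert out == {cls: cls for cls in out}

    def test_classify_profiles_vectorised(self, cell_study):
        truth = cell_study["truth"]
        planted = truth.index[truth.effect_class != "null"]
        profiles = celltype_association(cell_study["celltype_betas"],
                                        cell_study["sheet"], probes=planted)
        labels = classify_profiles(profiles)
        assert set(labels.index) == set(planted)
        assert labels.isin(["pan_cell", "myeloid", "myeloid_plus_B", "T_only",
                            "monocyte_only", "lymphoid", "none"]).all()


class TestWholeBloodPrediction:
    def test_single_cell_type_effect_scales_by_weight(self):
        probes = pd.Index(["p1"], name="probe_id")
        never = pd.DataFrame({"A": [0.5], "B": [0.5]}, index=probes)
        current = pd.DataFrame({"A": [0.3], "B": [0.5]}, index=probes)
        w = pd.Series({"A": 0.25, "B": 0.75})
        pred = predict_wholeblood_delta(never, current, w, w)
        assert pred["p1"] == pytest.approx(0.25 * -0.2)

    def test_composition_shift_alone_produces_delta(self):
        probes = pd.Index(["p1"], name="probe_id")
        beta = pd.DataFrame({"A": [0.8], "B": [0.2]}, index=probes)
        w_never = pd.Series({"A": 0.5, "B": 0.5})
        w_current = pd.Series({"A": 0.7, "B": 0.3})
        pred = predict_wholeblood_delta(beta, beta, w_never, w_current)
        expected = (0.7 - 0.5) * 0.8 + (0.3 - 0.5) * 0.2
        assert pred["p1"] == pytest.approx(expected)

    def test_noiseless_simulator_conservation(self):
        out = mixture_conservation(seed=1)
        assert out["max_abs_error"] <= 1e-12

    def test_equal_composition_attenuation_bound(self, cell_study):
        """With shared composition, the predicted whole-blood delta never
        exceeds the largest single-cell-type delta in magnitude."""
        truth = cell_study["truth"]
        planted = truth.index[truth.effect_class != "null"]
        cell_types = cell_study["panel"].cell_types
        sheet = cell_study["sheet"]
        current = sheet.index[sheet.smoking_status == "current"]
        never = sheet.index[sheet.smoking_status == "never"]
        mean_n = pd.DataFrame(
            {ct: cell_study["celltype_betas"][ct].loc[planted, never].mean(axis=1)
             for ct in cell_types})
        mean_c = pd.DataFrame(
            {ct: cell_study["celltype_betas"][ct].loc[planted, current].mean(axis=1)
             for ct in cell_types})
        w = pd.Series(1 / len(cell_types), index=cell_types)
        pred = predict_wholeblood_delta(mean_n, mean_c, w, w)
        max_cell = (mean_c - mean_n).abs().max(axis=1)
        assert (pred.abs() <= max_cell + 1e-12).all()

    def test_off_simplex_weights_rejected(self):
        probes = pd.Index(["p1"], name="probe_id")
        beta = pd.DataFrame({"A": [0.5], "B": [0.5]}, index=probes)
        bad = pd.Series({"A": 0.9, "B": 0.9})
        with pytest.raises(ValueError, match="simplex"):
            predict_wholeblood_delta(beta, beta, bad, bad)


class TestCotinineRegression:
    def test_perfect_linear_relationship(self):
        cot = pd.Series([10.0, 20, 40, 80, 160], index=list("abcde"))
        betas = pd.Series(0.9 - 0.05 * np.log2(cot), index=cot.index)
        out = cotinine_regression(betas, cot)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(-0.05)

    def test_constant_betas_flat_fit(self):
        cot = pd.Series([10.0, 20, 40], index=list("abc"))
        betas = pd.Series([0.5, 0.5, 0.5], index=cot.index)
        out = cotinine_regression(betas, cot)
        assert out["slope"] == 0.0 and out["r_squared"] == 0.0

    def test_five_point_closed_form(self):
        """Slope and intercept match the closed-form least-squares formulas."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([0.82, 0.70, 0.65, 0.55, 0.52])
        cot = pd.Series(2.0 ** x, index=list("abcde"))  # log2 -> x
        betas = pd.Series(y, index=cot.index)
        out = cotinine_regression(betas, cot)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert out["slope"] == pytest.approx(slope)
        assert out["intercept"] == pytest.approx(y.mean() - slope * x.mean())

    def test_zero_variance_predictor_rejected(self):
        cot = pd.Series([10.0, 10, 10], index=list("abc"))
        betas = pd.Series([0.5, 0.6, 0.7], index=cot.index)
        with pytest.raises(ValueError, match="zero variance"):
            cotinine_regression(betas, cot)

    def test_detection_floor_applied(self):
        cot = pd.Series([0.0, 10, 40, 80], index=list("abcd"))
        betas = pd.Series([0.9, 0.7, 0.6, 0.5], index=cot.index)
        out = cotinine_regression(betas, cot)  # would fail on log2(0)
        assert np.isfinite(out["slope"])


class TestDdctFoldChange:
    @staticmethod
    def _records_and_sheet():
        records = pd.DataFrame({
            "sample_id": ["n1", "n2", "s1", "s2"],
            "cell_type": "CD14",
            "target_gene": "AHRR",
            "ct_target": [25.0, 27.0, 23.0, 28.0],
            "ct_reference": [20.0, 22.0, 19.0, 21.0],
        })
        sheet = pd.DataFrame({
            "sample_id": ["n1", "n2", "s1", "s2"],
            "smoking_status": ["never", "never", "current", "current"],
            "age": 40.0,
        }).set_index("sample_id", drop=False)
        return records, sheet

    @pytest.mark.parametrize("ddct,expected_fc", [(0.0, 1.0), (-1.0, 2.0),
                                                  (2.0, 0.25)])
    def test_fold_change_arithmetic(self, ddct, expected_fc):
        records, sheet = self._records_and_sheet()
        records.loc[2, "ct_target"] = 19.0 + 5.0 + ddct  # dCt = 5 + ddct
        out = ddct_fold_change(records, sheet).set_index("sample_id")
        assert out.loc["s1", "fold_change"] == pytest.approx(expected_fc)

    def test_calibrator_mean_dct_maps_to_unit_fold_change(self):
        records, sheet = self._records_and_sheet()
        out = ddct_fold_change(records, sheet)
        calib = out[out.smoking_status == "never"]
        assert 2.0 ** (-calib["ddct"].mean()) == pytest.approx(1.0)

    def test_shift_invariance_per_sample(self):
        """Adding a constant to both cycle thresholds of a sample leaves its
        fold change unchanged."""
        records, sheet = self._records_and_sheet()
        base = ddct_fold_change(records, sheet).set_index("sample_id")
        shifted = records.copy()
        shifted.loc[shifted.sample_id == "s2", ["ct_target", "ct_reference"]] += 3.7
        out = ddct_fold_change(shifted, sheet).set_index("sample_id")
        assert out.loc["s2", "fold_change"] == pytest.approx(
            base.loc["s2", "fold_change"])

    def test_missing_reference_ct_rejected(self):
        records, sheet = self._records_and_sheet()
        records.loc[1, "ct_reference"] = np.nan
        with pytest.raises(ValueError, match="missing cycle thresholds"):
            ddct_fold_change(records, sheet)

    def test_no_calibrator_group_rejected(self):
        records, sheet = self._records_and_sheet()
        sheet["smoking_status"] = "current"
        with pytest.raises(ValueError, match="calibrator"):
            ddct_fold_change(records, sheet)
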