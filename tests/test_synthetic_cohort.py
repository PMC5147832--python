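import numpy as np
import pandas as pd
import pytest

from smokewas.preprocess import beta_to_m
from smokewas.synthetic_cohort import (generate_compositions,
                                       generate_reference_panel,
                                       generate_subjects, make_effect_truth,
                                       mix_to_whole_blood,
                                       synthesize_celltype_betas)


class TestGenerateSubjects:
    def test_pack_years_definition_exact(self):
        sheet = generate_subjects(10, 40, seed=3)
        smokers = sheet[sheet.smoking_status == "current"]
        np.testing.assert_array_equal(
            smokers.pack_years,
            smokers.cigarettes_per_day / 20.0 * smokers.years_smoked)

    def test_no_never_smokers_boundary(self):
        sheet = generate_subjects(0, 5, seed=0)
        assert (sheet.smoking_status == "current").all()

    def test_seed_reproducibility(self):
        a = generate_subjects(5, 10, seed=42)
        b = generate_subjects(5, 10, seed=42)
        c = generate_subjects(5, 10, seed=43)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_subjects(-1, 5, seed=0)

    def test_cpd_straddles_cutoff(self):
        sheet = generate_subjects(0, 100, heavy_fraction=0.5, cpd_cutoff=22,
                                  seed=5)
        cpd = sheet.cigarettes_per_day
        assert (cpd >= 22).sum() == 50 and (cpd < 22).sum() == 50

    def test_cotinine_tracks_smoking(self):
        sheet = generate_subjects(50, 100, seed=9)
        never = sheet[sheet.smoking_status == "never"].cotinine
        current = sheet[sheet.smoking_status == "current"].cotinine
        assert never.mean() < 10
        assert current.mean() > 10 * never.mean()


class TestReferencePanel:
    def test_discriminating_probe_gap(self):
        panel = generate_reference_panel(10, cell_types=("A", "B"),
                                         n_discriminating=1, seed=0)
        disc = panel.probe_ids[panel.discriminating != ""]
        for probe in disc:
            a, b = panel.baseline.loc[probe]
            assert abs(a - b) >= 0.76  # near-opposite poles

    def test_insufficient_probes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            generate_reference_panel(5, cell_types=("A", "B"),
                                     n_discriminating=10, seed=0)

    def test_no_discriminating_flagged(self):
        panel = generate_reference_panel(20, n_discriminating=0, seed=0)
        assert not panel.has_discriminating

    def test_seed_reproducibility(self):
        a = generate_reference_panel(50, n_discriminating=2, seed=1)
        b = generate_reference_panel(50, n_discriminating=2, seed=1)
        pd.testing.assert_frame_equal(a.baseline, b.baseline)


class TestPlantedEffects:
    def test_noiseless_null_probe_equals_baseline(self):
        panel = generate_reference_panel(60, n_discriminating=2, seed=2)
        sheet = generate_subjects(5, 5, seed=2)
        truth = make_effect_truth(panel, {}, seed=2)
        betas = synthesize_celltype_betas(panel, sheet, truth, noise_sd=0.0,
                                          seed=2)
        for ct, mat in betas.items():
            expected = np.repeat(panel.baseline[ct].to_numpy()[:, None],
                                 mat.shape[1], axis=1)
            np.testing.assert_allclose(mat.to_numpy(), expected, atol=1e-12)

    def test_myeloid_effect_confined_to_myeloid_lineage(self):
        panel = generate_reference_panel(100, n_discriminating=2, seed=3)
        sheet = generate_subjects(5, 5, seed=3)
        truth = make_effect_truth(panel, {"myeloid": 3},
                                  effect_sizes={"myeloid": -1.5}, seed=3)
        betas = synthesize_celltype_betas(panel, sheet, truth, noise_sd=0.0,
                                          seed=3)
        planted = truth.index[truth.effect_class == "myeloid"]
        smokers = sheet.sample_id[sheet.smoking_status == "current"]
        never = sheet.sample_id[sheet.smoking_status == "never"]
        for ct in ("CD14", "CD15"):
            delta = betas[ct].loc[planted, smokers].mean(axis=1) - \
                betas[ct].loc[planted, never].mean(axis=1)
            assert (delta < -0.01).all()
        for ct in ("CD4T", "CD8T", "CD19", "CD56"):
            delta = betas[ct].loc[planted, smokers].mean(axis=1) - \
                betas[ct].loc[planted, never].mean(axis=1)
            np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_duration_effect_linear_in_years_for_heavy_only(self):
        """Noiseless closed form: heavy smokers' logits fall linearly with
        years at slope -0.05; light smokers show no trend."""
        panel = generate_reference_panel(60, n_discriminating=2, seed=4)
        sheet = generate_subjects(0, 40, heavy_fraction=0.5, seed=4)
        truth = make_effect_truth(panel, {"duration_heavy": 1},
                                  duration_slope=-0.05, seed=4)
        probe = truth.index[truth.effect_class == "duration_heavy"][0]
        betas = synthesize_celltype_betas(panel, sheet, truth, noise_sd=0.0,
                                          seed=4)
        m = beta_to_m(betas["CD14"].loc[probe]) / np.log2(np.e)  # natural logit
        base = np.log(panel.baseline.loc[probe, "CD14"] /
                      (1 - panel.baseline.loc[probe, "CD14"]))
        heavy = sheet[sheet.cigarettes_per_day >= 22]
        light = sheet[(sheet.smoking_status == "current")
                      & (sheet.cigarettes_per_day < 22)]
        np.testing.assert_allclose(m[heavy.sample_id],
                                   base - 0.05 * heavy.years_smoked,
                                   atol=1e-9)
        np.testing.assert_allclose(m[light.sample_id], base, atol=1e-9)

    def test_unknown_class_rejected(self):
        panel = generate_reference_panel(30, n_discriminating=1, seed=0)
        with pytest.raises(ValueError, match="unknown effect classes"):
            make_effect_truth(panel, {"weird": 1}, seed=0)

    def test_all_betas_strictly_inside_unit_interval(self):
        panel = generate_reference_panel(80, n_discriminating=5, seed=5)
        sheet = generate_subjects(10, 10, seed=5)
        truth = make_effect_truth(panel, {"pan_cell": 5}, seed=5)
        betas = synthesize_celltype_betas(panel, sheet, truth, noise_sd=2.0,
                                          seed=5)
        for mat in betas.values():
            arr = mat.to_numpy()
            assert (arr > 0).all() and (arr < 1).all()


class TestMixing:
    @staticmethod
    def _mat(values, samples=("s1",)):
        return pd.DataFrame(values, index=pd.Index(["p1"], name="probe_id"),
                            columns=list(samples))

    def test_single_type_identity(self):
        mats = {"A": self._mat([[0.42]]), "B": self._mat([[0.9]])}
        comp = pd.DataFrame({"A": [1.0], "B": [0.0], "pbmc_depletion": [0.1]},
                            index=["s1"])
        out = mix_to_whole_blood(mats, comp)
        assert out.loc["p1", "s1"] == pytest.approx(0.42, abs=1e-15)

    def test_convex_combination_arithmetic(self):
        mats = {"A": self._mat([[0.2]]), "B": self._mat([[0.6]])}
        comp = pd.DataFrame({"A": [0.3], "B": [0.7], "pbmc_depletion": [0.1]},
                            index=["s1"])
        out = mix_to_whole_blood(mats, comp)
        assert out.loc["p1", "s1"] == pytest.approx(0.48, abs=1e-15)

    def test_pbmc_zero_retention_drops_granulocytes(self):
        mats = {"CD15": self._mat([[0.9]]), "CD4T": self._mat([[0.1]]),
                "CD19": self._mat([[0.3]])}
        comp = pd.DataFrame({"CD15": [0.5], "CD4T": [0.3], "CD19": [0.2],
                             "pbmc_depletion": [0.0]}, index=["s1"])
        out = mix_to_whole_blood(mats, comp, pbmc=True)
        # granulocytes absent; remaining weights renormalised to 0.6/0.4
        assert out.loc["p1", "s1"] == pytest.approx(0.6 * 0.1 + 0.4 * 0.3)

    def test_mismatched_probe_sets_rejected(self):
        a = self._mat([[0.2]])
        b = pd.DataFrame([[0.5]], index=pd.Index(["other"], name="probe_id"),
                         columns=["s1"])
        comp = pd.DataFrame({"A": [0.5], "B": [0.5], "pbmc_depletion": [1.0]},
                            index=["s1"])
        with pytest.raises(ValueError, match="probe sets differ"):
            mix_to_whole_blood({"A": a, "B": b}, comp)

    def test_mixture_conservation_against_manual_sum(self, tiny_cohort):
        comp = tiny_cohort["compositions"]
        cell_types = tiny_cohort["panel"].cell_types
        manual = sum(
            tiny_cohort["celltype_betas"][ct].to_numpy()
            * comp[ct].to_numpy()
            for ct in cell_types)
        np.testing.assert_allclose(tiny_cohort["whole_blood"].to_numpy(),
                                   manual, atol=1e-12)

    def test_composition_rows_on_simplex(self, tiny_cohort):
        comp = tiny_cohort["compositions"]
        weights = comp[tiny_cohort["panel"].cell_types].to_numpy()
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-9)
        assert (weights >= 0).all()

    def test_smokers_have_more_granulocytes(self):
        sheet = generate_subjects(80, 80, seed=6)
        comp = generate_compositions(sheet, seed=6)
        cd15 = comp["CD15"]
        current = sheet.sample_id[sheet.smoking_status == "current"]
        never = sheet.sample_id[sheet.smoking_status == "never"]
        assert cd15[current].mean() - cd15[never].mean() > 0.02


class TestEffectCalibration:
    def test_planted_delta_matches_logit_effect_within_mc_error(self):
        """At n=200+ the empirical smoker-vs-never delta at a planted probe
        reproduces the planted logit effect mapped to the beta scale."""
        panel = generate_reference_panel(80, n_discriminating=2, seed=8)
        sheet = generate_subjects(120, 120, seed=8)
        truth = make_effect_truth(panel, {"pan_cell": 5},
                                  effect_sizes={"pan_cell": -1.0}, seed=8)
        noise = 0.35
        betas = synthesize_celltype_betas(panel, sheet, truth,
                                          noise_sd=noise, seed=8)
        current = sheet.sample_id[sheet.smoking_status == "current"]
        never = sheet.sample_id[sheet.smoking_status == "never"]
        probes = truth.index[truth.effect_class == "pan_cell"]
        for probe in probes:
            base = panel.baseline.loc[probe, "CD14"]
            logit = np.log(base / (1 - base))
            # expected mean beta under logit-normal noise, by quadrature
            from scipy.stats import norm
            grid = np.linspace(-5, 5, 801)
            wts = norm.pdf(grid)
            wts /= wts.sum()

            def mean_beta(mu):
                return float((1 / (1 + np.exp(-(mu + noise * grid))) * wts).sum())

            expected_delta = mean_beta(logit - 1.0) - mean_beta(logit)
            mat = betas["CD14"]
            obs = mat.loc[probe, current].mean() - mat.loc[probe, never].mean()
            se = np.sqrt(mat.loc[probe, current].var() / len(current)
                         + mat.loc[probe, never].var() / len(never))
            assert abs(obs - expected_delta) < 3 * se
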