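import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from onset_omics.anova import (
    InestimableFeatureError,
    PairedAnova,
    TissueOnsetAnova,
    fold_change_from_log2,
    interaction_anova_table,
    mom_variance_components,
    paired_anova_table,
    paired_tests,
    paired_variance_components,
    signed_fold_change,
)
from onset_omics.io import OmicsMatrix, SampleSheet
from onset_omics.simulate import SimulationConfig, simulate_expression

from conftest import make_sheet, noise_free_matrix


def random_matrix(sheet, n_features, rng, sigma_person=1.0, sigma_error=0.5):
    persons = sheet.data["person_id"].to_numpy()
    unique = pd.unique(persons)
    pe = dict(zip(unique, rng.normal(0, sigma_person, len(unique))))
    base = np.array([pe[p] for p in persons])
    values = base[None, :] + rng.normal(
        0, sigma_error, size=(n_features, len(persons))
    )
    return OmicsMatrix(
        pd.DataFrame(values, index=[f"f{i}" for i in range(n_features)],
                     columns=sheet.data["sample_id"].to_numpy()),
        "expression_log2",
    )


class TestPairedFit:
    def test_constant_differences_flag_degenerate(self):
        sheet = make_sheet(3, 0)
        m = noise_free_matrix(sheet, {"f": 1.0}, {"f": 1.0})
        res = PairedAnova.from_matrix(m, sheet, "f").fit()
        assert res.effect == pytest.approx(1.0)
        assert res.degenerate
        assert res.vc.sigma2_error == 0.0
        assert 0 < res.p <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_paired_t_test_oracle(self, seed):
        """On balanced pairs, tissue p equals the paired t-test p, F = t^2."""
        rng = np.random.default_rng(seed)
        sheet = make_sheet(5, 7)
        m = random_matrix(sheet, 10, rng)
        pairs = sheet.complete_pairs()
        for fid in m.feature_ids[:5]:
            res = PairedAnova.from_matrix(m, sheet, fid).fit()
            t_or = stats.ttest_rel(
                m.values.loc[fid, pairs["tumor"]],
                m.values.loc[fid, pairs["normal"]],
            )
            assert res.p == pytest.approx(t_or.pvalue, abs=1e-10)
            assert res.F == pytest.approx(t_or.statistic ** 2, rel=1e-10)

    def test_noise_free_fold_change(self):
        sheet = make_sheet(4, 4)
        eff = float(np.log2(1.09))
        m = noise_free_matrix(sheet, {"f": eff}, {"f": eff},
                              person_offsets={"E001": 0.4, "L002": -0.7})
        res = PairedAnova.from_matrix(m, sheet, "f").fit()
        assert res.fold_change == pytest.approx(1.09, abs=1e-12)

    def test_too_few_pairs_reports_reason(self):
        sheet = make_sheet(1, 0)
        m = noise_free_matrix(sheet, {"f": 1.0}, {"f": 1.0})
        with pytest.raises(InestimableFeatureError) as exc:
            PairedAnova.from_matrix(m, sheet, "f").fit()
        assert exc.value.reason == "too_few_pairs"

    def test_missing_values_fit_on_complete_pairs(self, rng):
        sheet = make_sheet(4, 4)
        m = random_matrix(sheet, 1, rng)
        m.values.loc["f0", "E001-T"] = np.nan
        res = PairedAnova.from_matrix(m, sheet, "f0").fit()
        assert res.n_pairs == 7

    def test_sample_order_irrelevant(self, rng):
        sheet = make_sheet(4, 4)
        m = random_matrix(sheet, 3, rng)
        shuffled = OmicsMatrix(
            m.values[list(reversed(m.sample_ids))], "expression_log2"
        )
        a = PairedAnova.from_matrix(m, sheet, "f1").fit()
        b = PairedAnova.from_matrix(shuffled, sheet, "f1").fit()
        assert a.effect == b.effect and a.p == b.p


class TestVarianceComponents:
    def test_balanced_closed_form(self, rng):
        """Person component equals (MS_person - MS_error)/2 on paired data."""
        sheet = make_sheet(6, 6)
        m = random_matrix(sheet, 1, rng)
        tab = paired_tests(
            m.values[list(sheet.complete_pairs()["tumor"])].to_numpy(),
            m.values[list(sheet.complete_pairs()["normal"])].to_numpy(),
        ).iloc[0]
        vc = paired_variance_components(tab["ms_person"], tab["ms_error"])
        expected = (tab["ms_person"] - tab["ms_error"]) / 2
        assert vc.sigma2_person == pytest.approx(max(expected, 0.0))
        assert vc.sigma2_error == pytest.approx(tab["ms_error"])

    def test_simulation_recovery_200_pairs(self):
        """MoM recovers sigma2_person=1, sigma2_error=0.25 within 3 SE."""
        cfg = SimulationConfig(
            n_persons_per_group={"EOCRC": 100, "LOCRC": 100},
            n_features=400, n_gene_sets=0, set_size=0,
            sigma_person=1.0, sigma_error=0.5, seed=7,
        )
        m, sheet, _ = simulate_expression(cfg)
        pairs = sheet.complete_pairs()
        tab = paired_tests(
            m.values[list(pairs["tumor"])].to_numpy(),
            m.values[list(pairs["normal"])].to_numpy(),
        )
        # Error draws are independent across features, so the across-feature
        # SE applies; person effects are one shared draw across features, so
        # the person component's SE is the sampling sd of a variance over
        # n_persons normal draws: sigma2 * sqrt(2/(n-1)).
        err = tab["sigma2_error"]
        assert abs(err.mean() - 0.25) < 3 * err.std(ddof=1) / np.sqrt(len(err))
        se_person = 1.0 * np.sqrt(2.0 / (200 - 1))
        assert abs(tab["sigma2_person"].mean() - 1.0) < 3 * se_person

    def test_zero_person_variance_clamps_about_half(self):
        cfg = SimulationConfig(
            n_persons_per_group={"EOCRC": 30, "LOCRC": 30},
            n_features=500, n_gene_sets=0, set_size=0,
            sigma_person=0.0, sigma_error=0.5, seed=3,
        )
        m, sheet, _ = simulate_expression(cfg)
        pairs = sheet.complete_pairs()
        tab = paired_tests(
            m.values[list(pairs["tumor"])].to_numpy(),
            m.values[list(pairs["normal"])].to_numpy(),
        )
        # Unclamped estimate is centred at 0: clamped-to-zero fraction near half.
        frac_zero = (tab["sigma2_person"] == 0).mean()
        assert 0.35 < frac_zero < 0.65
        assert tab["sigma2_person"].mean() < 0.05

    def test_singular_system_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="confounded"):
            mom_variance_components([1.0, 1.0], [[1, 1], [1, 1]], ["a", "b"])

    def test_negative_component_clamped_and_flagged(self):
        vc = paired_variance_components(ms_person=0.5, ms_error=1.0)
        assert vc.sigma2_person == 0.0
        assert vc.clamped["person"]


class TestFoldChange:
    @pytest.mark.parametrize(
        "effect,expected",
        [(0.0, 1.0),
         (float(np.log2(1.46)), 1.46),
         (float(-np.log2(1.12)), -1.12)],
    )
    def test_signed_convention(self, effect, expected):
        assert signed_fold_change(effect) == pytest.approx(expected, abs=1e-12)

    def test_ci_ordering(self):
        fc, lo, hi = fold_change_from_log2(np.log2(1.46), se=0.02, df=70)
        assert lo <= fc <= hi

    def test_df_zero_keeps_point_estimate(self):
        fc, lo, hi = fold_change_from_log2(1.0, se=0.5, df=0)
        assert fc == 2.0
        assert np.isnan(lo) and np.isnan(hi)

    @given(e=st.floats(1e-6, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, e):
        assert signed_fold_change(-e) == pytest.approx(
            -signed_fold_change(e), rel=1e-12
        )

    @given(e1=st.floats(0.0, 10.0), e2=st.floats(0.0, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_magnitude_monotone(self, e1, e2):
        lo, hi = sorted([e1, e2])
        assert abs(signed_fold_change(hi)) >= abs(signed_fold_change(lo)) - 1e-12

    def test_larger_effect_smaller_p(self):
        """At fixed se/df, |fold change| grows and p shrinks with |effect|."""
        se, df = 0.1, 20
        effects = [0.1, 0.3, 0.8]
        ps = [2 * stats.t.sf(e / se, df) for e in effects]
        fcs = [abs(signed_fold_change(e)) for e in effects]
        assert ps == sorted(ps, reverse=True)
        assert fcs == sorted(fcs)


class TestInteraction:
    def test_noise_free_group_effects_recovered(self):
        sheet = make_sheet(30, 30)
        eff_e, eff_l = float(np.log2(1.09)), float(np.log2(1.14))
        m = noise_free_matrix(sheet, {"f": eff_e}, {"f": eff_l})
        res = TissueOnsetAnova.from_matrix(m, sheet, "f").fit()
        assert res.per_group["LOCRC"].fold_change == pytest.approx(1.14, abs=1e-9)
        assert res.per_group["EOCRC"].fold_change == pytest.approx(1.09, abs=1e-9)
        assert res.interaction_contrast == pytest.approx(eff_l - eff_e)

    def test_interaction_detected_with_noise(self):
        cfg = SimulationConfig(
            n_persons_per_group={"EOCRC": 400, "LOCRC": 400},
            n_features=12, n_gene_sets=1, set_size=12,
            sigma_person=0.1, sigma_error=0.1,
            tissue_effect_log2=float(np.log2(1.09)),
            interaction_effect_log2=float(np.log2(1.14) - np.log2(1.09)),
            seed=21,
        )
        m, sheet, truth = simulate_expression(cfg)
        fid = truth.features["feature_id"].iloc[0]
        res = TissueOnsetAnova.from_matrix(m, sheet, fid).fit()
        assert res.interaction_p < 0.05
        assert res.per_group["LOCRC"].fold_change == pytest.approx(1.14, abs=0.04)
        assert res.per_group["EOCRC"].fold_change == pytest.approx(1.09, abs=0.04)

    def test_group_relabel_symmetry(self, rng):
        sheet = make_sheet(5, 6)
        m = random_matrix(sheet, 3, rng)
        swapped = SampleSheet(
            sheet.data.assign(
                onset_group=sheet.data["onset_group"].map(
                    {"EOCRC": "LOCRC", "LOCRC": "EOCRC"}
                )
            )
        )
        a = TissueOnsetAnova.from_matrix(m, sheet, "f0").fit()
        b = TissueOnsetAnova.from_matrix(m, swapped, "f0").fit()
        assert a.interaction_p == pytest.approx(b.interaction_p, rel=1e-12)
        assert a.interaction_contrast == pytest.approx(
            -b.interaction_contrast, rel=1e-12
        )

    def test_missing_stratum_raises(self, rng):
        sheet = make_sheet(0, 5)
        m = random_matrix(sheet, 1, rng)
        with pytest.raises(InestimableFeatureError, match="EOCRC"):
            TissueOnsetAnova.from_matrix(m, sheet, "f0").fit()


class TestMatrixDrivers:
    def test_vectorized_equals_per_feature(self, rng):
        sheet = make_sheet(6, 8)
        m = random_matrix(sheet, 20, rng)
        table = paired_anova_table(m, sheet).set_index("feature_id")
        for fid in m.feature_ids[::5]:
            res = PairedAnova.from_matrix(m, sheet, fid).fit()
            row = table.loc[fid]
            assert row["effect"] == pytest.approx(res.effect, rel=1e-12)
            assert row["p"] == pytest.approx(res.p, rel=1e-12)
            assert row["fold_change"] == pytest.approx(res.fold_change, rel=1e-12)

    def test_interaction_table_matches_model(self, rng):
        sheet = make_sheet(6, 8)
        m = random_matrix(sheet, 10, rng)
        table = interaction_anova_table(m, sheet).set_index("feature_id")
        res = TissueOnsetAnova.from_matrix(m, sheet, "f3").fit()
        assert table.loc["f3", "interaction_p"] == pytest.approx(
            res.interaction_p, rel=1e-12
        )
        assert table.loc["f3", "fold_change_locrc"] == pytest.approx(
            res.per_group["LOCRC"].fold_change, rel=1e-12
        )
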