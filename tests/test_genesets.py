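import numpy as np
import pandas as pd
import pytest
from scipy import stats

from onset_omics.anova import PairedAnova, interaction_anova_table
from onset_omics.clinical import ContingencyTable, chi_square_test
from onset_omics.genesets import (
    GeneSetAnova,
    GeneSetError,
    enrichment_score,
    gene_level_matrix,
)
from onset_omics.io import FeatureAnnotation, OmicsMatrix
from onset_omics.simulate import SimulationConfig, simulate_expression

from conftest import make_sheet, noise_free_matrix


def annotation_for(matrix, gene_of=None):
    rows = []
    for fid in matrix.feature_ids:
        gene = gene_of[fid] if gene_of else fid.split("_")[0]
        rows.append({"feature_id": fid, "gene_symbol": gene,
                     "region_class": "na"})
    return FeatureAnnotation(pd.DataFrame(rows))


def sim_matrix(sheet, n_features, rng, sigma_person=0.6, sigma_error=0.3,
               effect=0.0):
    persons = sheet.data["person_id"].to_numpy()
    unique = pd.unique(persons)
    pe = dict(zip(unique, rng.normal(0, sigma_person, len(unique))))
    base = np.array([pe[p] for p in persons])
    tumor = (sheet.data["tissue"] == "tumor").to_numpy().astype(float)
    values = (base[None, :] + effect * tumor[None, :]
              + rng.normal(0, sigma_error, size=(n_features, len(persons))))
    return OmicsMatrix(
        pd.DataFrame(values, index=[f"G{i:03d}_p1" for i in range(n_features)],
                     columns=sheet.data["sample_id"].to_numpy()),
        "expression_log2",
    )


class TestGeneSetAnova:
    def test_single_gene_set_reduces_to_paired_fit(self, rng):
        sheet = make_sheet(5, 6)
        m = sim_matrix(sheet, 4, rng)
        ann = annotation_for(m)
        set_res = GeneSetAnova(m, sheet, ["G002"], ann, set_name="solo").fit()
        gene_res = PairedAnova(m.values.loc["G002_p1"], sheet).fit()
        assert set_res.overall.effect == pytest.approx(gene_res.effect, rel=1e-12)
        assert set_res.overall.p == pytest.approx(gene_res.p, rel=1e-12)
        assert set_res.n_genes == 1

    def test_identical_genes_keep_common_fold_change(self, rng):
        """A set of genes with one common effect reports that effect."""
        sheet = make_sheet(6, 6)
        eff = float(np.log2(1.09))
        effects = {f"G{i}_p1": eff for i in range(8)}
        m = noise_free_matrix(sheet, effects, effects,
                              person_offsets={"E001": 1.0})
        ann = annotation_for(m)
        res = GeneSetAnova(m, sheet, [f"G{i}" for i in range(8)], ann,
                           set_name="s").fit()
        assert res.overall.fold_change == pytest.approx(1.09, abs=1e-9)

    def test_gene_order_irrelevant(self, rng):
        sheet = make_sheet(5, 5)
        m = sim_matrix(sheet, 6, rng)
        ann = annotation_for(m)
        genes = [f"G{i:03d}" for i in range(6)]
        a = GeneSetAnova(m, sheet, genes, ann, set_name="s").fit()
        b = GeneSetAnova(m, sheet, list(reversed(genes)), ann,
                         set_name="s").fit()
        assert a.overall.effect == pytest.approx(b.overall.effect, rel=1e-12)
        assert a.overall.p == pytest.approx(b.overall.p, rel=1e-12)

    def test_noise_free_interaction_null(self):
        sheet = make_sheet(4, 4)
        eff = float(np.log2(1.09))
        effects = {f"G{i}_p1": eff for i in range(3)}
        m = noise_free_matrix(sheet, effects, effects)
        ann = annotation_for(m)
        res = GeneSetAnova(m, sheet, [f"G{i}" for i in range(3)], ann,
                           set_name="s", with_interaction=True).fit()
        assert res.overall.fold_change == pytest.approx(1.09, abs=1e-9)
        assert res.interaction_p == pytest.approx(1.0)

    def test_group_specific_effects_recovered(self):
        """Late-onset 1.26-fold vs early-onset 1.16-fold is detected."""
        cfg = SimulationConfig(
            n_persons_per_group={"EOCRC": 250, "LOCRC": 250},
            n_features=12, n_gene_sets=1, set_size=12,
            sigma_person=0.1, sigma_error=0.1,
            tissue_effect_log2=float(np.log2(1.16)),
            interaction_effect_log2=float(np.log2(1.26) - np.log2(1.16)),
            seed=17,
        )
        m, sheet, truth = simulate_expression(cfg)
        res = GeneSetAnova(m, sheet, truth.gene_sets["SET01"],
                           truth.annotation(), set_name="SET01",
                           with_interaction=True).fit()
        assert res.interaction_p < 0.05
        assert res.per_group["LOCRC"].fold_change == pytest.approx(1.26, abs=0.02)
        assert res.per_group["EOCRC"].fold_change == pytest.approx(1.16, abs=0.02)

    def test_missing_genes_counted_not_fatal(self, rng):
        sheet = make_sheet(4, 4)
        m = sim_matrix(sheet, 3, rng)
        ann = annotation_for(m)
        res = GeneSetAnova(m, sheet, ["G000", "G001", "ABSENT1", "ABSENT2"],
                           ann, set_name="s").fit()
        assert res.n_genes == 2
        assert res.n_genes_missing == 2
        assert res.missing_genes == ["ABSENT1", "ABSENT2"]

    def test_no_gene_found_is_error(self, rng):
        sheet = make_sheet(4, 4)
        m = sim_matrix(sheet, 2, rng)
        ann = annotation_for(m)
        with pytest.raises(GeneSetError, match="NOPE"):
            GeneSetAnova(m, sheet, ["NOPE"], ann, set_name="s").fit()

    def test_probes_averaged_per_gene(self, rng):
        sheet = make_sheet(3, 3)
        values = pd.DataFrame(
            rng.normal(size=(4, len(sheet.data))),
            index=["GA_p1", "GA_p2", "GB_p1", "GB_p2"],
            columns=sheet.data["sample_id"].to_numpy(),
        )
        m = OmicsMatrix(values, "expression_log2")
        ann = annotation_for(m)
        gene_df, missing, n_probes = gene_level_matrix(m, ann, ["GA", "GB"])
        assert n_probes == 4 and not missing
        expected = values.loc[["GA_p1", "GA_p2"]].mean(axis=0)
        pd.testing.assert_series_equal(gene_df.loc["GA"], expected,
                                       check_names=False)

    def test_variance_components_recovered(self):
        """Person/sample/error components estimated from a structured set."""
        rng = np.random.default_rng(5)
        sheet = make_sheet(60, 60)
        persons = sheet.data["person_id"].to_numpy()
        unique = pd.unique(persons)
        s2p, s2s, s2e, n_genes = 0.5, 0.2, 0.1, 10
        pe = dict(zip(unique, rng.normal(0, np.sqrt(s2p), len(unique))))
        sample_eff = rng.normal(0, np.sqrt(s2s), len(persons))
        base = np.array([pe[p] for p in persons]) + sample_eff
        gene_eff = rng.normal(0, 1.0, n_genes)
        values = (base[None, :] + gene_eff[:, None]
                  + rng.normal(0, np.sqrt(s2e), (n_genes, len(persons))))
        m = OmicsMatrix(
            pd.DataFrame(values,
                         index=[f"G{i:03d}_p1" for i in range(n_genes)],
                         columns=sheet.data["sample_id"].to_numpy()),
            "expression_log2",
        )
        ann = annotation_for(m)
        res = GeneSetAnova(m, sheet, [f"G{i:03d}" for i in range(n_genes)],
                           ann, set_name="s").fit()
        assert res.vc["person"] == pytest.approx(s2p, abs=0.25)
        assert res.vc["sample"] == pytest.approx(s2s, abs=0.08)
        assert res.vc["error"] == pytest.approx(s2e, abs=0.02)


class TestInteractionNullCalibration:
    def test_interaction_p_uniform_under_null(self):
        """Null interaction p-values pass a KS test against Uniform(0,1).

        Run on per-feature interaction fits, which a single-gene set reduces
        to exactly (verified separately); 2000 features stand in for 2000
        single-gene sets.
        """
        cfg = SimulationConfig(
            n_persons_per_group={"EOCRC": 15, "LOCRC": 20},
            n_features=2000, n_gene_sets=0, set_size=0,
            sigma_person=0.0, sigma_error=0.5,
            tissue_effect_log2=0.0, interaction_effect_log2=0.0,
            seed=23,
        )
        m, sheet, _ = simulate_expression(cfg)
        table = interaction_anova_table(m, sheet)
        ks = stats.kstest(table["interaction_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_single_gene_set_interaction_matches_feature_fit(self, rng):
        sheet = make_sheet(5, 6)
        m = sim_matrix(sheet, 2, rng)
        ann = annotation_for(m)
        set_res = GeneSetAnova(m, sheet, ["G001"], ann, set_name="s",
                               with_interaction=True).fit()
        table = interaction_anova_table(m, sheet).set_index("feature_id")
        assert set_res.interaction_p == pytest.approx(
            table.loc["G001_p1", "interaction_p"], rel=1e-12
        )


class TestEnrichment:
    def test_null_proportions_zero_score(self):
        chip = [f"g{i}" for i in range(100)]
        cat = chip[:20]
        sig = chip[:2] + chip[20:28]  # 2/10 in cat = 20/100 on chip
        res = enrichment_score(sig, cat, chip)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.enrichment_score == pytest.approx(0.0, abs=1e-12)

    def test_textbook_contingency_oracle(self):
        """{10,90,90,9810}: chi2 = N(ad-bc)^2 / (row/col margins product)."""
        chip = [f"g{i}" for i in range(10000)]
        cat = chip[:100]
        sig = chip[:10] + chip[100:190]
        res = enrichment_score(sig, cat, chip)
        a, b, c, d = 10.0, 90.0, 90.0, 9810.0
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.chi2 == pytest.approx(chi2, rel=1e-10)
        assert res.enrichment_score == pytest.approx(
            -np.log10(stats.chi2.sf(chi2, 1)), rel=1e-10
        )

    def test_doubling_counts_increases_score(self):
        chip = [f"g{i}" for i in range(400)]
        cat = chip[:40]
        sig = chip[:8] + chip[40:52]
        small = enrichment_score(sig, cat, chip)
        chip2 = [f"h{i}" for i in range(800)]
        cat2 = chip2[:80]
        sig2 = chip2[:16] + chip2[80:104]
        big = enrichment_score(sig2, cat2, chip2)
        assert big.chi2 == pytest.approx(2 * small.chi2, rel=1e-9)
        assert big.enrichment_score > small.enrichment_score

    def test_empty_sig_flagged_zero(self):
        chip = ["a", "b", "c", "d"]
        res = enrichment_score([], chip[:2], chip)
        assert res.enrichment_score == 0.0
        assert res.flag == "no_significant_genes"

    def test_category_equal_to_chip_flagged(self):
        chip = ["a", "b", "c", "d"]
        res = enrichment_score(["a"], chip, chip)
        assert res.enrichment_score == 0.0
        assert res.flag == "degenerate_category"

    def test_subset_precondition_enforced(self):
        with pytest.raises(GeneSetError):
            enrichment_score(["x"], ["a"], ["a", "b"])

    def test_consistent_with_chi_square_test(self):
        chip = [f"g{i}" for i in range(500)]
        cat = chip[:50]
        sig = chip[:20] + chip[50:80]
        res = enrichment_score(sig, cat, chip)
        a = 20
        table = ContingencyTable(
            ["in", "out"], ["sig", "rest"],
            np.array([[a, 50 - a], [len(sig) - a, (500 - 50) - (len(sig) - a)]]),
        )
        direct = chi_square_test(table)
        assert res.p == pytest.approx(direct.p, rel=1e-12)
        assert res.enrichment_score == pytest.approx(-np.log10(direct.p),
                                                     rel=1e-12)
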