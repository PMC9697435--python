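"""Gene-set-level mixed ANOVA and chi-square enrichment scoring.

The gene-set model is ``Y = mu + T + P + G + S(T*P) + error`` over the long
table of all member genes' values: T the tissue effect, P the random person
effect, G the fixed gene effect, and S(T*P) a random sample effect nested in
tissue x person that absorbs sample-to-sample correlation across genes.
Probes of one gene are averaged (log2 scale) per sample before the model,
since the model is gene-level while chips carry multiple probes per gene.

Because the sample effect is nested in tissue x person, the tissue contrast
(and the interaction contrast) collapses exactly onto the per-sample mean of
the member genes: the set-level test is the paired (or tissue x onset
interaction) model applied to those per-sample set means, and the set-level
effect equals the average of the member genes' tissue effects.  Variance
components for person, sample and residual come from the method of moments
on the balanced expected mean squares.

Enrichment of a category among significant genes is scored by a 2x2 Pearson
chi-square — the category's share among significant genes against its share
on the chip — with the enrichment score defined as -log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import (
    PairedAnova,
    PairedAnovaResults,
    TissueOnsetAnova,
    VarianceComponents,
    mom_variance_components,
)
from .clinical import ContingencyTable, chi_square_test
from .io import FeatureAnnotation, OmicsMatrix, SampleSheet

__all__ = [
    "GeneSetAnova",
    "GeneSetResults",
    "EnrichmentResult",
    "GeneSetError",
    "enrichment_score",
    "gene_level_matrix",
    "gene_set_table",
]


class GeneSetError(ValueError):
    pass


def gene_level_matrix(matrix: OmicsMatrix, annotation: FeatureAnnotation,
                      genes: list[str]) -> tuple[pd.DataFrame, list[str], int]:
    """Summarize probe rows to gene rows (mean per sample, log2 scale).

    Returns the gene x sample frame for the requested genes, the sorted
    list of requested genes absent from chip/annotation, and the number of
    probes used.
    """
    wanted = [g.upper() for g in genes]
    by_gene = annotation.features_for_genes(wanted)
    have = set(matrix.feature_ids)
    rows, used_probes = {}, 0
    for gene in wanted:
        probes = [p for p in by_gene.get(gene, []) if p in have]
        if not probes:
            continue
        rows[gene] = matrix.values.loc[probes].mean(axis=0)
        used_probes += len(probes)
    missing = sorted(set(wanted) - set(rows))
    gene_df = pd.DataFrame(rows).T
    return gene_df, missing, used_probes


@dataclass
class GeneSetResults:
    """Set-level fit: fold change / CI / p per onset group (or overall),
    the tissue x onset interaction p, counts and variance components."""

    set_name: str
    n_genes: int
    n_probes: int
    n_genes_missing: int
    missing_genes: list[str]
    overall: PairedAnovaResults
    per_group: dict[str, PairedAnovaResults] = field(default_factory=dict)
    interaction_p: float = np.nan
    interaction_contrast: float = np.nan
    vc: VarianceComponents | None = None

    @property
    def fold_change(self) -> float:
        return self.overall.fold_change

    @property
    def p(self) -> float:
        return self.overall.p

    def summary(self) -> str:
        lines = [
            f"Gene-set ANOVA: {self.set_name} "
            f"({self.n_genes} genes, {self.n_probes} probes"
            + (f", {self.n_genes_missing} missing" if self.n_genes_missing else "")
            + ")",
            f"overall: fold change {self.overall.fold_change:.3f} "
            f"({self.overall.ci_low:.3f} to {self.overall.ci_high:.3f}), "
            f"p = {self.overall.p:.3e}",
        ]
        for group, res in self.per_group.items():
            lines.append(
                f"{group}: fold change {res.fold_change:.3f} "
                f"({res.ci_low:.3f} to {res.ci_high:.3f}), p = {res.p:.3e}"
            )
        if not np.isnan(self.interaction_p):
            lines.append(f"tissue x onset interaction p = {self.interaction_p:.3e}")
        if self.vc is not None:
            comps = ", ".join(
                f"{k}={v:.4f}" for k, v in self.vc.components.items()
            )
            lines.append(f"variance components: {comps}")
        return "\n".join(lines)


class GeneSetAnova:
    """Mixed ANOVA over a gene set's member genes.

    Parameters
    ----------
    matrix : OmicsMatrix
        Probe-level expression (or beta) matrix.
    design : SampleSheet
    genes : list of str
        Member gene symbols; genes absent from the chip are dropped and
        counted, not errors.
    annotation : FeatureAnnotation
        Probe -> gene mapping.
    with_interaction : bool
        Add the tissue x onset term and report per-group fold changes.
    """

    def __init__(self, matrix: OmicsMatrix, design: SampleSheet,
                 genes: list[str], annotation: FeatureAnnotation,
                 set_name: str = "", with_interaction: bool = False):
        self.matrix = matrix
        self.design = design
        self.genes = list(genes)
        self.annotation = annotation
        self.set_name = set_name
        self.with_interaction = with_interaction

    def fit(self) -> GeneSetResults:
        scale = "beta" if self.matrix.kind == "methylation_beta" else "log2"
        gene_df, missing, n_probes = gene_level_matrix(
            self.matrix, self.annotation, self.genes
        )
        if gene_df.empty:
            raise GeneSetError(
                f"gene set {self.set_name!r}: no member gene found on chip; "
                f"missing {missing}"
            )
        set_means = gene_df.mean(axis=0)
        set_means.name = self.set_name
        overall = PairedAnova(set_means, self.design,
                              feature_id=self.set_name, scale=scale).fit()
        vc = self._variance_components(gene_df, set_means, overall)
        per_group: dict[str, PairedAnovaResults] = {}
        interaction_p = np.nan
        interaction_contrast = np.nan
        if self.with_interaction:
            inter = TissueOnsetAnova(set_means, self.design,
                                     feature_id=self.set_name, scale=scale).fit()
            per_group = inter.per_group
            interaction_p = inter.interaction_p
            interaction_contrast = inter.interaction_contrast
        return GeneSetResults(
            set_name=self.set_name,
            n_genes=gene_df.shape[0],
            n_probes=n_probes,
            n_genes_missing=len(missing),
            missing_genes=missing,
            overall=overall,
            per_group=per_group,
            interaction_p=interaction_p,
            interaction_contrast=interaction_contrast,
            vc=vc,
        )

    def _variance_components(self, gene_df: pd.DataFrame, set_means: pd.Series,
                             overall: PairedAnovaResults) -> VarianceComponents:
        """Method-of-moments components for person, nested sample and error.

        Balanced expected mean squares with G genes, n persons, 2 tissues:
        E[MS_error]  = s2_e                      (gene x sample residual)
        E[MS_sample] = s2_e + G s2_S             (samples within tissue x person)
        E[MS_person] = s2_e + G s2_S + 2G s2_P
        The sample and person strata are recovered from the paired
        decomposition of the per-sample set means (each set mean averages G
        gene values, so its mean squares scale by 1/G).  With a single gene
        the sample effect is confounded with error and the paired-model
        components are reported instead.
        """
        from .anova import _pair_arrays, paired_tests

        g, n_samples = gene_df.shape
        if g < 2:
            return VarianceComponents(
                {
                    "person": overall.vc.sigma2_person,
                    "sample": 0.0,
                    "error": overall.vc.sigma2_error,
                },
                {"sample": False, **overall.vc.clamped},
            )
        tumor, normal, _ = _pair_arrays(set_means.to_frame().T, self.design)
        row = paired_tests(tumor, normal).iloc[0]
        x = gene_df.to_numpy(float)
        gene_mean = np.nanmean(x, axis=1, keepdims=True)
        sample_mean = np.nanmean(x, axis=0, keepdims=True)
        grand = np.nanmean(x)
        resid = x - gene_mean - sample_mean + grand
        df_e = (g - 1) * (n_samples - 1)
        ms_error = float(np.nansum(resid ** 2) / df_e)
        ms_sample = g * float(row["ms_error"])
        ms_person = g * float(row["ms_person"])
        return mom_variance_components(
            [ms_person, ms_sample, ms_error],
            [[2.0 * g, g, 1.0], [0.0, g, 1.0], [0.0, 0.0, 1.0]],
            ["person", "sample", "error"],
        )


def gene_set_table(matrix: OmicsMatrix, design: SampleSheet,
                   collection, annotation: FeatureAnnotation,
                   with_interaction: bool = True) -> pd.DataFrame:
    """Fit every set in a collection; one row per set, table-style columns."""
    rows = []
    for name, genes in collection:
        res = GeneSetAnova(matrix, design, genes, annotation,
                           set_name=name, with_interaction=with_interaction).fit()
        row = {
            "set_name": name,
            "n_genes": res.n_genes,
            "n_probes": res.n_probes,
            "n_genes_missing": res.n_genes_missing,
            "fold_change": res.overall.fold_change,
            "ci_low": res.overall.ci_low,
            "ci_high": res.overall.ci_high,
            "p": res.overall.p,
        }
        if with_interaction:
            row["interaction_p"] = res.interaction_p
            for group, fit in res.per_group.items():
                suffix = group.lower()
                row[f"fold_change_{suffix}"] = fit.fold_change
                row[f"ci_low_{suffix}"] = fit.ci_low
                row[f"ci_high_{suffix}"] = fit.ci_high
                row[f"p_{suffix}"] = fit.p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Chi-square enrichment of a category among significant genes."""

    category: str
    k_sig_in_cat: int
    k_sig_total: int
    n_chip_in_cat: int
    n_chip_total: int
    chi2: float
    p: float
    enrichment_score: float
    flag: str = ""


def enrichment_score(sig_genes: list[str], category_genes: list[str],
                     chip_genes: list[str], category: str = "") -> EnrichmentResult:
    """Score a category's over-representation among significant genes.

    Builds the 2x2 table [in category vs not] x [significant vs remaining
    chip genes] and applies the Pearson chi-square without continuity
    correction; the enrichment score is -log10(p).  An empty significant
    list, or a category spanning the whole chip, is degenerate and scored 0
    with a flag.
    """
    chip = {g.upper() for g in chip_genes}
    cat = {g.upper() for g in category_genes}
    sig = {g.upper() for g in sig_genes}
    if not cat <= chip:
        raise GeneSetError("category genes must be a subset of chip genes")
    if not sig <= chip:
        raise GeneSetError("significant genes must be a subset of chip genes")

    a = len(sig & cat)
    b = len(sig) - a
    c = len(cat) - a
    d = (len(chip) - len(cat)) - b

    def _zero(flag: str) -> EnrichmentResult:
        return EnrichmentResult(category, a, len(sig), len(cat), len(chip),
                                0.0, 1.0, 0.0, flag)

    if not sig:
        return _zero("no_significant_genes")
    if cat == chip or not cat:
        return _zero("degenerate_category")
    if len(sig) == len(chip):
        return _zero("degenerate_significant")
    table = ContingencyTable(
        row_labels=["in_category", "not_in_category"],
        col_labels=["significant", "rest_of_chip"],
        counts=np.array([[a, c], [b, d]]),
    )
    res = chi_square_test(table)
    score = float(-np.log10(res.p)) if res.p > 0 else np.inf
    return EnrichmentResult(category, a, len(sig), len(cat), len(chip),
                            res.chi2, res.p, score)
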