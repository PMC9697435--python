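"""Clinical and histological association analyses.

Cross-tabulations of person-level covariates (stage, lymphovascular
invasion, perineural invasion, MSI status, ...) against the onset group are
tested with the Pearson chi-square — no continuity correction, asymptotic
p — plus stage-stratified variants and a two-sample t-test from summary
statistics for continuous markers reported as mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet, ValidationError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi_square_test",
    "crosstab",
    "stratified_tests",
    "t_test_from_summary",
    "clinical_association_table",
]


@dataclass
class ContingencyTable:
    """Labelled non-negative integer cross-tabulation (>= 2 x 2)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2 x 2")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("labels do not match count grid shape")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValidationError("contingency table has zero grand total")
        self.counts = counts.astype(float)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected_min: float

    def summary(self) -> str:
        return (
            f"Pearson chi-square = {self.chi2:.4f}, df = {self.df}, "
            f"p = {self.p:.4g} (min expected count {self.expected_min:.2f})"
        )


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction).

    The smallest expected cell count is reported so the caller can judge
    the asymptotic approximation.  A zero row or column margin leaves the
    test undefined and raises.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValidationError("zero row/column margin: chi-square undefined")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(float(chi2), int(df), float(p), float(expected.min()))


def crosstab(sheet: SampleSheet, outcome: str, exposure: str) -> ContingencyTable:
    """Person-level cross-tabulation of two covariates.

    Covariates are person attributes, so each person contributes once
    regardless of how many samples they have.
    """
    persons = sheet.persons()
    for cov in (outcome, exposure):
        if cov != "onset_group" and cov not in persons.columns:
            raise ValidationError(f"covariate {cov!r} not in sample sheet")
    sub = persons[[outcome, exposure]].dropna()
    grid = pd.crosstab(sub[outcome], sub[exposure])
    return ContingencyTable(
        row_labels=[str(r) for r in grid.index],
        col_labels=[str(c) for c in grid.columns],
        counts=grid.to_numpy(),
    )


def stratified_tests(sheet: SampleSheet, outcome: str, exposure: str,
                     stratum: str) -> dict[str, ChiSquareResult | None]:
    """One chi-square per stratum level of the outcome x exposure crosstab.

    Strata whose table is degenerate (zero margin, or fewer than two
    observed levels) are reported as None; the remaining strata are still
    computed.
    """
    persons = sheet.persons()
    for cov in (outcome, exposure, stratum):
        if cov != "onset_group" and cov not in persons.columns:
            raise ValidationError(f"covariate {cov!r} not in sample sheet")
    results: dict[str, ChiSquareResult | None] = {}
    for level in sorted(persons[stratum].dropna().unique()):
        sub = sheet.subset(
            list(sheet.data.loc[
                sheet.data["person_id"].isin(
                    persons.loc[persons[stratum] == level, "person_id"]
                ),
                "sample_id",
            ])
        )
        try:
            results[str(level)] = chi_square_test(crosstab(sub, outcome, exposure))
        except ValidationError:
            results[str(level)] = None
    return results


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Welch by default; set ``equal_var=True`` for the pooled-variance
    variant.  Returns (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2.0
    else:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def clinical_association_table(sheet: SampleSheet, exposure: str = "onset_group",
                               covariates: list[str] | None = None) -> pd.DataFrame:
    """Chi-square association of each clinical covariate with the exposure."""
    covariates = covariates or sheet.clinical_covariates
    rows = []
    for cov in covariates:
        try:
            res = chi_square_test(crosstab(sheet, cov, exposure))
            rows.append(
                {"covariate": cov, "chi2": res.chi2, "df": res.df,
                 "p": res.p, "expected_min": res.expected_min, "note": ""}
            )
        except ValidationError as exc:
            rows.append(
                {"covariate": cov, "chi2": np.nan, "df": 0, "p": np.nan,
                 "expected_min": np.nan, "note": str(exc)}
            )
    return pd.DataFrame(rows)
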