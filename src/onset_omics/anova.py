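"""Per-feature mixed-model ANOVA engines for paired tumor-normal designs.

Two model classes, in the statsmodels mold (construct from data, call
``fit()``, get a results object with estimates, uncertainties and
``summary()``):

* :class:`PairedAnova` fits ``Y = mu + Tissue + Person + error`` with Person
  a random effect, to one feature across the complete tumor/normal pairs.
  Variance components come from the method of moments (expected mean
  squares); on a paired design the tissue F-test is exactly the square of
  the paired t-test.
* :class:`TissueOnsetAnova` fits the fixed-effects interaction model
  ``Y = mu + Tissue + Onset + Tissue x Onset + error`` and additionally
  reports per-onset-group paired fits, giving the two-column
  (late-onset / early-onset) table layout with the interaction p-value.

Effects on the log2 scale are converted to signed fold changes with the
``-1/x`` convention for down-regulation: an effect of ``-log2(1.12)`` is
reported as fold change ``-1.12`` (12% lower in tumor).

Vectorized counterparts (:func:`paired_tests`, :func:`interaction_tests`)
compute the identical statistics for every row of a matrix at once; they are
what the differential-methylation and whole-matrix drivers use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ONSET_GROUPS, OmicsMatrix, SampleSheet

__all__ = [
    "PairedAnova",
    "TissueOnsetAnova",
    "PairedAnovaResults",
    "TissueOnsetAnovaResults",
    "VarianceComponents",
    "InestimableFeatureError",
    "mom_variance_components",
    "paired_variance_components",
    "fold_change_from_log2",
    "signed_fold_change",
    "paired_tests",
    "interaction_tests",
    "paired_anova_table",
    "interaction_anova_table",
]

# Smallest reportable p-value: a zero-residual feature is flagged degenerate
# and reported at this boundary rather than exactly 0 (p must lie in (0, 1]).
P_BOUNDARY = np.finfo(float).tiny


class InestimableFeatureError(ValueError):
    """Feature cannot be fitted; carries a machine-readable reason code."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(message)


# ---------------------------------------------------------------------------
# Signed fold change
# ---------------------------------------------------------------------------


def signed_fold_change(effect_log2: float) -> float:
    """Map a log2 difference to the signed ratio convention.

    Non-negative effects map to 2**e (>= 1); negative effects map to
    -2**(-e) (<= -1), i.e. down-regulation is reported as -1/x.
    """
    e = float(effect_log2)
    if np.isnan(e):
        return np.nan
    return float(2.0 ** e) if e >= 0 else float(-(2.0 ** (-e)))


def fold_change_from_log2(effect: float, se: float | None = None,
                          df: float | None = None, conf: float = 0.95):
    """Signed fold change with a t-based confidence interval.

    The CI is formed on the log2 scale as ``effect +/- t(1-(1-conf)/2, df)*se``
    and each endpoint is mapped through :func:`signed_fold_change`; the
    mapping is monotone, so the ordering is preserved.  With ``df <= 0`` or
    no ``se`` the point estimate is kept and the interval reported missing.
    """
    fc = signed_fold_change(effect)
    if se is None or df is None or df <= 0 or np.isnan(se):
        return fc, np.nan, np.nan
    if se < 0:
        raise ValueError("standard error must be non-negative")
    tcrit = stats.t.ppf(1 - (1 - conf) / 2, df)
    lo = signed_fold_change(effect - tcrit * se)
    hi = signed_fold_change(effect + tcrit * se)
    return fc, lo, hi


# ---------------------------------------------------------------------------
# Method-of-moments variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Variance-component estimates with negative-solution bookkeeping.

    ``components`` maps component name to the (clamped) estimate;
    ``clamped`` flags components whose method-of-moments solution was
    negative and was truncated to zero.
    """

    components: dict[str, float]
    clamped: dict[str, bool] = field(default_factory=dict)

    @property
    def sigma2_person(self) -> float:
        return self.components.get("person", np.nan)

    @property
    def sigma2_error(self) -> float:
        return self.components.get("error", np.nan)

    def __getitem__(self, name: str) -> float:
        return self.components[name]


def mom_variance_components(mean_squares, coefficients, names) -> VarianceComponents:
    """Solve the expected-mean-squares linear system for variance components.

    ``coefficients @ sigma2 = mean_squares`` where row i gives the EMS
    coefficients of observed mean square i on the components in ``names``.
    Negative solutions are clamped to zero and flagged.
    """
    a = np.asarray(coefficients, dtype=float)
    b = np.asarray(mean_squares, dtype=float)
    if a.shape[0] != b.shape[0] or a.shape[1] != len(names):
        raise ValueError("EMS system shape mismatch")
    if np.linalg.matrix_rank(a) < len(names):
        raise np.linalg.LinAlgError(
            f"singular EMS system: components {list(names)} are confounded"
        )
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    comps, clamped = {}, {}
    for name, value in zip(names, sol):
        clamped[name] = bool(value < 0)
        comps[name] = float(max(value, 0.0))
    return VarianceComponents(comps, clamped)


def paired_variance_components(ms_person: float, ms_error: float) -> VarianceComponents:
    """Components of the paired model from its two mean squares.

    With two observations (tumor, normal) per person the expected mean
    squares are E[MS_person] = sigma2_e + 2*sigma2_p and
    E[MS_error] = sigma2_e, so sigma2_p = (MS_person - MS_error)/2.
    """
    return mom_variance_components(
        [ms_person, ms_error], [[2.0, 1.0], [0.0, 1.0]], ["person", "error"]
    )


# ---------------------------------------------------------------------------
# Vectorized paired statistics
# ---------------------------------------------------------------------------


def _pair_arrays(values: pd.DataFrame, design: SampleSheet,
                 onset_group: str | None = None):
    """Tumor and normal value arrays (features x pairs) for complete pairs."""
    pairs = design.complete_pairs(onset_group)
    have = set(values.columns)
    pairs = pairs[
        pairs["tumor"].isin(have) & pairs["normal"].isin(have)
    ].reset_index(drop=True)
    tumor = values[list(pairs["tumor"])].to_numpy(float)
    normal = values[list(pairs["normal"])].to_numpy(float)
    return tumor, normal, pairs


def paired_tests(tumor: np.ndarray, normal: np.ndarray) -> pd.DataFrame:
    """Row-wise paired tumor-vs-normal ANOVA statistics.

    ``tumor`` and ``normal`` are (n_features, n_pairs) arrays with columns
    aligned by person; NaN in either member drops that pair for that row.
    Returns effect (mean paired difference), se, df, t, F, p, n_pairs,
    ms_person, ms_error, sigma2_person, sigma2_error and a ``degenerate``
    flag for rows with zero residual variance.  Rows with fewer than two
    complete pairs get NaN statistics.
    """
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    diffs = tumor - normal
    valid = ~np.isnan(diffs)
    n = valid.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        d0 = np.where(valid, diffs, 0.0)
        effect = d0.sum(axis=1) / np.maximum(n, 1)
        effect = np.where(n > 0, effect, np.nan)
        dev = np.where(valid, diffs - effect[:, None], 0.0)
        ss_d = (dev ** 2).sum(axis=1)
        var_d = ss_d / np.maximum(n - 1, 1)
        se = np.sqrt(var_d / np.maximum(n, 1))
        t = effect / se
        # Person mean squares from the pair means.
        pm0 = np.where(valid, (tumor + normal) / 2.0, 0.0)
        grand = pm0.sum(axis=1) / np.maximum(n, 1)
        pm_dev = np.where(valid, pm0 - grand[:, None], 0.0)
        ms_person = 2.0 * (pm_dev ** 2).sum(axis=1) / np.maximum(n - 1, 1)
        ms_error = var_d / 2.0
        f = t ** 2
        df = n - 1
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))

    degenerate = (var_d == 0) & (n >= 2)
    p = np.where(degenerate & (effect != 0), P_BOUNDARY, p)
    p = np.where(degenerate & (effect == 0), 1.0, p)
    bad = n < 2
    for arr in (effect, se, t, f, p, ms_person, ms_error):
        arr[bad] = np.nan

    sigma2_error = ms_error
    sigma2_person = np.maximum((ms_person - ms_error) / 2.0, 0.0)
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "df": df,
            "t": t,
            "F": f,
            "p": p,
            "n_pairs": n.astype(int),
            "ms_person": ms_person,
            "ms_error": ms_error,
            "sigma2_person": sigma2_person,
            "sigma2_error": sigma2_error,
            "degenerate": degenerate,
        }
    )


def interaction_tests(tumor_a: np.ndarray, normal_a: np.ndarray,
                      tumor_b: np.ndarray, normal_b: np.ndarray) -> pd.DataFrame:
    """Row-wise tissue x onset interaction test (fixed-effects two-way model).

    Groups a and b are the two onset strata; each pair of arrays is
    (n_features, n_pairs_group).  The model is the cell-means two-way layout
    ``Y = mu + Tissue + Onset + Tissue x Onset + error`` with no person
    term; the interaction F has (1, N - 4) degrees of freedom.  Returns the
    interaction contrast (group a tissue effect minus group b tissue
    effect), F, df and p per row, plus the per-group tissue effects.
    """
    cells = [np.atleast_2d(np.asarray(c, dtype=float))
             for c in (tumor_a, normal_a, tumor_b, normal_b)]
    means, counts, sse = [], [], 0.0
    for c in cells:
        valid = ~np.isnan(c)
        n = valid.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            mean = np.where(valid, c, 0.0).sum(axis=1) / np.maximum(n, 1)
            mean = np.where(n > 0, mean, np.nan)
            dev = np.where(valid, c - mean[:, None], 0.0)
        sse = sse + (dev ** 2).sum(axis=1)
        means.append(mean)
        counts.append(n)
    m_ta, m_na, m_tb, m_nb = means
    n_total = sum(counts)
    df_error = n_total - 4
    effect_a = m_ta - m_na
    effect_b = m_tb - m_nb
    contrast = effect_a - effect_b
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = sse / np.maximum(df_error, 1)
        inv_n = sum(1.0 / np.maximum(c, 1) for c in counts)
        f = contrast ** 2 / (s2 * inv_n)
        p = stats.f.sf(f, 1, np.maximum(df_error, 1))
    degenerate = (sse == 0) & (df_error > 0)
    p = np.where(degenerate & (contrast != 0), P_BOUNDARY, p)
    p = np.where(degenerate & (contrast == 0), 1.0, p)
    bad = (df_error < 1) | np.any([c < 1 for c in counts], axis=0)
    for arr in (f, p, contrast):
        arr[bad] = np.nan
    return pd.DataFrame(
        {
            "effect_a": effect_a,
            "effect_b": effect_b,
            "interaction_contrast": contrast,
            "interaction_F": f,
            "df_num": 1,
            "df_den": df_error,
            "interaction_p": p,
            "degenerate": degenerate,
        }
    )


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------


@dataclass
class PairedAnovaResults:
    """Results of the paired mixed ANOVA for one feature.

    ``effect`` is the estimated tumor - normal mean difference (log2 units
    for expression, beta units for methylation); ``fold_change`` and its CI
    follow the signed-ratio convention and are populated only on the log2
    scale.
    """

    feature_id: str | None
    effect: float
    se: float
    df_num: int
    df_den: float
    F: float
    p: float
    n_pairs: int
    n_excluded_samples: int
    vc: VarianceComponents
    fold_change: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    degenerate: bool = False
    scale: str = "log2"

    def summary(self) -> str:
        lines = [
            "Paired tumor-normal ANOVA (Person random; method of moments)",
            f"Feature: {self.feature_id}    complete pairs: {self.n_pairs}"
            f"    excluded samples: {self.n_excluded_samples}",
            f"{'term':<12}{'estimate':>12}{'se':>10}{'F':>12}"
            f"{'df':>10}{'p':>14}",
            f"{'tissue':<12}{self.effect:>12.4f}{self.se:>10.4f}{self.F:>12.3f}"
            f"{f'(1,{self.df_den:g})':>10}{self.p:>14.3e}",
            f"variance components: person={self.vc.sigma2_person:.4f}"
            f"{' (clamped)' if self.vc.clamped.get('person') else ''}, "
            f"error={self.vc.sigma2_error:.4f}",
        ]
        if self.scale == "log2" and not np.isnan(self.fold_change):
            lines.append(
                f"fold change: {self.fold_change:.3f} "
                f"(95% CI {self.ci_low:.3f} to {self.ci_high:.3f})"
            )
        if self.degenerate:
            lines.append("WARNING: zero residual variance; p at boundary")
        return "\n".join(lines)


class PairedAnova:
    """Paired tumor-vs-normal model ``Y = mu + Tissue + Person + error``.

    Parameters
    ----------
    values : pandas.Series
        One feature's values indexed by sample_id.
    design : SampleSheet
        Sample metadata; only complete tumor/normal pairs enter the fit,
        and pairs with a missing value in either member are dropped.
    scale : {"log2", "beta"}
        Response scale; fold changes are reported only for ``log2``.
    """

    def __init__(self, values: pd.Series, design: SampleSheet,
                 feature_id: str | None = None, scale: str = "log2"):
        self.values = values
        self.design = design
        self.feature_id = feature_id if feature_id is not None else values.name
        self.scale = scale

    @classmethod
    def from_matrix(cls, matrix: OmicsMatrix, design: SampleSheet,
                    feature_id: str) -> "PairedAnova":
        scale = "beta" if matrix.kind == "methylation_beta" else "log2"
        return cls(matrix.values.loc[feature_id], design,
                   feature_id=feature_id, scale=scale)

    def fit(self, onset_group: str | None = None) -> PairedAnovaResults:
        frame = self.values.to_frame().T
        tumor, normal, pairs = _pair_arrays(frame, self.design, onset_group)
        n_excluded = len(self.values.index) - 2 * len(pairs)
        row = paired_tests(tumor, normal).iloc[0]
        if row["n_pairs"] < 2:
            raise InestimableFeatureError(
                "too_few_pairs",
                f"feature {self.feature_id!r}: {int(row['n_pairs'])} complete "
                "pair(s); at least 2 required",
            )
        vc = paired_variance_components(row["ms_person"], row["ms_error"])
        fc = ci_lo = ci_hi = np.nan
        if self.scale == "log2":
            fc, ci_lo, ci_hi = fold_change_from_log2(
                row["effect"], row["se"], row["df"]
            )
        return PairedAnovaResults(
            feature_id=self.feature_id,
            effect=float(row["effect"]),
            se=float(row["se"]),
            df_num=1,
            df_den=float(row["df"]),
            F=float(row["F"]),
            p=float(row["p"]),
            n_pairs=int(row["n_pairs"]),
            n_excluded_samples=int(n_excluded),
            vc=vc,
            fold_change=fc,
            ci_low=ci_lo,
            ci_high=ci_hi,
            degenerate=bool(row["degenerate"]),
            scale=self.scale,
        )


@dataclass
class TissueOnsetAnovaResults:
    """Results of the tissue x onset interaction model for one feature.

    ``per_group`` holds the within-group paired fits keyed by onset group,
    providing the late/early two-column layout; ``interaction_p`` tests
    whether the tumor-normal effect differs between onset groups.
    """

    feature_id: str | None
    interaction_contrast: float
    interaction_F: float
    df_num: int
    df_den: float
    interaction_p: float
    tissue_effect: float
    onset_effect: float
    per_group: dict[str, PairedAnovaResults]
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Tissue x onset-group interaction ANOVA",
            f"Feature: {self.feature_id}",
            f"interaction contrast (LOCRC - EOCRC tissue effect): "
            f"{self.interaction_contrast:.4f}",
            f"interaction F = {self.interaction_F:.3f} "
            f"(1, {self.df_den:g}), p = {self.interaction_p:.3e}",
        ]
        for group, res in self.per_group.items():
            if res.scale == "log2":
                lines.append(
                    f"{group}: fold change {res.fold_change:.3f} "
                    f"({res.ci_low:.3f} to {res.ci_high:.3f}), p = {res.p:.3e}"
                )
            else:
                lines.append(
                    f"{group}: delta = {res.effect:.4f} "
                    f"(se {res.se:.4f}), p = {res.p:.3e}"
                )
        return "\n".join(lines)


class TissueOnsetAnova:
    """Interaction model ``Y = mu + Tissue + Onset + Tissue x Onset + error``.

    The interaction term is fitted as a fixed-effects two-way layout with no
    person term.  Per-onset-group tumor-vs-normal effects are additionally
    estimated by the paired model within each group.
    """

    def __init__(self, values: pd.Series, design: SampleSheet,
                 feature_id: str | None = None, scale: str = "log2"):
        self.values = values
        self.design = design
        self.feature_id = feature_id if feature_id is not None else values.name
        self.scale = scale

    @classmethod
    def from_matrix(cls, matrix: OmicsMatrix, design: SampleSheet,
                    feature_id: str) -> "TissueOnsetAnova":
        scale = "beta" if matrix.kind == "methylation_beta" else "log2"
        return cls(matrix.values.loc[feature_id], design,
                   feature_id=feature_id, scale=scale)

    def fit(self) -> TissueOnsetAnovaResults:
        frame = self.values.to_frame().T
        groups = {}
        for group in ONSET_GROUPS:
            tumor, normal, pairs = _pair_arrays(frame, self.design, group)
            if len(pairs) < 2:
                raise InestimableFeatureError(
                    "missing_stratum",
                    f"onset group {group!r} has {len(pairs)} complete pair(s); "
                    "both groups need at least 2",
                )
            groups[group] = (tumor, normal)
        # Contrast orientation: LOCRC minus EOCRC tissue effect.
        row = interaction_tests(
            groups["LOCRC"][0], groups["LOCRC"][1],
            groups["EOCRC"][0], groups["EOCRC"][1],
        ).iloc[0]
        per_group = {
            g: PairedAnova(self.values, self.design, self.feature_id,
                           self.scale).fit(onset_group=g)
            for g in ("LOCRC", "EOCRC")
        }
        tissue_effect = (row["effect_a"] + row["effect_b"]) / 2.0
        cells = {g: groups[g] for g in ONSET_GROUPS}
        onset_effect = float(
            (np.nanmean(cells["LOCRC"][0]) + np.nanmean(cells["LOCRC"][1])) / 2
            - (np.nanmean(cells["EOCRC"][0]) + np.nanmean(cells["EOCRC"][1])) / 2
        )
        return TissueOnsetAnovaResults(
            feature_id=self.feature_id,
            interaction_contrast=float(row["interaction_contrast"]),
            interaction_F=float(row["interaction_F"]),
            df_num=1,
            df_den=float(row["df_den"]),
            interaction_p=float(row["interaction_p"]),
            tissue_effect=float(tissue_effect),
            onset_effect=onset_effect,
            per_group=per_group,
            degenerate=bool(row["degenerate"]),
        )


# ---------------------------------------------------------------------------
# Whole-matrix drivers
# ---------------------------------------------------------------------------


def paired_anova_table(matrix: OmicsMatrix, design: SampleSheet,
                       onset_group: str | None = None) -> pd.DataFrame:
    """Paired fits for every feature of a matrix (vectorized).

    Produces one row per feature with effect, se, F, p, fold change and CI
    (log2 matrices only), variance components and the skip reason for
    features with fewer than two complete pairs.
    """
    matrix.check_samples(design)
    tumor, normal, pairs = _pair_arrays(matrix.values, design, onset_group)
    table = paired_tests(tumor, normal)
    table.insert(0, "feature_id", matrix.feature_ids)
    table["reason"] = np.where(table["n_pairs"] < 2, "too_few_pairs", "")
    if matrix.kind == "expression_log2":
        tcrit = stats.t.ppf(0.975, np.maximum(table["df"], 1))
        sfc = np.vectorize(signed_fold_change, otypes=[float])
        table["fold_change"] = sfc(table["effect"].to_numpy())
        table["ci_low"] = sfc((table["effect"] - tcrit * table["se"]).to_numpy())
        table["ci_high"] = sfc((table["effect"] + tcrit * table["se"]).to_numpy())
    return table


def interaction_anova_table(matrix: OmicsMatrix, design: SampleSheet) -> pd.DataFrame:
    """Interaction fits for every feature, with per-group paired columns."""
    matrix.check_samples(design)
    per_group = {}
    cells = {}
    for group in ONSET_GROUPS:
        tumor, normal, pairs = _pair_arrays(matrix.values, design, group)
        if len(pairs) < 2:
            raise InestimableFeatureError(
                "missing_stratum",
                f"onset group {group!r} has {len(pairs)} complete pair(s)",
            )
        cells[group] = (tumor, normal)
        per_group[group] = paired_tests(tumor, normal)
    inter = interaction_tests(
        cells["LOCRC"][0], cells["LOCRC"][1],
        cells["EOCRC"][0], cells["EOCRC"][1],
    )
    out = pd.DataFrame({"feature_id": matrix.feature_ids})
    for group, tab in per_group.items():
        suffix = group.lower()
        out[f"effect_{suffix}"] = tab["effect"].to_numpy()
        out[f"p_{suffix}"] = tab["p"].to_numpy()
        if matrix.kind == "expression_log2":
            tcrit = stats.t.ppf(0.975, np.maximum(tab["df"], 1))
            sfc = np.vectorize(signed_fold_change, otypes=[float])
            out[f"fold_change_{suffix}"] = sfc(tab["effect"].to_numpy())
            out[f"ci_low_{suffix}"] = sfc(
                (tab["effect"] - tcrit * tab["se"]).to_numpy()
            )
            out[f"ci_high_{suffix}"] = sfc(
                (tab["effect"] + tcrit * tab["se"]).to_numpy()
            )
    out["interaction_contrast"] = inter["interaction_contrast"].to_numpy()
    out["interaction_F"] = inter["interaction_F"].to_numpy()
    out["interaction_p"] = inter["interaction_p"].to_numpy()
    return out
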