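"""Differential-methylation calling and the five-class interaction partition.

Within each onset group, every non-deep-sea locus is tested tumor-vs-normal
with the paired model; delta beta is the mean within-person (tumor - normal)
beta difference.  Benjamini-Hochberg FDR is applied within each group's
locus list, and a locus is a DML in that group when its q-value is at or
below the FDR threshold.  The tissue x onset interaction model (fixed
effects, both groups jointly) then splits the DML into the partition:

* class I   — DML in both groups, interaction p >= alpha (same magnitude)
* class II  — DML in both groups, interaction p <  alpha
* class III — DML in the early-onset group only, interaction p >= alpha
* class IV  — early-onset-specific DML (early-only, interaction p < alpha)
* class V   — late-onset-specific DML (late-only, interaction p < alpha)
* locrc_only_ns — late-only DML whose interaction p is not significant
  (kept so the classes partition every locus; the remainder is not_dml)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .anova import interaction_tests, paired_tests, _pair_arrays
from .io import FeatureAnnotation, OmicsMatrix, SampleSheet, ValidationError

__all__ = [
    "bh_fdr",
    "call_dml",
    "classify_venn",
    "summarize_partition",
    "class_iv_export",
    "VENN_CLASSES",
]

VENN_CLASSES = ("I", "II", "III", "IV", "V", "locrc_only_ns", "not_dml")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    Monotonicity is enforced (q never decreases with p); an empty input
    yields an empty output.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_dml(beta_matrix: OmicsMatrix, design: SampleSheet,
             manifest: FeatureAnnotation, fdr_alpha: float = 0.05,
             interaction_alpha: float = 0.05) -> pd.DataFrame:
    """Per-locus differential methylation calls with interaction p-values.

    Deep-sea loci are excluded before any testing.  Returns one row per
    tested locus with delta beta, paired p, BH q (computed within each
    onset group across its tested loci), DML flags, the interaction p and
    the assigned ``venn_class``.
    """
    if beta_matrix.kind != "methylation_beta":
        raise ValidationError("call_dml expects a methylation beta matrix")
    beta_matrix.check_samples(design)
    region = manifest.region_of()
    missing = [f for f in beta_matrix.feature_ids if f not in region.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} locus/loci missing from manifest, e.g. {missing[:3]}"
        )
    keep = [f for f in beta_matrix.feature_ids
            if region.loc[f] != "deep_sea"]
    values = beta_matrix.values.loc[keep]

    stats_by_group = {}
    cells = {}
    for group in ("LOCRC", "EOCRC"):
        tumor, normal, pairs = _pair_arrays(values, design, group)
        if len(pairs) < 2:
            raise ValidationError(
                f"onset group {group!r} has {len(pairs)} complete pair(s); "
                "at least 2 required"
            )
        cells[group] = (tumor, normal)
        stats_by_group[group] = paired_tests(tumor, normal)

    inter = interaction_tests(
        cells["LOCRC"][0], cells["LOCRC"][1],
        cells["EOCRC"][0], cells["EOCRC"][1],
    )

    records = pd.DataFrame({"locus_id": keep})
    for group, tab in stats_by_group.items():
        suffix = group.lower()
        records[f"delta_beta_{suffix}"] = tab["effect"].to_numpy()
        records[f"p_{suffix}"] = tab["p"].to_numpy()
        records[f"fdr_{suffix}"] = bh_fdr(tab["p"].to_numpy())
        records[f"dml_{suffix}"] = records[f"fdr_{suffix}"] <= fdr_alpha
    records["interaction_p"] = inter["interaction_p"].to_numpy()
    records["region_class"] = region.loc[keep].to_numpy()
    return classify_venn(records, interaction_alpha)


def classify_venn(records: pd.DataFrame,
                  interaction_alpha: float = 0.05) -> pd.DataFrame:
    """Assign each locus its partition class from the stored flags.

    Requires columns ``dml_locrc``, ``dml_eocrc`` and ``interaction_p``;
    every locus receives exactly one class.
    """
    for col in ("dml_locrc", "dml_eocrc", "interaction_p"):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    if records["interaction_p"].isna().any():
        raise ValidationError("interaction_p must be populated for every record")
    both = records["dml_locrc"] & records["dml_eocrc"]
    eo_only = records["dml_eocrc"] & ~records["dml_locrc"]
    lo_only = records["dml_locrc"] & ~records["dml_eocrc"]
    sig = records["interaction_p"] < interaction_alpha

    venn = np.full(len(records), "not_dml", dtype=object)
    venn[(both & ~sig).to_numpy()] = "I"
    venn[(both & sig).to_numpy()] = "II"
    venn[(eo_only & ~sig).to_numpy()] = "III"
    venn[(eo_only & sig).to_numpy()] = "IV"
    venn[(lo_only & sig).to_numpy()] = "V"
    venn[(lo_only & ~sig).to_numpy()] = "locrc_only_ns"
    out = records.copy()
    out["venn_class"] = venn
    return out


def summarize_partition(records: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts, delta-beta extrema and magnitude bins.

    ``max_abs_delta`` per locus is the larger |delta beta| of the two onset
    groups; the >= 0.1 and >= 0.2 bins count loci whose magnitude reaches
    10% and 20% differential methylation.
    """
    if "venn_class" not in records.columns:
        raise ValidationError("records must be classified first")
    abs_delta = np.maximum(
        records["delta_beta_locrc"].abs(), records["delta_beta_eocrc"].abs()
    )
    rows = []
    for cls in VENN_CLASSES:
        sub = records[records["venn_class"] == cls]
        sub_abs = abs_delta[sub.index]
        rows.append(
            {
                "venn_class": cls,
                "n": len(sub),
                "delta_locrc_min": sub["delta_beta_locrc"].min(),
                "delta_locrc_max": sub["delta_beta_locrc"].max(),
                "delta_eocrc_min": sub["delta_beta_eocrc"].min(),
                "delta_eocrc_max": sub["delta_beta_eocrc"].max(),
                "n_abs_delta_ge_0.1": int((sub_abs >= 0.1).sum()),
                "n_abs_delta_ge_0.2": int((sub_abs >= 0.2).sum()),
            }
        )
    return pd.DataFrame(rows)


def class_iv_export(records: pd.DataFrame) -> pd.DataFrame:
    """Early-onset-specific loci (class IV) in scatter/PCA-ready form."""
    cols = ["locus_id", "delta_beta_locrc", "delta_beta_eocrc",
            "fdr_eocrc", "fdr_locrc", "interaction_p"]
    cols = [c for c in cols if c in records.columns]
    return records.loc[records["venn_class"] == "IV", cols].reset_index(drop=True)
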