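"""Pre-model transforms: beta-value computation and quantile normalization.

The methylation score (beta value) of a locus is M / (M + U) where M and U
are the methylated and unmethylated probe intensities; it lies in [0, 1] and
is scale-invariant in the intensities.  Expression matrices are quantile
normalized across samples before any model is fitted; beta matrices are not
cross-sample normalized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import OmicsMatrix, ValidationError

__all__ = ["compute_beta", "beta_from_intensities", "quantile_normalize"]


def compute_beta(methylated, unmethylated):
    """Beta value M / (M + U) for methylated/unmethylated intensity pairs.

    Accepts scalars or arrays.  Negative intensities are invalid.  Where
    M + U == 0 the locus is unmeasured and the result is missing (NaN),
    not zero and not an error.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValidationError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def beta_from_intensities(methylated: OmicsMatrix | pd.DataFrame,
                          unmethylated: OmicsMatrix | pd.DataFrame) -> OmicsMatrix:
    """Build a beta-value matrix from paired intensity matrices.

    The two matrices must share features and samples; rows/columns are
    aligned by label.
    """
    m = methylated.values if isinstance(methylated, OmicsMatrix) else methylated
    u = unmethylated.values if isinstance(unmethylated, OmicsMatrix) else unmethylated
    if set(m.index) != set(u.index) or set(m.columns) != set(u.columns):
        raise ValidationError(
            "methylated and unmethylated matrices must share features and samples"
        )
    u = u.loc[m.index, m.columns]
    beta = pd.DataFrame(
        compute_beta(m.to_numpy(float), u.to_numpy(float)),
        index=m.index,
        columns=m.columns,
    )
    return OmicsMatrix(beta, "methylation_beta")


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Quantile-normalize an expression matrix across samples.

    After normalization every sample's sorted value vector equals the
    across-sample mean of sorted vectors (the reference distribution) and
    within-sample ranks are preserved.  Ties receive the mean of the
    reference values at the tied ranks.  Missing cells are excluded from
    rank computation and restored as missing; samples with fewer non-missing
    values than the reference length are mapped through interpolation on
    quantile positions.  Idempotent.
    """
    if matrix.kind != "expression_log2":
        raise ValidationError("quantile normalization applies to expression matrices")
    df = matrix.values
    if df.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    counts = df.notna().sum(axis=0)
    if (counts == 0).any():
        empty = list(counts.index[counts == 0])
        raise ValidationError(f"sample(s) with all values missing: {empty}")

    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref)
    # Reference distribution: mean over samples of each sorted vector,
    # interpolated onto a common quantile grid when counts differ.
    ref = np.zeros(n_ref)
    for col in df.columns:
        vals = np.sort(df[col].dropna().to_numpy())
        if len(vals) == n_ref:
            ref += vals
        else:
            pos = np.linspace(0.0, 1.0, len(vals))
            ref += np.interp(grid, pos, vals)
    ref /= df.shape[1]

    ref_cumsum = np.concatenate([[0.0], np.cumsum(ref)])
    out = df.copy()
    for col in df.columns:
        mask = df[col].notna()
        m = int(mask.sum())
        vals = df.loc[mask, col].to_numpy(float)
        if m == n_ref:
            order = np.argsort(vals, kind="mergesort")
            sorted_vals = vals[order]
            # Tied blocks receive the mean of the reference values at the
            # tied rank positions.
            uniq, inverse, counts = np.unique(
                sorted_vals, return_inverse=True, return_counts=True
            )
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            block_means = (
                ref_cumsum[starts + counts] - ref_cumsum[starts]
            ) / counts
            assigned = np.empty(m)
            assigned[order] = block_means[inverse]
        else:
            # Shorter sample: map tie-averaged ranks through quantile
            # positions onto the reference distribution.
            ranks = pd.Series(vals).rank(method="average").to_numpy()
            pos = (ranks - 1.0) / (m - 1.0) if m > 1 else np.zeros(m)
            assigned = np.interp(pos, grid, ref)
        out.loc[mask, col] = assigned
    return OmicsMatrix(out, "expression_log2")
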