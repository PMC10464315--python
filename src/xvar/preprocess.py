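"""Pre-modelling transformations.

Methylation beta values are heavily non-normal (bimodal in males, trimodal
in females), so before any linear modelling each CpG is mapped to the
standard-normal scale by a rank-inverse-normal (RIN) transformation applied
within each cohort x sex group.  Residual between-cohort batch structure is
removed beforehand by a simplified location/scale adjustment, and unknown
confounders are summarised as the leading singular vectors of the
design-residualised data matrix ("latent factors").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "rin_transform",
    "rin_transform_frame",
    "batch_adjust",
    "estimate_latent_factors",
]


def rin_transform(values: np.ndarray) -> np.ndarray:
    """Rank-inverse-normal transform a 1-D vector, NaN-preserving.

    Uses Blom offsets: x_i -> Phi^{-1}((r_i - 3/8) / (n + 1/4)) with r_i the
    average rank among the n non-missing values.  Ties map to equal outputs;
    missing entries stay missing.  A fully tied (constant) vector maps to all
    zeros — the average-rank formula gives (n+1)/2 for every entry — and it is
    the caller's job (``rin_transform_frame``) to exclude such CpGs as
    rank-uninformative.

    Raises
    ------
    ValueError
        If fewer than two non-missing values are present.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rin_transform expects a 1-D vector")
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("rin_transform needs >= 2 non-missing values")
    obs = x[mask]
    ranks = stats.rankdata(obs, method="average")
    out = np.full_like(x, np.nan)
    out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def rin_transform_frame(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    group_cols: tuple[str, ...] = ("cohort", "sex"),
) -> pd.DataFrame:
    """RIN-transform every CpG within each sample group (default cohort x sex).

    Parameters
    ----------
    matrix : DataFrame, CpGs x samples (rows = CpG ids, columns = sample ids).
    samples : DataFrame indexed by sample id with the grouping columns.
    group_cols : columns of ``samples`` defining the transformation strata.

    CpGs that are constant (or nearly all missing) within some group are
    dropped from the output with a logged exclusion list.
    """
    missing = [c for c in group_cols if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks grouping columns: {missing}")
    matrix = matrix.loc[:, samples.index]
    out = np.full(matrix.shape, np.nan)
    bad: set[str] = set()
    values = matrix.to_numpy(dtype=float)
    for _, idx in samples.groupby(list(group_cols), observed=True).groups.items():
        cols = matrix.columns.get_indexer(idx)
        block = values[:, cols]
        for i in range(block.shape[0]):
            row = block[i]
            obs = row[~np.isnan(row)]
            if obs.size < 2 or np.all(obs == obs[0]):
                bad.add(matrix.index[i])  # constant within a group: excluded
                continue
            out[i, cols] = rin_transform(row)
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    if bad:
        logger.warning(
            "rin_transform_frame: excluding %d CpGs constant/degenerate within a group",
            len(bad),
        )
        result = result.drop(index=sorted(bad))
    result.attrs["rin_groups"] = tuple(group_cols)
    return result


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric design from a covariate frame: one-hot categoricals (drop
    first level), passthrough numerics, prepend intercept."""
    parts = [np.ones((len(covariates), 1))]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "ifu" and s.nunique() > 2:
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            d = pd.get_dummies(s.astype("category"), drop_first=True)
            if d.shape[1]:
                parts.append(d.to_numpy(dtype=float))
    return np.hstack(parts)


def batch_adjust(
    matrix: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remove batch-specific location and scale per CpG, preserving covariates.

    A simplified (non-empirical-Bayes) analogue of ComBat: per CpG, the batch
    means are estimated jointly with the covariate effects by least squares,
    subtracted, and the batch-specific residual scales are equalised to the
    pooled residual scale.  The covariate-explained part of the signal
    (for example an age trend) is untouched.

    Batches with fewer than 3 samples get a location-only adjustment (their
    scale estimate would be meaningless) with a logged warning.
    """
    batch = batch.loc[matrix.columns]
    levels = pd.unique(batch)
    if len(levels) < 2:
        return matrix.copy()

    X_cov = (
        _design_matrix(covariates.loc[matrix.columns])
        if covariates is not None
        else np.ones((matrix.shape[1], 1))
    )
    B = pd.get_dummies(batch.astype("category"), drop_first=True).to_numpy(dtype=float)
    X_full = np.hstack([X_cov, B])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("batch_adjust: covariates aliased with batch labels")

    Y = matrix.to_numpy(dtype=float).T  # samples x CpGs
    beta_full, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    fitted_cov = X_cov @ beta_full[: X_cov.shape[1]]
    resid = Y - X_full @ beta_full  # batch-centred residuals

    small = [lv for lv in levels if (batch == lv).sum() < 3]
    if small:
        logger.warning(
            "batch_adjust: batches %s have < 3 samples; location-only adjustment",
            small,
        )
    # equalise per-batch residual scale to the pooled scale
    adjusted = resid.copy()
    pooled_sd = resid.std(axis=0, ddof=1)
    pooled_sd[pooled_sd == 0] = 1.0
    for lv in levels:
        rows = (batch == lv).to_numpy()
        if lv in small:
            continue
        sd_b = resid[rows].std(axis=0, ddof=1)
        sd_b[sd_b == 0] = 1.0
        adjusted[rows] = resid[rows] / sd_b * pooled_sd
    out = (fitted_cov + adjusted).T
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def estimate_latent_factors(
    matrix: pd.DataFrame,
    known: pd.DataFrame | np.ndarray | None,
    k: int = 5,
) -> pd.DataFrame:
    """Estimate k latent factors as the top left singular vectors of the
    CpG-wise residuals after projecting out the known design.

    This plays the role surrogate-variable estimation plays in methylation
    studies: capturing shared unmodelled structure (unmeasured cell
    composition, technical drift) so it can enter the association models as
    covariates.  Returns a samples x k frame with orthonormal columns.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    Y = matrix.to_numpy(dtype=float).T  # samples x CpGs
    if k >= min(Y.shape):
        raise ValueError("k must be smaller than both matrix dimensions")
    if known is not None:
        D = _design_matrix(known) if isinstance(known, pd.DataFrame) else np.asarray(known, float)
        if D.ndim == 1:
            D = D[:, None]
        Q, _ = np.linalg.qr(D)
        Y = Y - Q @ (Q.T @ Y)
    else:
        Y = Y - Y.mean(axis=0)
    # column-centre CpGs so factors reflect covariance structure
    Y = Y - Y.mean(axis=0)
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    factors = U[:, :k]
    return pd.DataFrame(
        factors, index=matrix.columns, columns=[f"LF{i + 1}" for i in range(k)]
    )
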