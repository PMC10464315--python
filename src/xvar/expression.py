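"""Association of hit-CpG methylation with X-linked gene expression.

Lowly expressed genes (median CPM < 1) are removed; the kept genes'
log2-CPM values are RIN-transformed per cohort and sex, like the
methylation data.  For every (CpG, gene) pair a linear model of expression
on methylation plus covariates (age, cohort, cell fractions, technical
batches including flowcell, latent factors) yields a t statistic for the
methylation coefficient.  Because the covariate design is shared across
pairs, the fits are computed by Frisch–Waugh partialling: both matrices are
residualised on the design once, and each pair reduces to a simple
regression between residual vectors.  The t statistics are then
empirical-null corrected per CpG across genes, and significance is called
by Bonferroni over the total number of pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dglm import build_design
from .empirical_null import correct, estimate_null
from .preprocess import rin_transform

logger = logging.getLogger(__name__)

__all__ = ["log_cpm", "filter_genes", "associate"]


def log_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a small prior count."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + prior), index=counts.index, columns=counts.columns)


def filter_genes(counts: pd.DataFrame, min_median_cpm: float = 1.0) -> pd.Index:
    """Genes whose median CPM is at least ``min_median_cpm``.

    The boundary is inclusive: only genes strictly below the threshold are
    considered lowly expressed and removed.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    med = np.median(cpm, axis=1)
    return counts.index[med >= min_median_cpm]


def _rin_rows(mat: np.ndarray, groups: pd.Series) -> np.ndarray:
    out = np.empty_like(mat, dtype=float)
    for _, idx in groups.groupby(groups, observed=True).groups.items():
        cols = groups.index.get_indexer(idx)
        for i in range(mat.shape[0]):
            out[i, cols] = rin_transform(mat[i, cols])
    return out


def associate(
    meth: pd.DataFrame,
    expr_counts: pd.DataFrame,
    samples: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    min_genes_for_null: int = 100,
    gene_tss: pd.Series | None = None,
    cpg_pos: pd.Series | None = None,
) -> pd.DataFrame:
    """Test every (CpG, gene) pair for a methylation–expression association.

    Parameters
    ----------
    meth : CpGs x samples matrix on the RIN scale (hit CpGs only).
    expr_counts : genes x samples raw counts; filtered and RIN-transformed
        internally (per cohort and sex when those columns exist).
    samples : covariate table indexed by sample id.  Samples missing from
        any of the three inputs are dropped with a log message.
    covariates : model covariates; defaults to age, cohort, cell fractions,
        technical batches and flowcell where present.
    min_genes_for_null : below this many kept genes, the per-CpG
        empirical-null fit falls back to the robust median/MAD estimate.
    gene_tss, cpg_pos : optional positions used to report CpG–gene distance.

    Returns a tidy frame with one row per pair: delta1, t_raw, t_corrected,
    p_corrected, p_bonf, significant, and distance_bp when positions given.
    """
    common = meth.columns.intersection(expr_counts.columns).intersection(samples.index)
    dropped = max(meth.shape[1], expr_counts.shape[1]) - len(common)
    if dropped:
        logger.warning("associate: dropping %d unmatched samples", dropped)
    if len(common) < 10:
        raise ValueError("too few overlapping samples for association")
    meth = meth.loc[:, common]
    samples = samples.loc[common]
    expr_counts = expr_counts.loc[:, common]

    kept = filter_genes(expr_counts)
    logger.info("associate: %d / %d genes pass the median-CPM filter", len(kept), len(expr_counts))
    lcpm = log_cpm(expr_counts.loc[kept])
    if {"cohort", "sex"} <= set(samples.columns):
        grp = samples["cohort"].astype(str) + "|" + samples["sex"].astype(str)
    else:
        grp = pd.Series("all", index=samples.index)
    E = _rin_rows(lcpm.to_numpy(), grp)

    if covariates is None:
        candidates = [
            "age", "cohort", "cd8t", "cd4t", "nk", "bcell", "mono", "purity",
            "sentrix_position", "sample_plate", "flowcell",
        ]
        covariates = [
            c for c in candidates
            if c in samples.columns and samples[c].nunique(dropna=False) > 1
        ]
    X, _ = build_design(samples, covariates, factors)

    # Frisch–Waugh: residualise both blocks on the shared design
    Q, _ = np.linalg.qr(X)
    p = Q.shape[1]
    M = meth.to_numpy(dtype=float)
    Mr = M - (M @ Q) @ Q.T
    Er = E - (E @ Q) @ Q.T

    n = len(common)
    df = n - p - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")

    m_ss = np.einsum("ij,ij->i", Mr, Mr)
    e_ss = np.einsum("ij,ij->i", Er, Er)
    cross = Mr @ Er.T  # CpGs x genes
    denom = np.sqrt(np.outer(m_ss, e_ss))
    denom[denom == 0] = np.inf
    r = np.clip(cross / denom, -0.9999999, 0.9999999)
    slope = cross / m_ss[:, None]
    t_raw = r * np.sqrt(df / (1.0 - r * r))

    t_corr = np.empty_like(t_raw)
    for i in range(t_raw.shape[0]):
        row = t_raw[i]
        if row.size >= min_genes_for_null:
            est = estimate_null(row, min_n=min(100, row.size))
        else:
            logger.warning(
                "associate: only %d genes; robust null fallback for CpG %s",
                row.size, meth.index[i],
            )
            med = float(np.median(row))
            mad = float(1.4826 * np.median(np.abs(row - med)))
            from .empirical_null import NullEstimate

            est = NullEstimate(
                med, mad if mad > 0 else float(np.std(row)), 1.0,
                np.array([med] * 3), np.array([1.0] * 3), np.array([0.0, 1.0, 0.0]),
                np.nan, 0, "robust", med, mad,
            )
        t_corr[i], _ = correct(row, est)

    p_corr = 2.0 * stats.norm.sf(np.abs(t_corr))
    n_pairs = t_raw.size
    rows = []
    for i, cpg in enumerate(meth.index):
        for j, gene in enumerate(kept):
            rows.append((cpg, gene, slope[i, j], t_raw[i, j], t_corr[i, j], p_corr[i, j]))
    out = pd.DataFrame(
        rows, columns=["cpg_id", "gene_id", "delta1", "t_raw", "t_corrected", "p_corrected"]
    )
    out["p_bonf"] = np.minimum(out["p_corrected"] * n_pairs, 1.0)
    out["significant"] = out["p_bonf"] < alpha
    if gene_tss is not None and cpg_pos is not None:
        out["distance_bp"] = (
            out["gene_id"].map(gene_tss).to_numpy(dtype=float)
            - out["cpg_id"].map(cpg_pos).to_numpy(dtype=float)
        )
        out["distance_bp"] = out["distance_bp"].abs()
    return out
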