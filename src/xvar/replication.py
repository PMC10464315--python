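"""Hit calling and the dual-cohort replication scheme.

Discovery hits are called per sex at a Bonferroni-corrected threshold on the
empirical-null-corrected p-values.  A hit replicates in an external result
set if its BH/FDR-adjusted p-value (adjusted over the *unique* discovery
hits, pooling sexes) is below 0.05 *and* the effect direction matches
discovery.  A hit is doubly replicated when this holds in both replication
cohorts simultaneously.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["bonferroni_select", "bh_fdr", "replicate"]


def bonferroni_select(p: np.ndarray, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    """Indices with p < alpha / m.

    ``m`` defaults to ``len(p)``; passing a larger m supports testing a
    subset of a wider family (the convention used throughout: m is the full
    family size, p may be any subset of it).
    """
    p = np.asarray(p, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if p.size == 0:
        return np.array([], dtype=np.intp)
    if m is None:
        m = p.size
    if m <= 0:
        raise ValueError("m must be positive")
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.flatnonzero(p < alpha / m)


def bh_fdr(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    ``m`` defaults to ``len(p)`` but may be larger when the tested family is
    wider than the supplied vector (e.g. adjusting one cohort's p-values over
    the union of discovery hits from both sexes).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def _direction(z: float) -> int:
    """Sign of the corrected statistic; 0 (never replicating) for exact zero."""
    return int(np.sign(z))


def replicate(
    discovery: pd.DataFrame,
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    m_unique: int,
    alpha: float = 0.05,
    z_col: str = "z",
    p_col: str = "p",
    rep_names: tuple[str, str] = ("rep1", "rep2"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Apply the FDR + direction-consistency replication rule.

    Parameters
    ----------
    discovery : frame indexed by cpg_id with columns ``z_col`` (corrected
        statistic, gives the discovery direction) and ``p_col``.
    rep1, rep2 : result frames indexed by cpg_id with the same two columns;
        CpGs absent from a replication set count as non-replicated but stay
        in the denominator.
    m_unique : number of tests for the BH adjustment — the total number of
        unique discovery hits across sexes for this hit class.

    Returns the per-CpG hit table (direction, per-cohort adjusted p and
    flags, ``doubly_replicated``) and a dict of replication rates.
    """
    if m_unique < len(discovery):
        raise ValueError("m_unique cannot be smaller than the discovery hit count")
    out = pd.DataFrame(index=discovery.index)
    out["direction"] = [
        "gain" if s > 0 else ("loss" if s < 0 else "null")
        for s in np.sign(discovery[z_col].to_numpy())
    ]
    disc_sign = np.sign(discovery[z_col].to_numpy())

    for name, rep in zip(rep_names, (rep1, rep2)):
        present = discovery.index.intersection(rep.index)
        missing = discovery.index.difference(rep.index)
        if len(missing):
            logger.warning(
                "replicate: %d discovery CpGs absent from %s; counted as non-replicated",
                len(missing),
                name,
            )
        p_adj = pd.Series(np.nan, index=discovery.index)
        sign_rep = pd.Series(0.0, index=discovery.index)
        if len(present):
            p_adj.loc[present] = bh_fdr(
                rep.loc[present, p_col].to_numpy(), m=m_unique
            )
            sign_rep.loc[present] = np.sign(rep.loc[present, z_col].to_numpy())
        ok = (
            (p_adj.to_numpy() < alpha)
            & (sign_rep.to_numpy() == disc_sign)
            & (disc_sign != 0)
        )
        out[f"p_fdr_{name}"] = p_adj
        out[f"replicated_{name}"] = ok
    out["doubly_replicated"] = (
        out[f"replicated_{rep_names[0]}"] & out[f"replicated_{rep_names[1]}"]
    )

    n = len(out)
    rates = {
        f"rate_{rep_names[0]}": out[f"replicated_{rep_names[0]}"].mean() if n else np.nan,
        f"rate_{rep_names[1]}": out[f"replicated_{rep_names[1]}"].mean() if n else np.nan,
        "rate_doubly": out["doubly_replicated"].mean() if n else np.nan,
        "n_discovery": float(n),
        "n_doubly": float(out["doubly_replicated"].sum()),
    }
    return out, rates
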