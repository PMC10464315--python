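"""Double generalized linear model (DGLM) for mean and variance association.

For one CpG with response y (RIN-transformed methylation) and covariate
designs X (mean) and Z (dispersion) the model is

    y_i = x_i' beta + eps_i,     eps_i ~ N(0, phi_i),   phi_i = exp(z_i' gamma)

fitted by alternating (a) weighted least squares for beta with weights
1/phi_i and (b) a Levenberg-damped Fisher-scoring step for gamma on the
restricted (REML) likelihood, whose score Z'(d - (1-h) phi)/phi / 2 uses
the squared residuals d_i = e_i^2 and the weighted-hat leverages h_i, and
whose information [Z' diag(1-2h) Z + Z'(H.H) Z]/2 accounts exactly for the
degrees of freedom consumed by the mean fit (H.H is the elementwise square
of the hat matrix).  This exact leverage adjustment is what keeps the
dispersion Wald test calibrated; cruder schemes that feed e^2/(1-h) to a
gamma GLM with (1-h)/2 prior weights are noticeably conservative.  The age
coefficient of the mean model detects age-related differential methylation
(aDMC); the age coefficient of the dispersion submodel detects age-related
variability (aVMC).

Wald z statistics use a standard-normal reference so they can feed the
downstream empirical-null correction directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["DglmFit", "fit_dglm", "build_design", "scan"]

_ETA_CLIP = 30.0  # cap |z'gamma| so phi stays in a floating-point-safe range


@dataclass
class DglmFit:
    """Converged (or last-iterate) DGLM state for a single response."""

    mean_coefs: np.ndarray
    mean_se: np.ndarray
    disp_coefs: np.ndarray
    disp_se: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    mean_cols: list[str] = field(default_factory=list)
    disp_cols: list[str] = field(default_factory=list)

    def wald(self, term: str) -> tuple[float, float, float, float, float, float]:
        """(beta, se, z, p) for the mean model and (gamma, se, z, p) style
        lookups; returns mean-model and dispersion-model stats for `term`."""
        i = self.mean_cols.index(term)
        j = self.disp_cols.index(term)
        zb = self.mean_coefs[i] / self.mean_se[i]
        zg = self.disp_coefs[j] / self.disp_se[j]
        return (
            self.mean_coefs[i],
            self.mean_se[i],
            zb,
            self.disp_coefs[j],
            self.disp_se[j],
            zg,
        )


def _independent_columns(M: np.ndarray) -> list[int]:
    """Indices of a maximal linearly independent column subset, chosen
    greedily in column order (deterministic alias dropping)."""
    if np.linalg.matrix_rank(M) == M.shape[1]:
        return list(range(M.shape[1]))
    keep: list[int] = []
    rank = 0
    for j in range(M.shape[1]):
        cols = keep + [j]
        r = np.linalg.matrix_rank(M[:, cols])
        if r > rank:
            keep.append(j)
            rank = r
    return keep


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (coef, leverage, R) with R the
    triangular factor of the weighted design."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    Q, R = np.linalg.qr(Xw)
    coef = np.linalg.solve(R, Q.T @ (y * sw))
    h = np.einsum("ij,ij->i", Q, Q)
    return coef, h, R


def fit_dglm(
    y: np.ndarray,
    mean_design: np.ndarray,
    disp_design: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    mean_cols: list[str] | None = None,
    disp_cols: list[str] | None = None,
    assume_full_rank: bool = False,
) -> DglmFit:
    """Fit the double GLM by alternating WLS and a gamma dispersion GLM.

    Convergence is declared when the relative change of the restricted
    (REML-style) log-likelihood falls below ``tol``.  Aliased design columns
    are dropped deterministically in column order; dropped columns get NaN
    coefficients so the caller's column bookkeeping stays aligned.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(mean_design, dtype=float))
    Z = np.atleast_2d(np.asarray(disp_design, dtype=float))
    n = y.shape[0]
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("designs and response have mismatched lengths")
    if np.isnan(y).any():
        raise ValueError("fit_dglm requires a complete response (pre-filter NaNs)")

    mean_cols = mean_cols or [f"x{j}" for j in range(X.shape[1])]
    disp_cols = disp_cols or [f"z{j}" for j in range(Z.shape[1])]

    if assume_full_rank:
        kx = list(range(X.shape[1]))
        kz = list(range(Z.shape[1]))
    else:
        kx = _independent_columns(X)
        kz = _independent_columns(Z)
    if len(kx) < X.shape[1] or len(kz) < Z.shape[1]:
        logger.warning(
            "fit_dglm: dropped %d aliased mean and %d aliased dispersion columns",
            X.shape[1] - len(kx),
            Z.shape[1] - len(kz),
        )
    Xk, Zk = X[:, kx], Z[:, kz]

    p, q = Xk.shape[1], Zk.shape[1]
    if n <= p:
        raise ValueError("more mean-model parameters than observations")

    def _mean_fit(gamma_):
        """Weighted mean fit at dispersion surface exp(Z gamma); returns
        (log_phi, beta, e, d, Q, R, reml)."""
        log_phi_ = np.clip(Zk @ gamma_, -_ETA_CLIP, _ETA_CLIP)
        w = np.exp(-log_phi_)
        sw = np.sqrt(w)
        Q, R = np.linalg.qr(Xk * sw[:, None])
        beta = np.linalg.solve(R, Q.T @ (y * sw))
        e = y - Xk @ beta
        d = e * e
        reml = -0.5 * (
            np.sum(log_phi_)
            + np.sum(d * w)
            + 2.0 * np.sum(np.log(np.abs(np.diag(R))))
        )
        return log_phi_, beta, e, d, Q, R, reml

    # init: leverage-corrected log residual variance regressed on Z
    # (E[log chi2_1] ~ -1.27)
    _, _, _, d0, Q0, _, _ = _mean_fit(np.zeros(q))
    h0 = np.minimum(np.einsum("ij,ij->i", Q0, Q0), 1.0 - 1e-10)
    z0 = np.log(np.maximum(d0 / (1.0 - h0), 1e-300)) + 1.27
    sw0 = np.sqrt(1.0 - h0)
    Qz, Rz = np.linalg.qr(Zk * sw0[:, None])
    gamma = np.linalg.solve(Rz, Qz.T @ (z0 * sw0))

    log_phi, beta, e, d, Q, R, reml = _mean_fit(gamma)
    converged = False
    lam = None
    it = 0
    iu, ju = np.triu_indices(p)
    ZVZ = np.eye(q)
    for it in range(1, max_iter + 1):
        # REML score and information for gamma (Fisher scoring on the
        # restricted likelihood): score = Z'(d - (1-h) phi)/phi / 2,
        # information = [Z' diag(1-2h) Z + Z'(H*H)Z] / 2 with H the
        # weighted hat matrix, H*H its elementwise square obtained from
        # pairwise products of Q columns
        h = np.minimum(np.einsum("ij,ij->i", Q, Q), 1.0 - 1e-10)
        Q2 = Q[:, iu] * Q[:, ju]
        Q2[:, iu != ju] *= np.sqrt(2.0)
        Q2Z = Q2.T @ Zk
        ZVZ = (Zk.T @ (Zk * (1.0 - 2.0 * h)[:, None]) + Q2Z.T @ Q2Z) / 2.0
        phi = np.exp(log_phi)
        score = Zk.T @ ((d - (1.0 - h) * phi) / phi) / 2.0
        maxinfo = np.max(np.abs(np.diag(ZVZ)))
        if lam is None:
            lam = abs(np.mean(np.diag(ZVZ))) / q

        # Levenberg-damped scoring step: increase damping until the
        # restricted likelihood does not decrease
        gamma_old, reml_old = gamma, reml
        dgam = np.zeros(q)
        step_ok = False
        while True:
            try:
                dgam = np.linalg.solve(ZVZ + lam * np.eye(q), score)
            except np.linalg.LinAlgError:
                lam = max(lam, 1.0) * 10.0
                continue
            cand = gamma_old + dgam
            log_phi, beta, e, d, Q, R, reml = _mean_fit(cand)
            if reml > reml_old - 1e-15:
                gamma = cand
                step_ok = True
                break
            if lam / maxinfo > 1e15:
                gamma = gamma_old
                log_phi, beta, e, d, Q, R, reml = _mean_fit(gamma)
                break
            lam *= 2.0
        if not step_ok:
            logger.warning("fit_dglm: damping limit reached; stopping early")
            break
        lam = max(lam / 10.0, 1e-12)
        # converged when the scoring step promises no further gain or the
        # restricted likelihood has plateaued
        if (
            float(score @ dgam) < tol * (abs(reml_old) + 1.0)
            or abs(reml - reml_old) <= tol * (abs(reml_old) + 1.0)
        ):
            converged = True
            break

    Rinv = np.linalg.inv(R)
    cov_b = Rinv @ Rinv.T
    se_b = np.sqrt(np.diag(cov_b))

    # dispersion covariance: inverse REML information
    try:
        cov_g = np.linalg.inv(ZVZ)
        se_g = np.sqrt(np.maximum(np.diag(cov_g), 0.0))
    except np.linalg.LinAlgError:
        se_g = np.full(q, np.nan)

    full_beta = np.full(X.shape[1], np.nan)
    full_se_b = np.full(X.shape[1], np.nan)
    full_beta[kx], full_se_b[kx] = beta, se_b
    full_gamma = np.full(Z.shape[1], np.nan)
    full_se_g = np.full(Z.shape[1], np.nan)
    full_gamma[kz], full_se_g[kz] = gamma, se_g

    if not converged:
        logger.warning("fit_dglm: not converged after %d iterations", max_iter)
    return DglmFit(
        mean_coefs=full_beta,
        mean_se=full_se_b,
        disp_coefs=full_gamma,
        disp_se=full_se_g,
        residuals=e,
        converged=converged,
        n_iter=it,
        mean_cols=list(mean_cols),
        disp_cols=list(disp_cols),
    )


def build_design(
    samples: pd.DataFrame,
    covariates: list[str],
    factors: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix from a sample table.

    Numeric covariates enter as-is; categoricals are one-hot encoded with the
    first level dropped.  Latent factors, if given, are appended.  An
    intercept is always first.
    """
    missing = [c for c in covariates if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks covariates: {missing}")
    cols: list[str] = ["intercept"]
    parts: list[np.ndarray] = [np.ones((len(samples), 1))]
    for c in covariates:
        s = samples[c]
        if s.dtype.kind in "ifu":
            parts.append(s.to_numpy(dtype=float)[:, None])
            cols.append(c)
        else:
            d = pd.get_dummies(s.astype("category"), drop_first=True)
            for lv in d.columns:
                cols.append(f"{c}[{lv}]")
            if d.shape[1]:
                parts.append(d.to_numpy(dtype=float))
    if factors is not None:
        f = factors.loc[samples.index]
        parts.append(f.to_numpy(dtype=float))
        cols.extend(map(str, f.columns))
    return np.hstack(parts), cols


#: covariate sets matching the whole-blood and purified-monocyte designs
BLOOD_COVARIATES = [
    "age",
    "cohort",
    "cd8t",
    "cd4t",
    "nk",
    "bcell",
    "mono",
    "sentrix_position",
    "sample_plate",
]
MONOCYTE_COVARIATES = ["age", "cohort", "purity", "sentrix_position", "sample_plate"]


def scan(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    sex: str | None = None,
    covariates: list[str] | None = None,
    term: str = "age",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Run the DGLM over every CpG for one sex stratum.

    Parameters
    ----------
    matrix : CpGs x samples response matrix (RIN scale).
    samples : sample table indexed by sample id; must contain ``sex`` if a
        sex subset is requested, and every requested covariate.
    factors : optional samples x k latent-factor frame (subset is taken).
    sex : "F" or "M" to restrict to one sex, None to use all samples.
    covariates : model covariates; defaults to the whole-blood set, with
        single-level categoricals and all-constant columns dropped
        automatically (e.g. a single-cohort replication set).

    Returns a tidy frame: cpg_id, n, beta1, se_beta1, z_mean, p_mean,
    gamma1, se_gamma1, z_disp, p_disp, converged, n_iter.
    """
    if sex is not None:
        keep = samples.index[samples["sex"] == sex]
        if len(keep) == 0:
            raise ValueError(f"no samples with sex == {sex!r}")
        samples = samples.loc[keep]
    if covariates is None:
        covariates = [c for c in BLOOD_COVARIATES if c in samples.columns]
    # drop degenerate covariates (single level / constant) up front
    usable = []
    for c in covariates:
        if samples[c].nunique(dropna=False) > 1:
            usable.append(c)
    if term not in usable:
        raise ValueError(f"term {term!r} absent or constant in the sample table")
    ok = samples[usable].notna().all(axis=1)
    if not ok.all():
        logger.warning("scan: excluding %d samples with missing covariates", (~ok).sum())
        samples = samples.loc[ok]

    X, cols = build_design(samples, usable, factors)
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        logger.warning("scan: dropping %d aliased design columns", X.shape[1] - len(keep))
        X = X[:, keep]
        cols = [cols[j] for j in keep]
    sub = matrix.loc[:, samples.index].to_numpy(dtype=float)
    ti = cols.index(term)

    rows = []
    for i, cpg in enumerate(matrix.index):
        y = sub[i]
        m = ~np.isnan(y)
        fit = fit_dglm(
            y[m], X[m], X[m], tol=tol, max_iter=max_iter,
            mean_cols=cols, disp_cols=cols, assume_full_rank=bool(m.all()),
        )
        b, se_b = fit.mean_coefs[ti], fit.mean_se[ti]
        g, se_g = fit.disp_coefs[ti], fit.disp_se[ti]
        zb = b / se_b if se_b > 0 else np.nan
        zg = g / se_g if se_g > 0 else np.nan
        rows.append(
            (
                cpg,
                int(m.sum()),
                b,
                se_b,
                zb,
                2 * stats.norm.sf(abs(zb)),
                g,
                se_g,
                zg,
                2 * stats.norm.sf(abs(zg)),
                fit.converged,
                fit.n_iter,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "cpg_id",
            "n",
            "beta1",
            "se_beta1",
            "z_mean",
            "p_mean",
            "gamma1",
            "se_gamma1",
            "z_disp",
            "p_disp",
            "converged",
            "n_iter",
        ],
    ).set_index("cpg_id")
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        logger.warning("scan: %d CpGs did not converge; excluded from hit calling", n_bad)
    return out
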