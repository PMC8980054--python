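"""Per-CpG association of methylation with a binary predictor.

Two estimators are provided, matching the two cohort designs:

``ols``
    Ordinary least squares with classical standard errors and a t
    reference — appropriate for unrelated samples.

``cluster-exchangeable``
    Gaussian estimating equations with an exchangeable working correlation
    within family clusters and robust (sandwich) standard errors with a
    normal reference — appropriate for twin-family cohorts. The fit
    iterates the moment estimator of the working correlation to
    convergence (max parameter change < 1e-8, capped at 100 iterations);
    if it fails to converge the CpG falls back to an independence working
    correlation with sandwich errors and is flagged.

The outcome is the methylation beta-value; the predictor (handedness,
coded 1 = left, 0 = right) plus covariates form the design. Effects are
therefore methylation differences on the beta-value scale, positive when
carriers of predictor = 1 are more methylated.

Both estimators are vectorised across CpGs sharing a missingness pattern,
which keeps epigenome-scale null calibrations tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from twinewas.datatypes import (
    SUMMARY_COLUMNS,
    DataError,
    MethylationDataset,
    ModelSpec,
)

logger = logging.getLogger(__name__)

MIN_COMPLETE_CASES = 10
GEE_MAX_ITER = 100
GEE_TOL = 1e-8


def build_design(samples: pd.DataFrame, covariates, predictor: str | None = "handedness"):
    """Expand covariates into a numeric design matrix (no intercept column).

    Categorical/string covariates become indicator columns with the first
    level as reference. Returns (design DataFrame, column names).
    """
    cols = {}
    if predictor is not None:
        cols[predictor] = pd.to_numeric(samples[predictor], errors="coerce")
    for name in covariates:
        if name not in samples.columns:
            raise DataError(f"covariate {name!r} not in sample sheet")
        col = samples[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = pd.unique(col.dropna())
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col == lev).astype(float).where(col.notna())
        else:
            cols[name] = pd.to_numeric(col, errors="coerce")
    X = pd.DataFrame(cols, index=samples.index)
    return X


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns by greedy QR-style elimination.
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise DataError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _ols_batch(X: np.ndarray, Y: np.ndarray):
    """Classical OLS of every column of Y on X (with intercept already in X).

    Returns (coef matrix p×M, se of each coef p×M, df).
    """
    n, p = X.shape
    XtX = X.T @ X
    XtXinv = np.linalg.inv(XtX)
    B = XtXinv @ (X.T @ Y)
    resid = Y - X @ B
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtXinv), sigma2))
    return B, se, df


def _gee_exchangeable_batch(X: np.ndarray, Y: np.ndarray, cluster_codes: np.ndarray,
                            chunk: int = 4000, df_correction: bool = True):
    """Gaussian GEE with exchangeable working correlation, batched over the
    columns of Y (CpGs) that share the same complete-case rows.

    Uses the closed-form inverse of an exchangeable cluster covariance;
    the scale/(1-rho) prefactors cancel between bread and meat, so only the
    shape of the working covariance enters. Returns (coefficients p×M,
    sandwich SEs p×M, working rho per CpG, converged flags).
    """
    n, p = X.shape
    M = Y.shape[1]
    order = np.argsort(cluster_codes, kind="stable")
    Xs, Ys, cs = X[order], Y[order], cluster_codes[order]
    starts = np.flatnonzero(np.r_[True, cs[1:] != cs[:-1]])
    sizes = np.diff(np.r_[starts, len(cs)])
    n_clusters = len(starts)
    Sx = np.add.reduceat(Xs, starts, axis=0)  # cluster sums of rows of X
    XtX = Xs.T @ Xs
    T = np.einsum("cp,cq->cpq", Sx, Sx)  # per-cluster outer products
    n_pairs = float((sizes * (sizes - 1) // 2).sum())

    coef = np.empty((p, M))
    se = np.empty((p, M))
    rho_out = np.empty(M)
    conv_out = np.zeros(M, dtype=bool)

    XtXinv = np.linalg.inv(XtX)
    for c0 in range(0, M, chunk):
        Yc = Ys[:, c0:c0 + chunk]
        mc = Yc.shape[1]
        B = XtXinv @ (Xs.T @ Yc)  # OLS start
        rho = np.zeros(mc)
        converged = np.zeros(mc, dtype=bool)
        active = np.ones(mc, dtype=bool)
        for _ in range(GEE_MAX_ITER):
            E = Yc - Xs @ B
            phi = (E**2).sum(axis=0) / (n - p)
            Se = np.add.reduceat(E, starts, axis=0)
            cross = 0.5 * ((Se**2).sum(axis=0) - np.add.reduceat(E**2, starts, axis=0).sum(axis=0))
            denom = max(n_pairs - p, 1.0)
            new_rho = np.clip(cross / (denom * phi), -0.99, 0.99)
            if n_pairs == 0:
                new_rho = np.zeros(mc)
            delta = np.abs(new_rho - rho)
            rho = new_rho
            # GLS update with exchangeable V^{-1} (prefactor dropped):
            # H = X'X - sum_c g_c Sx_c Sx_c',  g_c = rho/(1+(m_c-1)rho)
            g = rho[None, :] / (1.0 + (sizes[:, None] - 1.0) * rho[None, :])  # c × mc
            H = XtX[None] - np.einsum("cm,cpq->mpq", g, T)
            # X'V^{-1} y = X'y - sum_c g_c Sx_c (1'y_c)
            Sy = np.add.reduceat(Yc, starts, axis=0)
            XtVy = (Xs.T @ Yc) - np.einsum("cp,cm->pm", Sx, g * Sy)
            B = np.linalg.solve(H, XtVy.T[:, :, None])[:, :, 0].T
            newly = active & (delta < GEE_TOL)
            converged |= newly
            active &= ~newly
            if not active.any():
                break
        # Non-converged CpGs: independence working correlation fallback.
        if active.any():
            rho[active] = 0.0
            B[:, active] = XtXinv @ (Xs.T @ Yc[:, active])
        # Sandwich covariance with the final working correlation.
        E = Yc - Xs @ B
        Se = np.add.reduceat(E, starts, axis=0)
        g = rho[None, :] / (1.0 + (sizes[:, None] - 1.0) * rho[None, :])
        H = XtX[None] - np.einsum("cm,cpq->mpq", g, T)
        Hinv = np.linalg.inv(H)
        # U_cm = X_c' e_c - g_cm Sx_c (1'e_c), meat = sum_c U U'
        XtE_c = np.empty((n_clusters, p, mc))
        for k in range(p):
            XtE_c[:, k, :] = np.add.reduceat(Xs[:, k:k + 1] * E, starts, axis=0)
        U = XtE_c - Sx[:, :, None] * (g[:, None, :] * Se[:, None, :])
        meat = np.einsum("cpm,cqm->mpq", U, U, optimize=True)
        cov = Hinv @ meat @ Hinv
        if df_correction and n_clusters > p:
            # cluster df correction: the raw (CR0) sandwich underestimates
            # the variance by roughly a factor (G - p)/G at G clusters and
            # p parameters, inflating null z-scores at epigenome scale
            cov *= n_clusters / (n_clusters - p)
        coef[:, c0:c0 + chunk] = B
        se[:, c0:c0 + chunk] = np.sqrt(np.maximum(
            np.diagonal(cov, axis1=1, axis2=2).T, 0.0))
        rho_out[c0:c0 + chunk] = rho
        conv_out[c0:c0 + chunk] = converged
    return coef, se, rho_out, conv_out


def run_ewas(dataset: MethylationDataset, spec: ModelSpec, cohort: str = "cohort",
             gee_df_correction: bool = True) -> pd.DataFrame:
    """Per-CpG regression of methylation on the predictor plus covariates.

    Returns an EWAS summary table (one row per CpG) with columns
    ``cpg, chr, pos, beta, se, z, p, n, cohort, model``. For the OLS
    estimator p-values use the t distribution with residual degrees of
    freedom; for the cluster-exchangeable estimator the normal reference is
    used with sandwich standard errors carrying a G/(G - p) cluster
    degrees-of-freedom correction (``gee_df_correction=False`` gives the
    raw Liang-Zeger sandwich).
    """
    samples = dataset.samples
    design = build_design(samples, spec.covariates, predictor=spec.predictor)
    complete = design.notna().all(axis=1)
    design = design[complete]
    beta = dataset.beta.loc[:, complete.index[complete]]
    h = design[spec.predictor].to_numpy()
    if np.nanstd(h) == 0:
        raise DataError("predictor is constant after complete-case filtering")
    if (h == 1).sum() < 2 or (h == 0).sum() < 2:
        raise DataError("need at least 2 cases and 2 controls")

    Xfull = np.column_stack([np.ones(design.shape[0]), design.to_numpy(dtype=float)])
    names = ["(intercept)"] + list(design.columns)
    _check_rank(Xfull, names)
    Y = beta.to_numpy(dtype=float).T  # samples × CpGs
    cpg_ids = beta.index.to_numpy()
    M = Y.shape[1]

    est_beta = np.full(M, np.nan)
    est_se = np.full(M, np.nan)
    est_n = np.zeros(M, dtype=int)
    df_col = np.full(M, np.nan)

    fam_codes, _ = pd.factorize(samples.loc[design.index, "family_id"])

    # Group CpGs by missingness pattern so each group is one batched fit.
    # The minimum-complete-cases floor guards against missingness-riddled
    # CpGs; tiny cohorts (toy examples) are capped by their own size.
    min_cases = min(MIN_COMPLETE_CASES, Xfull.shape[0])
    isnan = np.isnan(Y)
    est_n[:] = (~isnan).sum(axis=0)
    if not isnan.any():  # fast path: one shared pattern
        pat_ids = np.zeros((Y.shape[0], 1), dtype=bool)
        pat_inv = np.zeros(M, dtype=int)
    else:
        pat_ids, pat_inv = np.unique(isnan, axis=1, return_inverse=True)
    for pat in range(pat_ids.shape[1]):
        cols = np.flatnonzero(pat_inv == pat)
        rows = ~pat_ids[:, pat]
        n_complete = int(rows.sum())
        if n_complete < min_cases or n_complete <= Xfull.shape[1]:
            logger.warning(
                "%d CpGs have <%d complete cases; statistics set missing",
                len(cols), min_cases,
            )
            continue
        hr = Xfull[rows, 1]
        if hr.std() == 0 or (hr == 1).sum() < 2 or (hr == 0).sum() < 2:
            logger.warning("%d CpGs lack case/control contrast after missingness", len(cols))
            continue
        Xr, Yr = Xfull[rows], Y[np.ix_(rows, cols)]
        if spec.estimator == "ols":
            B, SE, df = _ols_batch(Xr, Yr)
            df_col[cols] = df
        else:
            B, SE, rho, conv = _gee_exchangeable_batch(
                Xr, Yr, fam_codes[rows], df_correction=gee_df_correction)
            if not conv.all():
                logger.warning(
                    "%d CpGs fell back to independence working correlation",
                    int((~conv).sum()),
                )
        est_beta[cols] = B[1]
        est_se[cols] = SE[1]

    z = est_beta / est_se
    if spec.estimator == "ols":
        with np.errstate(invalid="ignore"):
            p = 2 * t_dist.sf(np.abs(z), df_col)
    else:
        p = 2 * norm.sf(np.abs(z))

    manifest = dataset.manifest.loc[cpg_ids]
    out = pd.DataFrame(
        {
            "cpg": cpg_ids,
            "chr": manifest["chr"].to_numpy(),
            "pos": manifest["pos"].to_numpy(),
            "beta": est_beta,
            "se": est_se,
            "z": z,
            "p": p,
            "n": est_n,
            "cohort": cohort,
            "model": spec.tag,
        }
    )[SUMMARY_COLUMNS]
    out.attrs["estimator"] = spec.estimator
    out.attrs["reference"] = "t" if spec.estimator == "ols" else "normal"
    return out


def residualize(dataset: MethylationDataset, covariates) -> pd.DataFrame:
    """Per-CpG OLS residuals of methylation on the covariate design.

    The empty covariate list centres each CpG (intercept-only model).
    Residuals are orthogonal to the design; samples with missing covariates
    are dropped, CpG-level missing values propagate as NaN residuals.
    Returns a CpGs × samples data frame (complete-covariate samples only).
    """
    design = build_design(dataset.samples, covariates, predictor=None)
    complete = design.notna().all(axis=1) if design.shape[1] else pd.Series(
        True, index=dataset.samples.index)
    X = np.column_stack(
        [np.ones(int(complete.sum()))] + (
            [design[complete].to_numpy(dtype=float)] if design.shape[1] else [])
    )
    _check_rank(X, ["(intercept)"] + list(design.columns))
    cols = complete.index[complete]
    Y = dataset.beta.loc[:, cols].to_numpy(dtype=float).T
    # Complete-case fit per missingness pattern.
    isnan = np.isnan(Y)
    E = np.full_like(Y, np.nan)
    if not isnan.any():
        pat_ids = np.zeros((Y.shape[0], 1), dtype=bool)
        pat_inv = np.zeros(Y.shape[1], dtype=int)
    else:
        pat_ids, pat_inv = np.unique(isnan, axis=1, return_inverse=True)
    for pat in range(pat_ids.shape[1]):
        cidx = np.flatnonzero(pat_inv == pat)
        rows = ~pat_ids[:, pat]
        if rows.sum() <= X.shape[1]:
            continue
        Xr = X[rows]
        Yr = Y[np.ix_(rows, cidx)]
        B = np.linalg.lstsq(Xr, Yr, rcond=None)[0]
        E[np.ix_(rows, cidx)] = Yr - Xr @ B
    return pd.DataFrame(E.T, index=dataset.beta.index, columns=cols)
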