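"""Methylation and polygenic scores with liability-scale variance explained.

A score for sample *i* is the weighted sum over features (CpG beta-values
or SNP dosages)

    score_i = w_1 x_1i + w_2 x_2i + ... + w_n x_ni,

with weights taken from an independent discovery analysis (cross-cohort
rule: weights estimated in one cohort are only ever applied to another),
then standardized to mean 0 / SD 1. Variance explained in the binary
outcome is measured as the increment in linear-probability R² over a
covariate baseline and converted to the liability scale with the
ascertainment-corrected transformation of Lee et al. type, which maps an
observed-scale R² for a 0/1 outcome with population prevalence K and
sample case proportion P onto the latent liability scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from twinewas.datatypes import DataError

logger = logging.getLogger(__name__)


@dataclass
class WeightTable:
    """Per-feature weights from a discovery analysis."""

    weights: pd.Series  # index = feature id, values = weight
    source: str = ""
    threshold: float = np.nan

    def __post_init__(self) -> None:
        if not self.weights.index.is_unique:
            raise DataError("duplicate feature ids in weight table")
        if self.weights.size and not np.isfinite(self.weights.to_numpy()).all():
            raise DataError("non-finite weights")

    @property
    def n_features(self) -> int:
        return self.weights.size


@dataclass
class ScoreVector:
    """A standardized per-sample score."""

    values: pd.Series  # index = sample id
    n_features: int
    coverage: float  # fraction of weight-table features found in the data
    label: str = "score"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if abs(v.mean()) > 1e-10 or abs(v.std(ddof=1) - 1) > 1e-10:
            raise DataError("score is not standardized (mean 0, sd 1)")


@dataclass
class LiabilityR2Result:
    label: str
    r2_observed: float
    r2_liability: float
    incremental_r2_observed: float
    incremental_r2_liability: float
    K: float
    P: float
    p_value: float
    alpha: float
    n: int
    n_features: int = 0


def build_weight_table(discovery: pd.DataFrame, p_threshold: float,
                       source: str = "") -> WeightTable:
    """Select discovery CpGs at p < threshold; weight = discovery effect."""
    ok = np.isfinite(discovery["p"]) & np.isfinite(discovery["beta"])
    sel = discovery[ok & (discovery["p"] < p_threshold)]
    if sel.empty:
        logger.warning("no features pass p < %g; empty weight table", p_threshold)
    return WeightTable(
        weights=pd.Series(sel["beta"].to_numpy(), index=sel["cpg"].to_numpy(), dtype=float),
        source=source, threshold=p_threshold,
    )


def compute_score(features: pd.DataFrame, weights: WeightTable,
                  label: str = "score") -> ScoreVector:
    """Weighted feature sum per sample, standardized.

    ``features`` is samples × features. Missing feature values are
    mean-imputed per feature; features absent from the matrix are dropped
    and reported through the coverage fraction.
    """
    overlap = weights.weights.index.intersection(features.columns)
    if len(overlap) == 0:
        raise DataError("no overlap between weight table and feature matrix")
    F = features[list(overlap)].astype(float)
    F = F.fillna(F.mean())
    raw = F.to_numpy() @ weights.weights.loc[overlap].to_numpy()
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("raw score has zero variance; cannot standardize")
    return ScoreVector(
        values=pd.Series((raw - raw.mean()) / sd, index=features.index),
        n_features=len(overlap),
        coverage=len(overlap) / weights.n_features,
        label=label,
    )


def _lpm_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of a linear-probability (OLS) fit with intercept prepended."""
    Xd = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    b, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ b
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / tss


def _coef_p(y: np.ndarray, X: np.ndarray, col: int) -> float:
    """Two-sided t-test p of coefficient ``col`` (0-based, after intercept)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    XtXinv = np.linalg.inv(Xd.T @ Xd)
    b = XtXinv @ Xd.T @ y
    resid = y - Xd @ b
    df = len(y) - Xd.shape[1]
    s2 = (resid**2).sum() / df
    se = np.sqrt(s2 * XtXinv[col + 1, col + 1])
    return float(2 * t_dist.sf(abs(b[col + 1] / se), df))


def liability_transform(r2_obs: float, K: float, P: float) -> float:
    """Observed-scale R² of a 0/1 outcome → liability-scale R².

    With t = Phi^-1(1-K), z = phi(t), m = z/K:
        C = [K(1-K)]² / [z² P(1-P)],
        theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t),
        R²_liab = C R²_obs / (1 + C theta R²_obs).
    C rescales from the observed 0/1 scale to the liability scale; theta
    corrects for case-control ascertainment and vanishes when P = K.
    Small negative inputs (incremental R² can be negative) pass through
    the same formula.
    """
    if not (0 < K < 1) or not (0 < P < 1):
        raise DataError("K and P must lie in (0, 1)")
    if not -1 < r2_obs < 1:
        raise DataError("r2_obs must lie in (-1, 1)")
    t = norm.ppf(1 - K)
    z = norm.pdf(t)
    m = z / K
    C = (K * (1 - K)) ** 2 / (z**2 * P * (1 - P))
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
    return float(C * r2_obs / (1 + C * theta * r2_obs))


def evaluate_scores(outcome, scores: list, covariates: pd.DataFrame | None,
                    K: float, pgs_label: str | None = None) -> list:
    """Marginal and incremental liability-scale variance explained.

    For each score: observed-scale R² is the linear-probability increment
    of covariates+score over covariates alone; if ``pgs_label`` names one
    of the scores, every other score additionally gets its increment over
    covariates+PGS (variance explained *above* the polygenic score). Both
    are mapped to the liability scale. The recorded Bonferroni alpha is
    0.05 / (number of scores tested).
    """
    y = np.asarray(outcome, dtype=float)
    if np.nanstd(y) == 0:
        raise DataError("constant outcome")
    if set(np.unique(y[np.isfinite(y)])) - {0.0, 1.0}:
        raise DataError("outcome must be coded 0/1")
    if not scores:
        raise DataError("no scores supplied")
    C = covariates.to_numpy(dtype=float) if covariates is not None and covariates.shape[1] else np.empty((len(y), 0))
    P = float(np.nanmean(y))
    base_r2 = _lpm_r2(y, C)
    pgs_vals = None
    if pgs_label is not None:
        pgs_vals = next(s for s in scores if s.label == pgs_label).values.to_numpy()
        base_pgs_r2 = _lpm_r2(y, np.column_stack([C, pgs_vals]) if C.size else pgs_vals[:, None])
    alpha = 0.05 / len(scores)
    out = []
    for s in scores:
        sv = s.values.to_numpy(dtype=float)
        X1 = np.column_stack([C, sv]) if C.size else sv[:, None]
        r2_obs = _lpm_r2(y, X1) - base_r2
        inc_obs = np.nan
        if pgs_label is not None and s.label != pgs_label:
            X2 = np.column_stack([C, pgs_vals, sv])
            inc_obs = _lpm_r2(y, X2) - base_pgs_r2
        out.append(LiabilityR2Result(
            label=s.label,
            r2_observed=float(r2_obs),
            r2_liability=liability_transform(r2_obs, K, P),
            incremental_r2_observed=float(inc_obs),
            incremental_r2_liability=(
                liability_transform(inc_obs, K, P) if np.isfinite(inc_obs) else np.nan),
            K=K, P=P,
            p_value=_coef_p(y, X1, X1.shape[1] - 1),
            alpha=alpha,
            n=len(y),
            n_features=s.n_features,
        ))
    return out


def results_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score": r.label, "n_features": r.n_features,
                "R2_obs": r.r2_observed, "R2_liab": r.r2_liability,
                "incremental_R2_obs": r.incremental_r2_observed,
                "incremental_R2_liab": r.incremental_r2_liability,
                "K": r.K, "P": r.P, "p": r.p_value, "alpha": r.alpha, "n": r.n,
            }
            for r in results
        ]
    )
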