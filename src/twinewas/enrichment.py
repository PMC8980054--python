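"""GWAS-locus proximity enrichment of EWAS signal.

Tests whether CpGs lying near trait-associated SNPs carry, on average,
stronger association signal than the rest of the array, via the regression

    |Zscore| = intercept + beta_category * Category,

where Category indicates whether the CpG sits within a window of any SNP
in a locus set. With a binary regressor the OLS slope is exactly the
difference of mean |Z| between the in-window and out-of-window groups.
Standard errors come from a simple nonparametric bootstrap over CpG rows
(default 2000 resamples); significance is a two-sided normal test of
slope / bootstrap-SE. A control-locus mode (loci of an unrelated trait)
and an exclusion mode (e.g. removing mQTL-driven CpGs) are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from twinewas.datatypes import DataError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    locus_set: str
    window: int
    beta_category: float
    se: float
    p: float
    n_boot: int
    n_in: int
    n_out: int
    n_excluded: int
    ci_lower: float
    ci_upper: float


def annotate_proximity(manifest: pd.DataFrame, loci: pd.DataFrame, window: int) -> np.ndarray:
    """Indicator: 1 iff a CpG lies within ``window`` bp of any same-
    chromosome SNP (boundary inclusive).

    ``manifest`` needs columns ``chr``/``pos`` (CpG id index or column);
    ``loci`` needs ``chr``/``pos``.
    """
    if loci.empty:
        raise DataError("empty locus set")
    if window <= 0:
        raise DataError("window must be positive")
    chrom = manifest["chr"].astype(str).to_numpy()
    pos = manifest["pos"].to_numpy(dtype=np.int64)
    out = np.zeros(len(manifest), dtype=int)
    for c, grp in loci.groupby(loci["chr"].astype(str)):
        snp_pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        sel = chrom == c
        if not sel.any():
            continue
        idx = np.searchsorted(snp_pos, pos[sel])
        left = np.where(idx > 0, np.abs(pos[sel] - snp_pos[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
        right = np.where(idx < len(snp_pos), np.abs(snp_pos[np.minimum(idx, len(snp_pos) - 1)] - pos[sel]), np.iinfo(np.int64).max)
        out[sel] = (np.minimum(left, right) <= window).astype(int)
    return out


def enrichment_test(summary: pd.DataFrame, indicator, n_boot: int = 2000,
                    seed: int | None = None, exclude=None,
                    locus_set: str = "trait", window: int = 500_000,
                    chunk: int = 200) -> EnrichmentResult:
    """Mean-|Z| difference between in-window and out-of-window CpGs with
    bootstrap SE.

    ``exclude`` (a CpG id collection) drops CpGs before everything else —
    the mQTL-removal re-run. Bootstrap resamples CpG rows with replacement;
    SE is the SD of resampled slopes and the p-value the two-sided normal
    tail of slope/SE. A percentile 95% CI is also reported.
    """
    ind = np.asarray(indicator, dtype=int)
    if len(ind) != len(summary):
        raise DataError("indicator length does not match summary")
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap SE will be noisy", n_boot)
    keep = np.ones(len(summary), dtype=bool)
    n_excluded = 0
    if exclude is not None:
        excl = set(exclude)
        keep = ~summary["cpg"].isin(excl).to_numpy()
        n_excluded = int((~keep).sum())
    absz = np.abs(summary["z"].to_numpy(dtype=float))[keep]
    ind = ind[keep]
    fin = np.isfinite(absz)
    absz, ind = absz[fin], ind[fin]
    if ind.min() == ind.max():
        raise DataError("proximity indicator is constant after exclusions")
    slope = absz[ind == 1].mean() - absz[ind == 0].mean()
    rng = np.random.default_rng(seed)
    n = len(absz)
    boots = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        zb = absz[idx]
        ib = ind[idx]
        n_in = ib.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_in = (zb * ib).sum(axis=1) / n_in
            mean_out = (zb * (1 - ib)).sum(axis=1) / (n - n_in)
        boots[done:done + b] = mean_in - mean_out
        done += b
    ok = np.isfinite(boots)
    if ok.sum() < n_boot:
        logger.warning("%d degenerate bootstrap resamples dropped", int((~ok).sum()))
    se = float(np.std(boots[ok], ddof=1))
    zstat = slope / se
    return EnrichmentResult(
        locus_set=locus_set, window=window,
        beta_category=float(slope), se=se,
        p=float(2 * stats.norm.sf(abs(zstat))),
        n_boot=int(ok.sum()),
        n_in=int((ind == 1).sum()), n_out=int((ind == 0).sum()),
        n_excluded=n_excluded,
        ci_lower=float(np.percentile(boots[ok], 2.5)),
        ci_upper=float(np.percentile(boots[ok], 97.5)),
    )


def control_analysis(summary: pd.DataFrame, control_loci: pd.DataFrame,
                     manifest: pd.DataFrame, window: int = 500_000,
                     n_boot: int = 2000, seed: int | None = None,
                     exclude=None) -> EnrichmentResult:
    """Enrichment test against loci of an unrelated trait (negative control)."""
    ind = annotate_proximity(manifest, control_loci, window)
    return enrichment_test(summary, ind, n_boot=n_boot, seed=seed,
                           exclude=exclude, locus_set="control", window=window)
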