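"""Fixed-effects meta-analysis, multiplicity adjustment, inflation
diagnostics and cross-analysis top-CpG concordance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from twinewas.datatypes import DataError

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


def meta_fixed_effects(summaries: list) -> pd.DataFrame:
    """Inverse-variance (stderr-weighted) fixed-effects meta-analysis.

    CpGs are kept only if present with finite effect and SE in *every*
    input summary (intersection rule). Weights are w_i = 1/se_i^2; the
    combined effect is sum(w b)/sum(w) with SE = sum(w)^(-1/2) and a
    two-sided normal p-value. Adds BH q-values, a Bonferroni-significance
    flag at 0.05 / m, and a per-cohort effect-direction string.
    """
    if not summaries:
        raise DataError("need at least one summary to meta-analyse")
    for tag, s in enumerate(summaries):
        se = s["se"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.isfinite(se) & (se <= 0))
        if bad.size:
            raise DataError(
                f"non-positive SE in summary {tag} at CpG {s['cpg'].iloc[bad[0]]!r}"
            )
    k = len(summaries)
    frames = []
    for i, s in enumerate(summaries):
        f = s.set_index("cpg")[["beta", "se"]].rename(
            columns={"beta": f"b{i}", "se": f"s{i}"})
        ok = np.isfinite(f[f"b{i}"]) & np.isfinite(f[f"s{i}"])
        frames.append(f[ok])
    merged = pd.concat(frames, axis=1, join="inner")
    if merged.empty:
        raise DataError("no CpGs shared across all summaries")
    B = merged[[f"b{i}" for i in range(k)]].to_numpy()
    S = merged[[f"s{i}" for i in range(k)]].to_numpy()
    W = 1.0 / S**2
    meta_b = (W * B).sum(axis=1) / W.sum(axis=1)
    meta_se = W.sum(axis=1) ** -0.5
    z = meta_b / meta_se
    p = 2 * stats.norm.sf(np.abs(z))
    # extreme |z| underflows to p = 0; floor at the smallest normal double
    p = np.maximum(p, np.finfo(float).tiny)
    q = adjust_multiplicity(p, "bh")
    m = len(p)
    direction = ["".join("+" if b >= 0 else "-" for b in row) for row in B]
    coords = summaries[0].set_index("cpg").loc[merged.index, ["chr", "pos"]]
    out = pd.DataFrame(
        {
            "cpg": merged.index,
            "chr": coords["chr"].to_numpy(),
            "pos": coords["pos"].to_numpy(),
            "beta": meta_b,
            "se": meta_se,
            "z": z,
            "p": p,
            "q": q,
            "bonferroni_significant": p < 0.05 / m,
            "direction": direction,
            "k": k,
            "n": np.nan,
            "cohort": "meta",
            "model": summaries[0]["model"].iloc[0] if "model" in summaries[0] else "meta",
        }
    ).reset_index(drop=True)
    out.attrs["m_cpgs_tested"] = m
    out.attrs["bonferroni_threshold"] = 0.05 / m
    return out


def adjust_multiplicity(pvalues, method: str = "bh") -> np.ndarray:
    """Bonferroni, Benjamini-Hochberg, or fixed-lambda Storey q-values.

    ``storey`` scales BH q-values by pi0_hat = min(1, #{p > 0.5}/(0.5 m)),
    the single-lambda (lambda = 0.5) estimator of the null proportion.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value vector")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, (p > 0.5).sum() / (0.5 * m))
        return np.minimum(1.0, multipletests(p, method="fdr_bh")[1] * pi0)
    raise DataError(f"unknown multiplicity method {method!r}")


@dataclass
class InflationEstimate:
    """Genomic-control lambda plus a median/MAD empirical null."""

    lambda_gc: float
    null_mean: float
    null_sd: float


def estimate_inflation(zscores) -> InflationEstimate:
    """Median-based inflation diagnostics of a z-score vector.

    lambda_GC = median(z^2) / median(chi^2_1); the empirical null is
    summarised by the median and the MAD-based robust SD (1.4826 * MAD).
    A well-calibrated EWAS has lambda close to 1 and null SD close to 1.
    """
    z = np.asarray(zscores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 100:
        raise DataError(f"need >= 100 finite z-scores, got {z.size}")
    med = float(np.median(z))
    mad = float(np.median(np.abs(z - med)))
    if mad == 0:
        raise DataError("degenerate z-score vector (zero MAD)")
    return InflationEstimate(
        lambda_gc=float(np.median(z**2) / CHI2_MEDIAN_1DF),
        null_mean=med,
        null_sd=1.4826 * mad,
    )


@dataclass
class ConcordanceReport:
    analysis_a: str
    analysis_b: str
    k: int
    r: float
    p: float
    overlap: int
    alpha: float
    n_universe: int


def top_k_concordance(a: pd.DataFrame, b: pd.DataFrame, k: int, universe,
                      n_analyses: int = 13,
                      label_a: str = "a", label_b: str = "b") -> ConcordanceReport:
    """Effect-size concordance of the top-k CpGs of analysis ``a``.

    Both summaries are first restricted to the shared ``universe`` of CpGs;
    the top k of ``a`` are taken by ascending p (ties broken by CpG id,
    stable); the report holds the Pearson correlation between a's and b's
    effects on those CpGs, its test p-value, the overlap of the two top-k
    sets, and the Bonferroni alpha = 0.05 / (A^2 - A) for A analyses
    compared pairwise in both directions.
    """
    universe = pd.Index(universe)
    if k > len(universe):
        raise DataError(f"k={k} exceeds universe size {len(universe)}")
    ar = a[a["cpg"].isin(universe)].copy()
    br = b[b["cpg"].isin(universe)].copy()
    ar = ar.sort_values(["p", "cpg"], kind="stable")
    brs = br.sort_values(["p", "cpg"], kind="stable")
    top_a = ar.head(k)
    top_b_set = set(brs.head(k)["cpg"])
    b_eff = br.set_index("cpg")["beta"]
    x = top_a["beta"].to_numpy(dtype=float)
    y = b_eff.reindex(top_a["cpg"]).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    r, p = stats.pearsonr(x[ok], y[ok])
    return ConcordanceReport(
        analysis_a=label_a,
        analysis_b=label_b,
        k=k,
        r=float(r),
        p=float(p),
        overlap=len(set(top_a["cpg"]) & top_b_set),
        alpha=0.05 / (n_analyses**2 - n_analyses),
        n_universe=len(universe),
    )
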