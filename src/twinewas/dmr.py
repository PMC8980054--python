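"""Differentially-methylated-region (DMR) meta-analysis.

The approach follows the candidate-then-GLS scheme used for
covariance-aware region testing of EWAS summary statistics:

1. *Candidates* are found on the meta-analysis summary: per chromosome,
   CpGs nominally associated (p < 0.05) with a common effect sign are
   merged into maximal runs where consecutive qualifying CpGs are at most
   500 bp apart; runs of >= 2 CpGs are candidates, and every contiguous
   sub-window of >= 2 CpGs inside a run is a *tested region* counted
   toward the Bonferroni denominator.
2. The *region statistic* in each cohort combines the member-CpG EWAS
   effects b with covariance V = S R S (S = diag of CpG SEs, R = the
   CpG correlation matrix estimated from residualized methylation in
   that cohort): effect = (1'V^-1 b)/(1'V^-1 1), se = (1'V^-1 1)^(-1/2) —
   the generalized-least-squares combination that accounts for both the
   dependence between sites and the uncertainty of each effect.
3. Per-cohort region statistics are combined by inverse-variance
   fixed-effects meta-analysis, and p-values are Bonferroni-adjusted by
   multiplying by the total number of regions tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from twinewas.datatypes import DataError

logger = logging.getLogger(__name__)

RIDGE_EPS = 0.01
OFFDIAG_CAP = 0.99


@dataclass(frozen=True)
class RegionCandidate:
    """A run of nearby, same-direction, nominally associated CpGs."""

    chrom: str
    start: int  # 1-based inclusive = position of first member CpG
    end: int    # 1-based inclusive = position of last member CpG
    cpgs: tuple

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class DmrRecord:
    """Region-level GLS statistic (one cohort or the cross-cohort meta)."""

    chrom: str
    start: int
    end: int
    cpgs: tuple
    effect: float
    se: float
    z: float
    p: float
    mean_abs_effect: float
    cohort: str
    p_adjust: float = np.nan

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)


def find_candidate_regions(summary: pd.DataFrame, p_enter: float = 0.05,
                           max_gap: int = 500, require_same_sign: bool = True,
                           span_mode: str = "gap") -> list:
    """Maximal candidate runs of qualifying CpGs.

    ``span_mode='gap'`` bounds consecutive inter-CpG distances by
    ``max_gap``; ``span_mode='span'`` instead bounds the total region span.
    """
    if summary["pos"].isna().any() or "pos" not in summary:
        raise DataError("summary lacks genomic positions")
    if span_mode not in ("gap", "span"):
        raise DataError("span_mode must be 'gap' or 'span'")
    out = []
    for chrom, grp in summary.groupby("chr", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        qual = grp[(grp["p"] < p_enter) & np.isfinite(grp["beta"])]
        if qual.empty:
            continue
        pos = qual["pos"].to_numpy(dtype=int)
        sign = np.sign(qual["beta"].to_numpy())
        ids = qual["cpg"].to_numpy()
        run = [0]
        for i in range(1, len(qual)):
            gap_break = (
                pos[i] - pos[i - 1] > max_gap if span_mode == "gap"
                else pos[i] - pos[run[0]] > max_gap
            )
            sign_break = require_same_sign and sign[i] != sign[run[-1]]
            if gap_break or sign_break:
                if len(run) >= 2:
                    out.append(RegionCandidate(
                        chrom=str(chrom), start=int(pos[run[0]]),
                        end=int(pos[run[-1]]), cpgs=tuple(ids[run])))
                run = [i]
            else:
                run.append(i)
        if len(run) >= 2:
            out.append(RegionCandidate(
                chrom=str(chrom), start=int(pos[run[0]]),
                end=int(pos[run[-1]]), cpgs=tuple(ids[run])))
    return out


def enumerate_tested_regions(candidates: list, summary: pd.DataFrame | None = None) -> list:
    """All contiguous sub-windows of >= 2 CpGs within each candidate run.

    A run of k CpGs yields k(k-1)/2 tested regions; the total count is the
    Bonferroni denominator of the DMR stage. Positions are taken from
    ``summary`` when given, else from the candidate's own coordinates
    (member order is positional).
    """
    pos_map = None
    if summary is not None:
        pos_map = summary.set_index("cpg")["pos"]
    tested = []
    for cand in candidates:
        k = cand.n_cpgs
        for i in range(k - 1):
            for j in range(i + 1, k):
                members = cand.cpgs[i:j + 1]
                if pos_map is not None:
                    start, end = int(pos_map[members[0]]), int(pos_map[members[-1]])
                else:
                    start, end = cand.start, cand.end
                tested.append(RegionCandidate(
                    chrom=cand.chrom, start=start, end=end, cpgs=tuple(members)))
    return tested


def count_potential_regions(summary: pd.DataFrame, max_gap: int = 500) -> int:
    """Genome-wide Bonferroni denominator: the number of *potential*
    regions, i.e. all contiguous sub-windows of >= 2 CpGs within maximal
    runs of consecutive CpGs <= ``max_gap`` apart — counted over all CpGs,
    before any association filter.

    Counting only the windows that happen to qualify (nominally
    significant members) would make the denominator shrink exactly when
    selection has already inflated the region statistics; the potential
    count is data-independent given the manifest and keeps the adjusted
    p-values honest under correlated-null CpG blocks.
    """
    total = 0
    for _, grp in summary.groupby("chr", sort=False):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        if len(pos) < 2:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        run_lengths = np.diff(np.r_[0, breaks + 1, len(pos)])
        total += int((run_lengths * (run_lengths - 1) // 2).sum())
    return total


def cpg_correlations(residuals: pd.DataFrame, candidate: RegionCandidate) -> np.ndarray:
    """Pearson correlation matrix of the member CpGs' residualized
    methylation (pairwise complete observations)."""
    sub = residuals.loc[list(candidate.cpgs)].to_numpy(dtype=float)
    ok = ~np.isnan(sub).any(axis=0)
    if ok.sum() < 10:
        raise DataError(f"region {candidate.region_id}: fewer than 10 complete samples")
    sub = sub[:, ok]
    sds = sub.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = candidate.cpgs[int(np.flatnonzero(sds == 0)[0])]
        raise DataError(f"constant CpG {bad} in region {candidate.region_id}")
    R = np.corrcoef(sub)
    np.fill_diagonal(R, 1.0)
    return R


def _regularize(R: np.ndarray, eps: float = RIDGE_EPS) -> np.ndarray:
    Rc = np.clip(R, -OFFDIAG_CAP, OFFDIAG_CAP)
    np.fill_diagonal(Rc, 1.0)
    return (1 - eps) * Rc + eps * np.eye(R.shape[0])


def region_statistic(candidate: RegionCandidate, summary: pd.DataFrame,
                     R: np.ndarray, cohort: str = "cohort") -> DmrRecord:
    """GLS combination of member-CpG effects under covariance V = S R S.

    With w = V^-1 1: effect = (w'b)/(w'1), se = (w'1)^(-1/2). Reduces to
    the inverse-variance fixed-effects meta-analysis of the member CpGs
    when R = I.
    """
    rows = summary.set_index("cpg").loc[list(candidate.cpgs)]
    b = rows["beta"].to_numpy(dtype=float)
    s = rows["se"].to_numpy(dtype=float)
    if not (np.isfinite(b).all() and np.isfinite(s).all() and (s > 0).all()):
        raise DataError(f"region {candidate.region_id}: missing or invalid CpG statistics")
    Rreg = _regularize(np.asarray(R, dtype=float))
    V = Rreg * np.outer(s, s)
    try:
        cho = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        raise DataError(f"region {candidate.region_id}: singular covariance") from exc
    one = np.ones_like(b)
    Vinv_one = linalg.cho_solve(cho, one)
    Vinv_b = linalg.cho_solve(cho, b)
    denom = one @ Vinv_one
    if denom <= 0:
        raise DataError(f"region {candidate.region_id}: non-positive GLS precision")
    effect = (one @ Vinv_b) / denom
    se = denom**-0.5
    z = effect / se
    return DmrRecord(
        chrom=candidate.chrom, start=candidate.start, end=candidate.end,
        cpgs=candidate.cpgs, effect=float(effect), se=float(se), z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        mean_abs_effect=float(np.mean(np.abs(b))), cohort=cohort,
    )


def dmr_meta_analysis(per_cohort: list, n_regions_tested: int,
                      meta_summary: pd.DataFrame | None = None) -> list:
    """Inverse-variance meta-analysis of per-cohort region statistics.

    ``per_cohort`` is a list (one entry per cohort) of DmrRecord lists
    evaluated on the same candidates. Records missing from any cohort are
    dropped with a warning. ``p_adjust = min(1, p * n_regions_tested)``.
    The mean absolute CpG effect is recomputed from ``meta_summary`` when
    provided (the meta-analysis CpG effects), else averaged over cohorts.
    """
    if not per_cohort:
        raise DataError("no cohort DMR records supplied")
    keys = [{(r.chrom, r.start, r.end, r.cpgs): r for r in recs} for recs in per_cohort]
    common = set(keys[0])
    for k in keys[1:]:
        missing = common - set(k)
        for key in sorted(missing):
            logger.warning("candidate %s:%s-%s missing in a cohort; dropped", *key[:3])
        common &= set(k)
    meta_eff = None
    if meta_summary is not None:
        meta_eff = meta_summary.set_index("cpg")["beta"]
    out = []
    for key in sorted(common):
        recs = [k[key] for k in keys]
        w = np.array([1.0 / r.se**2 for r in recs])
        b = np.array([r.effect for r in recs])
        effect = float((w * b).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = effect / se
        p = float(2 * stats.norm.sf(abs(z)))
        if meta_eff is not None:
            mab = float(np.mean(np.abs(meta_eff.reindex(list(key[3])).to_numpy())))
        else:
            mab = float(np.mean([r.mean_abs_effect for r in recs]))
        out.append(DmrRecord(
            chrom=key[0], start=key[1], end=key[2], cpgs=key[3],
            effect=effect, se=se, z=z, p=p, mean_abs_effect=mab, cohort="meta",
            p_adjust=min(1.0, p * n_regions_tested),
        ))
    return out


@dataclass
class DmrAnalysisResult:
    """Full DMR stage output."""

    tested_meta: list            # meta DmrRecord per evaluated sub-window
    representatives: list        # best sub-window per maximal candidate run
    n_regions_tested: int        # genome-wide potential-region denominator
    candidates: list = field(default_factory=list)
    n_regions_evaluated: int = 0  # sub-windows actually given statistics


def run_dmr_analysis(meta_summary: pd.DataFrame, cohort_summaries: list,
                     cohort_residuals: list, cohort_names: list | None = None,
                     p_enter: float = 0.05, max_gap: int = 500,
                     require_same_sign: bool = True) -> DmrAnalysisResult:
    """Three-step DMR pipeline: candidates on the meta summary, per-cohort
    GLS statistics with each cohort's own CpG correlations, cross-cohort
    meta-analysis with Bonferroni over all tested sub-windows.

    The representative of each maximal run is its sub-window with the
    largest |z| in the meta-analysis. The Bonferroni denominator is the
    genome-wide count of potential sub-windows (see
    :func:`count_potential_regions`), not just the evaluated ones.
    """
    if cohort_names is None:
        cohort_names = [f"cohort{i}" for i in range(len(cohort_summaries))]
    n_potential = count_potential_regions(meta_summary, max_gap=max_gap)
    candidates = find_candidate_regions(
        meta_summary, p_enter=p_enter, max_gap=max_gap,
        require_same_sign=require_same_sign)
    tested = enumerate_tested_regions(candidates, meta_summary)
    n_tested = len(tested)
    if n_tested == 0:
        return DmrAnalysisResult([], [], n_potential, candidates, 0)
    per_cohort = []
    for summ, resid, name in zip(cohort_summaries, cohort_residuals, cohort_names):
        recs = []
        for cand in tested:
            R = cpg_correlations(resid, cand)
            recs.append(region_statistic(cand, summ, R, cohort=name))
        per_cohort.append(recs)
    meta_records = dmr_meta_analysis(per_cohort, n_potential, meta_summary=meta_summary)
    # Representative per maximal run: member sub-window with max |z|.
    reps = []
    by_key = {(r.chrom, r.cpgs): r for r in meta_records}
    for cand in candidates:
        subs = [
            by_key[(cand.chrom, cand.cpgs[i:j + 1])]
            for i in range(cand.n_cpgs - 1)
            for j in range(i + 1, cand.n_cpgs)
            if (cand.chrom, cand.cpgs[i:j + 1]) in by_key
        ]
        if subs:
            reps.append(max(subs, key=lambda r: abs(r.z)))
    return DmrAnalysisResult(meta_records, reps, n_potential, candidates, n_tested)


def dmr_records_to_frame(records: list) -> pd.DataFrame:
    """Tabular (1-based inclusive) view of DMR records."""
    return pd.DataFrame(
        [
            {
                "chr": r.chrom, "start": r.start, "end": r.end,
                "n_cpgs": r.n_cpgs, "effect": r.effect, "se": r.se,
                "z": r.z, "p": r.p, "p_adjust": r.p_adjust,
                "mean_abs_effect": r.mean_abs_effect, "cohort": r.cohort,
                "cpgs": ";".join(r.cpgs),
            }
            for r in records
        ]
    )
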