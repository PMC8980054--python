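"""Discordant monozygotic-twin within-pair analysis.

Comparing handedness-discordant MZ co-twins cancels everything the pair
shares — genotype, age, sex, gestational environment, family background —
so a within-pair methylation difference cannot be confounded by those
factors. Methylation is first residualized on pair-varying covariates
(technical covariates, cell proportions, and e.g. BMI/smoking in adults
or birth weight in children), then each CpG is tested with a paired
t-test on the left-minus-right residual differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from twinewas.datatypes import SUMMARY_COLUMNS, DataError, MethylationDataset
from twinewas.ewas import residualize

logger = logging.getLogger(__name__)


@dataclass
class TwinPairSet:
    """Handedness-discordant complete MZ pairs.

    ``pairs`` has one row per discordant pair with columns ``pair_id``,
    ``left_id`` (the left-handed co-twin) and ``right_id``; rows are
    ordered by family id so pairing is deterministic.
    """

    pairs: pd.DataFrame
    n_mz_complete: int
    n_discordant: int

    @property
    def discordance_fraction(self) -> float:
        return self.n_discordant / self.n_mz_complete if self.n_mz_complete else np.nan


def build_discordant_pairs(samples: pd.DataFrame) -> TwinPairSet:
    """Find complete MZ pairs and keep the handedness-discordant ones.

    MZ families with more than two assayed members are excluded with a
    warning; families with one member or missing handedness in either
    co-twin do not count as complete pairs.
    """
    if "family_id" not in samples or "zygosity" not in samples:
        raise DataError("sample sheet needs family_id and zygosity columns")
    mz = samples[samples["zygosity"] == "MZ"]
    n_complete = 0
    rows = []
    for fid in sorted(mz["family_id"].unique()):
        members = mz[mz["family_id"] == fid]
        if len(members) > 2:
            logger.warning("MZ family %s has %d members; excluded", fid, len(members))
            continue
        if len(members) < 2:
            continue
        hd = members["handedness"].to_numpy(dtype=float)
        if np.isnan(hd).any():
            continue
        n_complete += 1
        if hd[0] != hd[1]:
            left = members.index[int(np.argmax(hd))]
            right = members.index[int(np.argmin(hd))]
            rows.append({"pair_id": fid, "left_id": left, "right_id": right})
    pairs = pd.DataFrame(rows, columns=["pair_id", "left_id", "right_id"])
    return TwinPairSet(pairs=pairs, n_mz_complete=n_complete, n_discordant=len(pairs))


def within_pair_ewas(dataset: MethylationDataset, pairs: TwinPairSet,
                     covariates=(), cohort: str = "cohort") -> pd.DataFrame:
    """Paired t-test per CpG on residualized left-minus-right differences.

    Residualization is fitted on all twins with complete covariates (not
    only the discordant pairs) for stability; the within-pair difference
    then removes any pair-constant remainder. Covariates that are
    identical within every pair (age, sex, ...) carry no within-pair
    information and are rejected. Pairs missing methylation at a CpG are
    dropped for that CpG only; a CpG with zero difference variance gets
    missing statistics.
    """
    if len(pairs.pairs) < 3:
        raise DataError(f"need >= 3 discordant pairs, got {len(pairs.pairs)}")
    samples = dataset.samples
    for cov in covariates:
        if cov not in samples.columns:
            raise DataError(f"covariate {cov!r} not in sample sheet")
        lv = samples.loc[pairs.pairs["left_id"], cov].to_numpy()
        rv = samples.loc[pairs.pairs["right_id"], cov].to_numpy()
        if np.array_equal(lv, rv):
            raise DataError(
                f"covariate {cov!r} is identical within every MZ pair; "
                "it carries no within-pair information"
            )
    twin_ids = samples.index[samples["zygosity"].isin(["MZ", "DZ"])]
    resid = residualize(dataset.subset_samples(twin_ids), list(covariates))
    missing_pair_samples = (
        set(pairs.pairs["left_id"]) | set(pairs.pairs["right_id"])) - set(resid.columns)
    if missing_pair_samples:
        raise DataError(
            f"{len(missing_pair_samples)} pair members lost to covariate "
            "missingness; drop those pairs first")
    L = resid[pairs.pairs["left_id"].to_list()].to_numpy(dtype=float)
    Rm = resid[pairs.pairs["right_id"].to_list()].to_numpy(dtype=float)
    D = L - Rm  # CpGs × pairs
    ok = np.isfinite(D)
    n_pairs = ok.sum(axis=1)
    Dm = np.where(ok, D, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = Dm.sum(axis=1) / n_pairs
        sq = (np.where(ok, (D - eff[:, None]) ** 2, 0.0)).sum(axis=1)
        sd = np.sqrt(sq / np.maximum(n_pairs - 1, 1))
        se = sd / np.sqrt(n_pairs)
        tval = eff / se
        df = n_pairs - 1
        p = 2 * t_dist.sf(np.abs(tval), df)
    zero_sd = np.isfinite(sd) & (sd == 0)
    if zero_sd.any():
        logger.warning("%d CpGs with zero within-pair variance set missing", int(zero_sd.sum()))
        eff[zero_sd] = np.nan
        se[zero_sd] = np.nan
        tval[zero_sd] = np.nan
        p[zero_sd] = np.nan
    low = n_pairs < 3
    eff[low], se[low], tval[low], p[low] = np.nan, np.nan, np.nan, np.nan
    manifest = dataset.manifest.loc[resid.index]
    out = pd.DataFrame(
        {
            "cpg": resid.index.to_numpy(),
            "chr": manifest["chr"].to_numpy(),
            "pos": manifest["pos"].to_numpy(),
            "beta": eff,
            "se": se,
            "z": tval,
            "p": p,
            "n": n_pairs,
            "cohort": cohort,
            "model": "within-pair",
        }
    )[SUMMARY_COLUMNS]
    out.attrs["reference"] = "t"
    out.attrs["n_discordant_pairs"] = len(pairs.pairs)
    return out
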