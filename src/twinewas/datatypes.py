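"""Core data containers shared by every pipeline stage.

The unit of analysis is a :class:`MethylationDataset`: a CpG × sample matrix
of methylation beta-values together with a CpG manifest (genomic
coordinates) and a sample sheet (family structure, phenotype, covariates).
Per-CpG association results travel between stages as "summary" data frames
with a fixed column schema (``SUMMARY_COLUMNS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column schema of an EWAS summary table. ``beta`` is the effect of the
#: predictor (e.g. left-handedness) on the methylation beta-value scale; a
#: positive value means higher methylation in carriers of predictor = 1.
SUMMARY_COLUMNS = ["cpg", "chr", "pos", "beta", "se", "z", "p", "n", "cohort", "model"]

#: Sample-sheet columns with reserved meaning.
RESERVED_SAMPLE_COLUMNS = ["family_id", "zygosity", "handedness"]


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class MethylationDataset:
    """Methylation matrix plus manifest and sample sheet.

    Parameters
    ----------
    beta
        CpGs × samples data frame of methylation beta-values in [0, 1]
        (NaN allowed for missing). Index = CpG ids, columns = sample ids.
    manifest
        Per-CpG table indexed by CpG id with columns ``chr`` (string label
        without a ``chr`` prefix) and ``pos`` (1-based bp position).
    samples
        Sample sheet indexed by sample id with columns ``family_id``,
        ``zygosity`` (``MZ``/``DZ``/``NA``), ``handedness`` (1 = left-handed,
        0 = right-handed, NaN = missing/excluded) plus arbitrary covariates.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise DataError("beta values must lie in [0, 1] (or be missing)")
        missing_cpgs = self.beta.index.difference(self.manifest.index)
        if len(missing_cpgs):
            raise DataError(
                f"manifest does not cover {len(missing_cpgs)} CpGs "
                f"(first: {missing_cpgs[0]})"
            )
        if not self.beta.columns.equals(pd.Index(self.samples.index)):
            if set(self.beta.columns) != set(self.samples.index):
                raise DataError("beta columns and sample sheet ids disagree")
            # Same ids, different order: align the sheet to the matrix.
            self.samples = self.samples.loc[self.beta.columns]
        if not self.manifest.index.is_unique:
            raise DataError("duplicate CpG ids in manifest")
        pos = self.manifest.loc[self.beta.index, "pos"].to_numpy()
        if (pos <= 0).any():
            raise DataError("manifest positions must be positive 1-based integers")

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        """Return a new dataset restricted to ``sample_ids`` (order kept)."""
        return MethylationDataset(
            beta=self.beta[list(sample_ids)],
            manifest=self.manifest,
            samples=self.samples.loc[list(sample_ids)],
        )


@dataclass
class ModelSpec:
    """Which association model to fit.

    ``estimator='ols'`` is an ordinary least-squares fit with classical
    standard errors and a t reference (appropriate for unrelated samples);
    ``estimator='cluster-exchangeable'`` fits Gaussian estimating equations
    with an exchangeable working correlation within ``family_id`` clusters
    and robust sandwich standard errors (twin-family cohorts).
    """

    covariates: list = field(default_factory=list)
    estimator: str = "ols"
    tag: str = "basic"
    outcome: str = "methylation"
    predictor: str = "handedness"

    VALID_ESTIMATORS = ("ols", "cluster-exchangeable")

    def __post_init__(self) -> None:
        if self.estimator not in self.VALID_ESTIMATORS:
            raise DataError(
                f"estimator must be one of {self.VALID_ESTIMATORS}, got {self.estimator!r}"
            )


def empty_summary() -> pd.DataFrame:
    return pd.DataFrame(columns=SUMMARY_COLUMNS)


def validate_summary(summary: pd.DataFrame, require_positions: bool = False) -> None:
    """Check EWAS-summary schema and internal consistency of z = beta/se."""
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise DataError(f"summary table lacks columns {missing}")
    if summary["cpg"].duplicated().any():
        raise DataError("summary table has duplicate CpG rows")
    ok = np.isfinite(summary["se"].to_numpy(dtype=float))
    if (summary["se"].to_numpy(dtype=float)[ok] <= 0).any():
        raise DataError("summary standard errors must be positive")
    b = summary["beta"].to_numpy(dtype=float)
    s = summary["se"].to_numpy(dtype=float)
    z = summary["z"].to_numpy(dtype=float)
    fin = np.isfinite(b) & np.isfinite(s) & np.isfinite(z)
    if fin.any():
        err = np.abs(z[fin] - b[fin] / s[fin])
        if (err > 1e-8 * np.maximum(1.0, np.abs(z[fin]))).any():
            raise DataError("summary z-scores inconsistent with beta/se")
    if require_positions and summary["pos"].isna().any():
        raise DataError("summary table lacks genomic positions")
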