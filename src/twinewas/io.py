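"""Readers and writers for the pipeline's plain-text file formats.

Coordinates are 1-based inclusive everywhere in memory; only the BED-like
export converts to 0-based half-open. Chromosome labels are normalized to
strings without a ``chr`` prefix on input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from twinewas.datatypes import SUMMARY_COLUMNS, DataError, MethylationDataset
from twinewas.dmr import dmr_records_to_frame
from twinewas.scores import WeightTable


def normalize_chrom(values) -> pd.Series:
    s = pd.Series(values).astype(str).str.replace("^chr", "", regex=True)
    return s


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="cpg", float_format="%.6g")


def read_beta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg")


def write_manifest_csv(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index_label="cpg")


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="cpg")
    df["chr"] = normalize_chrom(df["chr"]).to_numpy()
    df["pos"] = df["pos"].astype(int)
    return df


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index_label="sample_id")


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    if "handedness" in df:
        hd = pd.to_numeric(df["handedness"], errors="coerce")
        hd[~hd.isin([0, 1])] = np.nan  # ambidextrous/mixed codes -> missing
        df["handedness"] = hd
    return df


def read_dataset(beta_path, manifest_path, samples_path) -> MethylationDataset:
    return MethylationDataset(
        beta=read_beta_tsv(beta_path),
        manifest=read_manifest_csv(manifest_path),
        samples=read_samples_csv(samples_path),
    )


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="sample_id")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in summary.columns]
    extra = [c for c in summary.columns if c not in cols]
    summary[cols + extra].to_csv(path, sep="\t", index=False)


def read_summary_tsv(path) -> pd.DataFrame:
    # converters bypass NA-parsing (tags like "null" stay strings);
    # round_trip parsing keeps write-read-write byte-stable
    df = pd.read_csv(path, sep="\t", converters={"cohort": str, "model": str},
                     float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"summary file {path} lacks columns {missing}")
    df["chr"] = normalize_chrom(df["chr"]).to_numpy()
    return df


def write_locus_tsv(loci: pd.DataFrame, path) -> None:
    loci[["snp", "chr", "pos", "p"]].to_csv(path, sep="\t", index=False)


def read_locus_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chr"] = normalize_chrom(df["chr"]).to_numpy()
    df["pos"] = df["pos"].astype(int)
    return df


def read_cpg_list(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_weight_table_tsv(table: WeightTable, path) -> None:
    pd.DataFrame(
        {
            "feature": table.weights.index,
            "weight": table.weights.to_numpy(),
            "source": table.source,
            "threshold": table.threshold,
        }
    ).to_csv(path, sep="\t", index=False)


def read_weight_table_tsv(path) -> WeightTable:
    df = pd.read_csv(path, sep="\t")
    return WeightTable(
        weights=pd.Series(df["weight"].to_numpy(), index=df["feature"].to_numpy()),
        source=str(df["source"].iloc[0]) if len(df) else "",
        threshold=float(df["threshold"].iloc[0]) if len(df) else np.nan,
    )


def write_dmr_bed(records: list, path) -> None:
    """BED-like export: 0-based half-open start, inclusive end."""
    df = dmr_records_to_frame(records)
    if not df.empty:
        df = df.assign(start=df["start"] - 1)
    df.to_csv(path, sep="\t", index=False)


def write_dmr_csv(records: list, path) -> None:
    """1-based inclusive region table."""
    dmr_records_to_frame(records).to_csv(path, index=False)


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
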