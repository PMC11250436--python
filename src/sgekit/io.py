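"""TSV readers/writers for the package's tabular interchange formats."""

from __future__ import annotations

import pandas as pd

COUNT_COLUMNS = [
    "region", "replicate", "timepoint", "analyte",
    "hgvs_c", "consequence", "codon_index", "read_count", "sample_total",
]


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (df["read_count"] < 0).any():
        raise ValueError("negative read counts")
    if (df["read_count"] > df["sample_total"]).any():
        raise ValueError("read_count exceeds sample_total")
    return df


def write_scores(scores: pd.DataFrame, path: str) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"hgvs_c", "clinvar", "ccrcc_obs", "gnomad_v2", "gnomad_v3", "topmed_het", "ukb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df
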