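"""Plain-text readers and writers for the pipeline's tabular interchange formats.

Everything is tab-separated. Expression matrices are written wide (one row per
probe or gene, one column per sample, empty cell = missing). Floats use the
``%.10g`` format so that rewriting the same data yields byte-identical files.
"""

from __future__ import annotations

import pandas as pd

FLOAT_FMT = "%.10g"


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a wide probe/gene x sample matrix; NaN becomes an empty cell."""
    df.to_csv(path, sep="\t", index_label="id", float_format=FLOAT_FMT, na_rep="")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    write_table(cohort, path)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df


def write_cq(cq: pd.DataFrame, path) -> None:
    write_table(cq, path)


def read_cq(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay_id": str})
    return df
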