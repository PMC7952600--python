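"""Tabular and sparse-matrix export helpers shared by the pipeline stages."""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_matrix_h5",
    "read_matrix_h5",
]


def write_counts_tsv(path: str, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(prefix: str, counts: pd.DataFrame) -> None:
    """Matrix-market triple: <prefix>.mtx with row/column label sidecars."""
    spio.mmwrite(prefix + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    with open(prefix + ".rows.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(prefix + ".cols.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix: str) -> pd.DataFrame:
    m = spio.mmread(prefix + ".mtx").toarray()
    with open(prefix + ".rows.txt") as fh:
        rows = [ln.strip() for ln in fh if ln.strip()]
    with open(prefix + ".cols.txt") as fh:
        cols = [ln.strip() for ln in fh if ln.strip()]
    return pd.DataFrame(m, index=pd.Index(rows, name="cell_barcode"), columns=cols)


def write_matrix_h5(path: str, df: pd.DataFrame, dataset: str = "matrix") -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset(dataset, data=df.to_numpy())
        h5.create_dataset("rows", data=np.array(df.index, dtype="S"))
        h5.create_dataset("cols", data=np.array(df.columns, dtype="S"))


def read_matrix_h5(path: str, dataset: str = "matrix") -> pd.DataFrame:
    with h5py.File(path, "r") as h5:
        return pd.DataFrame(
            h5[dataset][()],
            index=pd.Index([b.decode() for b in h5["rows"][()]], name="cell_barcode"),
            columns=[b.decode() for b in h5["cols"][()]],
        )
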