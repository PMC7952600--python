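"""Technical-covariate correction of antibody counts by SVD regression.

Raw deduplicated antibody counts are log-transformed (one pseudocount)
and each antibody column is regressed on the leading left-singular
vectors of a per-cell quality-metric matrix q with four columns: total
antibody reads, total antibody counts after UMI correction, isotype
(IgG1) count, and total amplicon reads. q is log-transformed with the
same pseudocount, scaled column-wise to unit standard deviation and
mean-centered before the SVD. The residual matrix u is the corrected
antibody signal; an intercept is always part of the design so residual
columns are mean-free.

The number of retained singular vectors follows the sample type: 3 for
patient samples, 2 for PBMC, 1 for cell lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QUALITY_COLUMNS",
    "N_VECTORS_BY_SAMPLE_TYPE",
    "transform_counts",
    "build_design",
    "correct_counts",
    "build_quality_matrix",
    "correction_diagnostics",
]

QUALITY_COLUMNS = (
    "total_antibody_reads",
    "total_antibody_umis",
    "isotype_count",
    "total_amplicon_reads",
)

N_VECTORS_BY_SAMPLE_TYPE = {"patient": 3, "pbmc": 2, "cell_lines": 1}


def transform_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Entrywise natural log of (count + 1)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return np.log1p(counts.astype(float))


def build_quality_matrix(
    raw_reads: pd.Series,
    umi_counts: pd.Series,
    isotype_counts: pd.Series,
    amplicon_reads: pd.Series,
) -> pd.DataFrame:
    """Assemble the cells x 4 quality-metric matrix q, row-aligned to cells."""
    q = pd.DataFrame(
        {
            QUALITY_COLUMNS[0]: raw_reads,
            QUALITY_COLUMNS[1]: umi_counts,
            QUALITY_COLUMNS[2]: isotype_counts,
            QUALITY_COLUMNS[3]: amplicon_reads,
        }
    )
    if q.isna().any().any():
        raise ValueError("quality metrics not aligned: missing values after join")
    if (q.to_numpy() < 0).any():
        raise ValueError("quality metrics must be non-negative")
    return q


@dataclass
class DesignMatrix:
    """Regression design: intercept + retained left-singular vectors of q."""

    X: np.ndarray  # cells x (1 + n_vectors)
    n_vectors: int
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    variance_explained: np.ndarray = field(default_factory=lambda: np.empty(0))


def build_design(
    q: pd.DataFrame, n_vectors: int, include_intercept: bool = True
) -> DesignMatrix:
    """Design matrix from the SVD of the transformed quality-metric matrix.

    q is log1p-transformed, scaled to unit standard deviation per column,
    mean-centered, and decomposed; the first ``n_vectors`` left-singular
    vectors (plus an intercept column) form the design. Columns that are
    constant after the transform carry no information and are dropped with
    a warning before the SVD.
    """
    if n_vectors not in (1, 2, 3):
        raise ValueError("n_vectors must be 1, 2 or 3")
    n_cells = q.shape[0]
    if n_cells < n_vectors + 1:
        raise ValueError("need at least n_vectors + 1 cells")
    z = np.log1p(q.to_numpy(dtype=float))
    sd = z.std(axis=0)
    # constant columns: tolerance absorbs float rounding of identical values
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(z).max(axis=0))
    if not keep.all():
        dropped = [c for c, k in zip(q.columns, keep) if not k]
        warnings.warn(f"dropping constant quality columns: {dropped}")
    z = z[:, keep]
    if z.shape[1] == 0:
        X = np.ones((n_cells, 1)) if include_intercept else np.empty((n_cells, 0))
        return DesignMatrix(X, 0)
    z = z / z.std(axis=0)
    z = z - z.mean(axis=0)
    U, s, _ = np.linalg.svd(z, full_matrices=False)
    # degenerate q (identical rows): everything centers to zero
    nonzero = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros_like(s, bool)
    k = min(n_vectors, int(nonzero.sum()))
    cols = [U[:, :k]]
    if include_intercept:
        cols.insert(0, np.ones((n_cells, 1)))
    X = np.hstack(cols) if cols else np.empty((n_cells, 0))
    total_var = (s**2).sum()
    var_exp = s**2 / total_var if total_var > 0 else s * 0.0
    return DesignMatrix(X, k, s, var_exp)


def correct_counts(log_c: pd.DataFrame, design: DesignMatrix) -> pd.DataFrame:
    """Corrected antibody signal: OLS residuals of each antibody column.

    Each column of ``log_c`` is regressed on the design; the residual
    vector u_j is the corrected signal of antibody j. Shape and cell
    order are preserved.
    """
    X = design.X
    if X.shape[0] != log_c.shape[0]:
        raise ValueError("row misalignment between counts and design")
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer cells than design columns")
    Y = log_c.to_numpy(dtype=float)
    if X.shape[1] == 0:
        resid = Y
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
    u = pd.DataFrame(resid, index=log_c.index, columns=log_c.columns)
    u.attrs["n_vectors"] = design.n_vectors
    return u


def correction_diagnostics(
    u: pd.DataFrame, design: DesignMatrix
) -> pd.DataFrame:
    """Residual-regressor diagnostics: per antibody, max |dot| and |Pearson r|
    against each retained design column (intercept excluded)."""
    rows = []
    X = design.X
    regs = X[:, 1:] if X.shape[1] > 1 else np.empty((X.shape[0], 0))
    for j, ab in enumerate(u.columns):
        col = u.iloc[:, j].to_numpy()
        dots = [abs(float(col @ regs[:, m])) for m in range(regs.shape[1])]
        cors = []
        # a residual column explained completely by the design has ~zero
        # variance; its correlation is undefined, not large
        col_sd = col.std()
        for m in range(regs.shape[1]):
            r = regs[:, m]
            if col_sd > 1e-12 and r.std() > 0:
                cors.append(abs(float(np.corrcoef(col, r)[0, 1])))
        rows.append(
            {
                "antibody": ab,
                "max_abs_dot": max(dots) if dots else 0.0,
                "max_abs_corr": max(cors) if cors else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("antibody")
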