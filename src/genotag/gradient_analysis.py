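"""Ordering of blast cells along the dominant immunophenotypic gradient.

Cells in blast-annotated phenotypic clusters are extracted from the
corrected antibody matrix u, the singular value decomposition of the
blast submatrix is taken, and cells are ordered by their entry in the
second left-singular vector. Antibody expression, clone composition and
embedding coordinates are then profiled along the ordering with a dense
moving window (200 cells by default, stride 1, fully-populated windows
only), and a third-order spline through the smoothed embedding positions
indicates the gradient's orientation.

The sign of a singular vector is arbitrary: negating it reverses the
ordering and mirrors every profile, leaving correlation magnitudes
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

__all__ = [
    "GradientProfile",
    "blast_subset",
    "order_by_gradient",
    "moving_profiles",
    "gradient_correlations",
    "fit_spline",
]


@dataclass
class GradientProfile:
    """Moving-window profiles along the phenotypic gradient."""

    ordering: pd.Index  # cell ids in gradient order
    antibody_profiles: pd.DataFrame  # windows x antibodies, smoothed means
    clone_fractions: pd.DataFrame  # windows x clones, smoothed fractions
    smoothed_coords: pd.DataFrame | None  # windows x (umap1, umap2)
    clone_indicators: pd.DataFrame  # per-cell 0/1 clone membership, ordered
    window: int


def blast_subset(
    u: pd.DataFrame,
    cluster_labels: pd.Series,
    blast_cluster_ids: list,
) -> pd.DataFrame:
    """Rows of u restricted to cells in blast-annotated clusters."""
    if not blast_cluster_ids:
        raise ValueError("no blast clusters configured")
    mask = cluster_labels.isin(blast_cluster_ids)
    cells = cluster_labels.index[mask].intersection(u.index)
    if len(cells) == 0:
        raise ValueError("blast subset is empty")
    return u.loc[cells]


def order_by_gradient(u_blast: pd.DataFrame) -> pd.Index:
    """Order blast cells by their value of the second left-singular vector.

    The SVD is taken of the blast submatrix as-is (residuals are mean-free
    over all cells, not within the subset, so the first singular vector
    typically captures the subset mean direction and the second the
    dominant within-subset gradient). Ties are broken by cell id for a
    stable, deterministic ordering. The returned ordering is defined up to
    global reversal (singular-vector sign ambiguity).
    """
    if u_blast.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    X = u_blast.to_numpy(dtype=float)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size < 2 or s[1] <= s[0] * 1e-12:
        raise ValueError("rank < 2: no second gradient direction")
    v2 = U[:, 1]
    order = sorted(range(len(v2)), key=lambda i: (v2[i], str(u_blast.index[i])))
    return u_blast.index[order]


def _moving_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Dense moving average over fully-populated windows (stride 1)."""
    kernel = np.full(window, 1.0 / window)
    if values.ndim == 1:
        return np.convolve(values, kernel, mode="valid")
    return np.column_stack(
        [np.convolve(values[:, j], kernel, mode="valid") for j in range(values.shape[1])]
    )


def moving_profiles(
    ordering: pd.Index,
    u_blast: pd.DataFrame,
    clone_labels: pd.Series,
    embedding: pd.DataFrame | None = None,
    window: int = 200,
) -> GradientProfile:
    """Moving-window means of antibodies, clone fractions and coordinates.

    Parameters
    ----------
    ordering
        Gradient ordering of the blast cells (from
        :func:`order_by_gradient`).
    clone_labels
        Clone label per cell; turned into one 0/1 indicator column per
        clone, whose moving mean is the local clone fraction.
    embedding
        Optional 2-D coordinates per cell; smoothed with the same window.
    window
        Window length in cells (stride 1; only fully-populated windows are
        reported, giving n - window + 1 profile points).
    """
    n = len(ordering)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > n:
        raise ValueError("window exceeds number of blast cells")
    u_ord = u_blast.loc[ordering]
    ab = pd.DataFrame(
        _moving_mean(u_ord.to_numpy(dtype=float), window),
        columns=u_blast.columns,
    )
    clones = sorted(clone_labels.loc[ordering].astype(str).unique())
    ind = pd.DataFrame(
        {c: (clone_labels.loc[ordering].astype(str) == c).astype(float).to_numpy()
         for c in clones},
        index=ordering,
    )
    frac = pd.DataFrame(
        _moving_mean(ind.to_numpy(), window), columns=clones
    )
    coords = None
    if embedding is not None:
        coords = pd.DataFrame(
            _moving_mean(embedding.loc[ordering].to_numpy(dtype=float), window),
            columns=embedding.columns,
        )
    return GradientProfile(ordering, ab, frac, coords, ind, window)


def gradient_correlations(profile: GradientProfile) -> pd.DataFrame:
    """Correlation of each antibody and clone with gradient position.

    Antibodies: Pearson r of the smoothed profile against window index.
    Clones: Kendall tau of the per-cell 0/1 indicator against the cell's
    rank along the ordering (the unsmoothed series). Two-sided p-values;
    zero-variance series are reported as not-applicable (NaN).
    """
    rows = []
    pos = np.arange(len(profile.antibody_profiles))
    for ab in profile.antibody_profiles.columns:
        y = profile.antibody_profiles[ab].to_numpy()
        if np.std(y) == 0 or np.std(pos) == 0:
            rows.append({"series": ab, "kind": "antibody", "stat": "pearson_r",
                         "value": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(pos, y)
        rows.append({"series": ab, "kind": "antibody", "stat": "pearson_r",
                     "value": float(r), "p_value": float(p)})
    ranks = np.arange(len(profile.ordering))
    for clone in profile.clone_indicators.columns:
        y = profile.clone_indicators[clone].to_numpy()
        if np.std(y) == 0:
            rows.append({"series": clone, "kind": "clone", "stat": "kendall_tau",
                         "value": np.nan, "p_value": np.nan})
            continue
        tau, p = stats.kendalltau(ranks, y)
        rows.append({"series": clone, "kind": "clone", "stat": "kendall_tau",
                     "value": float(tau), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("series")


def fit_spline(smoothed_coords: pd.DataFrame) -> CubicSpline:
    """Third-order interpolating spline through the smoothed cell positions.

    Parameterised by normalised arc position over the window index
    (0 at the first window, 1 at the last); evaluable at arbitrary
    positions in [0, 1] for overlay plotting. The spline interpolates its
    knots exactly.
    """
    pts = smoothed_coords.to_numpy(dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 smoothed points for a cubic spline")
    t = np.linspace(0.0, 1.0, pts.shape[0])
    return CubicSpline(t, pts, axis=0)
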