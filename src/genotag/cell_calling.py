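"""Cell calling from DNA read depth and antibody-count quality control.

Valid cell barcodes are selected at the knee of the barcode rank plot
(maximum perpendicular distance between the log-log rank curve and the
chord joining its endpoints), combined with an amplicon-coverage rule
(>= 60% of panel intervals covered by >= 8 reads) and antibody QC
(>= 100 total antibody UMIs, isotype-control count no greater than five
times the experiment median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeRankCurve",
    "rank_inflection",
    "amplicon_coverage_ok",
    "antibody_qc",
    "build_qc_table",
    "read_bed",
]


@dataclass
class BarcodeRankCurve:
    """Barcodes sorted by descending total amplicon reads."""

    barcodes: list[str]
    reads: np.ndarray  # same order, monotone non-increasing

    @classmethod
    def from_totals(cls, totals: dict[str, int] | pd.Series) -> "BarcodeRankCurve":
        s = pd.Series(totals).sort_values(ascending=False, kind="stable")
        s = s[s > 0]
        return cls(list(s.index), s.to_numpy(dtype=float))

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype=float)
        if np.any(np.diff(self.reads) > 0):
            raise ValueError("read totals must be non-increasing")


def rank_inflection(curve: BarcodeRankCurve, min_dynamic_range: float = 10.0) -> float:
    """Knee of the barcode rank plot: a read-count threshold for cell calling.

    The curve is taken in log10(rank) / log10(reads) space and the knee is
    the point of maximum perpendicular distance to the chord joining the
    first and last points. Returns the read count at the knee; barcodes
    with strictly more reads are cell candidates.

    Raises
    ------
    ValueError
        ``"no knee"`` when the curve spans less than ``min_dynamic_range``
        (default 10x) between its endpoints.
    """
    reads = curve.reads
    if reads.size < 2:
        raise ValueError("no knee: need at least 2 barcodes")
    if reads[0] < min_dynamic_range * reads[-1]:
        raise ValueError("no knee: dynamic range below threshold")
    x = np.log10(np.arange(1, reads.size + 1))
    y = np.log10(reads)
    # perpendicular distance from each point to the endpoint chord
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    if dist.max() < 1e-12:
        # collinear log-log curve (e.g. exactly two points): no interior
        # bend, split at the geometric mean of the endpoints
        return float(10 ** ((y[0] + y[-1]) / 2))
    knee = int(np.argmax(dist))
    return float(reads[knee])


def amplicon_coverage_ok(
    depths: np.ndarray | list[int], min_fraction: float = 0.6, min_reads: int = 8
) -> bool:
    """Whether a cell's per-interval amplicon depths pass the coverage rule.

    True iff the fraction of panel intervals with depth >= ``min_reads``
    is at least ``min_fraction``.
    """
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty interval list")
    return bool((depths >= min_reads).mean() >= min_fraction)


def antibody_qc(
    total_umis: int,
    isotype_count: int,
    median_isotype: float,
    min_umis: int = 100,
    isotype_factor: float = 5.0,
) -> bool:
    """Antibody-count QC for one cell barcode.

    True iff the cell has at least ``min_umis`` total antibody UMIs and an
    isotype-control (IgG1) count no greater than ``isotype_factor`` times
    the experiment-wide median isotype count. Both boundaries inclusive.
    """
    if total_umis < 0 or isotype_count < 0 or median_isotype < 0:
        raise ValueError("negative QC inputs")
    return total_umis >= min_umis and isotype_count <= isotype_factor * median_isotype


def build_qc_table(
    amplicon_depths: pd.DataFrame,
    ab_counts: pd.DataFrame,
    isotype_columns: list[str],
    min_fraction: float = 0.6,
    min_reads: int = 8,
    min_umis: int = 100,
    isotype_factor: float = 5.0,
    min_dynamic_range: float = 10.0,
) -> pd.DataFrame:
    """Apply knee, coverage and antibody QC and return a per-barcode table.

    Parameters
    ----------
    amplicon_depths
        Barcodes x intervals DNA read depth table (all observed barcodes,
        including ambient/empty droplets).
    ab_counts
        Deduplicated antibody count matrix (may cover a subset of barcodes).
    isotype_columns
        Panel columns flagged as isotype controls.

    Notes
    -----
    The isotype median is computed over knee candidates only, so that
    ambient barcodes do not distort it. The returned table stores every
    metric each flag is derived from; ``pass_all`` is the conjunction of
    the three rules.
    """
    totals = amplicon_depths.sum(axis=1)
    curve = BarcodeRankCurve.from_totals(totals)
    threshold = rank_inflection(curve, min_dynamic_range)
    iso = (
        ab_counts[isotype_columns].sum(axis=1)
        if isotype_columns
        else pd.Series(0, index=ab_counts.index)
    )
    umis = ab_counts.sum(axis=1)

    rows = []
    index = amplicon_depths.index
    pass_knee = totals > threshold
    candidates = index[pass_knee]
    cand_iso = iso.reindex(candidates).dropna()
    median_iso = float(cand_iso.median()) if len(cand_iso) else 0.0
    for bc in index:
        depths = amplicon_depths.loc[bc].to_numpy()
        total_umis = int(umis.get(bc, 0))
        iso_count = int(iso.get(bc, 0))
        cov_ok = amplicon_coverage_ok(depths, min_fraction, min_reads)
        ab_ok = antibody_qc(total_umis, iso_count, median_iso, min_umis, isotype_factor)
        rows.append(
            {
                "cell_barcode": bc,
                "total_amplicon_reads": int(totals[bc]),
                "fraction_intervals_covered": float((depths >= min_reads).mean()),
                "total_antibody_umis": total_umis,
                "isotype_count": iso_count,
                "pass_knee": bool(pass_knee[bc]),
                "pass_coverage": cov_ok,
                "pass_antibody": ab_ok,
            }
        )
    qc = pd.DataFrame(rows).set_index("cell_barcode")
    qc["pass_all"] = qc.pass_knee & qc.pass_coverage & qc.pass_antibody
    qc.attrs["knee_threshold"] = threshold
    qc.attrs["median_isotype"] = median_iso
    return qc


def read_bed(path: str) -> pd.DataFrame:
    """Read amplicon intervals from a BED file (0-based, half-open).

    Returns a DataFrame with chrom/start/end/name columns; the name column
    defaults to ``chrom:start-end`` when absent.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if raw.shape[1] < 3:
        raise ValueError("BED needs at least chrom/start/end columns")
    df = raw.iloc[:, :3].copy()
    df.columns = ["chrom", "start", "end"]
    if raw.shape[1] >= 4:
        df["name"] = raw.iloc[:, 3].astype(str)
    else:
        df["name"] = df.chrom + ":" + df.start.astype(str) + "-" + df.end.astype(str)
    if (df.end <= df.start).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df
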