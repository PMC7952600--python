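"""UMI deduplication with the adjacency network method and count-matrix assembly.

Reads sharing a (cell, antibody) pair are grouped by UMI sequence; the
number of underlying molecules is then estimated with the adjacency rule:
a directed edge a -> b is drawn when Hamming(a, b) = 1 and
count(a) >= 2 * count(b) - 1, and nodes are selected greedily by
descending read count until every UMI is either selected or one adjacency
step from a selected node. The number of selected nodes is the molecule
count. Ties in the greedy order are broken lexicographically for
determinism.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .read_structure import ParsedTagRead

__all__ = ["adjacency_dedup", "build_count_matrix", "group_umis"]


def adjacency_dedup(umis: Mapping[str, int]) -> int:
    """Molecule count of one (cell, antibody) UMI set under the adjacency rule.

    Parameters
    ----------
    umis
        Mapping of UMI sequence to read count; all sequences must have
        equal length and counts must be >= 1.

    Returns
    -------
    int
        Estimated number of distinct molecules (0 for an empty set).
    """
    if not umis:
        return 0
    seqs = sorted(umis)
    length = len(seqs[0])
    for s in seqs:
        if len(s) != length:
            raise ValueError("UMIs of unequal length")
        if umis[s] < 1:
            raise ValueError(f"UMI count < 1 for {s!r}")

    # Hamming-1 neighbour pairs via single-position masking: two UMIs are
    # at distance exactly 1 iff they share a masked key and differ
    adj: dict[str, list[str]] = {s: [] for s in seqs}
    buckets: dict[str, list[str]] = defaultdict(list)
    for s in seqs:
        for i in range(length):
            buckets[s[:i] + "\x00" + s[i + 1 :]].append(s)
    seen: set[tuple[str, str]] = set()
    for group in buckets.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                pair = (a, b) if a < b else (b, a)
                if pair in seen:
                    continue
                seen.add(pair)
                ca, cb = umis[a], umis[b]
                if ca >= 2 * cb - 1:
                    adj[a].append(b)
                if cb >= 2 * ca - 1:
                    adj[b].append(a)

    order = sorted(seqs, key=lambda s: (-umis[s], s))
    covered: set[str] = set()
    n_selected = 0
    for node in order:
        if node in covered:
            continue
        n_selected += 1
        covered.add(node)
        covered.update(adj[node])
    return n_selected


def group_umis(
    reads: Iterable[ParsedTagRead],
) -> tuple[dict[tuple[str, str], dict[str, int]], dict[str, int]]:
    """Group valid parsed reads into per-(cell, antibody) UMI sets.

    Returns the grouping and per-cell raw tag-read totals (valid reads
    only), which feed the quality-metric matrix downstream.
    """
    groups: dict[tuple[str, str], dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    raw_per_cell: dict[str, int] = defaultdict(int)
    for r in reads:
        if not r.valid:
            continue
        groups[(r.cell_barcode, r.antibody)][r.umi] += 1
        raw_per_cell[r.cell_barcode] += 1
    return {k: dict(v) for k, v in groups.items()}, dict(raw_per_cell)


def build_count_matrix(
    reads: Iterable[ParsedTagRead],
    antibodies: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the UMI-deduplicated antibody count matrix from parsed reads.

    Parameters
    ----------
    reads
        Stream of barcode-corrected :class:`ParsedTagRead`; invalid reads
        are ignored.
    antibodies
        Panel column order; inferred from the data when omitted.

    Returns
    -------
    counts : DataFrame
        Cells x antibodies integer matrix of deduplicated molecule counts.
    cell_totals : DataFrame
        Per-cell ``raw_reads`` (valid tag reads) and ``umi_counts``
        (deduplicated total) columns, aligned to the count-matrix rows.
    """
    groups, raw_per_cell = group_umis(reads)
    cells = sorted(raw_per_cell)
    if antibodies is None:
        antibodies = sorted({ab for (_, ab) in groups})
    counts = pd.DataFrame(
        np.zeros((len(cells), len(antibodies)), dtype=np.int64),
        index=pd.Index(cells, name="cell_barcode"),
        columns=antibodies,
    )
    for (cell, ab), umiset in groups.items():
        if ab in counts.columns:
            counts.at[cell, ab] = adjacency_dedup(umiset)
    totals = pd.DataFrame(
        {
            "raw_reads": [raw_per_cell[c] for c in cells],
            "umi_counts": counts.sum(axis=1).to_numpy(),
        },
        index=counts.index,
    )
    return counts, totals
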