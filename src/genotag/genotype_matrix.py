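"""Per-cell genotype condensation, call filtering and clone assignment.

Variant calls from a multi-sample VCF (one sample column per cell
barcode) are condensed into integer codes: 0 wild type, 1 heterozygous
alternate, 2 homozygous alternate, 3 no call. Calls with genotype quality
below 30 or total depth below 10 are marked as no call. Clones are
defined as the tuple of per-locus states over a configured set of
relevant loci; for patient samples heterozygous and homozygous alternate
states are merged into a single "mutant" state to reduce noise from
allele dropout.

Coordinate conventions: VCF positions are 1-based; BED intervals are
0-based half-open. Input VCFs are expected biallelic and left-aligned;
multiallelic records are rejected rather than normalized.
"""

from __future__ import annotations

import math

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "WILD_TYPE",
    "HET_ALT",
    "HOM_ALT",
    "NO_CALL",
    "condense_call",
    "assign_clone",
    "clone_fractions",
    "toy_pileup_genotype",
    "read_genotype_matrix",
    "write_genotype_h5",
    "read_genotype_h5",
]

WILD_TYPE, HET_ALT, HOM_ALT, NO_CALL = 0, 1, 2, 3

DEFAULT_MIN_GQ = 30
DEFAULT_MIN_DP = 10


def condense_call(
    gt: tuple[int | None, int | None] | None,
    gq: float | None,
    dp: float | None,
    min_gq: float = DEFAULT_MIN_GQ,
    min_dp: float = DEFAULT_MIN_DP,
) -> int:
    """Condense one diploid call into a code in {0, 1, 2, 3}.

    Parameters
    ----------
    gt
        Diploid genotype as a pair of allele indices (0 = ref, 1 = alt),
        or None / a pair containing None for a missing call.
    gq, dp
        Genotype quality and total read depth; a call below either
        threshold becomes no call (3).
    """
    if gt is None or any(a is None for a in gt):
        return NO_CALL
    if any(a not in (0, 1) for a in gt):
        raise ValueError(f"multiallelic genotype {gt!r}; input must be pre-split")
    if gq is None or dp is None or gq < min_gq or dp < min_dp:
        return NO_CALL
    n_alt = sum(gt)
    return (WILD_TYPE, HET_ALT, HOM_ALT)[n_alt]


def assign_clone(
    row: pd.Series | dict[str, int],
    loci: list[str],
    merge_alternates: bool = False,
) -> tuple[int | str, ...]:
    """Clone label for one cell: tuple of per-locus states over relevant loci.

    With ``merge_alternates`` the heterozygous and homozygous alternate
    states collapse to a single ``"mut"`` state, giving a per-locus state
    space of wild type / mutant / no call (3^k labels for k loci instead
    of 4^k).
    """
    if not loci:
        raise ValueError("empty relevant-loci list")
    states: list[int | str] = []
    for locus in loci:
        code = int(row[locus])
        if code not in (WILD_TYPE, HET_ALT, HOM_ALT, NO_CALL):
            raise ValueError(f"invalid genotype code {code}")
        if merge_alternates and code in (HET_ALT, HOM_ALT):
            states.append("mut")
        else:
            states.append(code)
    return tuple(states)


def clone_fractions(
    labels: pd.Series,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group clone fractions, with no-call-containing labels kept separate.

    Parameters
    ----------
    labels
        Clone label per cell (tuples from :func:`assign_clone`).
    groups
        Optional per-cell group (e.g. timepoint); a single group is
        assumed when omitted.

    Returns
    -------
    DataFrame with columns group, clone, n_cells, fraction, has_no_call;
    fractions are over all labelled cells of the group.
    """
    if groups is None:
        groups = pd.Series("all", index=labels.index)
    rows = []
    for grp, sub in labels.groupby(groups):
        total = len(sub)
        for clone, cnt in sub.value_counts().items():
            rows.append(
                {
                    "group": grp,
                    "clone": clone,
                    "n_cells": int(cnt),
                    "fraction": cnt / total,
                    "has_no_call": NO_CALL in clone,
                }
            )
    return pd.DataFrame(rows)


def toy_pileup_genotype(
    ref_reads: int, alt_reads: int
) -> tuple[tuple[int, int] | None, float, int]:
    """Toy diploid genotyper from ref/alt read counts at one site.

    A deliberately simple stand-in caller used for synthetic end-to-end
    runs: the genotype is decided by the alternate-allele fraction f
    (f < 0.2 hom-ref, 0.2 <= f <= 0.8 het, f > 0.8 hom-alt) and the
    quality score is -10*log10 of the binomial likelihood of the
    runner-up model (allele fractions 0.01 / 0.5 / 0.99). Not a
    substitute for a production variant caller.

    Returns ``(gt, gq, dp)``; ``gt`` is None when depth is zero.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("negative read counts")
    dp = ref_reads + alt_reads
    if dp == 0:
        return None, 0.0, 0
    f = alt_reads / dp
    if f < 0.2:
        gt = (0, 0)
    elif f <= 0.8:
        gt = (0, 1)
    else:
        gt = (1, 1)
    # binomial log-likelihood of alt_reads under each model's alt fraction
    models = {(0, 0): 0.01, (0, 1): 0.5, (1, 1): 0.99}
    logls = {
        g: alt_reads * math.log(p) + ref_reads * math.log(1 - p)
        for g, p in models.items()
    }
    runner_up = max(v for g, v in logls.items() if g != gt)
    gq = -10.0 * runner_up / math.log(10)
    return gt, gq, dp


def read_genotype_matrix(
    vcf_path: str,
    min_gq: float = DEFAULT_MIN_GQ,
    min_dp: float = DEFAULT_MIN_DP,
    quality_field: str = "GQ",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condense a multi-sample VCF into a coded genotype matrix.

    One VCF sample column per cell barcode; records must be biallelic.
    ``quality_field`` selects the per-sample GQ (default) or the site-level
    QUAL as the quality gate.

    Returns
    -------
    matrix : DataFrame
        Cells x variants with codes in {0,1,2,3}; variant columns are the
        VCF ID when present, else ``CHROM:POS:REF:ALT``.
    variants : DataFrame
        Variant metadata (locus id, chrom, pos, ref, alt).
    """
    import pysam

    vf = pysam.VariantFile(vcf_path)
    cells = list(vf.header.samples)
    columns: list[str] = []
    meta_rows = []
    data: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"record {rec.chrom}:{rec.pos} is not biallelic; split upstream"
            )
        vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
        columns.append(vid)
        meta_rows.append(
            {
                "locus": vid,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
        )
        col = np.empty(len(cells), dtype=np.int8)
        for i, cell in enumerate(cells):
            s = rec.samples[cell]
            gt = s.get("GT")
            if quality_field == "QUAL":
                q = rec.qual
            else:
                q = s.get("GQ")
            dp = s.get("DP")
            col[i] = condense_call(gt, q, dp, min_gq, min_dp)
        data.append(col)
    matrix = pd.DataFrame(
        np.column_stack(data) if data else np.empty((len(cells), 0), dtype=np.int8),
        index=pd.Index(cells, name="cell_barcode"),
        columns=columns,
    )
    return matrix, pd.DataFrame(meta_rows)


def write_genotype_h5(path: str, matrix: pd.DataFrame) -> None:
    """Write the coded genotype matrix to an HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("codes", data=matrix.to_numpy(dtype=np.int8))
        h5.create_dataset(
            "cell_barcodes", data=np.array(matrix.index, dtype="S")
        )
        h5.create_dataset("variants", data=np.array(matrix.columns, dtype="S"))


def read_genotype_h5(path: str) -> pd.DataFrame:
    with h5py.File(path, "r") as h5:
        return pd.DataFrame(
            h5["codes"][()],
            index=pd.Index(
                [b.decode() for b in h5["cell_barcodes"][()]], name="cell_barcode"
            ),
            columns=[b.decode() for b in h5["variants"][()]],
        )
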