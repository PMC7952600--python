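"""Genotype-phenotype concordance statistics.

Two measures of agreement between the genotypic clone partition and the
phenotypic (Leiden) partition of the same cells:

* the adjusted Rand index (ARI), a pair-counting agreement corrected for
  chance under the permutation model;
* the uncertainty coefficient U(X|Y) = I(X;Y) / H(X), the fraction of the
  information in X that is predictable given Y (asymmetric in its
  arguments).

Genotypic clusters are the combined variant call over the configured
relevant loci; cells with a no-call at any relevant locus are dropped
from both label vectors by default (configurable to keep no-call as its
own category). Entropies use plug-in (maximum-likelihood) estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from .genotype_matrix import NO_CALL, assign_clone

__all__ = [
    "adjusted_rand_index",
    "uncertainty_coefficient",
    "genotype_cluster_labels",
    "concordance_report",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same cells.

    Chance-corrected under the permutation model:
    (sum_xy C(n_xy,2) - E) / (0.5*[sum_x C(a_x,2) + sum_y C(b_y,2)] - E)
    with E the expected pair agreement given the marginals. Symmetric,
    bounded by 1, invariant to label renaming.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return float(adjusted_rand_score(a, b))


def uncertainty_coefficient(x_labels, y_labels) -> float:
    """U(X|Y) = I(X;Y) / H(X): information in X predictable from Y.

    Computed from empirical joint frequencies with natural logarithms
    (the ratio is base-free). Raises when H(X) = 0 (a single category in
    X leaves the coefficient undefined).
    """
    x = np.asarray(x_labels)
    y = np.asarray(y_labels)
    if x.shape != y.shape:
        raise ValueError("label vectors differ in length")
    _, x_counts = np.unique(x, return_counts=True)
    hx = float(entropy(x_counts))
    if hx == 0.0:
        raise ValueError("undefined: H(X) = 0 (single category)")
    mi = float(mutual_info_score(x, y))
    return mi / hx


def genotype_cluster_labels(
    gm: pd.DataFrame,
    loci: list[str],
    merge_alternates: bool = True,
    drop_no_call: bool = True,
) -> pd.Series:
    """Per-cell genotypic cluster labels from the coded genotype matrix.

    Delegates to clone assignment over the relevant loci; with
    ``drop_no_call`` cells whose label contains a no-call at any relevant
    locus are excluded (the returned Series covers the remaining cells).
    """
    labels = gm.apply(
        lambda row: assign_clone(row, loci, merge_alternates), axis=1
    )
    if drop_no_call:
        labels = labels[labels.map(lambda t: NO_CALL not in t)]
    return labels


def concordance_report(
    gm: pd.DataFrame,
    loci: list[str],
    pheno_labels: pd.Series,
    merge_alternates: bool = True,
    drop_no_call: bool = True,
) -> dict:
    """ARI and uncertainty coefficients between clones and phenotype clusters.

    Aligns the genotypic clone labels with the phenotypic cluster labels
    on their shared cells and reports ARI, U(genotype|phenotype) and
    U(phenotype|genotype). When either partition has a single category
    the coefficients are reported as not-applicable (None).
    """
    clone = genotype_cluster_labels(gm, loci, merge_alternates, drop_no_call)
    shared = clone.index.intersection(pheno_labels.index)
    clone = clone.loc[shared]
    pheno = pheno_labels.loc[shared]
    out: dict = {"n_cells": int(len(shared)), "loci": list(loci)}
    if len(shared) < 2 or clone.nunique() < 2 or pheno.nunique() < 2:
        out.update(ari=None, u_genotype_given_phenotype=None,
                   u_phenotype_given_genotype=None, applicable=False)
        return out
    clone_ids = clone.map(str).to_numpy()
    pheno_ids = pheno.to_numpy()
    out["ari"] = adjusted_rand_index(clone_ids, pheno_ids)
    out["u_genotype_given_phenotype"] = uncertainty_coefficient(clone_ids, pheno_ids)
    out["u_phenotype_given_genotype"] = uncertainty_coefficient(pheno_ids, clone_ids)
    out["applicable"] = True
    return out
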