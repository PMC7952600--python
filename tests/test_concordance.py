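"""Adjusted Rand index and uncertainty coefficient, with hand-built oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genotag.concordance import (
    adjusted_rand_index,
    concordance_report,
    genotype_cluster_labels,
    uncertainty_coefficient,
)
from genotag.genotype_matrix import NO_CALL


def ari_pair_counting(a, b):
    """ARI by exhaustive enumeration of all item pairs (independent oracle)."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    index = ss
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def labels_from_table(table):
    """Expand a contingency table into two label vectors."""
    a, b = [], []
    for x, row in enumerate(table):
        for y, count in enumerate(row):
            a += [x] * count
            b += [y] * count
    return np.array(a), np.array(b)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        a = [0, 0, 1, 1, 2, 2]
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)

    def test_against_single_cluster_is_zero(self):
        a = [0, 0, 1, 1, 2, 2]
        assert adjusted_rand_index(a, [0] * 6) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle_on_table(self):
        a, b = labels_from_table([[2, 1], [1, 2]])
        assert adjusted_rand_index(a, b) == pytest.approx(ari_pair_counting(a, b))

    def test_matches_oracle_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 4, n)
            if len(set(a)) < 2 and len(set(b)) < 2:
                continue
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_pair_counting(a, b), abs=1e-12
            )

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        remap = {0: "x", 1: "y", 2: "z"}
        a2 = np.array([remap[v] for v in a])
        assert adjusted_rand_index(a2, b) == pytest.approx(adjusted_rand_index(a, b))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0], [0])


def plug_in_u(table):
    """U(X|Y) computed directly from joint frequencies (independent oracle)."""
    table = np.asarray(table, float)
    n = table.sum()
    p = table / n
    px = p.sum(1)
    py = p.sum(0)
    hx = -sum(v * math.log(v) for v in px if v > 0)
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return mi / hx


class TestUncertaintyCoefficient:
    def test_self_information_is_one(self):
        x = [0, 0, 1, 1, 2]
        assert uncertainty_coefficient(x, x) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        x, y = labels_from_table([[4, 4], [4, 4]])
        assert uncertainty_coefficient(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_is_one(self):
        x, y = labels_from_table([[5, 0], [0, 5]])
        assert uncertainty_coefficient(x, y) == pytest.approx(1.0)

    def test_matches_plug_in_oracle(self):
        table = [[4, 1], [1, 4]]
        x, y = labels_from_table(table)
        assert uncertainty_coefficient(x, y) == pytest.approx(plug_in_u(table))

    def test_asymmetric_in_arguments(self):
        # X has 2 categories, Y has 3 and resolves X perfectly but not
        # conversely: U(X|Y) = 1 while U(Y|X) < 1
        x, y = labels_from_table([[3, 3, 0], [0, 0, 6]])
        assert uncertainty_coefficient(x, y) == pytest.approx(1.0)
        assert uncertainty_coefficient(y, x) < 1.0

    def test_single_category_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            uncertainty_coefficient([0, 0, 0], [0, 1, 2])

    def test_relabeling_invariance(self):
        x, y = labels_from_table([[4, 1], [2, 5]])
        x2 = np.array(["a" if v == 0 else "b" for v in x])
        assert uncertainty_coefficient(x2, y) == pytest.approx(
            uncertainty_coefficient(x, y)
        )


class TestGenotypeClusterLabels:
    def _gm(self):
        return pd.DataFrame(
            {
                "L1": [0, 1, 2, 3, 0, 1],
                "L2": [0, 0, 1, 1, 3, 2],
            },
            index=[f"c{i}" for i in range(6)],
        )

    def test_no_call_cells_dropped_by_default(self):
        labels = genotype_cluster_labels(self._gm(), ["L1", "L2"], merge_alternates=False)
        assert len(labels) == 4  # c3 (L1) and c4 (L2) carry a no-call

    def test_no_call_kept_when_requested(self):
        labels = genotype_cluster_labels(
            self._gm(), ["L1", "L2"], merge_alternates=False, drop_no_call=False
        )
        assert len(labels) == 6
        assert any(NO_CALL in t for t in labels)

    def test_merge_mode_shrinks_label_space(self):
        merged = genotype_cluster_labels(self._gm(), ["L1", "L2"], merge_alternates=True)
        unmerged = genotype_cluster_labels(self._gm(), ["L1", "L2"], merge_alternates=False)
        assert len(set(merged)) <= len(set(unmerged))


class TestConcordanceReport:
    def test_single_category_not_applicable(self):
        gm = pd.DataFrame({"L1": [0, 0, 0, 0]}, index=list("abcd"))
        pheno = pd.Series([0, 0, 1, 1], index=list("abcd"))
        rep = concordance_report(gm, ["L1"], pheno)
        assert rep["applicable"] is False
        assert rep["ari"] is None

    def test_perfect_correspondence(self):
        gm = pd.DataFrame({"L1": [0] * 10 + [1] * 10}, index=[f"c{i}" for i in range(20)])
        pheno = pd.Series([5] * 10 + [9] * 10, index=gm.index)
        rep = concordance_report(gm, ["L1"], pheno)
        assert rep["ari"] == pytest.approx(1.0)
        assert rep["u_genotype_given_phenotype"] == pytest.approx(1.0)


def test_simulated_concordance_recovers_planted_structure(small_run):
    """Clean three-population mixture: clones and phenotype clusters agree."""
    from genotag.genotype_matrix import read_genotype_matrix
    from genotag.phenotype_clustering import cluster

    gm, _ = read_genotype_matrix(small_run["vcf"])
    asg = cluster(small_run["u"], resolution=0.1, seed=0)
    rep = concordance_report(gm, list(gm.columns), asg.labels)
    assert rep["applicable"]
    assert rep["ari"] >= 0.9
    assert rep["u_genotype_given_phenotype"] >= 0.9
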