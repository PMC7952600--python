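"""Shared fixtures: small synthetic experiments reused across test modules."""

from __future__ import annotations

import warnings

import pytest

from genotag.antibody_correction import (
    build_design,
    build_quality_matrix,
    correct_counts,
    transform_counts,
)
from genotag.scenarios import get_scenario
from genotag.synthetic_data import (
    default_amplicon_panel,
    default_panel,
    default_schema,
    default_whitelist,
    emit_dna_fixtures,
    simulate_truth,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def whitelist():
    return default_whitelist()


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Three-population scenario at reduced size, truth through correction.

    Returns a dict with the scenario, truth table, amplicon depth table,
    VCF path, quality matrix and corrected matrix; computed once per
    session because several modules exercise the same artifacts.
    """
    tmp = tmp_path_factory.mktemp("small_run")
    sc = get_scenario("three_populations", scale=0.15)
    truth = simulate_truth(sc.populations, sc.tech, seed=0)
    vcf = str(tmp / "cells.vcf")
    depths = emit_dna_fixtures(truth, default_amplicon_panel(), sc.tech, vcf, seed=0)
    cells = truth.cells.index
    q = build_quality_matrix(
        truth.counts.sum(axis=1),
        truth.counts.sum(axis=1),
        truth.counts["IgG1"],
        depths.loc[cells].sum(axis=1),
    )
    design = build_design(q, 3)
    u = correct_counts(transform_counts(truth.counts), design)
    return {
        "scenario": sc,
        "truth": truth,
        "depths": depths,
        "vcf": vcf,
        "q": q,
        "design": design,
        "u": u,
    }


@pytest.fixture(scope="session")
def gradient_run(tmp_path_factory):
    """Blast-gradient scenario at reduced size, truth through correction."""
    tmp = tmp_path_factory.mktemp("gradient_run")
    sc = get_scenario("blast_gradient", scale=0.25)
    truth = simulate_truth(sc.populations, sc.tech, seed=0)
    vcf = str(tmp / "cells.vcf")
    depths = emit_dna_fixtures(truth, default_amplicon_panel(), sc.tech, vcf, seed=0)
    cells = truth.cells.index
    q = build_quality_matrix(
        truth.counts.sum(axis=1),
        truth.counts.sum(axis=1),
        truth.counts["IgG1"],
        depths.loc[cells].sum(axis=1),
    )
    u = correct_counts(transform_counts(truth.counts), build_design(q, 3))
    return {"scenario": sc, "truth": truth, "depths": depths, "vcf": vcf, "u": u}
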