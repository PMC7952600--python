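"""Bundled simulation scenarios.

Two desk-scale study designs ship with the package:

``three_populations``
    A clean mixture of three well-separated populations with distinct
    driver genotypes and marker profiles — the synthetic analogue of a
    cell-line mixing experiment. Used to demonstrate parameter recovery:
    phenotype clusters and genotype clones should coincide almost
    perfectly.

``blast_gradient``
    Two mutually exclusive mutant blast clones sharing one
    immunophenotypic continuum (identical base profile, common antibody
    slopes over a latent position, overlapping position ranges, the
    mutant clones enriched at opposite ends) plus a separated wild-type
    lymphoid population. Used for the gradient analysis: ordering blast
    cells by the second left-singular vector of the corrected antibody
    matrix should recover the latent position, with rising and falling
    markers and opposite clone-fraction trends along it.

Scenario sizes (~3,000 cells) are desk-scale choices that keep full runs
in the minutes range while leaving every planted effect clearly
resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synthetic_data import PopulationSpec, TechModel

__all__ = ["Scenario", "three_populations", "blast_gradient", "get_scenario"]

# sample-type presets mirroring the analysis parameterisation:
# number of retained singular vectors, UMAP min_dist, Leiden resolution
SAMPLE_TYPE_PRESETS = {
    "patient": {"n_vectors": 3, "min_dist": 0.1, "resolution": 1.0},
    "pbmc": {"n_vectors": 2, "min_dist": 0.2, "resolution": 1.0},
    "cell_lines": {"n_vectors": 1, "min_dist": 0.2, "resolution": 0.1},
}


@dataclass
class Scenario:
    name: str
    populations: list[PopulationSpec]
    tech: TechModel
    sample_type: str  # patient | pbmc | cell_lines
    relevant_loci: list[str]
    merge_alternates: bool
    blast_populations: list[str] = field(default_factory=list)

    @property
    def presets(self) -> dict:
        return SAMPLE_TYPE_PRESETS[self.sample_type]

    @property
    def n_cells(self) -> int:
        return sum(p.n_cells for p in self.populations)


def three_populations(scale: float = 1.0) -> Scenario:
    """Clean three-population mixture with one driver mutation each.

    ``scale`` shrinks every population proportionally for fast tests.
    """
    base = {a: 3.0 for a in ("CD33", "CD38", "CD34", "CD11b", "CD15", "CD56", "CD3")}
    base["CD45"] = 6.0
    base["IgG1"] = 1.5

    def prof(**high: float) -> dict[str, float]:
        p = dict(base)
        p.update(high)
        return p

    n = lambda k: max(20, int(round(k * scale)))
    pops = [
        PopulationSpec(
            "KRAS_clone", n(1000), {"KRAS_G13D": 1},
            prof(CD33=5.2, CD38=5.0), dispersion=0.15,
        ),
        PopulationSpec(
            "FLT3_clone", n(1000), {"FLT3_D835Y": 1},
            prof(CD11b=5.2, CD15=5.0), dispersion=0.15,
        ),
        PopulationSpec(
            "wildtype", n(1000), {},
            prof(CD3=5.2, CD56=5.0), dispersion=0.15,
        ),
    ]
    tech = TechModel(
        depth_sigma=0.35,
        ambient_per_droplet=0.0,
        allele_dropout=0.05,
        n_empty_droplets=max(60, int(3000 * scale)),
        empty_depth_mean=2.0,
        reads_per_molecule=1.0,
        dna_mean_depth=100.0,
    )
    return Scenario(
        name="three_populations",
        populations=pops,
        tech=tech,
        sample_type="cell_lines",
        relevant_loci=["KRAS_G13D", "FLT3_D835Y"],
        merge_alternates=True,
    )


def blast_gradient(scale: float = 1.0) -> Scenario:
    """Two mutant blast clones on one immunophenotypic continuum + wild type."""
    # sloped markers come in endpoint-balanced falling/rising pairs and the
    # CD45 anchor dominates library size, so total molecule count stays
    # nearly flat along the gradient (phenotype change, not depth change)
    blast = {
        "CD45": 7.6, "CD33": 5.3, "CD38": 4.1, "CD34": 3.6, "CD11b": 5.5,
        "CD15": 3.4, "CD56": 5.2, "CD3": 2.0, "IgG1": 1.5,
    }
    slopes = {
        "CD11b": -2.1, "CD56": -1.6, "CD33": -1.2,
        "CD15": 2.1, "CD34": 1.6, "CD38": 1.2,
    }
    normal = {
        "CD45": 7.6, "CD33": 1.0, "CD38": 1.5, "CD34": 1.0, "CD11b": 1.0,
        "CD15": 1.0, "CD56": 1.5, "CD3": 6.0, "IgG1": 1.5,
    }
    n = lambda k: max(30, int(round(k * scale)))
    pops = [
        PopulationSpec(
            "KRAS_blast", n(1200), {"KRAS_G13D": 1}, dict(blast),
            dispersion=0.10, gradient_slopes=dict(slopes),
            position_range=(0.0, 0.6),
        ),
        PopulationSpec(
            "FLT3_blast", n(1200), {"FLT3_D835Y": 1}, dict(blast),
            dispersion=0.10, gradient_slopes=dict(slopes),
            position_range=(0.4, 1.0),
        ),
        PopulationSpec(
            "normal", n(1200), {}, normal, dispersion=0.15,
        ),
    ]
    tech = TechModel(
        depth_sigma=0.35,
        ambient_per_droplet=0.0,
        allele_dropout=0.05,
        n_empty_droplets=max(60, int(3000 * scale)),
        reads_per_molecule=1.0,
        dna_mean_depth=100.0,
    )
    return Scenario(
        name="blast_gradient",
        populations=pops,
        tech=tech,
        sample_type="patient",
        relevant_loci=["KRAS_G13D", "FLT3_D835Y"],
        merge_alternates=True,
        blast_populations=["KRAS_blast", "FLT3_blast"],
    )


_SCENARIOS = {
    "three_populations": three_populations,
    "blast_gradient": blast_gradient,
}


def get_scenario(name: str, scale: float = 1.0) -> Scenario:
    try:
        return _SCENARIOS[name](scale)
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        ) from None
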