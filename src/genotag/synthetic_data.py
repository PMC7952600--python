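"""Synthetic droplet-experiment generator with planted genotype-phenotype structure.

Generates everything the pipeline consumes — paired antibody-library
FASTQ reads, per-cell amplicon depth tables, a multi-sample VCF of
per-cell calls, whitelists, panels and BED intervals — from explicit
population specifications, together with a truth table recording every
planted quantity. This makes every pipeline stage testable offline, with
known answers.

Model
-----
Each population has fixed per-locus genotypes, a mean log antibody
profile, a log-normal per-cell dispersion, and optionally linear antibody
slopes over a latent within-population gradient position in [0, 1].
Molecule counts are Poisson with log-mean

    profile_j + slope_j * position + cell jitter + log(depth factor),

so every antibody shares a per-cell technical depth factor — exactly the
confounder the quality-metric regression assumes it can remove. DNA
amplicon depths scale with the same depth factor. Allele dropout converts
heterozygous sites to homozygous reads upstream of the toy caller.

UMIs within one (cell, antibody) group are assigned at pairwise Hamming
distance >= 2: the generator's idealisation of molecule identity, under
which adjacency deduplication at zero sequencing-error rate is exactly
information-preserving.

All randomness flows from one seed through named substreams (truth /
antibody_reads / dna), so fixed seeds reproduce every file byte for byte.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotype_matrix import HET_ALT, HOM_ALT, WILD_TYPE, toy_pileup_genotype
from .read_structure import AntibodyPanel, BarcodeSchema, Whitelist, hamming

__all__ = [
    "PopulationSpec",
    "TechModel",
    "LocusSpec",
    "TruthTable",
    "simulate_truth",
    "emit_antibody_reads",
    "emit_dna_fixtures",
    "default_schema",
    "default_whitelist",
    "default_panel",
    "default_amplicon_panel",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class LocusSpec:
    """A targeted variant site: name plus its VCF coordinates."""

    name: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class PopulationSpec:
    """One planted cell population (clone) with genotype and phenotype."""

    name: str
    n_cells: int
    genotypes: dict[str, int]  # locus name -> 0/1/2
    mean_log_profile: dict[str, float]  # antibody -> mean of log molecule count
    dispersion: float = 0.15  # per-cell log-normal jitter (sd, log scale)
    gradient_slopes: dict[str, float] = field(default_factory=dict)
    # latent-position distribution within [0,1]; clones along a shared
    # continuum can occupy different sub-ranges
    position_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("population cell count must be positive")
        for g in self.genotypes.values():
            if g not in (WILD_TYPE, HET_ALT, HOM_ALT):
                raise ValueError("planted genotypes must be 0, 1 or 2")


@dataclass
class TechModel:
    """Technical noise model shared by all populations of a run."""

    depth_sigma: float = 0.35  # sd of log depth factor (log-normal, mean log 0)
    ambient_per_droplet: float = 0.0  # expected ambient tag molecules per barcode
    barcode_sub_rate: float = 0.0  # per-read prob of one substitution in Read 1
    umi_sub_rate: float = 0.0  # per-read prob of one substitution in the UMI
    allele_dropout: float = 0.0  # per het site per cell
    n_empty_droplets: int = 0
    empty_depth_mean: float = 2.0  # amplicon reads per interval, empty droplets
    reads_per_molecule: float = 1.0  # mean amplification copies (>= 1)
    dna_mean_depth: float = 60.0  # per-site coverage scale for genotyping
    dna_site_error: float = 0.001  # alt fraction at hom-ref sites

    def __post_init__(self) -> None:
        for r in (self.barcode_sub_rate, self.umi_sub_rate, self.allele_dropout):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_sigma < 0 or self.reads_per_molecule < 1:
            raise ValueError("invalid technical model")


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment."""

    cells: pd.DataFrame  # per-cell: barcode, population, position, depth_factor
    genotypes_planted: pd.DataFrame  # cells x loci, codes 0/1/2
    genotypes_observed: pd.DataFrame  # after allele dropout
    counts: pd.DataFrame  # cells x antibodies, planted molecule counts
    log_mean: pd.DataFrame  # cells x antibodies, Poisson log-means
    loci: list[LocusSpec]
    empty_barcodes: list[str]
    panel: AntibodyPanel
    seed: int

    def self_check(self) -> None:
        """Internal consistency of the truth table."""
        assert list(self.cells.index) == list(self.counts.index)
        assert (self.counts.to_numpy() >= 0).all()
        assert set(self.genotypes_planted.columns) == {l.name for l in self.loci}
        assert self.genotypes_planted.shape == self.genotypes_observed.shape
        # dropout only moves het calls
        moved = self.genotypes_planted != self.genotypes_observed
        assert (self.genotypes_planted.to_numpy()[moved.to_numpy()] == HET_ALT).all()
        assert not set(self.empty_barcodes) & set(self.cells.index)

    def write_tsv(self, path: str) -> None:
        df = self.cells.copy()
        for l in self.loci:
            df[f"planted_{l.name}"] = self.genotypes_planted[l.name]
            df[f"observed_{l.name}"] = self.genotypes_observed[l.name]
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bundled synthetic schema, whitelist, panels


def default_schema() -> BarcodeSchema:
    """Two 9 bp combinatorial segments with a fixed adapter and linker."""
    return BarcodeSchema(
        segment_lengths=(9, 9),
        linker_sequences=("GTACTCGC",),
        adapter_5p="CGATGT",
    )


@lru_cache(maxsize=None)
def _whitelist_segment(n_entries: int, length: int, seed: int) -> tuple[str, ...]:
    # greedy minimum-distance-3 code so Hamming-1 correction is unambiguous
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    attempts = 0
    while len(kept) < n_entries:
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("could not build whitelist segment")
        cand = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, k) >= 3 for k in kept):
            kept.append(cand)
    return tuple(kept)


def default_whitelist(n_per_segment: int = 192) -> Whitelist:
    """Deterministic synthetic whitelist: two 9 bp segments, min distance 3."""
    return Whitelist(
        [
            _whitelist_segment(n_per_segment, 9, 11),
            _whitelist_segment(n_per_segment, 9, 13),
        ]
    )


def default_panel() -> AntibodyPanel:
    """Synthetic 9-antibody myeloid-flavoured panel incl. an IgG1 isotype control.

    Tag sequences are two 4-base blocks, giving pairwise Hamming
    distance >= 4. CD45 plays the pan-leukocyte anchor present at high
    level on every population.
    """
    return AntibodyPanel(
        [
            ("CD45", "AAAATTTT", False),
            ("CD33", "AAAACCCC", False),
            ("CD38", "CCCCAAAA", False),
            ("CD34", "GGGGTTTT", False),
            ("CD11b", "TTTTGGGG", False),
            ("CD15", "AAAAGGGG", False),
            ("CD56", "CCCCTTTT", False),
            ("CD3", "GGGGAAAA", False),
            ("IgG1", "TTTTCCCC", True),
        ]
    )


def default_amplicon_panel(n_intervals: int = 49) -> pd.DataFrame:
    """Synthetic amplicon BED-style interval table (0-based half-open)."""
    starts = 1000 + 500 * np.arange(n_intervals)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + 250,
            "name": [f"AMP{i:03d}" for i in range(n_intervals)],
        }
    )


def default_loci() -> list[LocusSpec]:
    """Two relevant loci emulating mutually exclusive driver mutations."""
    return [
        LocusSpec("KRAS_G13D", "chr1", 1105, "G", "A"),
        LocusSpec("FLT3_D835Y", "chr1", 2610, "G", "T"),
    ]


# ---------------------------------------------------------------------------
# truth simulation


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("truth", "antibody_reads", "dna")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_barcodes(
    rng: np.random.Generator, wl: Whitelist, n: int
) -> list[str]:
    seg1 = sorted(wl.segments[0])
    seg2 = sorted(wl.segments[1])
    total = len(seg1) * len(seg2)
    if n > total:
        raise ValueError(f"whitelist supports only {total} barcodes, need {n}")
    idx = rng.choice(total, size=n, replace=False)
    return [seg1[i // len(seg2)] + seg2[i % len(seg2)] for i in idx]


def simulate_truth(
    populations: list[PopulationSpec],
    tech: TechModel,
    seed: int,
    panel: AntibodyPanel | None = None,
    loci: list[LocusSpec] | None = None,
    whitelist: Whitelist | None = None,
) -> TruthTable:
    """Draw the per-cell ground truth of one synthetic experiment.

    Records each cell's barcode, population, latent gradient position,
    depth factor, genotypes before and after allele dropout, the Poisson
    log-means and the realised planted molecule counts per antibody.
    """
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("duplicate population names")
    panel = panel or default_panel()
    loci = loci if loci is not None else default_loci()
    whitelist = whitelist or default_whitelist()
    rng = _substreams(seed)["truth"]

    n_cells = sum(p.n_cells for p in populations)
    barcodes = _draw_barcodes(
        rng, whitelist, n_cells + tech.n_empty_droplets
    )
    cell_bcs, empty_bcs = barcodes[:n_cells], barcodes[n_cells:]

    rows = []
    planted = np.zeros((n_cells, len(loci)), dtype=np.int8)
    observed = np.zeros_like(planted)
    log_mean = np.zeros((n_cells, len(panel)), dtype=float)
    i = 0
    for pop in populations:
        missing = set(pop.mean_log_profile) - set(panel.names)
        if missing:
            raise ValueError(f"profile antibodies not in panel: {missing}")
        for _ in range(pop.n_cells):
            lo, hi = pop.position_range
            position = float(rng.uniform(lo, hi))
            depth = float(np.exp(rng.normal(0.0, tech.depth_sigma)))
            jitter = float(rng.normal(0.0, pop.dispersion))
            for j, ab in enumerate(panel.names):
                base = pop.mean_log_profile.get(ab, 0.0)
                slope = pop.gradient_slopes.get(ab, 0.0)
                log_mean[i, j] = base + slope * position + jitter + np.log(depth)
            for v, locus in enumerate(loci):
                g = pop.genotypes.get(locus.name, WILD_TYPE)
                planted[i, v] = g
                if g == HET_ALT and rng.random() < tech.allele_dropout:
                    observed[i, v] = WILD_TYPE if rng.random() < 0.5 else HOM_ALT
                else:
                    observed[i, v] = g
            rows.append(
                {
                    "cell_barcode": cell_bcs[i],
                    "population": pop.name,
                    "position": position,
                    "depth_factor": depth,
                }
            )
            i += 1

    cells = pd.DataFrame(rows).set_index("cell_barcode")
    counts = rng.poisson(np.exp(log_mean))
    locus_names = [l.name for l in loci]
    truth = TruthTable(
        cells=cells,
        genotypes_planted=pd.DataFrame(
            planted, index=cells.index, columns=locus_names
        ),
        genotypes_observed=pd.DataFrame(
            observed, index=cells.index, columns=locus_names
        ),
        counts=pd.DataFrame(counts, index=cells.index, columns=panel.names),
        log_mean=pd.DataFrame(log_mean, index=cells.index, columns=panel.names),
        loci=list(loci),
        empty_barcodes=empty_bcs,
        panel=panel,
        seed=seed,
    )
    truth.self_check()
    return truth


# ---------------------------------------------------------------------------
# read emission


def _spaced_umis(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    """n UMIs at pairwise Hamming distance >= 2 (rejection sampling).

    Two sequences at distance <= 1 share a single-position-masked key, so
    rejection only needs a key-set lookup.
    """
    kept: list[str] = []
    masked: set[str] = set()
    while len(kept) < n:
        cand = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        keys = [cand[:i] + "\x00" + cand[i + 1 :] for i in range(length)]
        if any(k in masked for k in keys):
            continue
        kept.append(cand)
        masked.update(keys)
    return kept


def _mutate(rng: np.random.Generator, seq: str) -> str:
    """One random substitution at a random position."""
    pos = int(rng.integers(0, len(seq)))
    choices = [b for b in _BASES if b != seq[pos]]
    new = choices[int(rng.integers(0, 3))]
    return seq[:pos] + new + seq[pos + 1 :]


def emit_antibody_reads(
    truth: TruthTable,
    r1_path: str,
    r2_path: str,
    schema: BarcodeSchema | None = None,
    tech: TechModel | None = None,
    seed: int | None = None,
) -> int:
    """Write paired antibody-library FASTQ files for a simulated truth.

    One read pair per molecule per amplification copy; UMIs are distinct
    (pairwise Hamming >= 2) within each (cell, antibody) group;
    substitution errors and ambient molecules are injected at the
    configured rates. Returns the number of read pairs written.
    """
    schema = schema or default_schema()
    tech = tech or TechModel()
    rng = _substreams(seed if seed is not None else truth.seed)["antibody_reads"]
    panel = truth.panel
    linker = schema.linker_sequences[0] if schema.linker_sequences else ""
    seg_len = schema.segment_lengths[0]

    def r1_for(barcode: str) -> str:
        s1, s2 = barcode[:seg_len], barcode[seg_len:]
        seq = schema.adapter_5p + s1 + linker + s2
        if tech.barcode_sub_rate and rng.random() < tech.barcode_sub_rate:
            # substitution within the barcode segments only
            mutated = _mutate(rng, barcode)
            seq = schema.adapter_5p + mutated[:seg_len] + linker + mutated[seg_len:]
        return seq

    def _open_out(path: str):
        # pin the gzip mtime so identical runs give identical bytes
        if str(path).endswith(".gz"):
            import io

            return io.TextIOWrapper(
                gzip.GzipFile(path, mode="wb", mtime=0), encoding="ascii"
            )
        return open(path, "w")

    n_pairs = 0
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:

        def write_pair(barcode: str, tag: str, umi: str) -> None:
            nonlocal n_pairs
            n_pairs += 1
            seq1 = r1_for(barcode)
            umi_out = umi
            if tech.umi_sub_rate and rng.random() < tech.umi_sub_rate:
                umi_out = _mutate(rng, umi)
            seq2 = tag + umi_out
            f1.write(f"@r{n_pairs}/1\n{seq1}\n+\n{'I' * len(seq1)}\n")
            f2.write(f"@r{n_pairs}/2\n{seq2}\n+\n{'I' * len(seq2)}\n")

        tag_by_name = dict(zip(panel.names, panel.tags))
        for barcode, row in truth.counts.iterrows():
            for ab in panel.names:
                n_mol = int(row[ab])
                if n_mol == 0:
                    continue
                umis = _spaced_umis(rng, n_mol)
                for umi in umis:
                    copies = (
                        1
                        if tech.reads_per_molecule == 1
                        else 1 + int(rng.poisson(tech.reads_per_molecule - 1))
                    )
                    for _ in range(copies):
                        write_pair(barcode, tag_by_name[ab], umi)

        if tech.ambient_per_droplet > 0:
            droplets = list(truth.counts.index) + list(truth.empty_barcodes)
            for barcode in droplets:
                for _ in range(int(rng.poisson(tech.ambient_per_droplet))):
                    ab = panel.names[int(rng.integers(0, len(panel)))]
                    umi = "".join(_BASES[i] for i in rng.integers(0, 4, size=10))
                    write_pair(barcode, tag_by_name[ab], umi)
    return n_pairs


# ---------------------------------------------------------------------------
# DNA fixtures


def emit_dna_fixtures(
    truth: TruthTable,
    amplicon_panel: pd.DataFrame,
    tech: TechModel,
    vcf_path: str,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell amplicon depth table plus a multi-sample VCF of toy calls.

    Interval depths are Poisson around the cell's depth factor times the
    model's mean DNA depth; empty droplets draw around the empty-droplet
    mean. Per-locus ref/alt read counts follow the post-dropout genotype
    (alt fraction ~ site error rate, 0.5, or 1 - site error rate) and are
    passed through the toy pileup genotyper to populate GT/GQ/DP.

    Returns the depth table (barcodes x interval names, cells first).
    """
    rng = _substreams(seed if seed is not None else truth.seed)["dna"]
    intervals = list(amplicon_panel["name"])
    cells = list(truth.cells.index)
    barcodes = cells + list(truth.empty_barcodes)
    depth_scale = np.concatenate(
        [
            truth.cells["depth_factor"].to_numpy() * tech.dna_mean_depth,
            np.full(len(truth.empty_barcodes), tech.empty_depth_mean),
        ]
    )
    depths = rng.poisson(depth_scale[:, None], size=(len(barcodes), len(intervals)))
    depth_table = pd.DataFrame(depths, index=pd.Index(barcodes, name="cell_barcode"),
                               columns=intervals)

    alt_frac = {
        WILD_TYPE: tech.dna_site_error,
        HET_ALT: 0.5,
        HOM_ALT: 1.0 - tech.dna_site_error,
    }
    with open(vcf_path, "w") as vf:
        vf.write("##fileformat=VCFv4.2\n")
        vf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        vf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        vf.write("##contig=<ID=chr1>\n")
        vf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cells)
            + "\n"
        )
        for v, locus in enumerate(truth.loci):
            fields = []
            for i, cell in enumerate(cells):
                dp = int(rng.poisson(truth.cells["depth_factor"].iloc[i] * tech.dna_mean_depth))
                g = int(truth.genotypes_observed.iloc[i, v])
                alt = int(rng.binomial(dp, alt_frac[g])) if dp > 0 else 0
                gt, gq, dp_out = toy_pileup_genotype(dp - alt, alt)
                if gt is None:
                    fields.append("./.:0:0")
                else:
                    gt_s = f"{gt[0]}/{gt[1]}"
                    fields.append(f"{gt_s}:{min(int(round(gq)), 99)}:{dp_out}")
            vf.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.name}\t{locus.ref}\t"
                f"{locus.alt}\t.\tPASS\t.\tGT:GQ:DP\t" + "\t".join(fields) + "\n"
            )
    return depth_table
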