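# genotag

Joint single-cell DNA genotyping and antibody-based immunophenotyping from
droplet sequencing reads.

Droplet platforms that amplify a targeted DNA panel and capture barcoded
antibodies in the same cell produce two read libraries per experiment:
Read 1 carries a combinatorial cell barcode, and Read 2 carries either a
genomic amplicon or an 8 bp antibody tag followed by a 10 bp unique
molecular identifier (UMI). `genotag` turns such reads into per-cell
genotype and corrected surface-protein matrices and quantifies how well
the *genetic* clones of a sample map onto its *immunophenotypic*
clusters — the central question in, for example, tracking leukemic blast
populations across therapy.

The package is written for computational biologists who want the full
pipeline as an importable library (every stage is a plain function on
pandas/AnnData objects), with a thin `genotag` CLI for shell-driven runs
and a synthetic-data generator that plants known genotype–phenotype
structure so every stage can be validated offline.

## What it computes

1. **Read parsing** — combinatorial cell barcodes are matched per segment
   to a whitelist within Hamming distance 1 (ambiguous matches are
   discarded); antibody tags are corrected the same way against the panel
   (tags are validated at pairwise distance ≥ 3); UMIs require Phred ≥ 20
   on every base.
2. **UMI deduplication** — the adjacency network method: a directed edge
   *a → b* joins UMIs at Hamming distance 1 when
   count(*a*) ≥ 2·count(*b*) − 1, and molecules are counted by greedy
   selection of nodes (descending count) until every UMI is selected or
   one step from a selected node. This yields the count matrix
   **c** (cells × antibodies).
3. **Cell calling** — knee of the log–log barcode rank curve (maximum
   distance to the endpoint chord) AND ≥ 60% of panel intervals covered by
   ≥ 8 reads AND ≥ 100 antibody UMIs with isotype-control (IgG1) count
   ≤ 5× the experiment median.
4. **Genotype condensation** — per-cell VCF calls become codes
   0 (wild type), 1 (het), 2 (hom alt), 3 (no call); calls with GQ < 30 or
   DP < 10 are no-calls. Clones are the combined call over the relevant
   loci; for patient-style analyses het and hom-alt merge into one
   "mutant" state (two loci: 16 labels unmerged, 9 merged).
5. **Antibody correction** — log(**c**+1) columns are regressed on the
   leading left-singular vectors (3 / 2 / 1 for patient / PBMC /
   cell-line samples) of the per-cell quality matrix **q** (total antibody
   reads, deduplicated counts, IgG1 count, total amplicon reads;
   log-transformed, z-scored). The residual matrix **u** is the corrected
   signal.
6. **Clustering & concordance** — PCA → k-NN graph → UMAP embedding and
   Leiden communities of **u**; agreement between clone labels X and
   cluster labels Y via the adjusted Rand index and the uncertainty
   coefficient U(X|Y) = I(X;Y)/H(X).
7. **Gradient analysis** — blast-cluster cells are ordered by their entry
   in the second left-singular vector of **u** restricted to the blast
   compartment; antibody expression, clone composition and UMAP positions
   are profiled with a 200-cell moving window, with Pearson r (smoothed
   profiles) and Kendall τ (per-cell clone indicators) against gradient
   position, and a cubic spline through the smoothed embedding.

## Worked example

`examples/03_correct_cluster_concordance.py` simulates a clean
three-population mixture (three clones with distinct driver mutations and
marker profiles, log-normal per-cell depth, 5% allele dropout), corrects
and clusters the antibody counts, and compares clusters with clones:

```
cells: 900, Leiden clusters: 3
ARI(clones, clusters)        = 0.957
U(genotype | phenotype)      = 0.939
U(phenotype | genotype)      = 0.938
```

An ARI of 0.96 means the genetic clones and the antibody-defined clusters
partition the cells almost identically (1.0 = identical up to label
names); the residual gap comes from allele-dropout mislabelling, not from
clustering error. `examples/04_gradient_analysis.py` runs the
blast-continuum scenario instead:

```
blast cells ordered: 1200
|Kendall tau| vs latent position: 0.932
marker correlations along the gradient (Pearson r on smoothed profiles):
  CD15   r = +0.985
  CD34   r = +0.977
  CD11b  r = -0.983
  CD56   r = -0.977
clone-fraction trends (Kendall tau on per-cell indicators):
  KRAS_blast  tau = -0.614
  FLT3_blast  tau = +0.614
```

The opposite clone signs show two mutually exclusive mutant clones
occupying opposite ends of a single continuous immunophenotype — the
situation in which cluster-level concordance statistics break down and
the gradient view is needed.

The other examples cover read parsing/counting round-trips
(`01_simulate_parse_count.py`), cell calling (`02_cell_calling.py`) and
the shell pipeline (`05_cli_pipeline.sh`, using `genotag run-all`).

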