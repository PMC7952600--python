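# Methods

This note documents the models, parameter choices and numerical details
behind `genotag`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Read structure and barcode correction

Read 1 is modelled as a fixed 5' adapter, barcode segments and fixed
linker sequences at fixed offsets; the bundled synthetic schema uses two
9 bp segments. Platform whitelists and barcode layouts vary, so both are
configuration, not constants. Each segment is corrected independently:
exact whitelist matches resolve at distance 0, otherwise the unique entry
within Hamming distance 1 is taken. When two or more entries are
equidistant the read is discarded rather than assigned at random — random
assignment would create chimeric cells, and a whitelist with pairwise
distance ≥ 3 (validated at load, and guaranteed by the bundled greedy
minimum-distance-3 whitelist) makes ambiguity impossible anyway. Quality
strings are Phred+33; all ten UMI bases must reach Q20. Indel-tolerant
matching is out of scope: droplet barcode errors are dominated by
substitutions, and the fixed-offset schema would misparse after an indel
regardless.

## UMI adjacency deduplication

For one (cell, antibody) group, a directed edge a→b joins UMIs at Hamming
distance 1 when count(a) ≥ 2·count(b) − 1 (the asymmetric threshold that
separates true molecules from PCR/sequencing offspring of a more abundant
UMI). Molecules are counted by greedily selecting nodes in descending
read count until every node is selected or one adjacency step from a
selected node. The published rule leaves ties unspecified; ties are
broken lexicographically so counts are reproducible. Note that the greedy
count is not always the minimum covering selection (a Hamming-1 chain of
five singleton UMIs yields three under lexicographic greedy but two at
minimum); the greedy discipline *is* the method, and the test suite
checks both equivalence with an independently coded replay of the rule
and the bracketing property (minimum cover ≤ greedy ≤ distinct UMIs).
Neighbour pairs are found by single-position masking (O(k·L) buckets)
rather than all-pairs scanning; the result is identical.

## Cell calling

Candidates are barcodes above the knee of the log10(rank)–log10(reads)
curve, located at the maximum perpendicular distance to the chord joining
the curve's endpoints — deterministic and parameter-free. Two properties
matter in practice. First, the detector needs a real cliff: curves whose
dynamic range is below 10× raise "no knee" instead of guessing, and an
exactly collinear (e.g. two-point) curve splits at the geometric mean of
its endpoints. Second, when per-cell depth is spread log-normally the
maximum-distance point sits slightly *inside* the sloping cell arc, so
recall is conservative (roughly 70% of cells at the bundled scenario's
depth spread of σ = 0.35, >99% on a tight-Poisson curve) while the
ambient false-positive rate stays ≈ 0. Cell calling is then the AND of
three rules: the knee, ≥ 60% of panel intervals covered by ≥ 8 reads, and
antibody QC (≥ 100 total UMIs; isotype count ≤ 5× the experiment median,
boundary inclusive). The isotype median is computed over knee candidates
only: ambient barcodes are far more numerous than cells and would drag
the median toward zero, making the 5× rule spuriously strict.

## Genotype condensation and clones

VCF ingestion expects one sample column per cell barcode and biallelic,
left-aligned records; anything else is rejected rather than silently
normalized. Calls become codes 0/1/2/3 (wild type, het, hom alt, no
call); a call with GQ < 30 or DP < 10 becomes a no-call. "Quality"
defaults to the per-sample GQ with site QUAL available as an option,
since per-cell filtering is the point of the thresholds. Clone labels are
tuples of per-locus states over the configured relevant loci; in merged
mode {het, hom alt} collapse to "mutant", which absorbs the main effect
of allele dropout (a het cell that drops an allele is still "mutant"
unless it drops to the reference, so the residual mislabelling rate is
about half the dropout rate). Cells with a no-call at any relevant locus
are excluded from concordance statistics by default (configurable): a
no-call is missing data, not a clone.

The bundled `toy_pileup_genotype` is a deliberately simple caller used
only so synthetic end-to-end runs need no alignment stack: genotype by
alt-read fraction (< 0.2 / 0.2–0.8 / > 0.8) and a quality score from the
binomial log-likelihood of the runner-up model. It is not a substitute
for a production caller and is labelled accordingly.

## Antibody-count correction

Counts get one pseudocount and a natural log. The per-cell quality
matrix **q** (total antibody reads, deduplicated counts, isotype count,
total amplicon reads) is log1p-transformed, scaled to unit standard
deviation per column, mean-centred and decomposed by SVD; each antibody
column of log(**c**+1) is regressed (OLS) on the first 1–3 left-singular
vectors plus an intercept, and the residuals **u** are the corrected
signal. Choices worth recording:

* "column-wise normalized" is implemented as unit-SD scaling (z-score);
  unit-L2 scaling differs only by a per-column scalar and leaves the
  singular subspace, hence the residuals, unchanged.
* scale-then-centre vs centre-then-scale are identical for z-scoring.
* An intercept is always included even though the method description
  lists only singular-vector regressors: without it residual columns are
  not mean-free and downstream PCA shifts. It is toggleable.
* **q** uses the same pseudocount convention as **c** because isotype
  counts can be zero.
* All cells of one patient (all timepoints) are corrected jointly; batch
  differences between timepoints are exactly what the regression absorbs.
* The retained-vector count follows sample type (patient 3, PBMC 2, cell
  lines 1), reflecting how many technical axes the quality matrix of each
  design actually carries.

A structural caveat: any *biological* signal that co-varies with library
size lies partly in the span of **q** and is partly removed. The
correction trades a small amount of real signal for removal of the depth
confounder; the gradient scenario below is constructed so this trade-off
is small, which is also the regime in which the method is trustworthy on
real data.

## Embedding, clustering, concordance

PCA (first 16 components by default, or all) → k-nearest-neighbour graph
(15 neighbours, Euclidean metric on component scores) → UMAP (min_dist
0.1 for the gradient-style analysis, 0.2 otherwise) → Leiden (resolution
0.1 for the well-separated cell-line-style mixture, 1 otherwise). Seeds
are mandatory; a fixed seed reproduces coordinates and labels exactly.
Resolution → 0 collapses to one community per *connected component* of
the graph — disconnected components can never merge, so the "single
cluster in the limit" property holds only on connected graphs.

ARI uses the permutation-model chance correction (scikit-learn
implementation; the tests verify it against exhaustive pair counting).
The uncertainty coefficient U(X|Y) = I(X;Y)/H(X) uses plug-in entropy
estimates in natural log (the ratio is base-free); with the large n this
method targets, plug-in bias is negligible. U is undefined when H(X) = 0
and reported as not-applicable rather than forced to a number.

## Gradient analysis

Within the blast compartment (blast clusters are a required config input;
the pipeline can fall back to marker-based auto-selection), the SVD of
the *uncentred* residual submatrix is taken and cells are ordered by
their entries in the second left-singular vector: the first singular
vector carries the blast-subset mean direction (the subset is not
mean-free even though **u** is), the second the dominant within-subset
gradient. This presumes the blast-vs-rest contrast dominates the
within-blast variation; when it does not, the gradient migrates into the
first vector. Sliding-window means (window 200, stride 1, only fully
populated windows, so n − 199 points) profile each antibody, each clone's
indicator and the embedding coordinates; a cubic interpolating spline
through the smoothed coordinates, parameterised on [0, 1], draws the
gradient's orientation. Pearson r is computed on smoothed antibody
profiles, Kendall τ on the *unsmoothed* per-cell clone indicators —
smoothing would inflate the significance of the fraction trends. The
entire analysis is defined up to sign (SVD ambiguity): negating the
vector reverses the ordering and flips correlation signs with unchanged
magnitudes, and tests compare orientations accordingly.

## Synthetic data generator

Per population: fixed per-locus genotypes; a mean log antibody profile; a
per-cell log-normal jitter (dispersion); optional linear log-scale
antibody slopes over a latent position in [0, 1]. Molecule counts are
Poisson with log-mean = profile + slope·position + jitter + log(depth
factor), the depth factor being log-normal (σ = 0.35 by default) and
shared between the antibody and DNA libraries — a Poisson–log-normal
model whose technical component lies exactly in the span of the quality
matrix, which is what the correction assumes it can remove. Allele
dropout converts het sites to hom-ref or hom-alt reads upstream of the
toy caller. Reads: one pair per molecule per amplification copy, with
configurable substitution rates on barcodes and UMIs and Poisson ambient
molecules on all droplets including empties. UMIs within one (cell,
antibody) group are drawn at pairwise Hamming distance ≥ 2 — the
generator's idealisation of molecule identity, under which adjacency
deduplication at zero error rate is exactly information-preserving (true
UMI collisions exist in real data at a rate of order k²/4·4¹⁰ per group
and are deliberately not modelled). All randomness flows from one seed
through named substreams (truth / antibody_reads / dna), so outputs are
byte-reproducible; gzip headers are written with a pinned mtime for the
same reason.

Two scenarios are bundled. `three_populations` is a clean cell-line-style
mixture: three equally sized populations (1,000 cells each at full
scale), each with one driver mutation and two high markers (Δlog ≈ 2.2
over baseline), dropout 5%. `blast_gradient` plants the continuum
situation: two mutant clones (1,200 each) share one blast profile with
six sloped markers and overlapping position ranges (0–0.6 and 0.4–1.0),
plus an equally sized, strongly contrasted normal population. Two design
constraints make this scenario faithful to the method's assumptions:
the blast-vs-normal contrast must dominate the first singular vector
(otherwise the gradient itself would occupy it and ordering by the second
vector would fail by construction), and the sloped markers come in
endpoint-balanced rising/falling pairs under a high-abundance CD45
anchor so total molecule count stays nearly flat along the gradient —
the gradient is a phenotype change, not a library-size change, keeping it
out of the quality matrix that the correction removes. Scenario sizes
(~3,000–3,600 cells) are desk-scale choices that resolve every planted
effect while keeping full runs in the minutes range.

What passing these benchmarks shows: the pipeline inverts its own
generative model exactly at zero noise, removes planted technical
covariates to numerical precision, and recovers planted cluster and
gradient structure under realistic Poisson/log-normal noise. What it does
not show: robustness to features the generator omits — doublets,
cell-type-dependent ambient contamination, UMI collisions, indel barcode
errors, alignment and variant-calling artefacts, and biological library-
size differences between cell types.

## Numerical details

* Constant columns (after log transform) are dropped from **q** with a
  warning before the SVD; a fully degenerate **q** leaves an
  intercept-only design, so correction reduces to column centring.
* Singular vectors with s ≤ s₁·10⁻¹² are treated as null; a residual
  column whose variance is ~0 (fully explained by the design, e.g. the
  isotype column when raw reads equal deduplicated counts) has an
  undefined correlation and is reported as such, not as large.
* Ordering ties in the gradient (duplicated rows) break by cell id;
  greedy UMI ties break lexicographically; cluster labels are relabelled
  contiguously by descending size.
* Coordinates: VCF 1-based, BED 0-based half-open, enforced at the
  readers.
* Pipeline exit codes: 0 success, 2 config validation, 3 stage failure;
  the run manifest stores seeds, parameters, per-stage row counts and
  SHA-256 checksums of every artifact.
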