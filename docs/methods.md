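# Methods

`demuxbench` reproduces, at desk scale, the ground-truth benchmarking loop
used to evaluate SNP-based demultiplexing of pooled single-cell RNA-seq:
simulate per-individual data with known cell origins, pool it in silico with
synthetic doublets, demultiplex by genotype, derive orthogonal "wet-lab"
truth labels, and score the demultiplexer against both truths. This note
records the models, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## Genotype panels

A panel holds biallelic SNPs for `k` individuals on one or more contigs.
The locus count is Poisson with mean `snp_density × genome_length / 1000`
(a fixed-count mode pins it exactly), positions are uniform without
replacement, and each locus gets a minor-allele frequency drawn uniformly
from `maf_bounds` (default 0.05–0.5; the lower bound mirrors the MAF ≥ 0.05
filter conventionally applied to common-variant files). Individual dosages
are binomial(2, MAF) — Hardy–Weinberg equilibrium with no linkage and no
population structure. SNP density is the pivotal knob: the regimes of
interest span ~0.013 SNPs/kb (inbred mouse strains, where genotype
demultiplexing fails) to ~3.6 SNPs/kb (outbred zebrafish); densities below
roughly 0.2–0.34 SNPs/kb are flagged as the band where the method becomes
unreliable. An *isogenic* mode copies one individual's genotype vector to
all individuals, keeping per-locus MAF metadata but zero between-individual
variance.

## Per-cell allele counts

Per cell, total mapped depth is log-normal with median 12,000 and
log-sigma 0.35, truncated to [1, 10⁶]. These defaults put ≥95% of cells
inside the 5,000–40,000 mapped-read quality window used for cell filtering
while leaving tails that exercise the filter; no published depth
distribution was available to copy, so they are stand-ins exposed as
configuration. A fraction of each cell's depth (`informative_fraction`,
default 0.05) lands on panel loci via a multinomial over locus weights drawn
once per simulation from a symmetric Dirichlet(1) — uneven coverage without
a full expression model. At a locus with alt dosage g, each read is alt with
probability ε (g=0), 0.5 (g=1), or 1−ε (g=2), with ε the per-read miscall
rate (default 0.001), applied symmetrically to both homozygote classes.

What the generator does *not* emulate: ambient RNA, UMI collisions,
expression differences between individuals, allele-specific expression, and
linkage. Passing tests therefore show that the pipeline arithmetic and the
statistical machinery behave as claimed under clean genotype signal; they do
not certify performance on real tissue.

## Pooling and synthetic doublets

Pooling samples `cells_per_sample` cells per input without replacement and
emits a fraction `d` (default 0.1, the simulated doublet rate used
throughout) of pooled barcodes as synthetic doublets: with N cells drawn,
D = round(dN/(1+d)) doublets are formed by pairing 2D cells chosen uniformly
from the pooled candidate set and summing their ref/alt counts and depths.
Defining `d` over *emitted barcodes* makes the manifest doublet fraction
directly checkable against the requested rate. Uniform partner sampling
makes the heterotypic share among doublets converge to `1 − Σ pᵢ²` of the
pool proportions — 2/3 for three equal samples, 3/4 for four. Pooled
barcodes are renamed `<stem>-s<i>` (sample index), which resolves collisions
while keeping traceability. Homotypic doublets (same-individual parents) can
be stripped before benchmarking, since genotype-based tools detect only
intergenotypic doublets.

Read-level pooling applies the same sampling plan to aligned-read files:
each input is streamed once, reads are kept if their CB tag is in the
sample's selected set (and, when a variant file is given, if they overlap a
listed locus ±200 bp), CB tags are rewritten to pooled barcodes, and a
doublet's second parent inherits the first parent's pooled barcode. Molecule
(UB) tags are left untouched — duplicate molecule identifiers across the two
parents are allowed, as in a physical doublet. Peak memory is bounded by the
selected-barcode maps plus one in-flight read. Count-level and read-level
pooling share one deterministic plan, so a pileup of the pooled reads
reproduces the pooled count matrix exactly.

`--nCELL` ambiguity: the per-sample interpretation is used (each input
contributes `cells_per_sample` cells), and the collision policy above is
this package's contract.

## The reference demultiplexer

Cells are clustered into k genotype groups by EM on a per-cell
product-binomial likelihood with continuous per-cluster alt-read
probabilities θ (clusters × loci):

    loglik(i, c) = Σ_l [ alt_il · log θ_cl + ref_il · log(1 − θ_cl) ]

M-step: θ_cl = (Σᵢ γᵢc alt_il + 1) / (Σᵢ γᵢc (alt+ref)_il + 2); the α=β=1
pseudocounts keep θ strictly inside (0,1) and act as a Beta(2,2) prior. The
tracked objective is the penalized log-likelihood (data likelihood with
uniform mixing weights plus the prior term), which EM increases
monotonically; θ is additionally clipped to [10⁻⁴, 1−10⁻⁴] as a safety net
for the log terms. Initialization is per-cell Dirichlet(1) responsibilities;
default 8 restarts, tolerance 10⁻⁶ relative, best restart by final
objective. Continuous θ rather than discrete genotypes keeps the model
small; it is benchmark plumbing, not a production demultiplexer.

Doublet calling compares each cell's best singlet likelihood against the
best two-cluster mixture θ_pair = (θ_c + θ_c′)/2. The prior places
`doublet_prior` (default 0.10, the simulated doublet rate) on the doublet
status as a whole and splits the remainder evenly over the k singlet
identities. The status-level doublet prior matters: each singlet identity
carries prior (1−d)/k, so the singlet-vs-doublet decision margin shrinks as
k grows, and heterotypic doublet recall improves with pool size — the
direction reported for real tools. (Splitting the doublet prior across the
k(k−1)/2 pairs instead cancels the k-dependence and was rejected.) Cells
covering fewer than `min_informative_loci` (default 10) panel loci, or whose
winning posterior is below `posterior_threshold` (default 0.8), are
unassigned. Ties resolve toward the lower cluster index for determinism.
Homotypic doublets are called singlets of the shared origin by construction.

On isogenic panels the EM still converges, but its clusters capture sampling
noise: assignments can be confident yet carry no information about the true
individual (adjusted Rand index ≈ 0). The benchmark treats
"chance-level clustering" and "mostly unassigned" as the same failure mode.

## Wet-lab truth labels

**Tag counts** (fluorescent transgene mRNAs or CMOs) are Poisson: a
singlet's own tag at `mean_capture`, everything else at `background_rate`;
doublets superpose both parents. Low capture produces all-zero rows — the
"negative" droplets that dominate low-capture fluorescent labelling.

**Tag classification** log1p-transforms counts; for each candidate quantile
in the grid (default 0.10–0.90, step 0.05) every tag's threshold is that
quantile of its positive-cell distribution, and the shared quantile
maximizing the overall singlet proportion is kept. Exactly one positive tag
→ that tag; several → doublet; none → negative. Two documented behaviours
follow from this contract. First, in sparse regimes one or two stray counts
on two tags can clear their thresholds, producing erroneous doublet calls —
a known failure of threshold classifiers on sparse hashing data. Second,
because per-tag background fractions differ by a few percent, no shared
quantile lands in every tag's background/signal gap simultaneously, so even
at generous capture (≥20 reads/cell) roughly 1–4% of singlets are clipped
into negatives; singlet accuracy ≥95% is what the contract delivers.
Optimizing quantiles per tag was tried and rejected: it degenerately
suppresses true doublets by pushing one tag's threshold above its signal
mode. Users needing fidelity to a specific upstream hashing tool should
import that tool's calls instead.

**Barnyard classification** (two-species pools) calls a droplet a species
when that species' read fraction is ≥ `purity_threshold` (default 0.8,
inclusive; no published value existed to copy), otherwise a doublet;
zero-read droplets are excluded.

**Cell filtering** keeps barcodes with depth inside [5,000, 40,000]
(inclusive on both ends — "between X and Y" is ambiguous, so inclusivity is
stated once here and tested) and optionally requires a positive summed tag
count.

## Evaluation statistics

- **Cluster–truth matching**: optimal one-to-one assignment maximizing
  matched counts (Hungarian algorithm on the truth × predicted contingency
  table; doublet/unassigned/negative labels never participate). A
  correlation objective (Pearson correlation of truth/predicted indicator
  vectors) is available for fidelity to the "correlation analysis" wording;
  the two coincide on well-separated tables, and the count objective is
  brute-force verifiable against all k! assignments for k ≤ 5.
- **Accuracy report**: per truth identity, counts and percentages assigned
  to each mapped identity, doublet, and unassigned; identities with zero
  cells stay in the report.
- **Doublet confusion**: *confirmed* doublets (both truth and demuxer agree)
  versus *contested* doublets, split into truth-only and prediction-only;
  heterotypic recall = confirmed heterotypic / true heterotypic, with
  homotypic doublets excluded.
- **Depth-binned curves**: cells sorted by depth (ties broken by barcode)
  into 40 contiguous near-equal bins, remainder cells going to the
  lowest-depth bins; per bin, Cell ID % (share of cells given a singlet
  identity) or percent agreement between two call sets. The bin-size-
  weighted mean of bin percentages equals the overall rate exactly.
- **SNP density**: fixed 1-kb windows from position 1; without contig
  lengths tiling stops at the last variant-bearing window, with lengths the
  whole contig is tiled (a documented divergence from window tools that
  only report variant-bearing windows). The mean includes zero windows;
  means below 0.2 SNPs/kb are flagged against the 0.2–0.34 viability band.
- **Cluster composition**: per transcriptional cluster, distinct-animal
  count, per-animal cells, and doublet %; clusters with fewer animals than
  the pool size are flagged as breaking the every-replicate-in-every-cluster
  assumption.

Percentages are reported to full float precision in tables; truncation
toward zero to a whole percent is applied only where a quoted headline
number uses that convention (the 66% three-way heterotypic share).

## Reproducibility

Every generator is a pure function of its arguments including the seed. The
pipeline derives one seed per stage from the master seed by hashing
`"<master>:<stage>"` (BLAKE2b, reduced mod 2³¹), so adding or reordering
stages does not perturb unrelated streams. Reruns with identical
configuration are bit-identical.

## Problem sizes

The recovery benchmarks run k=3 (or 5) individuals at 0.35 SNPs/kb over a
10-Mb genome — ~3,500 loci — with 150–500 cells per individual and doublet
rate 0.1. The doublet-recall comparison between pool sizes runs at
`informative_fraction` 0.015, a sparse-coverage stress regime chosen so that
recall sits in the ~45–60% range typical of reported benchmarks rather than
saturating near 1, where the pool-size effect is invisible. On-disk
aligned-read fixtures are capped at 50 cells × 500 loci; they exist to
verify read-level pooling against count-level pooling exactly, not to carry
realistic volumes.

## Known limitations

- The demultiplexer models allele counts only; it ignores total-depth
  differences between singlets and doublets, which real tools exploit.
- Tag classification is a deliberately simple quantile-threshold contract;
  see above for its documented failure modes.
- No ambient RNA, no UMI collisions, no expression model beyond fixed
  Dirichlet locus weights; absolute accuracies here are optimistic relative
  to experimentally pooled data, and the benchmark's value is in relative
  and structural comparisons (density regimes, pool sizes, isogenic
  failure), not absolute rates.
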