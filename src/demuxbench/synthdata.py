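"""Synthetic genotype panels, per-cell allele counts, tag counts, and on-disk fixtures.

The generators emulate the statistical structure a pooled single-cell
demultiplexing benchmark rests on: per-individual biallelic genotype panels
at a configurable SNP density (the regimes of interest span roughly
0.01-3.6 SNPs/kb, from near-isogenic inbred strains up to outbred fish),
per-cell ref/alt read counts whose total depths straddle the 5,000-40,000
mapped-read quality window, and sparse sample-tag counts (fluorescent
transgene mRNAs or cell-multiplexing oligos) with realistically low capture.

Everything is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantPanel",
    "AlleleCountMatrix",
    "TagCountMatrix",
    "TruthManifest",
    "simulate_genotypes",
    "simulate_cells",
    "simulate_tag_counts",
    "write_fixtures",
    "make_barcodes",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantPanel:
    """Biallelic genotypes for a set of individuals.

    Attributes
    ----------
    contig_names : list of str
    contig_lengths : dict contig -> length in bp
    contigs : array of contig name per locus
    positions : 1-based locus coordinates, strictly increasing within a contig
    ref_allele, alt_allele : single bases per locus
    genotypes : (n_individuals, n_loci) alt-allele dosage in {0, 1, 2}
    maf : per-locus minor-allele frequency in (0, 0.5]
    individuals : individual identifiers
    """

    contig_names: list[str]
    contig_lengths: dict[str, int]
    contigs: np.ndarray
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    maf: np.ndarray
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.individuals:
            self.individuals = [f"ind{i}" for i in range(self.genotypes.shape[0])]
        self.validate()

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def genome_length(self) -> int:
        return int(sum(self.contig_lengths.values()))

    @property
    def snp_density(self) -> float:
        """Loci per kilobase implied by the panel."""
        return self.n_loci / (self.genome_length / 1000.0)

    def validate(self) -> None:
        for contig in self.contig_names:
            pos = self.positions[self.contigs == contig]
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
            if pos.size and pos.max() > self.contig_lengths[contig]:
                raise ValueError(f"position beyond length of {contig}")
        if self.n_loci and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be alt dosages in {0,1,2}")
        if self.n_loci and (np.any(self.maf <= 0) or np.any(self.maf > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")

    def subset_loci(self, mask: np.ndarray) -> "VariantPanel":
        return replace(
            self,
            contigs=self.contigs[mask],
            positions=self.positions[mask],
            ref_allele=self.ref_allele[mask],
            alt_allele=self.alt_allele[mask],
            genotypes=self.genotypes[:, mask],
            maf=self.maf[mask],
        )


@dataclass
class AlleleCountMatrix:
    """Per-cell ref/alt read counts at panel loci plus total mapped depth."""

    barcodes: list[str]
    ref_counts: np.ndarray  # (cells, loci) non-negative ints
    alt_counts: np.ndarray
    total_depth: np.ndarray  # (cells,) informative + background reads

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if np.any(self.ref_counts < 0) or np.any(self.alt_counts < 0):
            raise ValueError("counts must be non-negative")
        informative = self.ref_counts.sum(axis=1) + self.alt_counts.sum(axis=1)
        if np.any(informative > self.total_depth):
            raise ValueError("per-cell informative reads exceed total depth")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_loci(self) -> int:
        return self.ref_counts.shape[1]

    def subset(self, indices: np.ndarray) -> "AlleleCountMatrix":
        return AlleleCountMatrix(
            barcodes=[self.barcodes[i] for i in indices],
            ref_counts=self.ref_counts[indices],
            alt_counts=self.alt_counts[indices],
            total_depth=self.total_depth[indices],
        )


@dataclass
class TagCountMatrix:
    """Cells x tags counts for fluorescent-gene or CMO labels."""

    barcodes: list[str]
    tags: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("tag names must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.barcodes, columns=self.tags)


MANIFEST_COLUMNS = [
    "barcode", "droplet_type", "origin1", "origin2", "doublet_class", "source_sample",
]


@dataclass
class TruthManifest:
    """Ground-truth droplet table: barcode -> origin(s), singlet/doublet class.

    Simulation parameters (doublet rate d, seed, cells per sample) ride along
    so every downstream report can echo the conditions that produced it.
    """

    table: pd.DataFrame
    doublet_rate: float = 0.0
    seed: int | None = None
    cells_per_sample: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        t = self.table
        singles = t.droplet_type == "singlet"
        if not (t.loc[singles, "origin2"].isna().all()
                and (t.loc[singles, "doublet_class"] == "not-applicable").all()):
            raise ValueError("singlets must have one origin and doublet_class not-applicable")
        doubles = t[t.droplet_type == "doublet"]
        if doubles.origin2.isna().any():
            raise ValueError("doublets must carry two origins")
        het = doubles.origin1 != doubles.origin2
        if not (doubles.doublet_class == np.where(het, "heterotypic", "homotypic")).all():
            raise ValueError("doublet_class inconsistent with origins")

    @property
    def barcodes(self) -> list[str]:
        return self.table.barcode.tolist()

    @property
    def doublet_fraction(self) -> float:
        return float((self.table.droplet_type == "doublet").mean())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **params) -> "TruthManifest":
        table = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        return cls(table=table, **params)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """Unique 16-mer droplet barcodes with the conventional '-1' suffix."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=16)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_genotypes(
    n_individuals: int,
    genome_length: int,
    snp_density: float,
    maf_bounds: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    *,
    n_loci: int | None = None,
    isogenic: bool = False,
    contig_name: str = "chr1",
) -> VariantPanel:
    """Draw a biallelic variant panel under Hardy-Weinberg equilibrium.

    The locus count is Poisson with mean ``snp_density * genome_length / 1000``
    unless ``n_loci`` pins it exactly (fixed-count mode). Positions are uniform
    without replacement, per-locus MAF uniform over ``maf_bounds``, and each
    individual's dosage is binomial(2, maf). ``isogenic`` copies the first
    individual's genotype vector to all individuals, emulating an inbred
    (e.g., C57BL/6) pool where between-individual variance is zero.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    if genome_length < 1000:
        raise ValueError("genome_length must be at least 1000 bp")
    if snp_density < 0:
        raise ValueError("snp_density must be non-negative")
    lo, hi = maf_bounds
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_bounds must satisfy 0 < lo <= hi <= 0.5")

    rng = np.random.default_rng(seed)
    if n_loci is None:
        n_loci = int(rng.poisson(snp_density * genome_length / 1000.0))
    n_loci = min(n_loci, genome_length)

    positions = np.sort(rng.choice(genome_length, size=n_loci, replace=False)) + 1
    maf = rng.uniform(lo, hi, size=n_loci)
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4

    genotypes = rng.binomial(2, maf, size=(n_individuals, n_loci))
    if isogenic and n_individuals > 1:
        genotypes = np.tile(genotypes[:1], (n_individuals, 1))

    return VariantPanel(
        contig_names=[contig_name],
        contig_lengths={contig_name: int(genome_length)},
        contigs=np.full(n_loci, contig_name, dtype=object),
        positions=positions.astype(np.int64),
        ref_allele=_BASES[ref_idx],
        alt_allele=_BASES[alt_idx],
        genotypes=genotypes.astype(np.int8),
        maf=maf,
    )


def simulate_cells(
    panel: VariantPanel,
    cells_per_individual: int,
    *,
    depth_log_mean: float = math.log(12_000.0),
    depth_log_sigma: float = 0.35,
    informative_fraction: float = 0.05,
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[AlleleCountMatrix, TruthManifest]:
    """Simulate per-cell ref/alt counts for every individual in a panel.

    Per cell, total depth is log-normal (defaults put the median at 12,000
    reads, inside the 5,000-40,000 quality window, with tails that exercise
    the filter), truncated to [1, 1e6]. A fraction of reads is informative
    and lands on panel loci via a multinomial over Dirichlet(1) locus weights
    shared by all cells. At a locus with alt dosage g, each read is alt with
    probability ``error_rate`` (g=0), 0.5 (g=1), or ``1 - error_rate`` (g=2).
    """
    if panel.n_loci == 0:
        raise ValueError("panel has no loci")
    if cells_per_individual < 1:
        raise ValueError("cells_per_individual must be >= 1")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    if not (0 < informative_fraction <= 1):
        raise ValueError("informative_fraction must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    n_cells = cells_per_individual * panel.n_individuals
    barcodes = make_barcodes(n_cells, rng)
    origins = np.repeat(panel.individuals, cells_per_individual)

    weights = rng.dirichlet(np.ones(panel.n_loci))
    depths = np.exp(rng.normal(depth_log_mean, depth_log_sigma, size=n_cells))
    depths = np.clip(np.round(depths), 1, 1_000_000).astype(np.int64)

    p_alt_by_g = np.array([error_rate, 0.5, 1.0 - error_rate])
    ref = np.zeros((n_cells, panel.n_loci), dtype=np.int64)
    alt = np.zeros_like(ref)
    ind_index = {name: i for i, name in enumerate(panel.individuals)}
    for c in range(n_cells):
        n_inf = int(round(depths[c] * informative_fraction))
        reads = rng.multinomial(n_inf, weights)
        p_alt = p_alt_by_g[panel.genotypes[ind_index[origins[c]]]]
        alt[c] = rng.binomial(reads, p_alt)
        ref[c] = reads - alt[c]

    counts = AlleleCountMatrix(
        barcodes=barcodes, ref_counts=ref, alt_counts=alt, total_depth=depths,
    )
    table = pd.DataFrame({
        "barcode": barcodes,
        "droplet_type": "singlet",
        "origin1": origins,
        "origin2": pd.Series([None] * n_cells, dtype=object),
        "doublet_class": "not-applicable",
        "source_sample": origins,
    })
    manifest = TruthManifest(
        table=table, doublet_rate=0.0, seed=seed, cells_per_sample=cells_per_individual,
    )
    return counts, manifest


def simulate_tag_counts(
    truth: TruthManifest,
    tag_map: dict[str, str],
    mean_capture: float = 5.0,
    background_rate: float = 0.1,
    seed: int = 0,
) -> TagCountMatrix:
    """Poisson tag counts for each droplet.

    Singlets draw Poisson(mean_capture) on their own tag and
    Poisson(background_rate) elsewhere; doublets superpose both parents'
    signal (a shared tag, as when several samples carry one CMO, simply
    accumulates). Low ``mean_capture`` leaves all-zero rows -- the
    "negative" droplets that plague low-capture fluorescent labelling.
    """
    origins = set(truth.table.origin1) | set(truth.table.origin2.dropna())
    unmapped = origins - set(tag_map)
    if unmapped:
        raise ValueError(f"origins without a tag: {sorted(unmapped)}")

    tags = sorted(set(tag_map.values()))
    tag_idx = {t: j for j, t in enumerate(tags)}
    rng = np.random.default_rng(seed)
    n = len(truth.table)
    lam = np.full((n, len(tags)), background_rate, dtype=float)
    for i, row in enumerate(truth.table.itertuples(index=False)):
        lam[i, tag_idx[tag_map[row.origin1]]] += mean_capture
        if row.droplet_type == "doublet":
            lam[i, tag_idx[tag_map[row.origin2]]] += mean_capture
    counts = rng.poisson(lam)
    return TagCountMatrix(barcodes=truth.barcodes, tags=tags, counts=counts)


# ---------------------------------------------------------------------------
# On-disk fixtures (aligned reads + variants)
# ---------------------------------------------------------------------------

MAX_FIXTURE_CELLS = 50
MAX_FIXTURE_LOCI = 500
READ_LENGTH = 1  # single-base reads pin each read to exactly one locus


def write_fixtures(
    counts: AlleleCountMatrix,
    panel: VariantPanel,
    bam_path: str,
    vcf_path: str,
    *,
    sort_and_index: bool = True,
) -> None:
    """Emit a sorted, indexed aligned-read file plus a matching variant file.

    Each counted allele becomes one single-end, single-base read placed on
    its locus carrying the ref or alt base, tagged with the cell barcode (CB)
    and a unique molecule identifier (UB). A pileup over the emitted reads
    reproduces the input counts exactly. Fixture-scale only.
    """
    import pysam

    if counts.n_cells > MAX_FIXTURE_CELLS or panel.n_loci > MAX_FIXTURE_LOCI:
        raise ValueError(
            f"fixture scale exceeded (<= {MAX_FIXTURE_CELLS} cells, "
            f"<= {MAX_FIXTURE_LOCI} loci)"
        )
    if counts.n_loci != panel.n_loci:
        raise ValueError("counts and panel disagree on locus count")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": int(panel.contig_lengths[name])}
            for name in panel.contig_names
        ],
    }
    tid = {name: i for i, name in enumerate(panel.contig_names)}

    order = np.lexsort((panel.positions, np.array(
        [tid[c] for c in panel.contigs])))
    umi = 0
    mode = "wb" if str(bam_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(bam_path), mode, header=header) as out:
        for l in order:
            for c in range(counts.n_cells):
                for base, k in (
                    (panel.ref_allele[l], counts.ref_counts[c, l]),
                    (panel.alt_allele[l], counts.alt_counts[c, l]),
                ):
                    for _ in range(int(k)):
                        a = pysam.AlignedSegment()
                        a.query_name = f"read{umi}"
                        a.query_sequence = str(base)
                        a.query_qualities = pysam.qualitystring_to_array("I")
                        a.reference_id = tid[panel.contigs[l]]
                        a.reference_start = int(panel.positions[l]) - 1
                        a.cigarstring = f"{READ_LENGTH}M"
                        a.mapping_quality = 60
                        a.set_tag("CB", counts.barcodes[c])
                        a.set_tag("UB", f"UMI{umi:08d}")
                        out.write(a)
                        umi += 1
    if sort_and_index and str(bam_path).endswith(".bam"):
        tmp = str(bam_path) + ".sorted"
        pysam.sort("-o", tmp, str(bam_path))
        import os
        os.replace(tmp, str(bam_path))
        pysam.index(str(bam_path))

    write_panel_vcf(panel, vcf_path)


def write_panel_vcf(panel: VariantPanel, vcf_path: str) -> None:
    """Write the panel as VCF v4.2 with a GT column per individual."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name in panel.contig_names:
        header.contigs.add(name, length=int(panel.contig_lengths[name]))
    for ind in panel.individuals:
        header.add_sample(ind)

    gt_by_dosage = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for l in range(panel.n_loci):
            rec = out.new_record(
                contig=str(panel.contigs[l]),
                start=int(panel.positions[l]) - 1,
                stop=int(panel.positions[l]),
                alleles=(str(panel.ref_allele[l]), str(panel.alt_allele[l])),
            )
            rec.info["MAF"] = float(panel.maf[l])
            for i, ind in enumerate(panel.individuals):
                rec.samples[ind]["GT"] = gt_by_dosage[int(panel.genotypes[i, l])]
            out.write(rec)


def read_panel_vcf(vcf_path: str) -> VariantPanel:
    """Load a VariantPanel from a VCF written by :func:`write_panel_vcf`."""
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vf:
        individuals = list(vf.header.samples)
        lengths = {c: vf.header.contigs[c].length for c in vf.header.contigs}
        contigs, positions, refs, alts, mafs, gts = [], [], [], [], [], []
        for rec in vf:
            contigs.append(rec.contig)
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            mafs.append(rec.info.get("MAF", np.nan))
            gts.append([sum(rec.samples[s]["GT"]) for s in individuals])
    n = len(positions)
    genotypes = np.array(gts, dtype=np.int8).T if n else np.zeros((len(individuals), 0), np.int8)
    names = list(dict.fromkeys(contigs)) or list(lengths)
    return VariantPanel(
        contig_names=names,
        contig_lengths={c: int(lengths[c]) for c in names},
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        genotypes=genotypes,
        maf=np.array(mafs, dtype=float),
        individuals=individuals,
    )


def pileup_allele_counts(bam_path: str, panel: VariantPanel, barcodes: list[str]) -> AlleleCountMatrix:
    """Recount ref/alt reads per cell by pileup over an aligned-read fixture.

    Serves as the independent recount path for fixture fidelity checks and as
    the bridge from read-level pooling back to count matrices.
    """
    import pysam

    bc_idx = {b: i for i, b in enumerate(barcodes)}
    ref = np.zeros((len(barcodes), panel.n_loci), dtype=np.int64)
    alt = np.zeros_like(ref)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for l in range(panel.n_loci):
            pos0 = int(panel.positions[l]) - 1
            for col in bam.pileup(
                str(panel.contigs[l]), pos0, pos0 + 1, truncate=True,
                min_base_quality=0,
            ):
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip:
                        continue
                    read = pr.alignment
                    if not read.has_tag("CB"):
                        continue
                    cb = read.get_tag("CB")
                    if cb not in bc_idx:
                        continue
                    base = read.query_sequence[pr.query_position]
                    if base == str(panel.ref_allele[l]):
                        ref[bc_idx[cb], l] += 1
                    elif base == str(panel.alt_allele[l]):
                        alt[bc_idx[cb], l] += 1
    depth = ref.sum(axis=1) + alt.sum(axis=1)
    return AlleleCountMatrix(
        barcodes=list(barcodes), ref_counts=ref, alt_counts=alt, total_depth=depth,
    )
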