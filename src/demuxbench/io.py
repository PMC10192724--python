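"""Configuration, file formats, logging, and the end-to-end pipeline.

Every stochastic stage of the pipeline draws its own seed from the master
seed by hashing ``"<master>:<stage>"`` (BLAKE2, reduced mod 2^31), so a stage
keeps its stream when unrelated stages are added or reordered.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .demux import DemuxConfig
from .demux import demux as run_demux
from .pooling import expected_heterotypic_fraction, pool_counts, strip_homotypic_doublets
from .synthdata import simulate_cells, simulate_genotypes, simulate_tag_counts
from .truth_labels import classify_by_tags, filter_cells

__all__ = [
    "RunConfig",
    "stage_seed",
    "read_clusters_table",
    "write_clusters_table",
    "write_counts_mtx",
    "read_counts_mtx",
    "run_pipeline",
]

log = logging.getLogger("demuxbench")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything needed to reproduce a benchmark run."""

    seed: int = 50
    # panel
    n_individuals: int = 3
    genome_length: int = 10_000_000
    snp_density: float = 0.35
    maf_min: float = 0.05
    maf_max: float = 0.5
    isogenic: bool = False
    # cells
    cells_per_individual: int = 500
    informative_fraction: float = 0.05
    error_rate: float = 0.001
    # pooling
    doublet_rate: float = 0.1
    cells_per_sample: int | None = None
    strip_homotypic: bool = True
    # demux
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    # tags
    mean_capture: float = 20.0
    background_rate: float = 0.1
    # filters / reporting
    depth_bounds: tuple[float, float] = (5_000, 40_000)
    require_positive_tags: bool = False
    n_bins: int = 40

    def validate(self) -> None:
        if not (0 <= self.doublet_rate < 1):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.cells_per_individual < 1:
            raise ValueError("cells_per_individual must be >= 1")
        if not (0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < min <= max <= 0.5")
        if self.snp_density < 0:
            raise ValueError("snp_density must be non-negative")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["depth_bounds"] = list(self.depth_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "demux" in data and isinstance(data["demux"], dict):
            data["demux"] = DemuxConfig(**data["demux"])
        if "depth_bounds" in data:
            data["depth_bounds"] = tuple(data["depth_bounds"])
        return cls(**data)


# ---------------------------------------------------------------------------
# clusters table (souporcell dialect)
# ---------------------------------------------------------------------------

def write_clusters_table(assignments: pd.DataFrame, path) -> None:
    """Write assignments in the souporcell ``clusters.tsv`` dialect.

    Columns: barcode, status, assignment, log_prob_singleton,
    log_prob_doublet, cluster0..cluster{k-1}; doublet assignments are encoded
    "c/c'".
    """
    cluster_cols = [c for c in assignments.columns if c.startswith("cluster")]
    cols = ["barcode", "status", "assignment",
            "log_prob_singleton", "log_prob_doublet"] + cluster_cols
    assignments[cols].to_csv(path, sep="\t", index=False)


def read_clusters_table(path) -> pd.DataFrame:
    """Parse a clusters-format table, validating structure row by row."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["barcode", "status", "assignment",
                    "log_prob_singleton", "log_prob_doublet"]
        if header[: len(required)] != required:
            raise ValueError(f"malformed clusters header: {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} fields, got {len(parts)}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=header)
    for col in header[3:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def parse_doublet_assignment(assignment: str) -> tuple[int, int] | None:
    """Souporcell encodes doublets as "c/c'"; return the ordered pair."""
    if "/" not in str(assignment):
        return None
    a, b = str(assignment).split("/")
    return int(a), int(b)


# ---------------------------------------------------------------------------
# matrices (MTX + TSV sidecars)
# ---------------------------------------------------------------------------

def write_counts_mtx(counts, panel, outdir) -> None:
    """Write ref/alt matrices as MatrixMarket with barcode/feature sidecars."""
    from scipy import io as sio
    from scipy.sparse import coo_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "ref.mtx", coo_matrix(counts.ref_counts))
    sio.mmwrite(outdir / "alt.mtx", coo_matrix(counts.alt_counts))
    pd.Series(counts.barcodes).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.DataFrame({
        "contig": panel.contigs, "position": panel.positions,
        "ref": panel.ref_allele, "alt": panel.alt_allele,
    }).to_csv(outdir / "features.tsv", sep="\t", index=False)
    pd.Series(counts.total_depth, index=counts.barcodes).to_csv(
        outdir / "depths.tsv", sep="\t", header=False)


def read_counts_mtx(outdir):
    from scipy import io as sio

    from .synthdata import AlleleCountMatrix

    outdir = Path(outdir)
    ref = np.asarray(sio.mmread(outdir / "ref.mtx").todense()).astype(np.int64)
    alt = np.asarray(sio.mmread(outdir / "alt.mtx").todense()).astype(np.int64)
    barcodes = pd.read_csv(outdir / "barcodes.tsv", header=None)[0].tolist()
    depths = pd.read_csv(outdir / "depths.tsv", sep="\t", header=None, index_col=0)[1]
    return AlleleCountMatrix(
        barcodes=barcodes, ref_counts=ref, alt_counts=alt,
        total_depth=depths.loc[barcodes].to_numpy(),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate → pool → (strip homotypic) → demux → label → evaluate.

    Writes the manifest, assignments, tag calls, evaluation reports, a config
    snapshot and a log into ``outdir`` and returns the headline statistics.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    config.to_yaml(outdir / "config.yaml")
    log.info("config: %s", asdict(config))

    panel = simulate_genotypes(
        config.n_individuals, config.genome_length, config.snp_density,
        (config.maf_min, config.maf_max),
        seed=stage_seed(config.seed, "genotypes"), isogenic=config.isogenic,
    )
    log.info("panel: %d loci, %.3f SNPs/kb", panel.n_loci, panel.snp_density)

    cells, singlet_truth = simulate_cells(
        panel, config.cells_per_individual,
        informative_fraction=config.informative_fraction,
        error_rate=config.error_rate,
        seed=stage_seed(config.seed, "cells"),
    )

    by_individual = singlet_truth.table.groupby("origin1", sort=True)
    samples = []
    bc_index = {bc: i for i, bc in enumerate(cells.barcodes)}
    for ind, grp in by_individual:
        idx = np.array([bc_index[b] for b in grp.barcode])
        samples.append((cells.subset(idx), str(ind)))

    pooled = pool_counts(
        samples, doublet_rate=config.doublet_rate,
        cells_per_sample=config.cells_per_sample,
        seed=stage_seed(config.seed, "pool"),
    )
    doublet_fraction = pooled.truth.doublet_fraction
    het_expected = expected_heterotypic_fraction(list(pooled.pool_proportions.values()))
    log.info("pooled: %d barcodes, doublet fraction %.4f, expected heterotypic share %.4f",
             pooled.counts.n_cells, doublet_fraction, het_expected)
    if config.strip_homotypic:
        pooled = strip_homotypic_doublets(pooled)
    pooled.truth.to_tsv(outdir / "manifest.tsv")

    assignments, model = run_demux(
        pooled.counts, config.n_individuals, config.demux,
        clusters_path=outdir / "clusters.tsv",
    )

    tag_map = {sid: f"tag_{sid}" for sid in pooled.pool_proportions}
    tag_counts = simulate_tag_counts(
        pooled.truth, tag_map,
        mean_capture=config.mean_capture, background_rate=config.background_rate,
        seed=stage_seed(config.seed, "tags"),
    )
    tag_calls = classify_by_tags(tag_counts)
    tag_calls.to_csv(outdir / "tag_calls.tsv", sep="\t", index=False)

    # evaluation
    truth_ident = pooled.truth.table.set_index("barcode").apply(
        lambda r: "doublet" if r.droplet_type == "doublet" else r.origin1, axis=1,
    )
    pred = assignments.set_index("barcode").apply(
        lambda r: r.status if r.status != "singlet" else r.assignment, axis=1,
    )
    table = ev.contingency_table(truth_ident, pred)
    table.to_csv(outdir / "contingency.tsv", sep="\t")
    singlet_table = table.loc[
        [r for r in table.index if r not in ev.RESERVED_LABELS],
        [c for c in table.columns if c not in ev.RESERVED_LABELS],
    ]
    match = ev.match_clusters(singlet_table) if singlet_table.size else {"mapping": {}}
    mapped = ev.map_predictions(pred, match)
    report, overall_accuracy = ev.accuracy_report(truth_ident, mapped)
    report.to_csv(outdir / "accuracy.tsv", sep="\t", index=False)

    dmetrics = ev.doublet_metrics(pooled.truth, assignments)
    depths = pd.Series(pooled.counts.total_depth, index=pooled.counts.barcodes)
    n_bins = min(config.n_bins, len(depths))
    id_curve = ev.binned_id_rate(depths, mapped, n_bins=n_bins)
    id_curve.to_csv(outdir / "binned_id_rate.tsv", sep="\t", index=False)
    density_table, mean_density = ev.snp_density(
        {c: panel.positions[panel.contigs == c] for c in panel.contig_names},
        panel.contig_lengths,
    )
    density_table.to_csv(outdir / "snp_density.tsv", sep="\t", index=False)

    retained = filter_cells(
        depths,
        tag_sums=pd.Series(tag_counts.counts.sum(axis=1), index=tag_counts.barcodes),
        depth_bounds=config.depth_bounds,
        require_positive_tags=config.require_positive_tags,
    )

    unassigned_pct = 100.0 * float((assignments.status == "unassigned").mean())
    summary = {
        "n_pooled_barcodes": int(pooled.counts.n_cells),
        "doublet_fraction": float(doublet_fraction),
        "expected_heterotypic_fraction": float(het_expected),
        "mean_snps_per_kb": mean_density,
        "overall_singlet_accuracy_pct": float(overall_accuracy),
        "unassigned_pct": unassigned_pct,
        "heterotypic_recall": dmetrics.heterotypic_recall,
        "confirmed_doublets": dmetrics.confirmed,
        "contested_truth_only": dmetrics.contested_truth_only,
        "contested_prediction_only": dmetrics.contested_prediction_only,
        "n_cells_passing_filter": len(retained),
    }
    pd.Series(summary).to_csv(outdir / "summary.tsv", sep="\t", header=False)
    log.info("summary: %s", summary)
    return summary
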