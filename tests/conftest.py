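import numpy as np
import pandas as pd
import pytest

import demuxbench as db


def split_by_individual(counts, truth):
    """Per-sample (AlleleCountMatrix, sample_id) pairs from a singlet run."""
    bc = {b: i for i, b in enumerate(counts.barcodes)}
    samples = []
    for ind, grp in truth.table.groupby("origin1", sort=True):
        idx = np.array([bc[b] for b in grp.barcode])
        samples.append((counts.subset(idx), str(ind)))
    return samples


def simulate_pooled(k, seed, *, cells=150, density=0.35, genome=10_000_000,
                    doublet_rate=0.1, informative_fraction=0.05, strip=True):
    """simulate -> pool (-> strip homotypic) at benchmark conditions."""
    panel = db.simulate_genotypes(k, genome, density, seed=seed)
    counts, truth = db.simulate_cells(
        panel, cells, informative_fraction=informative_fraction, seed=seed + 1000)
    pooled = db.pool_counts(
        split_by_individual(counts, truth), doublet_rate, seed=seed + 2000)
    if strip:
        pooled = db.strip_homotypic_doublets(pooled)
    return panel, pooled


def truth_identity(manifest):
    """Series: barcode -> individual for singlets, 'doublet' for doublets."""
    t = manifest.table.set_index("barcode")
    return pd.Series(
        np.where(t.droplet_type == "doublet", "doublet", t.origin1),
        index=t.index,
    )


def predicted_identity(assignments):
    """Series: barcode -> cluster id for singlets, else the status."""
    a = assignments.set_index("barcode")
    return pd.Series(
        np.where(a.status == "singlet", a.assignment, a.status), index=a.index)


@pytest.fixture(scope="session")
def recovery_run():
    """The diverse-panel recovery regime: k=3 pool at 0.35 SNPs/kb.

    500 cells per individual, doublet rate 0.1, seed 50 — the benchmark's
    reference pooling conditions.
    """
    panel, pooled = simulate_pooled(3, seed=50, cells=500)
    assignments, model = db.demux(pooled.counts, 3, db.DemuxConfig(seed=50))
    return panel, pooled, assignments, model


@pytest.fixture(scope="session")
def isogenic_run():
    """Isogenic pool: identical genotype vectors across three individuals."""
    panel = db.simulate_genotypes(3, 10_000_000, 0.35, seed=50, isogenic=True)
    counts, truth = db.simulate_cells(panel, 150, seed=1050)
    pooled = db.pool_counts(split_by_individual(counts, truth), 0.1, seed=2050)
    pooled = db.strip_homotypic_doublets(pooled)
    assignments, model = db.demux(pooled.counts, 3, db.DemuxConfig(seed=50, n_restarts=4))
    return panel, pooled, assignments, model


@pytest.fixture()
def small_panel():
    return db.simulate_genotypes(3, 100_000, 0.3, seed=7)
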