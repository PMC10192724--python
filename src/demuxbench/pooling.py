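"""In silico pooling of per-sample cell sets with synthetic doublets.

Pooling works at two levels that share one sampling plan: count-level
(summing ref/alt count vectors of doublet partners) and read-level
(streaming aligned-read files, rewriting cell-barcode tags so a doublet's
two parents share one pooled barcode). Ground truth — which pooled barcode
came from which sample, and which are synthetic doublets — is recorded in a
:class:`~demuxbench.synthdata.TruthManifest`.

The doublet rate ``d`` is defined as the fraction of *emitted pooled
barcodes* that are doublets, so a pool built with ``d = 0.1`` can be checked
directly against its manifest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthdata import AlleleCountMatrix, TruthManifest

__all__ = [
    "PooledDataset",
    "PoolPlan",
    "plan_pool",
    "pool_counts",
    "pool_alignment_files",
    "expected_heterotypic_fraction",
    "strip_homotypic_doublets",
]

REGION_PAD = 200  # bp around each variant locus retained in region mode


@dataclass
class PooledDataset:
    counts: AlleleCountMatrix
    truth: TruthManifest
    pool_proportions: dict[str, float]


@dataclass
class PoolPlan:
    """Deterministic sampling plan shared by count- and read-level pooling.

    ``selected`` holds, per sample, the original barcodes drawn; ``members``
    maps each pooled barcode to its (sample_id, original barcode) parents
    (one for singlets, two for doublets).
    """

    sample_ids: list[str]
    selected: dict[str, list[str]]
    members: dict[str, list[tuple[str, str]]]
    truth: TruthManifest


def _pooled_barcode(barcode: str, sample_index: int) -> str:
    stem = barcode[:-2] if barcode.endswith("-1") else barcode
    return f"{stem}-s{sample_index}"


def plan_pool(
    barcode_lists: list[tuple[str, list[str]]],
    doublet_rate: float,
    cells_per_sample: int | None,
    seed: int,
) -> PoolPlan:
    """Choose cells and doublet pairings.

    Samples ``cells_per_sample`` barcodes per input without replacement
    (all barcodes when None). With N cells drawn in total, the number of
    doublets D solves D / (N - D) = d, so the manifest doublet fraction
    matches ``doublet_rate`` up to rounding. Doublet partners are drawn
    uniformly from the pooled candidate set, making the heterotypic share
    follow 1 - sum(p_i^2) of the pool proportions.
    """
    if not (0 <= doublet_rate < 1):
        raise ValueError("doublet_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    selected: dict[str, list[str]] = {}
    candidates: list[tuple[int, str, str]] = []  # (sample index, sample id, barcode)
    for i, (sample_id, barcodes) in enumerate(barcode_lists):
        if cells_per_sample is None:
            chosen = list(barcodes)
        else:
            if cells_per_sample > len(barcodes):
                raise ValueError(
                    f"sample {sample_id!r} has {len(barcodes)} cells, "
                    f"{cells_per_sample} requested"
                )
            idx = rng.choice(len(barcodes), size=cells_per_sample, replace=False)
            chosen = [barcodes[j] for j in sorted(idx)]
        selected[sample_id] = chosen
        candidates.extend((i, sample_id, bc) for bc in chosen)

    n = len(candidates)
    n_doublets = int(round(doublet_rate * n / (1 + doublet_rate)))
    order = rng.permutation(n)
    doublet_cells = order[: 2 * n_doublets]
    singlet_cells = np.sort(order[2 * n_doublets:])

    members: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for j in singlet_cells:
        i, sid, bc = candidates[j]
        pooled = _pooled_barcode(bc, i)
        members[pooled] = [(sid, bc)]
        rows.append((pooled, "singlet", sid, None, "not-applicable", sid))
    for a, b in zip(doublet_cells[::2], doublet_cells[1::2]):
        ia, sa, bca = candidates[a]
        ib, sb, bcb = candidates[b]
        pooled = _pooled_barcode(bca, ia)
        members[pooled] = [(sa, bca), (sb, bcb)]
        cls = "heterotypic" if sa != sb else "homotypic"
        rows.append((pooled, "doublet", sa, sb, cls, sa))

    table = pd.DataFrame(
        rows,
        columns=["barcode", "droplet_type", "origin1", "origin2",
                 "doublet_class", "source_sample"],
    ).sort_values("barcode", kind="stable", ignore_index=True)
    truth = TruthManifest(
        table=table, doublet_rate=doublet_rate, seed=seed,
        cells_per_sample=cells_per_sample,
    )
    return PoolPlan(
        sample_ids=[sid for sid, _ in barcode_lists],
        selected=selected, members=members, truth=truth,
    )


def pool_counts(
    samples: list[tuple[AlleleCountMatrix, str]],
    doublet_rate: float = 0.1,
    cells_per_sample: int | None = None,
    seed: int = 0,
) -> PooledDataset:
    """Pool count matrices with synthetic doublets.

    Every singlet's pooled count vector equals its source vector; a doublet's
    vector is the element-wise sum of its two parents' ref/alt counts and
    depths, exactly as two cells sharing a droplet would superpose.
    """
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    n_loci = samples[0][0].n_loci
    if any(m.n_loci != n_loci for m, _ in samples):
        raise ValueError("samples must be indexed against the same variant panel")

    plan = plan_pool(
        [(sid, m.barcodes) for m, sid in samples],
        doublet_rate, cells_per_sample, seed,
    )
    lookup = {
        sid: ({bc: i for i, bc in enumerate(m.barcodes)}, m)
        for m, sid in samples
    }

    pooled_barcodes = plan.truth.table.barcode.tolist()
    ref = np.zeros((len(pooled_barcodes), n_loci), dtype=np.int64)
    alt = np.zeros_like(ref)
    depth = np.zeros(len(pooled_barcodes), dtype=np.int64)
    for row, pooled in enumerate(pooled_barcodes):
        for sid, bc in plan.members[pooled]:
            idx, m = lookup[sid]
            i = idx[bc]
            ref[row] += m.ref_counts[i]
            alt[row] += m.alt_counts[i]
            depth[row] += m.total_depth[i]

    counts = AlleleCountMatrix(
        barcodes=pooled_barcodes, ref_counts=ref, alt_counts=alt, total_depth=depth,
    )
    n_selected = sum(len(v) for v in plan.selected.values())
    proportions = {sid: len(v) / n_selected for sid, v in plan.selected.items()}
    return PooledDataset(counts=counts, truth=plan.truth, pool_proportions=proportions)


# ---------------------------------------------------------------------------
# Read-level pooling
# ---------------------------------------------------------------------------

def _region_index(region_file: str, pad: int = REGION_PAD) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged padded intervals per contig from a variant file (0-based half-open)."""
    import pysam

    by_contig: dict[str, list[tuple[int, int]]] = {}
    with pysam.VariantFile(str(region_file)) as vf:
        for rec in vf:
            by_contig.setdefault(rec.contig, []).append(
                (max(0, rec.start - pad), rec.stop + pad)
            )
    index = {}
    for contig, ivals in by_contig.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        index[contig] = (arr[:, 0], arr[:, 1])
    return index


def _overlaps(index, contig: str, start: int, end: int) -> bool:
    if contig not in index:
        return False
    starts, ends = index[contig]
    i = int(np.searchsorted(ends, start, side="right"))
    return i < starts.size and starts[i] < end


def pool_alignment_files(
    read_files: list[str],
    barcode_lists: list[str] | list[list[str]],
    out_bam: str,
    out_barcodes: str,
    doublet_rate: float = 0.1,
    cells_per_sample: int | None = None,
    seed: int = 0,
    region_file: str | None = None,
    no_region_mode: bool = False,
    sample_ids: list[str] | None = None,
) -> tuple[TruthManifest, dict]:
    """Pool aligned-read files into one with synthetic doublets.

    Streams each input once, keeping only reads whose CB tag belongs to that
    sample's selected cells and — when a variant file is supplied — only
    reads overlapping a listed locus (padded by ±200 bp). ``no_region_mode``
    retains all reads of selected barcodes, for species without a usable
    variant file. Each retained read's CB is rewritten to the pooled barcode;
    a synthetic doublet's second parent is rewritten to the first parent's
    pooled barcode. Output is coordinate-sorted and indexed, alongside a
    pooled barcode list. Peak memory is bounded by the selected-barcode maps
    plus one in-flight read, independent of total read count.
    """
    import pysam

    if region_file is None and not no_region_mode:
        raise ValueError("supply region_file or set no_region_mode")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(len(read_files))]

    lists: list[tuple[str, list[str]]] = []
    for sid, bl in zip(sample_ids, barcode_lists):
        if isinstance(bl, str):
            with open(bl) as fh:
                barcodes = [line.strip() for line in fh if line.strip()]
        else:
            barcodes = list(bl)
        if not barcodes:
            raise ValueError(f"empty barcode list for {sid}")
        lists.append((sid, barcodes))

    plan = plan_pool(lists, doublet_rate, cells_per_sample, seed)
    # per-sample map: original barcode -> pooled barcode
    rewrite: list[dict[str, str]] = [dict() for _ in read_files]
    sid_to_idx = {sid: i for i, sid in enumerate(sample_ids)}
    for pooled, parents in plan.members.items():
        for sid, bc in parents:
            rewrite[sid_to_idx[sid]][bc] = pooled

    regions = None if region_file is None else _region_index(region_file)
    stats = {
        "barcode_map_entries": sum(len(m) for m in rewrite),
        "reads_in": 0,
        "reads_out": 0,
        "missing_barcodes": [],
    }
    for (sid, barcodes), m in zip(lists, rewrite):
        missing = set(m) - set(barcodes)
        if missing:  # cannot happen via plan_pool; guards external plans
            stats["missing_barcodes"].extend(sorted(missing))

    tmp = str(out_bam) + ".unsorted"
    first = pysam.AlignmentFile(str(read_files[0]))
    header = first.header.to_dict()
    first.close()
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for path, mapping in zip(read_files, rewrite):
            seen: set[str] = set()
            with pysam.AlignmentFile(str(path)) as bam:
                if not bam.has_index():
                    raise ValueError(f"{path} is not indexed")
                for read in bam.fetch():
                    stats["reads_in"] += 1
                    if not read.has_tag("CB"):
                        continue
                    cb = read.get_tag("CB")
                    if cb not in mapping:
                        continue
                    if regions is not None and not _overlaps(
                        regions, read.reference_name,
                        read.reference_start, read.reference_end or read.reference_start + 1,
                    ):
                        continue
                    seen.add(cb)
                    read.set_tag("CB", mapping[cb])
                    out.write(read)
                    stats["reads_out"] += 1
            absent = set(mapping) - seen
            if absent:
                stats["missing_barcodes"].extend(sorted(absent))
    pysam.sort("-o", str(out_bam), tmp)
    os.remove(tmp)
    pysam.index(str(out_bam))

    with open(out_barcodes, "w") as fh:
        for bc in plan.truth.table.barcode:
            fh.write(bc + "\n")
    return plan.truth, stats


# ---------------------------------------------------------------------------
# Pool arithmetic and filtering
# ---------------------------------------------------------------------------

def expected_heterotypic_fraction(pool_proportions) -> float:
    """Expected share of doublets that are heterotypic: 1 - sum(p_i^2).

    With k equal pools this is (k-1)/k — 2/3 for three samples, 3/4 for four —
    the arithmetic behind heterotypic-only doublet detection losing more
    doublets in smaller pools.
    """
    p = np.asarray(list(pool_proportions), dtype=float)
    if p.size == 0 or np.any(p < 0):
        raise ValueError("proportions must be non-negative and non-empty")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return float(1.0 - np.sum(p ** 2))


def strip_homotypic_doublets(pooled: PooledDataset) -> PooledDataset:
    """Drop homotypic synthetic doublets from counts and manifest.

    Genotype-based demultiplexers detect only intergenotypic doublets, so
    same-individual doublets are removed before doublet benchmarking.
    """
    table = pooled.truth.table
    keep = table.doublet_class != "homotypic"
    idx = np.flatnonzero(keep.to_numpy())
    truth = replace(pooled.truth, table=table.loc[keep].reset_index(drop=True))
    return PooledDataset(
        counts=pooled.counts.subset(idx),
        truth=truth,
        pool_proportions=pooled.pool_proportions,
    )
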