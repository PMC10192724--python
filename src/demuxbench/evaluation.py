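"""Benchmark statistics: cluster-truth matching, accuracy, doublet confusion,
depth-binned identification and agreement curves, SNP density, and
cluster-composition reports.

Predicted cluster labels are arbitrary integers, so every accuracy statistic
first maps clusters onto truth identities; the default objective is the
optimal one-to-one assignment maximizing matched cell counts (solved exactly
with the Hungarian algorithm), with a correlation-based objective available
as an alternative. Reserved labels — "doublet", "unassigned", "negative" —
never participate in matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .synthdata import TruthManifest, VariantPanel

__all__ = [
    "RESERVED_LABELS",
    "DENSITY_BAND",
    "DoubletMetrics",
    "contingency_table",
    "match_clusters",
    "accuracy_report",
    "doublet_metrics",
    "binned_id_rate",
    "agreement_curve",
    "snp_density",
    "cluster_composition",
    "filter_variants_by_maf",
]

RESERVED_LABELS = ("doublet", "unassigned", "negative")
# SNP densities below this band make genotype-based demultiplexing unreliable
DENSITY_BAND = (0.2, 0.34)


def contingency_table(truth: pd.Series, predicted: pd.Series) -> pd.DataFrame:
    """Truth x predicted cell-count table over the shared barcodes."""
    shared = truth.index.intersection(predicted.index)
    return pd.crosstab(truth.loc[shared], predicted.loc[shared])


def match_clusters(
    contingency: pd.DataFrame,
    method: str = "counts",
) -> dict:
    """One-to-one map from predicted cluster to truth identity.

    ``method='counts'`` maximizes the total count on matched pairs (optimal
    assignment); ``method='correlation'`` maximizes summed Pearson
    correlation between truth and predicted indicator vectors, the
    "correlation analysis" wording used when relabelling genotype clusters
    after the fact. Both coincide on well-separated tables. Rows/columns with
    reserved labels are excluded; surplus predicted clusters map to None.
    """
    rows = [r for r in contingency.index if str(r) not in RESERVED_LABELS]
    cols = [c for c in contingency.columns if str(c) not in RESERVED_LABELS]
    if not rows or not cols:
        raise ValueError("need at least one truth identity and one predicted cluster")
    sub = contingency.loc[rows, cols].to_numpy(dtype=float)

    if method == "counts":
        score = sub
    elif method == "correlation":
        n = sub.sum()
        score = np.zeros_like(sub)
        rs, cs = sub.sum(axis=1), sub.sum(axis=0)
        for i in range(len(rows)):
            for j in range(len(cols)):
                # Pearson correlation of the truth/predicted 0-1 indicators
                num = sub[i, j] / n - (rs[i] / n) * (cs[j] / n)
                den = np.sqrt(rs[i] / n * (1 - rs[i] / n) * cs[j] / n * (1 - cs[j] / n))
                score[i, j] = num / den if den > 0 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    ri, ci = linear_sum_assignment(score, maximize=True)
    mapping = {cols[j]: rows[i] for i, j in zip(ri, ci)}
    for c in cols:
        mapping.setdefault(c, None)
    return {
        "mapping": mapping,
        "scores": {cols[j]: float(score[i, j]) for i, j in zip(ri, ci)},
        "method": method,
    }


def map_predictions(predicted: pd.Series, mapping: dict) -> pd.Series:
    """Relabel predicted clusters through a match_clusters mapping."""
    m = mapping["mapping"] if isinstance(mapping, dict) and "mapping" in mapping else mapping
    return predicted.map(lambda x: x if str(x) in RESERVED_LABELS else m.get(x))


def accuracy_report(
    truth: pd.Series,
    predicted_mapped: pd.Series,
    identities: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-identity assignment counts/percentages and overall singlet accuracy.

    ``truth`` holds each barcode's true identity ("doublet" for true
    doublets); ``predicted_mapped`` holds mapped predictions. Identities with
    zero cells (e.g., an animal absent from the pool) stay in the report with
    zero counts rather than being dropped.
    """
    if identities is None:
        identities = sorted(set(truth.unique()) - set(RESERVED_LABELS))
    shared = truth.index.intersection(predicted_mapped.index)
    truth, predicted_mapped = truth.loc[shared], predicted_mapped.loc[shared]

    columns = identities + ["doublet", "unassigned", "other"]
    rows = []
    correct = total = 0
    for ident in identities:
        mask = truth == ident
        preds = predicted_mapped[mask]
        counts = {c: 0 for c in columns}
        for p in preds:
            if p in identities:
                counts[p] += 1
            elif p == "doublet":
                counts["doublet"] += 1
            elif p in ("unassigned", "negative", None):
                counts["unassigned"] += 1
            else:
                counts["other"] += 1
        n = int(mask.sum())
        correct += counts[ident]
        total += n
        row = {"identity": ident, "n_cells": n}
        row.update({f"n_{c}": counts[c] for c in columns})
        row.update({
            f"pct_{c}": (100.0 * counts[c] / n if n else 0.0) for c in columns
        })
        rows.append(row)
    report = pd.DataFrame(rows)
    overall = 100.0 * correct / total if total else float("nan")
    return report, overall


@dataclass
class DoubletMetrics:
    """Doublet confusion between ground truth and a demultiplexer.

    A *confirmed* doublet is called doublet by both; a *contested* doublet is
    disputed — split into truth-only (true doublet the demuxer missed) and
    prediction-only (true singlet the demuxer called doublet). Heterotypic
    recall counts only intergenotypic doublets, the sole kind a genotype
    demuxer can see; homotypic doublets are excluded.
    """

    confirmed: int
    contested_truth_only: int
    contested_prediction_only: int
    n_true_heterotypic: int
    confirmed_heterotypic: int

    @property
    def heterotypic_recall(self) -> float | None:
        if self.n_true_heterotypic == 0:
            return None
        return self.confirmed_heterotypic / self.n_true_heterotypic


def doublet_metrics(truth: TruthManifest, predictions: pd.DataFrame) -> DoubletMetrics:
    """Compare manifest doublet ground truth with demultiplexer status calls.

    ``predictions`` needs columns barcode and status.
    """
    t = truth.table.set_index("barcode")
    p = predictions.set_index("barcode")["status"].reindex(t.index)

    is_true_doublet = t.droplet_type == "doublet"
    is_pred_doublet = p == "doublet"

    confirmed = int((is_true_doublet & is_pred_doublet).sum())
    truth_only = int((is_true_doublet & ~is_pred_doublet).sum())
    pred_only = int((~is_true_doublet & is_pred_doublet).sum())
    het = is_true_doublet & (t.doublet_class == "heterotypic")
    return DoubletMetrics(
        confirmed=confirmed,
        contested_truth_only=truth_only,
        contested_prediction_only=pred_only,
        n_true_heterotypic=int(het.sum()),
        confirmed_heterotypic=int((het & is_pred_doublet).sum()),
    )


def _depth_bins(depths: pd.Series, n_bins: int) -> list[np.ndarray]:
    """Contiguous near-equal bins over depth-sorted cells.

    Ties broken by barcode; remainder cells go to the lowest-depth bins, so
    bin sizes differ by at most one with the larger bins first.
    """
    if n_bins > len(depths):
        raise ValueError("more bins than cells")
    order = depths.reset_index()
    order.columns = ["barcode", "depth"]
    order = order.sort_values(["depth", "barcode"], kind="stable")
    idx = order.index.to_numpy()
    base, rem = divmod(len(idx), n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    bins, start = [], 0
    for s in sizes:
        bins.append(np.arange(start, start + s))
        start += s
    positions = order.barcode.to_numpy()
    return [positions[b] for b in bins]


def binned_id_rate(
    depths: pd.Series,
    calls: pd.Series,
    n_bins: int = 40,
    assigned_predicate=None,
    tag_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """Cell ID % against read depth: the depth-binned identification curve.

    Cells are sorted by depth and split into ``n_bins`` contiguous groups;
    per bin, the metric is the percentage of cells whose call satisfies
    ``assigned_predicate`` (default: any singlet identity, i.e., neither
    doublet, negative nor unassigned).
    """
    if assigned_predicate is None:
        assigned_predicate = lambda c: c is not None and str(c) not in RESERVED_LABELS
    out = []
    for b, barcodes in enumerate(_depth_bins(depths, n_bins)):
        sub = calls.loc[barcodes]
        pct = 100.0 * np.mean([assigned_predicate(c) for c in sub])
        row = {
            "bin": b,
            "mean_depth": float(depths.loc[barcodes].mean()),
            "metric_pct": float(pct),
            "n_cells": len(barcodes),
        }
        if tag_reads is not None:
            row["mean_tag_reads"] = float(tag_reads.loc[barcodes].mean())
        out.append(row)
    return pd.DataFrame(out)


def agreement_curve(
    calls_a: pd.Series,
    calls_b: pd.Series,
    depths: pd.Series,
    n_bins: int = 40,
) -> pd.DataFrame:
    """Percent agreement between two call sets, binned by read depth.

    Both call series must already live in a common label space (e.g., one of
    them mapped through match_clusters).
    """
    shared = calls_a.index.intersection(calls_b.index).intersection(depths.index)
    a, b, d = calls_a.loc[shared], calls_b.loc[shared], depths.loc[shared]
    out = []
    for i, barcodes in enumerate(_depth_bins(d, n_bins)):
        agree = 100.0 * float((a.loc[barcodes] == b.loc[barcodes]).mean())
        out.append({
            "bin": i,
            "mean_depth": float(d.loc[barcodes].mean()),
            "metric_pct": agree,
            "n_cells": len(barcodes),
        })
    return pd.DataFrame(out)


def snp_density(
    positions: dict[str, np.ndarray],
    contig_lengths: dict[str, int] | None = None,
    window: int = 1000,
) -> tuple[pd.DataFrame, float]:
    """Variant density in fixed windows and the mean SNPs/kb across windows.

    Each contig is tiled with ``window``-bp windows starting at position 1.
    Without contig lengths, tiling stops at the last variant-bearing window;
    with lengths supplied, the whole contig is tiled. The mean includes
    zero-count windows. Means inside or below the 0.2–0.34 SNPs/kb band mark
    panels where genotype demultiplexing is expected to degrade or fail.
    """
    rows = []
    for contig, pos in positions.items():
        pos = np.asarray(pos)
        if contig_lengths is not None:
            n_windows = max(1, -(-int(contig_lengths[contig]) // window))
        elif pos.size:
            n_windows = int((pos.max() - 1) // window) + 1
        else:
            n_windows = 0
        counts = np.zeros(n_windows, dtype=int)
        if pos.size and n_windows:
            w = (pos - 1) // window
            np.add.at(counts, w[w < n_windows], 1)
        for i in range(n_windows):
            rows.append({
                "contig": contig,
                "window_start": i * window + 1,
                "n_variants": int(counts[i]),
                "snps_per_kb": counts[i] / (window / 1000.0),
            })
    table = pd.DataFrame(rows, columns=["contig", "window_start", "n_variants", "snps_per_kb"])
    if table.empty:
        import warnings
        warnings.warn("no variants supplied: density 0")
        return table, 0.0
    mean = float(table.snps_per_kb.mean())
    table.attrs["mean_snps_per_kb"] = mean
    table.attrs["below_viability_band"] = mean < DENSITY_BAND[0]
    table.attrs["in_viability_band"] = DENSITY_BAND[0] <= mean <= DENSITY_BAND[1]
    return table, mean


def cluster_composition(
    cluster_labels: pd.Series,
    identities: pd.Series,
    pool_size: int | None = None,
) -> pd.DataFrame:
    """Animal makeup of each transcriptional cluster.

    For each cluster: number of distinct animals, per-animal cell counts, and
    doublet percentage. Clusters containing fewer animals than the pool size
    are flagged — they break the common assumption that every cluster holds
    cells from all biological replicates.
    """
    shared = cluster_labels.index.intersection(identities.index)
    cl, ids = cluster_labels.loc[shared], identities.loc[shared]
    animals = sorted(set(ids.unique()) - set(RESERVED_LABELS))
    rows = []
    for cluster in sorted(cl.unique(), key=str):
        sub = ids[cl == cluster]
        per_animal = {a: int((sub == a).sum()) for a in animals}
        n_animals = sum(1 for v in per_animal.values() if v > 0)
        row = {
            "cluster": cluster,
            "n_cells": len(sub),
            "n_animals": n_animals,
            "pct_doublet": 100.0 * float((sub == "doublet").mean()),
        }
        row.update({f"n_{a}": per_animal[a] for a in animals})
        if pool_size is not None:
            row["missing_animals"] = n_animals < pool_size
        rows.append(row)
    return pd.DataFrame(rows)


def filter_variants_by_maf(panel: VariantPanel, min_maf: float = 0.05) -> VariantPanel:
    """Keep variants with minor-allele frequency >= ``min_maf`` (inclusive)."""
    return panel.subset_loci(panel.maf >= min_maf)
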