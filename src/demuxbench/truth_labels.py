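"""Orthogonal "wet-lab" ground-truth labels and cell-quality filters.

Three experimental truth sources are modelled: fluorescent-transgene or CMO
tag counts (classified by a quantile-threshold sweep in the spirit of
MULTIseq-style auto-thresholding), two-species read fractions (barnyard
classification), and the mapped-read-depth quality window used to restrict
benchmarking to cells whose truth label is trustworthy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthdata import TagCountMatrix

__all__ = [
    "classify_by_tags",
    "classify_barnyard",
    "filter_cells",
    "DEFAULT_QUANTILE_GRID",
    "DEPTH_BOUNDS",
]

DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.10, 0.901, 0.05), 2))
DEPTH_BOUNDS = (5_000, 40_000)  # mapped-read quality window, inclusive


def classify_by_tags(
    tags: TagCountMatrix,
    quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Call each droplet from its tag counts: one tag, doublet, or negative.

    Counts are log1p-transformed. For each candidate quantile ``q`` in the
    grid, every tag's threshold is the ``q``-quantile of that tag's
    *positive-cell* (count > 0) distribution; a cell is positive for a tag
    when its transformed count meets the threshold. The shared quantile
    maximizing the overall singlet proportion is kept (ties to the lowest
    quantile — deterministic; ``seed`` is accepted for interface symmetry).
    Optimizing quantiles per tag instead would degenerately suppress true
    doublets by pushing one tag's threshold above its signal mode, so the
    quantile is shared.

    Call rule: exactly one positive tag -> that tag; two or more -> doublet;
    none -> negative. With sparse capture, one or two stray counts on two
    tags can clear their thresholds, producing the erroneous doublet calls
    low-capture labelling is known for.

    Returns a frame with columns barcode, call, threshold and one
    ``signal_<tag>`` column per tag; per-tag thresholds and the chosen
    quantile ride in ``.attrs``.
    """
    if len(tags.tags) < 1:
        raise ValueError("need at least one tag")
    if len(tags.barcodes) < 10:
        raise ValueError("need at least 10 cells")

    x = np.log1p(tags.counts.astype(float))
    n_cells, n_tags = x.shape

    if tags.counts.sum() == 0:
        warnings.warn("all-zero tag matrix: every cell called negative")
        out = pd.DataFrame({"barcode": tags.barcodes, "call": "negative",
                            "threshold": np.nan})
        for j, t in enumerate(tags.tags):
            out[f"signal_{t}"] = x[:, j]
        out.attrs["thresholds"] = {t: np.nan for t in tags.tags}
        out.attrs["quantile"] = np.nan
        return out

    candidates = np.full((n_tags, len(quantile_grid)), np.inf)
    for j in range(n_tags):
        pos = x[tags.counts[:, j] > 0, j]
        if pos.size:
            candidates[j] = np.quantile(pos, quantile_grid)

    best_q, best_thresholds, best_singlets = None, None, -1
    for qi, q in enumerate(quantile_grid):
        thresholds = candidates[:, qi]
        n_singlet = int(np.sum((x >= thresholds).sum(axis=1) == 1))
        if n_singlet > best_singlets:
            best_singlets, best_q, best_thresholds = n_singlet, q, thresholds

    positive = x >= best_thresholds
    n_pos = positive.sum(axis=1)
    calls = np.where(
        n_pos == 0, "negative",
        np.where(n_pos >= 2, "doublet",
                 np.array(tags.tags, dtype=object)[np.argmax(positive, axis=1)]),
    )
    called_thr = np.where(
        n_pos == 1, best_thresholds[np.argmax(positive, axis=1)], np.nan,
    )
    out = pd.DataFrame({"barcode": tags.barcodes, "call": calls, "threshold": called_thr})
    for j, t in enumerate(tags.tags):
        out[f"signal_{t}"] = x[:, j]
    out.attrs["thresholds"] = dict(zip(tags.tags, best_thresholds))
    out.attrs["quantile"] = best_q
    return out


def classify_barnyard(
    species_counts: pd.DataFrame,
    purity_threshold: float = 0.8,
) -> pd.DataFrame:
    """Classify droplets of a two-species pool by read-fraction purity.

    A droplet is called a species when that species' fraction of its reads
    is at least ``purity_threshold`` (inclusive); otherwise it is a doublet.
    Zero-read droplets are excluded and listed in ``.attrs['excluded']``.

    ``species_counts``: barcode-indexed frame with exactly two species
    columns of read counts.
    """
    if species_counts.shape[1] != 2:
        raise ValueError("barnyard classification requires exactly 2 species")
    if not (0.5 < purity_threshold <= 1):
        raise ValueError("purity_threshold must lie in (0.5, 1]")

    totals = species_counts.sum(axis=1)
    excluded = species_counts.index[totals == 0].tolist()
    kept = species_counts[totals > 0]
    fractions = kept.div(kept.sum(axis=1), axis=0)

    sp = list(species_counts.columns)
    call = np.where(
        fractions[sp[0]] >= purity_threshold, sp[0],
        np.where(fractions[sp[1]] >= purity_threshold, sp[1], "doublet"),
    )
    out = pd.DataFrame({
        "barcode": kept.index,
        f"fraction_{sp[0]}": fractions[sp[0]].to_numpy(),
        f"fraction_{sp[1]}": fractions[sp[1]].to_numpy(),
        "call": call,
    }).reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out


def filter_cells(
    depths: pd.Series,
    tag_sums: pd.Series | None = None,
    depth_bounds: tuple[float, float] = DEPTH_BOUNDS,
    require_positive_tags: bool = False,
) -> list[str]:
    """Retain barcodes inside the mapped-read window, optionally with tags.

    Both depth bounds are inclusive. With ``require_positive_tags``, cells
    with a zero summed tag count are dropped as well (no truth label can be
    derived for them).
    """
    lo, hi = depth_bounds
    keep = (depths >= lo) & (depths <= hi)
    if require_positive_tags:
        if tag_sums is None:
            raise ValueError("require_positive_tags needs tag_sums")
        keep &= tag_sums.reindex(depths.index).fillna(0) > 0
    return depths.index[keep].tolist()
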