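"""State-feature enrichment, genic occupancy, and the rank-difference DGE
statistic.

Fold enrichment of a feature in a state is the frequency of the feature
among the state's bins relative to its genome-wide frequency,
``P(bin in f | bin in s) / P(bin in f)``; the state-probability-weighted
average of folds is identically 1 for every feature.  Differential gene
expression (DGE) is the absolute difference of a gene's rank fractions
(rank / N, ties mid-ranked) in the two tissues, binned at 0.2 intervals
into five classes; it is invariant under any strictly monotone transform of
either tissue's expression scale.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import BinGrid, ValidationError, rasterize
from .genes import GeneModel
from .hmm import StateSegmentation

__all__ = [
    "overlap_enrichment",
    "occupancy_split",
    "dge_rank",
    "state_enrichment_by_dge",
    "rolling_dge",
    "gene_bin_footprints",
]

DGE_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _feature_masks(
    features: Mapping[str, object], grid: BinGrid
) -> dict[str, np.ndarray]:
    out = {}
    for name, f in features.items():
        if isinstance(f, np.ndarray):
            if f.shape != (grid.total_bins,):
                raise ValidationError(f"feature mask {name!r} has wrong length")
            out[name] = f.astype(bool)
        else:
            out[name] = rasterize(f, grid)
    return out


def overlap_enrichment(
    seg: StateSegmentation,
    features: Mapping[str, object],
    grid: BinGrid | None = None,
) -> pd.DataFrame:
    """States x features fold-enrichment matrix over grid bins.

    ``features`` maps names to interval frames (rasterized at >=1 bp
    overlap) or precomputed boolean bin masks.  Features covering zero bins
    get a NaN column and a warning, never silent zeros.
    """
    grid = grid or seg.grid
    if grid.total_bins != seg.grid.total_bins:
        raise ValidationError("segmentation and grid disagree on bin count")
    masks = _feature_masks(features, grid)
    T = grid.total_bins
    out = np.empty((seg.K, len(masks)))
    state_counts = np.bincount(seg.labels, minlength=seg.K).astype(float)
    for j, (name, mask) in enumerate(masks.items()):
        cf = mask.sum()
        if cf == 0:
            warnings.warn(f"feature {name!r} covers zero bins; enrichment undefined")
            out[:, j] = np.nan
            continue
        joint = np.bincount(seg.labels[mask], minlength=seg.K).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = (joint / state_counts) / (cf / T)
        out[state_counts == 0, j] = np.nan
    return pd.DataFrame(out, index=list(seg.state_names), columns=list(masks))


def occupancy_split(seg: StateSegmentation, genic: object) -> pd.DataFrame:
    """Percentage of genic and of intergenic bins occupied by each state.

    Each column sums to 100 over states.
    """
    mask = _feature_masks({"genic": genic}, seg.grid)["genic"]
    rows = {}
    for name, m in (("genic_pct", mask), ("intergenic_pct", ~mask)):
        tot = m.sum()
        counts = np.bincount(seg.labels[m], minlength=seg.K).astype(float)
        rows[name] = 100.0 * counts / tot if tot else np.full(seg.K, np.nan)
    return pd.DataFrame(rows, index=list(seg.state_names))


# ---------------------------------------------------------------------------
# DGE


def dge_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Rank-difference differential expression between the two tissues.

    Each tissue's expression is ranked ascending with ties mid-ranked, and
    divided by the gene count to give a rank fraction in (0, 1]; DGE is the
    absolute difference of the two fractions.  Bins are half-open
    ``[0.2 k, 0.2 (k+1))`` with 0.8 and above in the top bin (labels 1..5).
    """
    if len(table) < 2:
        raise ValidationError("need at least two genes to rank")
    t = table.copy()
    n = len(t)
    t["r_root"] = rankdata(t["root_rpkm"], method="average") / n
    t["r_leaf"] = rankdata(t["leaf_rpkm"], method="average") / n
    t["dge"] = (t["r_root"] - t["r_leaf"]).abs()
    t["dge_bin"] = np.minimum(np.floor(t["dge"] / 0.2).astype(int), 4) + 1
    return t


def gene_bin_footprints(
    models: Sequence[GeneModel], grid: BinGrid
) -> tuple[np.ndarray, dict[str, int]]:
    """Per-bin gene index (-1 intergenic); bins shared by two genes go to the
    lexicographically smaller gene id (rare, deterministic)."""
    order = sorted(range(len(models)), key=lambda i: models[i].gene_id)
    owner = np.full(grid.total_bins, -1, dtype=np.int64)
    w = grid.width
    slices = grid.chrom_slices()
    index = {}
    for i in order:
        g = models[i]
        index[g.gene_id] = i
        sl = slices[g.chrom]
        first, last = g.start // w, (g.end - 1) // w
        view = owner[sl.start + first : sl.start + last + 1]
        view[view == -1] = i
    return owner, index


def state_enrichment_by_dge(
    seg: StateSegmentation,
    models: Sequence[GeneModel],
    dge: pd.DataFrame,
) -> pd.DataFrame:
    """States x DGE-bin fold enrichment over genic bins.

    fold(state, bin) = (fraction of the state's genic bins lying in genes of
    that DGE bin) / (fraction of all genic bins lying in such genes).  Empty
    DGE bins yield NaN columns with a warning.
    """
    owner, _ = gene_bin_footprints(models, seg.grid)
    genic = owner >= 0
    dge_of_gene = dict(zip(dge["gene_id"], dge["dge_bin"]))
    bin_of_bin = np.zeros(seg.grid.total_bins, dtype=np.int64)  # 0 = not scored
    ids = [g.gene_id for g in models]
    lut = np.array([dge_of_gene.get(gid, 0) for gid in ids] + [0], dtype=np.int64)
    bin_of_bin[genic] = lut[owner[genic]]
    scored = genic & (bin_of_bin > 0)

    labels = seg.labels[scored]
    dbins = bin_of_bin[scored]
    total = len(labels)
    state_tot = np.bincount(labels, minlength=seg.K).astype(float)
    out = np.empty((seg.K, 5))
    for b in range(1, 6):
        sel = dbins == b
        nb = sel.sum()
        if nb == 0:
            warnings.warn(f"DGE bin {b} contains no genic bins; enrichment undefined")
            out[:, b - 1] = np.nan
            continue
        joint = np.bincount(labels[sel], minlength=seg.K).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, b - 1] = (joint / state_tot) / (nb / total)
        out[state_tot == 0, b - 1] = np.nan
    return pd.DataFrame(out, index=list(seg.state_names), columns=[1, 2, 3, 4, 5])


def rolling_dge(
    dge: pd.DataFrame,
    models: Sequence[GeneModel],
    windows: tuple[int, int] = (25, 250),
) -> pd.Series:
    """Two-pass centered rolling mean of DGE along each chromosome.

    Genes are ordered by genomic start; the first pass smooths with the
    small window, the second smooths the first pass's output with the large
    window.  Windows shrink at chromosome edges.  A chromosome with fewer
    genes than a window is skipped (NaN) with a warning.
    """
    pos = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start) for g in models],
        columns=["gene_id", "chrom", "start"],
    ).drop_duplicates("gene_id")
    t = dge.merge(pos, on="gene_id", how="inner").sort_values(
        ["chrom", "start", "gene_id"], kind="stable"
    )
    out = pd.Series(np.nan, index=dge["gene_id"], name="rolling_dge")
    for chrom, sub in t.groupby("chrom", sort=True):
        if max(windows) > len(sub):
            warnings.warn(
                f"{chrom}: {len(sub)} genes < window {max(windows)}; skipped"
            )
            continue
        s = sub["dge"].reset_index(drop=True)
        for w in windows:
            s = s.rolling(w, center=True, min_periods=1).mean()
        out.loc[sub["gene_id"].to_numpy()] = s.to_numpy()
    return out
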