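"""Chromosome-scale density profiles and epigenomic zone classification.

Chromatin-state bp-fractions, peak counts, gene and LTR-retrotransposon
counts are tabulated in 1-Mbp bins; chromosomes are then partitioned into
telomere-proximal (TP), gene-rich-interior (GRI) and low-recombining
pericentromeric (LR-PC) zones from z-scored densities of the facultative-
heterochromatin states, the constitutive-heterochromatin states and genes.
The classifier is an explicit operationalization of zones that are otherwise
read visually from density plots; all thresholds are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import BinGrid, PeakSet, ValidationError
from .hmm import StateSegmentation

__all__ = ["DensityProfile", "state_density_profile", "classify_regions", "boundary_distance"]


@dataclass
class DensityProfile:
    """Per-1-Mbp-bin densities: state bp-fractions and feature counts.

    ``frame`` has one row per bin (``chrom, start, end``), a
    ``state_frac_<name>`` column per state, a ``peaks_<mark>`` count column
    per mark, and ``genes`` / ``ltrs`` counts.
    """

    grid: BinGrid
    frame: pd.DataFrame
    state_names: tuple[str, ...]
    mark_names: tuple[str, ...]

    def state_fraction(self, state: str) -> np.ndarray:
        return self.frame[f"state_frac_{state}"].to_numpy()


def _midpoint_counts(df: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    """Count intervals per bin by midpoint, so each element counts once."""
    out = np.zeros(grid.total_bins, dtype=np.int64)
    if len(df) == 0:
        return out
    for chrom, sl in grid.chrom_slices().items():
        sub = df[df["chrom"] == chrom]
        if len(sub) == 0:
            continue
        mid = ((sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2)
        mid = np.clip(mid, 0, grid.layout.length_of(chrom) - 1)
        out[sl] += np.bincount(mid // grid.width, minlength=grid.n_bins(chrom))
    return out


def state_density_profile(
    seg: StateSegmentation,
    genes: pd.DataFrame,
    retros: pd.DataFrame,
    peaks: Mapping[str, PeakSet],
    grid: BinGrid,
) -> DensityProfile:
    """Tabulate state bp-fractions and feature counts on a coarse grid.

    Peaks, genes and retroelements count once each, in the bin holding their
    midpoint; state fractions are exact bp overlaps divided by the actual
    bin length, so the fractions over all states sum to 1 in every bin.
    """
    if grid.layout.names != seg.grid.layout.names:
        raise ValidationError("segmentation and density grid use different layouts")
    frame = grid.bins_frame()
    lengths = grid.bin_lengths().astype(float)
    K = seg.K
    frac = np.zeros((grid.total_bins, K))
    segments = seg.segments()
    w = grid.width
    for r in segments.itertuples(index=False):
        off = grid.offset(r.chrom)
        for b in range(r.start // w, (r.end - 1) // w + 1):
            bs, be = b * w, min((b + 1) * w, grid.layout.length_of(r.chrom))
            ov = min(r.end, be) - max(r.start, bs)
            if ov > 0:
                frac[off + b, r.state_index] += ov
    frac /= lengths[:, None]
    for k, name in enumerate(seg.state_names):
        frame[f"state_frac_{name}"] = frac[:, k]
    for mark in peaks:
        frame[f"peaks_{mark}"] = _midpoint_counts(peaks[mark].df, grid)
    frame["genes"] = _midpoint_counts(genes, grid)
    frame["ltrs"] = _midpoint_counts(retros, grid)
    return DensityProfile(
        grid=grid,
        frame=frame,
        state_names=tuple(seg.state_names),
        mark_names=tuple(peaks),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _majority_smooth(labels: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return labels
    half = width // 2
    out = labels.copy()
    n = len(labels)
    for i in range(n):
        window = labels[max(0, i - half) : min(n, i + half + 1)]
        vals, counts = np.unique(window, return_counts=True)
        top = counts.max()
        winners = set(vals[counts == top])
        if labels[i] not in winners:  # keep current label on ties
            out[i] = sorted(winners, key=lambda v: str(v))[0]
    return out


def classify_regions(
    profile: DensityProfile,
    tp_states: Sequence[str] = ("S2", "S3"),
    het_states: Sequence[str] = ("S9", "S10"),
    thr_tp: float = 0.5,
    thr_het: float = 0.5,
    thr_gene: float = -0.5,
    smoothing: int = 3,
    lrpc_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Partition chromosomes into TP / GRI / LR-PC zones.

    Per 1-Mbp bin, z-scores (pooled over the genome) are computed for the
    summed density of the TP-defining states, of the heterochromatic states,
    and for gene counts.  A bin is TP where the TP-state z exceeds
    ``thr_tp`` and the heterochromatin z; LR-PC where the heterochromatin z
    exceeds ``thr_het`` and the gene z is below ``thr_gene``; GRI otherwise.
    Labels are majority-smoothed and merged into segments tiling each
    chromosome.  A known LR-PC mask (interval frame) bypasses the
    heterochromatin/gene rules for the bins it covers.
    """
    for s in (*tp_states, *het_states):
        if s not in profile.state_names:
            raise ValidationError(f"profile lacks referenced state {s!r}")
    f = profile.frame
    tp_d = sum(profile.state_fraction(s) for s in tp_states)
    het_d = sum(profile.state_fraction(s) for s in het_states)
    gene_d = f["genes"].to_numpy(float)
    z_tp, z_het, z_gene = _zscore(tp_d), _zscore(het_d), _zscore(gene_d)

    labels = np.full(profile.grid.total_bins, "GRI", dtype=object)
    labels[(z_het > thr_het) & (z_gene < thr_gene)] = "LRPC"
    labels[(z_tp > thr_tp) & (z_tp > z_het)] = "TP"
    if lrpc_mask is not None:
        from .core_io import rasterize

        labels[rasterize(lrpc_mask, profile.grid)] = "LRPC"

    rows = []
    for chrom, sl in profile.grid.chrom_slices().items():
        lab = labels[sl]
        if len(lab) < smoothing:
            warnings.warn(f"{chrom}: fewer bins than smoothing window; labels unsmoothed")
        else:
            lab = _majority_smooth(lab, smoothing)
        clen = profile.grid.layout.length_of(chrom)
        w = profile.grid.width
        change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(lab)]))
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s) * w, min(int(e) * w, clen), lab[s]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def boundary_distance(truth: pd.DataFrame, calls: pd.DataFrame) -> float:
    """Worst-case distance (bp) between true and called zone boundaries.

    When both partitions have the same per-chromosome label sequence the
    boundaries pair up positionally and the maximum absolute offset is
    returned; otherwise the symmetric Hausdorff distance between internal
    boundary sets is used (infinite if one side has none).
    """
    worst = 0.0
    for chrom in truth["chrom"].unique():
        t = truth[truth["chrom"] == chrom].sort_values("start")
        c = calls[calls["chrom"] == chrom].sort_values("start")
        tb = t["start"].to_numpy(np.int64)[1:]
        cb = c["start"].to_numpy(np.int64)[1:]
        if list(t["label"]) == list(c["label"]) and len(tb) == len(cb):
            if len(tb):
                worst = max(worst, float(np.abs(tb - cb).max()))
            continue
        if len(tb) == 0 and len(cb) == 0:
            continue
        if len(tb) == 0 or len(cb) == 0:
            return float("inf")
        d1 = max(np.abs(cb[:, None] - tb[None, :]).min(axis=1).max(), 0)
        d2 = max(np.abs(tb[:, None] - cb[None, :]).min(axis=1).max(), 0)
        worst = max(worst, float(d1), float(d2))
    return worst
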