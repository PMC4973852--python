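"""Replicate peak consolidation, mark-mark sharing correlation, qPCR calls.

Consolidation applies the study's filter chain to each replicate of a mark --
keep peaks with fold change strictly greater than 4, keep the 100 000
highest-scoring peaks, then retain merged intervals observed in at least two
independent replicates.  Peak sharing between marks is the Pearson (phi)
correlation of 0/1 bin-occupancy vectors on a common grid, and the qPCR
validation rule converts Ct cycle differences into peak / no-peak calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import BinGrid, PeakSet, ValidationError, rasterize

__all__ = [
    "QPCRRecord",
    "consolidate_replicates",
    "peak_sharing_correlation",
    "qpcr_call",
    "PEAK",
    "NO_PEAK",
    "INDETERMINATE",
]

PEAK = "peak"
NO_PEAK = "no-peak"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class QPCRRecord:
    """One qPCR validation assay: Ct cycles for input control and ChIP sample.

    ``None`` encodes "no qPCR product detected".
    """

    target: str
    ct_input: Optional[float]
    ct_sample: Optional[float]

    def __post_init__(self):
        for label, ct in (("input", self.ct_input), ("sample", self.ct_sample)):
            if ct is not None and ct <= 0:
                raise ValidationError(f"{self.target}: non-positive Ct_{label} {ct}")


def qpcr_call(record: QPCRRecord, threshold: float = 5.0) -> str:
    """Call peak / no-peak from a qPCR record.

    Fold change is ``2**(Ct_input - Ct_sample)``; a peak is called when it
    strictly exceeds ``threshold``.  If no product was detected in the input
    but was in the sample, a peak is called; if no product was detected in
    the sample, a peak is not called.  Both undetected is indeterminate.
    """
    if record.ct_sample is None:
        return INDETERMINATE if record.ct_input is None else NO_PEAK
    if record.ct_input is None:
        return PEAK
    fold = 2.0 ** (record.ct_input - record.ct_sample)
    return PEAK if fold > threshold else NO_PEAK


def _rank_truncate(df: pd.DataFrame, top_n: int) -> pd.DataFrame:
    # stable ordering: score descending, then (chrom, start) for ties
    return (
        df.sort_values(["score", "chrom", "start"], ascending=[False, True, True], kind="stable")
        .head(top_n)
        .sort_values(["chrom", "start", "end"], kind="stable")
        .reset_index(drop=True)
    )


def consolidate_replicates(
    replicates: Sequence[PeakSet],
    fc_min: float = 4.0,
    top_n: int = 100_000,
    min_reps: int = 2,
) -> PeakSet:
    """Consolidate replicate peak calls for one mark.

    Per replicate, peaks with ``score > fc_min`` are kept and truncated to the
    ``top_n`` highest-scoring; surviving intervals from all replicates are
    merged (overlapping or book-ended), and merged intervals contributed to by
    at least ``min_reps`` distinct replicates are returned, scored with the
    mean of the contributing peak scores.
    """
    if len(replicates) < min_reps:
        raise ValidationError(
            f"need at least {min_reps} replicates, got {len(replicates)}"
        )
    marks = {ps.mark for ps in replicates}
    if len(marks) != 1:
        raise ValidationError(f"replicates span multiple marks: {sorted(marks)}")
    mark = marks.pop()

    surviving = []
    for i, ps in enumerate(replicates):
        d = ps.df[ps.df["score"] > fc_min]
        d = _rank_truncate(d, top_n)
        d = d.assign(rep=i)
        if len(d):
            surviving.append(d)
    if not surviving:
        return PeakSet.empty(mark, "consolidated")
    pooled = pd.concat(surviving, ignore_index=True)

    rows = []
    for chrom, sub in pooled.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur = None  # [start, end, reps, scores]
        for r in sub.itertuples(index=False):
            if cur is None:
                cur = [r.start, r.end, {r.rep}, [r.score]]
            elif r.start <= cur[1]:
                cur[1] = max(cur[1], r.end)
                cur[2].add(r.rep)
                cur[3].append(r.score)
            else:
                rows.append((chrom, *cur))
                cur = [r.start, r.end, {r.rep}, [r.score]]
        rows.append((chrom, *cur))

    out = [
        (chrom, s, e, "", float(np.mean(scores)), ".")
        for chrom, s, e, reps, scores in rows
        if len(reps) >= min_reps
    ]
    return PeakSet(
        mark,
        "consolidated",
        pd.DataFrame(out, columns=["chrom", "start", "end", "name", "score", "strand"]),
    )


def peak_sharing_correlation(
    consolidated: Mapping[str, PeakSet],
    grid: BinGrid,
) -> pd.DataFrame:
    """Pairwise Pearson (phi) correlation of per-bin peak occupancy.

    Each mark is converted to a 0/1 occupancy vector over the grid; the
    returned marks x marks frame is symmetric with unit diagonal.  Marks with
    constant occupancy (e.g. no peaks at all) have undefined correlations,
    reported as NaN and flagged with a warning -- never coerced to 0.
    """
    marks = list(consolidated)
    if len(marks) < 2:
        raise ValidationError("need at least two marks for sharing correlation")
    occ = np.stack([rasterize(consolidated[m].df, grid) for m in marks]).astype(float)
    centered = occ - occ.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        bad = [m for m, d in zip(marks, degenerate) if d]
        warnings.warn(f"constant occupancy, correlations undefined for: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ centered.T) / occ.shape[1] / np.outer(sd, sd)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(corr, index=marks, columns=marks)
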