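"""Gene-centric epigenetics: peak assignment, expression bins, metagene profiles.

Peaks attach to a transcript when they overlap the window from 1.5 kb
upstream of the TSS to 1.5 kb downstream of the TES.  Genes split into
zero/low/mid/high expression groups on mean two-tissue RPKM, and metagene
profiles average peak fold change over 100 equal bins along the mature
(intron-excluded) transcript plus 100 bins across each 1-kb flank, always
oriented TSS-left regardless of strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PeakSet, ValidationError

__all__ = [
    "GeneModel",
    "gene_models_from_gff3",
    "gene_models_from_frame",
    "write_gff3",
    "assign_peaks_to_transcripts",
    "bin_expression",
    "metagene_profile",
    "gene_fold_change",
    "primary_transcripts",
]

EXPRESSION_GROUPS = ("zero", "low", "mid", "high")


@dataclass(frozen=True)
class GeneModel:
    """One transcript: genomic span, strand and ordered exons.

    ``start``/``end`` are the genomic span (0-based half-open); TSS and TES
    are strand-aware.  Exons must be non-overlapping, sorted, inside the span
    and of positive total (mature) length.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.transcript_id}: invalid span")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev = self.start
        for s, e in exons:
            if s < prev or e <= s or e > self.end:
                raise ValidationError(f"{self.transcript_id}: bad exon ({s}, {e})")
            prev = e
        object.__setattr__(self, "exons", exons)
        if self.mature_length <= 0:
            raise ValidationError(f"{self.transcript_id}: zero mature length")

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def gene_models_from_frame(genes: pd.DataFrame) -> list[GeneModel]:
    """Build transcript models from the synthetic annotation frame
    (one transcript per gene, ``exons`` column holding [start, end] pairs)."""
    return [
        GeneModel(
            gene_id=r.gene_id,
            transcript_id=f"{r.gene_id}.1",
            chrom=r.chrom,
            strand=r.strand,
            start=int(r.start),
            end=int(r.end),
            exons=tuple((int(s), int(e)) for s, e in r.exons),
        )
        for r in genes.itertuples(index=False)
    ]


def gene_models_from_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon models from GFF3 (1-based closed -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                start=mrna.start - 1,
                end=mrna.end,
                exons=tuple(exons),
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.transcript_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features (internal 0-based -> GFF3 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s1 = g.start + 1
            fh.write(
                f"{g.chrom}\tchromstate\tgene\t{s1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tchromstate\tmRNA\t{s1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tchromstate\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}\n"
                )


def primary_transcripts(models: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene: the longest mature transcript (ties by id)."""
    best: dict[str, GeneModel] = {}
    for g in models:
        cur = best.get(g.gene_id)
        if (
            cur is None
            or g.mature_length > cur.mature_length
            or (g.mature_length == cur.mature_length and g.transcript_id < cur.transcript_id)
        ):
            best[g.gene_id] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.start, g.transcript_id))


# ---------------------------------------------------------------------------
# assignment


def assign_peaks_to_transcripts(
    peaks: PeakSet,
    models: Sequence[GeneModel],
    offset: int = 1500,
) -> dict[str, pd.DataFrame]:
    """Map peaks to transcripts within ``offset`` bp of the TSS or TES.

    A peak is assigned iff it overlaps ``[span_start - offset, span_end +
    offset)``; one peak may attach to several transcripts.  Returns
    transcript id -> frame of assigned peaks (possibly empty dict entries
    are omitted).
    """
    out: dict[str, pd.DataFrame] = {}
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in peaks.df.groupby("chrom")}
    for g in models:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        ws, we = g.start - offset, g.end + offset
        hit = sub[(sub["start"] < we) & (sub["end"] > ws)]
        if len(hit):
            out[g.transcript_id] = hit.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# expression binning


def bin_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Label genes zero/low/mid/high on mean root/leaf RPKM.

    Genes with mean RPKM exactly 0 form the zero group; the rest are sorted
    ascending (ties broken by gene id) and split into three contiguous groups
    as equal as possible, remainder genes going to the outer (low, then high)
    groups.  Returns the table with ``mean_rpkm`` and ``group`` columns.
    """
    if len(table) == 0:
        raise ValidationError("empty expression table")
    t = table.copy()
    t["mean_rpkm"] = (t["root_rpkm"] + t["leaf_rpkm"]) / 2.0
    t["group"] = "zero"
    nz = t[t["mean_rpkm"] > 0].sort_values(["mean_rpkm", "gene_id"], kind="stable")
    n = len(nz)
    q, r = divmod(n, 3)
    n_low = q + (1 if r >= 1 else 0)
    n_high = q + (1 if r >= 2 else 0)
    idx = nz.index
    t.loc[idx[:n_low], "group"] = "low"
    t.loc[idx[n_low : n - n_high], "group"] = "mid"
    t.loc[idx[n - n_high :], "group"] = "high"
    return t


# ---------------------------------------------------------------------------
# metagene profiles


def _gene_bin_values(
    g: GeneModel,
    assigned: pd.DataFrame,
    body_bins: int,
    flank: int,
    flank_bins: int,
    uncovered: str,
) -> np.ndarray | None:
    """Per-positional-bin fold change for one transcript (TSS-left layout).

    Per-base fold change is the maximum over covering assigned peaks (0
    where uncovered, or NaN under ``uncovered="skip"``); a positional bin
    averages the bases it contains.  Base -> body-bin mapping is exact
    integer arithmetic: mature base p of L maps to bin (p * B) // L.
    """
    L = g.mature_length
    win_s, win_e = g.start - flank, g.end + flank
    cov = np.zeros(win_e - win_s)
    for r in assigned.itertuples(index=False):
        s, e = max(r.start, win_s), min(r.end, win_e)
        if e > s:
            seg = cov[s - win_s : e - win_s]
            np.maximum(seg, r.score, out=seg)

    body = np.concatenate([cov[s - win_s : e - win_s] for s, e in g.exons])
    up = cov[: flank]
    down = cov[-flank:]
    if g.strand == "-":
        body = body[::-1]
        up, down = down[::-1], up[::-1]

    def binned(vals: np.ndarray, n_bins: int) -> np.ndarray:
        # positional bins holding no base (mature length < n_bins) are NaN
        # and excluded from per-bin averaging across genes
        n = len(vals)
        idx = (np.arange(n, dtype=np.int64) * n_bins) // n
        mask = vals > 0 if uncovered == "skip" else np.ones(n, dtype=bool)
        tot = np.bincount(idx[mask], weights=vals[mask], minlength=n_bins)
        cnt = np.bincount(idx[mask], minlength=n_bins)
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    return np.concatenate(
        [binned(up, flank_bins), binned(body, body_bins), binned(down, flank_bins)]
    )


def metagene_profile(
    peaks: PeakSet,
    models: Sequence[GeneModel],
    groups: Mapping[str, str],
    body_bins: int = 100,
    flank: int = 1000,
    flank_bins: int = 100,
    offset: int = 1500,
    uncovered: str = "zero",
) -> pd.DataFrame:
    """Intron-excluded metagene fold-change profile for one mark.

    Only transcripts with at least one assigned peak contribute (their counts
    are reported per expression group).  The profile has ``2 * flank_bins +
    body_bins`` positions ordered upstream flank, gene body, downstream
    flank, with the TSS on the left for both strands.  Returns a long frame
    ``group, bin_index, mean_fc, n_genes``.

    ``uncovered="zero"`` (default) counts uncovered bases as fold change 0;
    ``"skip"`` averages covered bases only.
    """
    if uncovered not in ("zero", "skip"):
        raise ValidationError(f"unknown uncovered policy {uncovered!r}")
    models = primary_transcripts(models)
    assignments = assign_peaks_to_transcripts(peaks, models, offset=offset)
    n_pos = 2 * flank_bins + body_bins
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    n_genes: dict[str, int] = {}
    for g in models:
        assigned = assignments.get(g.transcript_id)
        if assigned is None:
            continue
        if g.mature_length <= 0:  # pragma: no cover - blocked by GeneModel
            warnings.warn(f"{g.transcript_id}: zero-length mature transcript skipped")
            continue
        grp = groups.get(g.gene_id)
        if grp is None:
            continue
        vals = _gene_bin_values(g, assigned, body_bins, flank, flank_bins, uncovered)
        if grp not in sums:
            sums[grp] = np.zeros(n_pos)
            counts[grp] = np.zeros(n_pos)
            n_genes[grp] = 0
        ok = ~np.isnan(vals)
        sums[grp][ok] += vals[ok]
        counts[grp][ok] += 1
        n_genes[grp] += 1
    rows = []
    for grp in sorted(sums):
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[grp] > 0, sums[grp] / np.maximum(counts[grp], 1), np.nan)
        for b in range(n_pos):
            rows.append((grp, b, float(mean[b]), n_genes[grp]))
    return pd.DataFrame(rows, columns=["group", "bin_index", "mean_fc", "n_genes"])


def gene_fold_change(peaks: PeakSet, models: Sequence[GeneModel]) -> pd.Series:
    """Mean fold change of peaks intersecting each gene body.

    Genes with no intersecting peak are absent from the result.
    """
    models = primary_transcripts(models)
    by_chrom = {c: sub for c, sub in peaks.df.groupby("chrom")}
    out = {}
    for g in models:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] < g.end) & (sub["end"] > g.start)]
        if len(hit):
            out[g.gene_id] = float(hit["score"].mean())
    return pd.Series(out, name="fold_change", dtype=float)
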