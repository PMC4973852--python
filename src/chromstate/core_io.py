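"""Genomic containers and flat-file I/O for the chromatin-state pipeline.

All coordinates are 0-based, half-open throughout the package.  BED is the
native interchange format; GFF3 (1-based, closed) is converted at the
boundary.  This removes every off-by-one ambiguity from downstream overlap
arithmetic.

The module provides:

* :class:`GenomeLayout` -- ordered chromosome names and lengths, with
  chrom-sizes TSV round-trip.
* :func:`assemble_pseudogenome` -- concatenates genetically mapped contigs
  into pseudochromosomes, randomly permuting contig order within each
  centimorgan map bin and inserting a fixed run of ambiguous bases between
  consecutive contigs.
* :class:`PeakSet` -- scored ChIP-seq peak intervals for one histone mark and
  replicate, the unit the whole pipeline consumes.
* :class:`BinGrid` / :func:`make_bins` -- a fixed-width tiling of the genome
  (150 bp for state learning, 1 Mbp for chromosome-scale densities); the last
  bin of each chromosome is truncated, never dropped or extended, so density
  denominators conserve genome length.
* :func:`rasterize` -- interval set -> boolean per-bin occupancy vector, the
  common discretization used by binarization, peak-sharing correlation and
  overlap enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomeLayout",
    "Contig",
    "Interval",
    "EmissionMatrix",
    "PeakSet",
    "BinGrid",
    "make_bins",
    "assemble_pseudogenome",
    "read_bed",
    "write_bed",
    "read_gff3_table",
    "read_intervals",
    "rasterize",
    "merge_intervals",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """A malformed line in an input file (message names file and line)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# genome layout


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes of a (pseudo)genome assembly.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs.  Names must be unique and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for n, l in chroms:
            if l <= 0:
                raise ValidationError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``name<TAB>length`` chrom-sizes file."""
        chroms = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{ln}: expected 'name length'")
                try:
                    chroms.append((parts[0], int(parts[1])))
                except ValueError as e:
                    raise ParseError(f"{path}:{ln}: bad length {parts[1]!r}") from e
        return cls(chroms)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n, l in self.chromosomes:
                fh.write(f"{n}\t{l}\n")


@dataclass(frozen=True)
class Contig:
    """A genetically mapped assembly contig destined for a pseudochromosome."""

    id: str
    length: int
    chromosome: str
    cm_bin: int


@dataclass(frozen=True)
class Interval:
    """A scored, stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.score < 0:
            raise ValidationError(f"negative score {self.score} on {self.chrom}")


@dataclass(frozen=True)
class EmissionMatrix:
    """States x marks matrix of Bernoulli emission probabilities.

    One row per hidden chromatin state, one column per histone mark; each
    entry is the probability that the mark is observed (binarized 1) in a bin
    occupied by that state.  A "zero state" is a row that is near-zero
    everywhere, covering unmarked genome.
    """

    probs: np.ndarray
    states: tuple[str, ...]
    marks: tuple[str, ...]

    def __init__(self, probs, states, marks):
        probs = np.asarray(probs, dtype=float)
        states = tuple(states)
        marks = tuple(marks)
        if probs.shape != (len(states), len(marks)):
            raise ValidationError(
                f"emission shape {probs.shape} != ({len(states)}, {len(marks)})"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValidationError("emission probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "marks", marks)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.states), columns=list(self.marks))


# ---------------------------------------------------------------------------
# BED / GFF3 parsing


def _sort_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a 3-6 column BED file into a sorted interval frame.

    The score column (5th) carries the CCAT-style peak fold change as a
    float.  Malformed lines raise :class:`ParseError` naming the line number;
    ``end <= start`` raises :class:`ValidationError`.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from e
            if end <= start or start < 0:
                raise ValidationError(f"{path}:{ln}: end <= start ({start}, {end})")
            name = parts[3] if len(parts) > 3 else ""
            score = 0.0
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError as e:
                    raise ParseError(f"{path}:{ln}: bad score {parts[4]!r}") from e
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return _sort_frame(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write an interval frame as 6-column BED."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out = out[BED_COLUMNS]
    with open(path, "w") as fh:
        for r in out.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{r.score:g}\t{r.strand}\n")


def read_gff3_table(path: str | Path) -> pd.DataFrame:
    """Parse GFF3 into a flat feature table with 0-based half-open coordinates.

    Returns columns ``chrom, source, type, start, end, score, strand, id,
    parent``.  Use :func:`chromstate.genes.gene_models_from_gff3` for
    hierarchical gene/mRNA/exon models.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, source, ftype, start, end, score, strand, _phase, attrs = parts
            try:
                s1, e1 = int(start), int(end)
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from e
            if e1 < s1 or s1 < 1:
                raise ValidationError(f"{path}:{ln}: bad GFF3 coordinates ({s1}, {e1})")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            rows.append(
                (
                    chrom,
                    source,
                    ftype,
                    s1 - 1,  # GFF3 is 1-based closed; internal is 0-based half-open
                    e1,
                    float(score) if score not in (".", "") else np.nan,
                    strand,
                    attr.get("ID", ""),
                    attr.get("Parent", ""),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "source", "type", "start", "end", "score", "strand", "id", "parent"],
    )
    return _sort_frame(df)


def read_intervals(path: str | Path, format: str = "BED") -> pd.DataFrame:
    """Read a BED or GFF3 file into a sorted 0-based interval frame."""
    fmt = format.upper()
    if fmt == "BED":
        return read_bed(path)
    if fmt == "GFF3":
        return read_gff3_table(path)
    raise ValidationError(f"unknown interval format {format!r}")


# ---------------------------------------------------------------------------
# peak sets


@dataclass
class PeakSet:
    """Scored peak intervals for one histone mark and one replicate.

    The frame is always sorted by (chrom, start) and carries the columns
    ``chrom, start, end, name, score, strand`` with non-negative fold-change
    scores.
    """

    mark: str
    replicate: str
    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col, default in (("name", ""), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[BED_COLUMNS]
        if len(df) and (df["score"] < 0).any():
            raise ValidationError(f"negative peak score in {self.mark}/{self.replicate}")
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValidationError(f"empty/inverted interval in {self.mark}/{self.replicate}")
        self.df = _sort_frame(df)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls, mark: str, replicate: str = "") -> "PeakSet":
        return cls(mark, replicate, pd.DataFrame(columns=BED_COLUMNS))

    @classmethod
    def from_intervals(cls, mark: str, replicate: str, intervals: Iterable[Interval]) -> "PeakSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand) for iv in intervals]
        return cls(mark, replicate, pd.DataFrame(rows, columns=BED_COLUMNS))

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end), r.strand, float(r.score), r.name)
            for r in self.df.itertuples(index=False)
        ]

    @classmethod
    def read_bed(cls, path: str | Path, mark: str, replicate: str = "") -> "PeakSet":
        return cls(mark, replicate, read_bed(path))

    def write_bed(self, path: str | Path) -> None:
        df = self.df.copy()
        blank = df["name"] == ""
        if blank.any():
            df.loc[blank, "name"] = [
                f"{self.mark}_{self.replicate}_{i}" if self.replicate else f"{self.mark}_{i}"
                for i in df.index[blank]
            ]
        write_bed(df, path)


# ---------------------------------------------------------------------------
# binning


class BinGrid:
    """A fixed-width tiling of every chromosome of a layout.

    Bins are numbered genome-wide in layout order; the last bin of each
    chromosome is truncated at the chromosome end.  Bins tile each chromosome
    without gaps or overlaps.
    """

    def __init__(self, layout: GenomeLayout, width: int):
        if width <= 0:
            raise ValidationError(f"bin width must be positive, got {width}")
        self.layout = layout
        self.width = int(width)
        self._n_bins = {n: math.ceil(l / width) for n, l in layout.chromosomes}
        offsets = {}
        pos = 0
        for n, _ in layout.chromosomes:
            offsets[n] = pos
            pos += self._n_bins[n]
        self._offsets = offsets
        self.total_bins = pos

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slices(self) -> dict[str, slice]:
        """Genome-wide row slice per chromosome, in layout order."""
        return {
            n: slice(self._offsets[n], self._offsets[n] + self._n_bins[n])
            for n in self.layout.names
        }

    def bin_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome; last end is clipped."""
        n = self._n_bins[chrom]
        starts = np.arange(n, dtype=np.int64) * self.width
        ends = np.minimum(starts + self.width, self.layout.length_of(chrom))
        return starts, ends

    def bins_frame(self) -> pd.DataFrame:
        """All bins as a ``chrom, start, end`` frame in genome-wide order."""
        frames = []
        for chrom in self.layout.names:
            starts, ends = self.bin_bounds(chrom)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)

    def bin_lengths(self) -> np.ndarray:
        out = np.empty(self.total_bins, dtype=np.int64)
        for chrom, sl in self.chrom_slices().items():
            starts, ends = self.bin_bounds(chrom)
            out[sl] = ends - starts
        return out


def make_bins(layout: GenomeLayout, width: int) -> BinGrid:
    """Tile ``layout`` into ``width``-bp bins (last bin truncated)."""
    return BinGrid(layout, width)


def rasterize(
    intervals: pd.DataFrame,
    grid: BinGrid,
    min_overlap: float = 0.0,
) -> np.ndarray:
    """Project an interval frame onto a grid as a boolean occupancy vector.

    A bin is set if some interval overlaps it by at least one bp (default),
    or by at least ``min_overlap`` of the bin's actual length when
    ``min_overlap > 0``.  Intervals beyond the chromosome end are clipped;
    intervals on chromosomes absent from the layout are ignored.
    """
    out = np.zeros(grid.total_bins, dtype=bool)
    if len(intervals) == 0:
        return out
    w = grid.width
    for chrom, sl in grid.chrom_slices().items():
        sub = intervals[intervals["chrom"] == chrom]
        if len(sub) == 0:
            continue
        clen = grid.layout.length_of(chrom)
        starts = np.clip(sub["start"].to_numpy(np.int64), 0, clen)
        ends = np.clip(sub["end"].to_numpy(np.int64), 0, clen)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        nb = grid.n_bins(chrom)
        if min_overlap <= 0.0:
            first = starts // w
            last = (ends - 1) // w
            diff = np.zeros(nb + 1, dtype=np.int64)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            out[sl] |= np.cumsum(diff[:-1]) > 0
        else:
            view = out[sl]
            for s, e in zip(starts, ends):
                for b in range(s // w, (e - 1) // w + 1):
                    bs, be = b * w, min((b + 1) * w, clen)
                    ov = min(e, be) - max(s, bs)
                    if ov >= min_overlap * (be - bs):
                        view[b] = True
    return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals per chromosome (BEDtools-style)."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# pseudogenome assembly


def assemble_pseudogenome(
    contigs: Sequence[Contig],
    spacer_len: int = 10,
    seed: int = 0,
) -> tuple[GenomeLayout, dict[str, tuple[str, int]]]:
    """Concatenate mapped contigs into pseudochromosomes.

    Contigs are ordered on chromosomes by centimorgan map bin; order within a
    bin is a seed-determined random permutation; ``spacer_len`` ambiguous
    bases separate consecutive contigs.  The result is independent of the
    input ordering of ``contigs`` (contigs are canonicalized by id within
    each bin before permuting), so a given seed is fully reproducible.

    Returns the resulting :class:`GenomeLayout` and a map
    ``contig id -> (chromosome, start offset)``.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate contig ids")
    by_chrom: dict[str, dict[int, list[Contig]]] = {}
    for c in contigs:
        if c.length <= 0:
            raise ValidationError(f"contig {c.id!r} has non-positive length")
        by_chrom.setdefault(c.chromosome, {}).setdefault(c.cm_bin, []).append(c)

    rng = np.random.default_rng(seed)
    offsets: dict[str, tuple[str, int]] = {}
    lengths = []
    for chrom in sorted(by_chrom):
        pos = 0
        first = True
        for cm in sorted(by_chrom[chrom]):
            group = sorted(by_chrom[chrom][cm], key=lambda c: c.id)
            for idx in rng.permutation(len(group)):
                c = group[idx]
                if not first:
                    pos += spacer_len
                offsets[c.id] = (chrom, pos)
                pos += c.length
                first = False
        lengths.append((chrom, pos))
    return GenomeLayout(lengths), offsets
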