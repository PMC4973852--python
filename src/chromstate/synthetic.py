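"""Synthetic epigenome with planted chromatin-state ground truth.

Generates a desk-scale mirror of a large cereal seedling epigenome: two
pseudochromosomes partitioned into telomere-proximal (TP), gene-rich-interior
(GRI) and low-recombining pericentromeric (LR-PC) compartments; a hidden
chromatin-state sequence per 150-bp bin whose state frequencies differ by
compartment; nine histone-mark peak tracks in three replicates emitted from a
planted Bernoulli emission matrix; and root/leaf expression in which genes
dominated by the facultative-heterochromatin genic state carry high
differential expression while the H3K36me3-bearing states carry high,
balanced ("constitutive") expression.

The hidden chain inside a compartment is a mixture of a persistence term and
the compartment's target state distribution,

    T = a * I + (1 - a) * 1 pi^T,   a = 1 - 1/persistence,

whose stationary distribution is exactly ``pi``; the expected run length of
the persistence term is the ``persistence`` parameter in bins.  When gene and
retrotransposon annotations are overlaid, the renewal distribution is
conditioned on the local context (genic states over gene bodies, repressive
states over retroelements) and the chain renews at every context change.

Every generator is a pure function of its parameters and one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    BinGrid,
    EmissionMatrix,
    GenomeLayout,
    PeakSet,
    ValidationError,
    make_bins,
)

__all__ = [
    "MARKS",
    "STATE_NAMES",
    "ACTIVE_MARKS",
    "DEFAULT_STATE_ORDER",
    "GENIC_STATES",
    "REPRESSIVE_STATES",
    "TP_STATES",
    "HET_STATES",
    "default_emissions",
    "default_region_profiles",
    "Scenario",
    "RegionTruth",
    "SyntheticTruth",
    "SyntheticWorld",
    "make_region_truth",
    "generate_annotation",
    "generate_state_sequence",
    "emit_peak_tracks",
    "generate_expression",
    "bernoulli_observations",
    "simulate",
]

# Nine histone marks, ordered by chromosomal distribution class
# (I: gene/telomere-biased, II: genic, III: patchy, IV: heterochromatic).
MARKS = (
    "H3K4me3",
    "H3K56ac",
    "H3K27me3",
    "H3K4me2",
    "H3K36me3",
    "H3K27me2",
    "H3K9me3",
    "H3K27me1",
    "H3K9me2",
)

STATE_NAMES = tuple(f"S{i}" for i in range(1, 12))

# Reporting order: decreasing involvement with the active genic environment.
DEFAULT_STATE_ORDER = ("S7", "S5", "S6", "S4", "S3", "S2", "S1", "S8", "S9", "S10", "S11")
ACTIVE_MARKS = ("H3K4me3", "H3K56ac", "H3K4me2", "H3K36me3")

GENIC_STATES = ("S3", "S4", "S5", "S6", "S7")
REPRESSIVE_STATES = ("S1", "S8", "S9", "S10", "S11")
TP_STATES = ("S2", "S3")  # facultative-heterochromatin (H3K27me3) states
HET_STATES = ("S9", "S10")  # constitutive-heterochromatin (H3K27me1/H3K9me2) states

_BASE = 0.02


def default_emissions() -> EmissionMatrix:
    """Planted 11-state emission matrix (10 marked states + one zero state).

    Row design: S7 a TSS-like state (H3K4me3/H3K56ac), S5/S6 genic states
    dominated by H3K36me3, S4 by H3K4me2, S3 active genic marks plus
    H3K27me3, S2 intergenic H3K27me3, S1/S8 patchy repressive marks, S9/S10
    constitutive heterochromatin (H3K27me1/H3K9me2), S11 the zero state.
    """
    P = np.full((11, 9), _BASE)
    m = {name: j for j, name in enumerate(MARKS)}

    def row(i: int, **probs: float) -> None:
        for mark, p in probs.items():
            P[i, m[mark]] = p

    row(0, H3K9me3=0.80)                                                # S1
    row(1, H3K27me3=0.85)                                               # S2
    row(2, H3K27me3=0.80, H3K4me3=0.60, H3K56ac=0.45, H3K4me2=0.50,
        H3K36me3=0.30)                                                  # S3
    row(3, H3K4me2=0.85, H3K36me3=0.20, H3K4me3=0.15)                   # S4
    row(4, H3K4me2=0.65, H3K36me3=0.65, H3K4me3=0.35, H3K56ac=0.20)     # S5
    row(5, H3K36me3=0.85, H3K4me3=0.40, H3K4me2=0.15)                   # S6
    row(6, H3K4me3=0.90, H3K56ac=0.85, H3K4me2=0.40)                    # S7
    row(7, H3K27me2=0.80, H3K9me3=0.25)                                 # S8
    row(8, H3K27me1=0.85, H3K9me2=0.30)                                 # S9
    row(9, H3K9me2=0.85, H3K27me1=0.35)                                 # S10
    # S11 stays at the background rate everywhere (zero state)
    return EmissionMatrix(P, STATE_NAMES, MARKS)


def default_region_profiles() -> dict[str, np.ndarray]:
    """Target chromatin-state frequencies per chromosomal compartment."""
    return {
        #         S1    S2    S3    S4    S5    S6    S7    S8    S9    S10   S11
        "TP": np.array(
            [0.01, 0.30, 0.17, 0.05, 0.05, 0.05, 0.06, 0.02, 0.01, 0.01, 0.27]
        ),
        "GRI": np.array(
            [0.05, 0.02, 0.03, 0.11, 0.09, 0.09, 0.10, 0.05, 0.09, 0.07, 0.30]
        ),
        "LRPC": np.array(
            [0.07, 0.01, 0.01, 0.02, 0.02, 0.02, 0.02, 0.07, 0.22, 0.22, 0.32]
        ),
    }


# ---------------------------------------------------------------------------
# scenario and truth containers


@dataclass
class Scenario:
    """All knobs of the synthetic epigenome.

    Defaults are the desk-scale study conditions: 2 chromosomes x 30 Mbp,
    150-bp bins, 9 marks, 11 planted states, 3 replicates at 0.8 concordance,
    log-normal peak fold changes with median 9 (comfortably above the
    fold-change > 4 consolidation filter), and a ~3.5% unexpressed gene
    fraction.
    """

    n_chromosomes: int = 2
    chrom_length: int = 30_000_000
    bin_width: int = 150
    tp_frac: float = 0.10  # each chromosome end
    gri_frac: float = 0.20  # each flank between TP and LR-PC
    persistence: float = 8.0  # expected state run length, bins
    replicates: int = 3
    concordance: float = 0.8
    fc_log_mean: float = float(np.log(9.0))
    fc_log_sd: float = 0.5
    zero_fraction: float = 0.035
    gene_density: dict = field(
        default_factory=lambda: {"TP": 18.0, "GRI": 14.0, "LRPC": 2.0}
    )  # genes per Mbp
    ltr_density: dict = field(
        default_factory=lambda: {"TP": 3.0, "GRI": 10.0, "LRPC": 30.0}
    )  # LTR retrotransposons per Mbp

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            (f"chr{i + 1}", self.chrom_length) for i in range(self.n_chromosomes)
        )

    def grid(self) -> BinGrid:
        return make_bins(self.layout(), self.bin_width)

    @classmethod
    def small(cls) -> "Scenario":
        """2 x 7.5 Mbp (1e5 150-bp bins) -- parameter-recovery scale."""
        return cls(chrom_length=7_500_000)

    @classmethod
    def tiny(cls) -> "Scenario":
        """2 x 1.5 Mbp -- end-to-end smoke/determinism scale."""
        return cls(chrom_length=1_500_000)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


RegionTruth = pd.DataFrame  # columns: chrom, start, end, label in {TP, GRI, LRPC}


@dataclass
class SyntheticTruth:
    """Planted ground truth: everything downstream tests compare against."""

    grid: BinGrid
    states: np.ndarray  # per-bin 0-based planted state index
    emissions: EmissionMatrix
    regions: RegionTruth
    seed: int

    def __post_init__(self):
        if self.states.shape != (self.grid.total_bins,):
            raise ValidationError("state sequence length must equal bin count")

    def region_labels_per_bin(self) -> np.ndarray:
        lab = np.empty(self.grid.total_bins, dtype=object)
        w = self.grid.width
        for r in self.regions.itertuples(index=False):
            sl = self.grid.chrom_slices()[r.chrom]
            first, last = r.start // w, (r.end - 1) // w
            lab[sl.start + first : sl.start + last + 1] = r.label
        return lab

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "bin_width": self.grid.width,
            "chromosomes": [[n, l] for n, l in self.grid.layout.chromosomes],
            "states": self.states.tolist(),
            "state_names": list(self.emissions.states),
            "marks": list(self.emissions.marks),
            "emissions": self.emissions.probs.tolist(),
            "regions": self.regions.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        layout = GenomeLayout(tuple((n, l) for n, l in d["chromosomes"]))
        grid = make_bins(layout, d["bin_width"])
        return cls(
            grid=grid,
            states=np.array(d["states"], dtype=np.int64),
            emissions=EmissionMatrix(np.array(d["emissions"]), d["state_names"], d["marks"]),
            regions=pd.DataFrame(d["regions"], columns=["chrom", "start", "end", "label"]),
            seed=d["seed"],
        )


@dataclass
class SyntheticWorld:
    """A fully simulated study: truth plus every observable input."""

    scenario: Scenario
    truth: SyntheticTruth
    genes: pd.DataFrame  # chrom,start,end,strand,gene_id,exons(list of [s,e])
    retros: pd.DataFrame  # chrom,start,end,strand,id
    peak_tracks: dict  # mark -> list[PeakSet] (one per replicate)
    expression: pd.DataFrame  # gene_id, root_rpkm, leaf_rpkm
    gene_state: pd.Series  # gene_id -> dominant planted state name


# ---------------------------------------------------------------------------
# region architecture


def make_region_truth(layout: GenomeLayout, tp_frac: float, gri_frac: float) -> RegionTruth:
    """TP / GRI / LRPC / GRI / TP segments per chromosome.

    TP compartments sit at both chromosome ends, GRI flanks them, and the
    LR-PC compartment fills the middle (fractions are of chromosome length;
    2*(tp+gri) must be < 1).
    """
    if tp_frac <= 0 or gri_frac <= 0 or 2 * (tp_frac + gri_frac) >= 1:
        raise ValidationError("region fractions must be positive and sum below 1")
    rows = []
    for chrom, L in layout.chromosomes:
        tp, gri = int(round(L * tp_frac)), int(round(L * gri_frac))
        bounds = [0, tp, tp + gri, L - tp - gri, L - tp, L]
        labels = ["TP", "GRI", "LRPC", "GRI", "TP"]
        for (s, e), lab in zip(zip(bounds[:-1], bounds[1:]), labels):
            rows.append((chrom, s, e, lab))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


# ---------------------------------------------------------------------------
# annotation


def _place_elements(
    rng: np.random.Generator,
    seg_start: int,
    seg_end: int,
    density_per_mbp: float,
    length_sampler,
    occupied: list[tuple[int, int]],
    max_tries: int = 10,
) -> list[tuple[int, int]]:
    """Place non-overlapping elements in [seg_start, seg_end) at the given
    density; raises after bounded retries if the density is unplaceable."""
    target = rng.poisson(density_per_mbp * (seg_end - seg_start) / 1e6)
    placed: list[tuple[int, int]] = []
    taken = sorted(occupied)
    tries = 0
    while len(placed) < target:
        tries += 1
        if tries > max_tries * max(target, 1) + 10:
            raise ValidationError(
                f"could not place {target} elements in segment of "
                f"{seg_end - seg_start} bp without overlap"
            )
        length = int(length_sampler(rng))
        if seg_end - seg_start <= length:
            continue
        s = int(rng.integers(seg_start, seg_end - length))
        e = s + length
        if any(s < te and ts < e for ts, te in taken):
            continue
        placed.append((s, e))
        taken.append((s, e))
    return placed


def _gene_length(rng: np.random.Generator) -> int:
    return int(rng.integers(2000, 6001))


def _ltr_length(rng: np.random.Generator) -> int:
    return int(rng.integers(5000, 12001))


def _make_exons(rng: np.random.Generator, start: int, end: int) -> list[list[int]]:
    """Split a gene span into 2-5 exons separated by introns."""
    n_ex = int(rng.integers(2, 6))
    length = end - start
    # 2*n_ex - 1 alternating blocks (exon/intron/...); draw positive widths
    n_blocks = 2 * n_ex - 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_blocks - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [length])) + start
    return [[int(bounds[i]), int(bounds[i + 1])] for i in range(0, n_blocks, 2)]


def generate_annotation(
    layout: GenomeLayout,
    regions: RegionTruth,
    gene_density: Mapping[str, float],
    ltr_density: Mapping[str, float],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place multi-exon genes and LTR retrotransposons per compartment.

    Gene density is highest in TP/GRI and lowest in LR-PC; retroelement
    density is the reverse, mirroring the compartment structure of a large
    cereal genome.  Elements never overlap each other (genes are placed
    first; retroelements avoid them).
    """
    for d in (*gene_density.values(), *ltr_density.values()):
        if d < 0:
            raise ValidationError("densities must be non-negative")
    rng = np.random.default_rng(seed)
    gene_rows, retro_rows = [], []
    gid = rid = 0
    for chrom, _L in layout.chromosomes:
        segs = regions[regions["chrom"] == chrom]
        occupied: list[tuple[int, int]] = []
        for r in segs.itertuples(index=False):
            spans = _place_elements(
                rng, r.start, r.end, gene_density.get(r.label, 0.0), _gene_length, occupied
            )
            for s, e in sorted(spans):
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                exons = _make_exons(rng, s, e)
                gene_rows.append((chrom, s, e, strand, f"gene{gid:05d}", exons))
            occupied.extend(spans)
        for r in segs.itertuples(index=False):
            spans = _place_elements(
                rng, r.start, r.end, ltr_density.get(r.label, 0.0), _ltr_length, occupied
            )
            for s, e in sorted(spans):
                rid += 1
                retro_rows.append((chrom, s, e, ".", f"ltr{rid:05d}"))
            occupied.extend(spans)
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "strand", "gene_id", "exons"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    retros = pd.DataFrame(
        retro_rows, columns=["chrom", "start", "end", "strand", "id"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, retros


# ---------------------------------------------------------------------------
# hidden state chain


def _context_per_bin(
    grid: BinGrid, genes: pd.DataFrame | None, retros: pd.DataFrame | None
) -> np.ndarray:
    """0 = intergenic, 1 = genic, 2 = retroelement (genes win conflicts)."""
    ctx = np.zeros(grid.total_bins, dtype=np.int8)
    w = grid.width
    slices = grid.chrom_slices()

    def paint(df: pd.DataFrame, value: int) -> None:
        for r in df.itertuples(index=False):
            sl = slices[r.chrom]
            first, last = r.start // w, (r.end - 1) // w
            view = ctx[sl.start + first : sl.start + last + 1]
            view[view == 0] = value

    if genes is not None and len(genes):
        paint(genes, 1)
    if retros is not None and len(retros):
        paint(retros, 2)
    return ctx


def generate_state_sequence(
    regions: RegionTruth,
    grid: BinGrid,
    region_profiles: Mapping[str, np.ndarray] | None = None,
    persistence: float = 8.0,
    seed: int = 0,
    genes: pd.DataFrame | None = None,
    retros: pd.DataFrame | None = None,
    state_names: Sequence[str] = STATE_NAMES,
) -> np.ndarray:
    """Sample the hidden chromatin-state chain (0-based indices per bin).

    Within a compartment the chain is ``T = a I + (1-a) 1 pi^T`` with
    ``a = 1 - 1/persistence``; its stationary distribution is exactly the
    compartment's target profile.  With annotations supplied, the renewal
    distribution over gene bodies is the profile restricted to genic states
    and over retroelements restricted to repressive states, and the chain
    renews at every annotation boundary.
    """
    if persistence < 1:
        raise ValidationError(f"persistence must be >= 1 bin, got {persistence}")
    profiles = region_profiles if region_profiles is not None else default_region_profiles()
    K = len(state_names)
    for lab, pi in profiles.items():
        pi = np.asarray(pi, float)
        if pi.shape != (K,) or abs(pi.sum() - 1.0) > 1e-8 or (pi < 0).any():
            raise ValidationError(f"profile for {lab!r} is not a distribution over {K} states")

    genic_idx = np.array(
        [i for i, s in enumerate(state_names) if s in GENIC_STATES], dtype=np.int64
    )
    rep_idx = np.array(
        [i for i, s in enumerate(state_names) if s in REPRESSIVE_STATES], dtype=np.int64
    )

    a = 1.0 - 1.0 / persistence
    rng = np.random.default_rng(seed)
    ctx = _context_per_bin(grid, genes, retros)

    # per-bin region label index
    region_of_bin = np.empty(grid.total_bins, dtype=np.int8)
    labels = sorted(profiles)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    w = grid.width
    for r in regions.itertuples(index=False):
        sl = grid.chrom_slices()[r.chrom]
        first, last = r.start // w, (r.end - 1) // w
        region_of_bin[sl.start + first : sl.start + last + 1] = lab_idx[r.label]

    # conditional renewal distributions: (region, context) -> cdf over states
    floor = 1e-3
    cdfs = np.empty((len(labels), 3, K))
    for li, lab in enumerate(labels):
        pi = np.asarray(profiles[lab], float)
        for ci, restrict in enumerate((None, genic_idx, rep_idx)):
            q = pi.copy()
            if restrict is not None and len(restrict):
                massed = np.full(K, 0.0)
                massed[restrict] = np.maximum(q[restrict], floor)
                q = massed
            q = q / q.sum()
            cdfs[li, ci] = np.cumsum(q)

    states = np.empty(grid.total_bins, dtype=np.int64)
    for sl in grid.chrom_slices().values():
        n = sl.stop - sl.start
        if n == 0:
            continue
        reg = region_of_bin[sl]
        con = ctx[sl]
        renew = rng.random(n) >= a
        renew[0] = True
        # renew whenever annotation context changes (gene/retro boundaries)
        renew[1:] |= con[1:] != con[:-1]
        u = rng.random(n)
        draw = np.empty(n, dtype=np.int64)
        for li in range(len(labels)):
            for ci in range(3):
                sel = (reg == li) & (con == ci)
                if sel.any():
                    draw[sel] = np.searchsorted(cdfs[li, ci], u[sel], side="right")
        idx = np.where(renew, np.arange(n), 0)
        np.maximum.accumulate(idx, out=idx)
        states[sl] = draw[idx]
    return states


# ---------------------------------------------------------------------------
# observable tracks


def bernoulli_observations(
    states: np.ndarray,
    emissions: EmissionMatrix,
    grid: BinGrid,
    seed: int = 0,
) -> np.ndarray:
    """Draw the bins x marks 0/1 matrix directly from the planted model."""
    rng = np.random.default_rng(seed)
    p = emissions.probs[states]
    return (rng.random(p.shape) < p).astype(np.uint8)


def emit_peak_tracks(
    states: np.ndarray,
    grid: BinGrid,
    emissions: EmissionMatrix,
    replicates: int = 3,
    concordance: float = 0.8,
    fc_log_mean: float = float(np.log(9.0)),
    fc_log_sd: float = 0.5,
    seed: int = 0,
) -> dict[str, list[PeakSet]]:
    """Emit per-mark, per-replicate scored peak tracks from the hidden chain.

    For every bin and mark, presence is Bernoulli(emission[state, mark]);
    adjacent present bins merge into one interval carrying a log-normal fold
    change.  Replicates are degraded copies of this master track: each
    interval is dropped independently with probability ``1 - concordance``
    (whole intervals, mimicking replicate-level peak-calling variability),
    so at concordance 1 the replicates are identical.
    """
    if not 0 <= concordance <= 1:
        raise ValidationError(f"concordance must lie in [0, 1], got {concordance}")
    rng = np.random.default_rng(seed)
    present = bernoulli_observations(states, emissions, grid, seed=int(rng.integers(2**31)))
    w = grid.width
    out: dict[str, list[PeakSet]] = {}
    for j, mark in enumerate(emissions.marks):
        master_rows = []
        for chrom, sl in grid.chrom_slices().items():
            col = present[sl, j]
            if not col.any():
                continue
            clen = grid.layout.length_of(chrom)
            padded = np.concatenate(([0], col, [0]))
            d = np.diff(padded)
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                master_rows.append((chrom, int(s) * w, min(int(e) * w, clen)))
        fc = np.exp(rng.normal(fc_log_mean, fc_log_sd, size=len(master_rows)))
        reps = []
        for r in range(replicates):
            keep = (
                np.ones(len(master_rows), dtype=bool)
                if concordance >= 1.0
                else rng.random(len(master_rows)) < concordance
            )
            rows = [
                (chrom, s, e, f"{mark}_r{r + 1}_{i}", float(fc[i]), ".")
                for i, ((chrom, s, e), k) in enumerate(zip(master_rows, keep))
                if k
            ]
            reps.append(
                PeakSet(
                    mark,
                    f"r{r + 1}",
                    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
                )
            )
        out[mark] = reps
    return out


# ---------------------------------------------------------------------------
# expression


#: per dominant state: (mean log2 RPKM, sd, tissue-divergence effect in log2)
DEFAULT_EXPRESSION_EFFECTS: dict[str, tuple[float, float, float]] = {
    "S2": (1.0, 1.0, 1.5),
    "S3": (2.5, 1.0, 3.5),
    "S4": (3.0, 1.0, 1.0),
    "S5": (4.5, 1.0, 0.3),
    "S6": (4.5, 1.0, 0.3),
    "S7": (3.5, 1.0, 0.5),
}
_FALLBACK_EFFECT = (0.5, 1.0, 0.5)  # repressive / zero-state dominated genes


def dominant_state_per_gene(
    genes: pd.DataFrame,
    states: np.ndarray,
    grid: BinGrid,
    state_names: Sequence[str] = STATE_NAMES,
    tie_order: Sequence[str] = DEFAULT_STATE_ORDER,
) -> pd.Series:
    """State with the largest bin-count footprint over each gene body.

    Ties break toward the more active state in the reporting order.
    """
    rank = {s: i for i, s in enumerate(tie_order)}
    w = grid.width
    slices = grid.chrom_slices()
    out = {}
    for r in genes.itertuples(index=False):
        sl = slices[r.chrom]
        first, last = r.start // w, (r.end - 1) // w
        lab = states[sl.start + first : sl.start + last + 1]
        counts = np.bincount(lab, minlength=len(state_names))
        best = max(
            range(len(state_names)),
            key=lambda k: (counts[k], -rank.get(state_names[k], len(rank))),
        )
        out[r.gene_id] = state_names[best]
    return pd.Series(out, name="state")


def generate_expression(
    genes: pd.DataFrame,
    gene_state: pd.Series,
    effects: Mapping[str, tuple[float, float, float]] | None = None,
    zero_fraction: float = 0.035,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-tissue RPKM per gene, driven by the gene's dominant state.

    Genes dominated by the H3K36me3 states receive high, balanced expression;
    genes in the H3K27me3 genic state receive strongly tissue-divergent
    expression (the planted differential-expression signal); a
    ``zero_fraction`` of genes is unexpressed in both tissues.
    """
    if not 0 <= zero_fraction <= 1:
        raise ValidationError("zero_fraction must lie in [0, 1]")
    eff = dict(DEFAULT_EXPRESSION_EFFECTS if effects is None else effects)
    rng = np.random.default_rng(seed)
    rows = []
    n = len(genes)
    zero = rng.random(n) < zero_fraction
    for i, gene_id in enumerate(genes["gene_id"]):
        if zero[i]:
            rows.append((gene_id, 0.0, 0.0))
            continue
        mean, sd, effect = eff.get(gene_state.get(gene_id), _FALLBACK_EFFECT)
        base = rng.normal(mean, sd)
        d = rng.choice((-1.0, 1.0)) * effect + rng.normal(0.0, 0.3)
        rows.append((gene_id, float(2.0 ** (base + d / 2)), float(2.0 ** (base - d / 2))))
    return pd.DataFrame(rows, columns=["gene_id", "root_rpkm", "leaf_rpkm"])


# ---------------------------------------------------------------------------
# whole-study simulation


def simulate(scenario: Scenario | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete synthetic study from one seed.

    Sub-seeds for annotation, chain, peak emission and expression are
    expanded deterministically from ``seed`` so stages are individually
    reproducible.
    """
    sc = scenario or Scenario()
    layout = sc.layout()
    grid = sc.grid()
    sub = [int(s) for s in np.random.SeedSequence(seed).generate_state(4) % (2**31)]
    regions = make_region_truth(layout, sc.tp_frac, sc.gri_frac)
    genes, retros = generate_annotation(
        layout, regions, sc.gene_density, sc.ltr_density, seed=sub[0]
    )
    emissions = default_emissions()
    states = generate_state_sequence(
        regions,
        grid,
        persistence=sc.persistence,
        seed=sub[1],
        genes=genes,
        retros=retros,
    )
    tracks = emit_peak_tracks(
        states,
        grid,
        emissions,
        replicates=sc.replicates,
        concordance=sc.concordance,
        fc_log_mean=sc.fc_log_mean,
        fc_log_sd=sc.fc_log_sd,
        seed=sub[2],
    )
    gene_state = dominant_state_per_gene(genes, states, grid)
    expression = generate_expression(
        genes, gene_state, zero_fraction=sc.zero_fraction, seed=sub[3]
    )
    truth = SyntheticTruth(grid=grid, states=states, emissions=emissions, regions=regions, seed=seed)
    return SyntheticWorld(
        scenario=sc,
        truth=truth,
        genes=genes,
        retros=retros,
        peak_tracks=tracks,
        expression=expression,
        gene_state=gene_state,
    )
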