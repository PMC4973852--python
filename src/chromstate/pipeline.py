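"""End-to-end orchestration: simulate -> consolidate -> learn -> annotate -> zones.

One global seed is expanded into per-stage sub-seeds through
``numpy.random.SeedSequence(seed).generate_state(...) % 2**31`` so partial
re-runs are reproducible; re-running with the same config and seed is
bit-identical, which the manifest certifies with a SHA-256 content hash per
output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import genes as genes_mod
from . import hmm as hmm_mod
from . import peaks as peaks_mod
from . import regions as regions_mod
from . import synthetic as syn
from .core_io import make_bins

log = logging.getLogger("chromstate")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a full run.

    Defaults equal the study's printed analysis parameters: fold-change
    filter 4, top 100 000 peaks, >= 2 replicates, 150-bp state bins, 1-Mbp
    density bins, 11 states selected at emission correlation 0.7, 1.5-kb
    assignment offset, 25/250-gene rolling DGE windows.
    """

    scenario: syn.Scenario = field(default_factory=syn.Scenario)
    fc_min: float = 4.0
    top_n: int = 100_000
    min_reps: int = 2
    hmm_k: int = 11
    k_min: Optional[int] = None  # set both bounds to sweep + select instead
    k_max: Optional[int] = None
    rho: float = 0.7
    n_restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-4
    decode_method: str = "posterior"
    assignment_offset: int = 1500
    dge_windows: tuple[int, int] = (25, 250)
    density_bin: int = 1_000_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sc = syn.Scenario(**d.pop("scenario", {}))
        if "dge_windows" in d:
            d["dge_windows"] = tuple(d["dge_windows"])
        return cls(scenario=sc, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dge_windows"] = list(self.dge_windows)
        return d


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence(seed).generate_state(stage + 1)[stage] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_feature_gff3(df: pd.DataFrame, path: Path, ftype: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in df.itertuples(index=False):
            strand = getattr(r, "strand", ".") or "."
            fh.write(
                f"{r.chrom}\tchromstate\t{ftype}\t{r.start + 1}\t{r.end}\t.\t{strand}\t.\tID={r.id}\n"
            )


def feature_sets(world: syn.SyntheticWorld) -> dict[str, pd.DataFrame]:
    """Interval frames for enrichment: gene, exon, intron, TSS, TES, LTR."""
    genes = world.genes
    exon_rows, intron_rows, tss_rows, tes_rows = [], [], [], []
    for r in genes.itertuples(index=False):
        prev = None
        for s, e in r.exons:
            exon_rows.append((r.chrom, s, e))
            if prev is not None:
                intron_rows.append((r.chrom, prev, s))
            prev = e
        tss = r.start if r.strand == "+" else r.end - 1
        tes = r.end - 1 if r.strand == "+" else r.start
        tss_rows.append((r.chrom, tss, tss + 1))
        tes_rows.append((r.chrom, tes, tes + 1))
    cols = ["chrom", "start", "end"]
    return {
        "gene": genes[cols],
        "exon": pd.DataFrame(exon_rows, columns=cols),
        "intron": pd.DataFrame(intron_rows, columns=cols),
        "TSS": pd.DataFrame(tss_rows, columns=cols),
        "TES": pd.DataFrame(tes_rows, columns=cols),
        "LTR": world.retros[cols],
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int = 0) -> dict:
    """Execute every stage in dependency order and write a hashed manifest.

    A failing stage aborts with the stage name in the raised error.  Returns
    the manifest dict (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config": config.to_dict(), "stages": [], "outputs": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    stage = "simulate"
    try:
        world = syn.simulate(config.scenario, seed=seed)
        grid = world.truth.grid
        peak_dir = out / "peaks"
        peak_dir.mkdir(exist_ok=True)
        written = []
        for mark, reps in world.peak_tracks.items():
            for ps in reps:
                p = peak_dir / f"{mark}_{ps.replicate}.bed"
                ps.write_bed(p)
                written.append(p)
        models = genes_mod.gene_models_from_frame(world.genes)
        genes_mod.write_gff3(models, out / "genes.gff3")
        _write_feature_gff3(world.retros, out / "retros.gff3", "repeat_region")
        world.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        world.truth.to_json(out / "truth.json")
        record(stage, *written, out / "genes.gff3", out / "retros.gff3",
               out / "expression.tsv", out / "truth.json")

        stage = "consolidate"
        consolidated = {}
        cons_dir = out / "consolidated"
        cons_dir.mkdir(exist_ok=True)
        written = []
        for mark, reps in world.peak_tracks.items():
            ps = peaks_mod.consolidate_replicates(
                reps, fc_min=config.fc_min, top_n=config.top_n, min_reps=config.min_reps
            )
            consolidated[mark] = ps
            p = cons_dir / f"{mark}.bed"
            ps.write_bed(p)
            written.append(p)
        record(stage, *written)

        stage = "sharing"
        sharing = peaks_mod.peak_sharing_correlation(consolidated, grid)
        sharing.to_csv(out / "sharing.tsv", sep="\t")
        record(stage, out / "sharing.tsv")

        stage = "binarize"
        data = hmm_mod.binarize(consolidated, grid, marks=world.truth.emissions.marks)
        data.write_tsv(out / "binarized.tsv")
        record(stage, out / "binarized.tsv")

        stage = "learn"
        hseed = stage_seed(seed, 1)
        if config.k_min is not None and config.k_max is not None:
            fits = [
                hmm_mod.fit_hmm(data, K=k, seed=hseed + k, n_restarts=config.n_restarts,
                                max_iter=config.max_iter, tol=config.tol)
                for k in range(config.k_min, config.k_max + 1)
            ]
            chosen = hmm_mod.select_model(fits[:-1], fits[-1], rho=config.rho)
            model = next(m for m in fits if m.K == chosen)
        else:
            model = hmm_mod.fit_hmm(data, K=config.hmm_k, seed=hseed,
                                    n_restarts=config.n_restarts,
                                    max_iter=config.max_iter, tol=config.tol)
        model = hmm_mod.order_states(model, syn.ACTIVE_MARKS)
        model.to_json(out / "model.json")
        record(stage, out / "model.json")

        stage = "decode"
        seg = hmm_mod.decode(model, data, method=config.decode_method)
        seg.to_bed(out / "segmentation.bed")
        record(stage, out / "segmentation.bed")

        stage = "enrich"
        feats = feature_sets(world)
        enr = ann.overlap_enrichment(seg, feats)
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        occ = ann.occupancy_split(seg, feats["gene"])
        occ.to_csv(out / "occupancy.tsv", sep="\t")
        record(stage, out / "enrichment.tsv", out / "occupancy.tsv")

        stage = "dge"
        expressed = world.expression[
            (world.expression["root_rpkm"] > 0) | (world.expression["leaf_rpkm"] > 0)
        ].reset_index(drop=True)
        dge = ann.dge_rank(expressed)
        dge.to_csv(out / "dge.tsv", sep="\t", index=False)
        dge_models = [m for m in models if m.gene_id in set(dge["gene_id"])]
        denr = ann.state_enrichment_by_dge(seg, dge_models, dge)
        denr.to_csv(out / "dge_enrichment.tsv", sep="\t")
        windows = tuple(config.dge_windows)
        usable = min(windows) <= len(dge)
        rolled = ann.rolling_dge(dge, dge_models, windows=windows) if usable else None
        if rolled is not None:
            rolled.to_frame().to_csv(out / "rolling_dge.tsv", sep="\t")
            record(stage, out / "dge.tsv", out / "dge_enrichment.tsv", out / "rolling_dge.tsv")
        else:
            record(stage, out / "dge.tsv", out / "dge_enrichment.tsv")

        stage = "density"
        mb_grid = make_bins(grid.layout, config.density_bin)
        profile = regions_mod.state_density_profile(
            seg, world.genes, world.retros, consolidated, mb_grid
        )
        profile.frame.to_csv(out / "density.tsv", sep="\t", index=False)
        record(stage, out / "density.tsv")

        stage = "zones"
        # pick zone-defining states from the learned emissions: the two states
        # most involved with H3K27me3 (facultative) and with H3K27me1/H3K9me2
        # (constitutive heterochromatin)
        em = model.emission
        if {"H3K27me3", "H3K27me1", "H3K9me2"} <= set(em.marks):
            fac = em.probs[:, em.marks.index("H3K27me3")]
            het = em.probs[:, [em.marks.index("H3K27me1"), em.marks.index("H3K9me2")]].mean(1)
            tp_states = [em.states[i] for i in np.argsort(-fac, kind="stable")[:2]]
            het_states = [em.states[i] for i in np.argsort(-het, kind="stable")[:2]]
        else:  # pragma: no cover - non-default mark panels
            tp_states, het_states = ("S2", "S3"), ("S9", "S10")
        zones = regions_mod.classify_regions(profile, tp_states=tp_states, het_states=het_states)
        zones.to_csv(out / "zones.bed", sep="\t", index=False, header=False)
        record(stage, out / "zones.bed")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(manifest["config"], fh, sort_keys=True)
    manifest["outputs"]["config.yaml"] = _sha256(out / "config.yaml")
    Path(out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
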