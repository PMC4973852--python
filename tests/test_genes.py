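"""Peak-transcript assignment, expression binning, metagene profiles."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from chromstate.core_io import ValidationError
from chromstate.genes import (
    GeneModel,
    assign_peaks_to_transcripts,
    bin_expression,
    gene_fold_change,
    gene_models_from_frame,
    gene_models_from_gff3,
    metagene_profile,
    primary_transcripts,
    write_gff3,
)

from conftest import peakset


def single_exon_gene(start=10_000, end=13_000, strand="+", gid="g1"):
    return GeneModel(gid, f"{gid}.1", "chr1", strand, start, end, ((start, end),))


class TestGeneModel:
    def test_strand_aware_tss_tes(self):
        g = single_exon_gene(strand="+")
        assert (g.tss, g.tes) == (10_000, 13_000)
        m = single_exon_gene(strand="-")
        assert (m.tss, m.tes) == (13_000, 10_000)

    def test_bad_exons_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel("g", "t", "c", "+", 0, 100, ((0, 60), (50, 100)))

    def test_gff3_roundtrip(self, tmp_path):
        genes = [
            GeneModel("g1", "g1.1", "chr1", "+", 100, 900, ((100, 300), (500, 900))),
            GeneModel("g2", "g2.1", "chr2", "-", 50, 400, ((50, 400),)),
        ]
        p = tmp_path / "g.gff3"
        write_gff3(genes, p)
        back = gene_models_from_gff3(p)
        assert back == genes

    def test_primary_transcript_is_longest_mature(self):
        a = GeneModel("g", "g.1", "c", "+", 0, 1000, ((0, 200),))
        b = GeneModel("g", "g.2", "c", "+", 0, 1000, ((0, 200), (400, 800)))
        assert primary_transcripts([a, b]) == [b]


class TestAssignment:
    @pytest.mark.parametrize(
        "peak_start,peak_end,expected",
        [
            (8_600, 8_700, True),   # 1.4 kb upstream of the TSS
            (8_300, 8_400, False),  # 1.6 kb upstream: outside the window
            (11_000, 11_100, True),  # inside the gene body
            (14_400, 14_450, True),  # 1.45 kb downstream of the TES
        ],
    )
    def test_offset_window(self, peak_start, peak_end, expected):
        g = single_exon_gene()
        ps = peakset("m", "c", [("chr1", peak_start, peak_end, 5.0)])
        out = assign_peaks_to_transcripts(ps, [g], offset=1500)
        assert ("g1.1" in out) is expected

    def test_peak_may_serve_multiple_transcripts(self):
        g1 = single_exon_gene(10_000, 13_000, gid="g1")
        g2 = single_exon_gene(13_500, 16_000, gid="g2")
        ps = peakset("m", "c", [("chr1", 12_900, 13_700, 5.0)])
        out = assign_peaks_to_transcripts(ps, [g1, g2])
        assert set(out) == {"g1.1", "g2.1"}


class TestExpressionBins:
    def test_worked_example_remainder_to_low(self):
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(9)],
                "root_rpkm": [0, 0, 1, 2, 3, 4, 5, 6, 7],
                "leaf_rpkm": [0, 0, 1, 2, 3, 4, 5, 6, 7],
            }
        )
        out = bin_expression(t)
        groups = dict(zip(out["gene_id"], out["group"]))
        assert [groups[f"g{i}"] for i in range(9)] == [
            "zero", "zero", "low", "low", "low", "mid", "mid", "high", "high"
        ]

    def test_all_zero_table(self):
        t = pd.DataFrame({"gene_id": ["a", "b"], "root_rpkm": [0, 0], "leaf_rpkm": [0, 0]})
        assert (bin_expression(t)["group"] == "zero").all()

    def test_group_sizes_at_study_scale(self):
        # 21 965 genes of which 774 unexpressed: the three non-zero groups
        # split 21 191 genes as evenly as possible, outer groups absorbing
        # the remainder
        n, zeros = 21_965, 774
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i:05d}" for i in range(n)],
                "root_rpkm": [0.0] * zeros + list(np.arange(1, n - zeros + 1, dtype=float)),
                "leaf_rpkm": [0.0] * zeros + list(np.arange(1, n - zeros + 1, dtype=float)),
            }
        )
        sizes = bin_expression(t)["group"].value_counts()
        assert sizes["zero"] == 774
        assert (sizes["low"], sizes["mid"], sizes["high"]) == (7064, 7063, 7064)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            bin_expression(pd.DataFrame(columns=["gene_id", "root_rpkm", "leaf_rpkm"]))

    def test_nonzero_groups_differ_by_at_most_one(self):
        for n in range(4, 40):
            t = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "root_rpkm": np.arange(1, n + 1, dtype=float),
                    "leaf_rpkm": np.arange(1, n + 1, dtype=float),
                }
            )
            sizes = bin_expression(t)["group"].value_counts()
            nz = [sizes.get(g, 0) for g in ("low", "mid", "high")]
            assert max(nz) - min(nz) <= 1


def oracle_profile(gene: GeneModel, peaks, body_bins=100, flank=1000, flank_bins=100):
    """Rational-arithmetic metagene oracle: exact per-base bin boundaries."""
    L = gene.mature_length
    win_s = gene.start - flank
    cov = {}
    for c, s, e, fc in peaks:
        for pos in range(max(s, win_s), min(e, gene.end + flank)):
            cov[pos] = max(cov.get(pos, 0.0), fc)

    def val(pos):
        return cov.get(pos, 0.0)

    body_positions = [p for s, e in gene.exons for p in range(s, e)]
    up = list(range(gene.start - flank, gene.start))
    down = list(range(gene.end, gene.end + flank))
    if gene.strand == "-":
        body_positions = body_positions[::-1]
        up, down = down[::-1], up[::-1]

    def binned(positions, n_bins):
        sums = [Fraction(0)] * n_bins
        counts = [0] * n_bins
        for i, pos in enumerate(positions):
            b = int(Fraction(i * n_bins, len(positions)))  # floor(i*B/L) exactly
            sums[b] += Fraction(val(pos))
            counts[b] += 1
        return [float(s / c) if c else float("nan") for s, c in zip(sums, counts)]

    return binned(up, flank_bins) + binned(body_positions, body_bins) + binned(down, flank_bins)


class TestMetagene:
    def test_uniform_coverage_fills_every_bin(self):
        g = single_exon_gene(10_000, 13_000)
        ps = peakset("m", "c", [("chr1", 8_000, 15_000, 10.0)])
        prof = metagene_profile(ps, [g], {"g1": "high"})
        assert (prof["mean_fc"] == 10.0).all()
        assert len(prof) == 300 and prof["n_genes"].iloc[0] == 1

    def test_half_body_coverage_splits_bins(self):
        g = single_exon_gene(10_000, 13_000)
        ps = peakset("m", "c", [("chr1", 10_000, 11_500, 10.0)])
        prof = metagene_profile(ps, [g], {"g1": "mid"}).set_index("bin_index")
        body = prof.loc[100:199, "mean_fc"].to_numpy()
        assert (body[:50] == 10.0).all() and (body[50:] == 0.0).all()

    def test_minus_strand_profile_mirrors_plus_strand(self):
        plus = single_exon_gene(10_000, 13_000, "+", "gp")
        minus = single_exon_gene(10_000, 13_000, "-", "gm")
        # peak hugging the genomic left end = TSS side of plus, TES side of minus
        ps = peakset("m", "c", [("chr1", 9_000, 10_500, 8.0)])
        pp = metagene_profile(ps, [plus], {"gp": "high"})["mean_fc"].to_numpy()
        pm = metagene_profile(ps, [minus], {"gm": "high"})["mean_fc"].to_numpy()
        np.testing.assert_allclose(pm, pp[::-1])

    def test_only_genes_with_assigned_peaks_contribute(self):
        g1 = single_exon_gene(10_000, 13_000, gid="g1")
        g2 = single_exon_gene(50_000, 53_000, gid="g2")
        ps = peakset("m", "c", [("chr1", 10_500, 11_000, 5.0)])
        prof = metagene_profile(ps, [g1, g2], {"g1": "high", "g2": "high"})
        assert prof["n_genes"].iloc[0] == 1

    def test_matches_rational_arithmetic_oracle_on_random_small_genes(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            start = int(rng.integers(2_000, 5_000))
            length = int(rng.integers(150, 1_000))
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False))
            bounds = np.concatenate(([0], cuts, [length])) + start
            exons = tuple(
                (int(bounds[i]), int(bounds[i + 1])) for i in range(0, 2 * n_ex - 1, 2)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel("g", "g.1", "chr1", strand, start, start + length, exons)
            peaks = [
                ("chr1", int(s), int(s) + int(rng.integers(20, 400)), float(rng.uniform(4, 12)))
                for s in rng.integers(start - 1_200, start + length + 800, size=3)
            ]
            ps = peakset("m", "c", peaks)
            prof = metagene_profile(ps, [g], {"g": "high"})
            expect = oracle_profile(g, peaks)
            np.testing.assert_allclose(prof["mean_fc"].to_numpy(), expect, atol=1e-9)

    def test_profile_invariant_under_translation_and_renaming(self):
        g = GeneModel("g", "g.1", "chr1", "+", 10_000, 12_500,
                      ((10_000, 10_900), (11_300, 12_500)))
        peaks = [("chr1", 9_500, 11_000, 6.0), ("chr1", 12_000, 13_000, 9.0)]
        base = metagene_profile(peakset("m", "c", peaks), [g], {"g": "low"})
        shift = 55_555
        g2 = GeneModel("g", "g.1", "X", "+", 10_000 + shift, 12_500 + shift,
                       ((10_000 + shift, 10_900 + shift), (11_300 + shift, 12_500 + shift)))
        peaks2 = [("X", s + shift, e + shift, fc) for _, s, e, fc in peaks]
        moved = metagene_profile(peakset("m", "c", peaks2), [g2], {"g": "low"})
        pd.testing.assert_frame_equal(base, moved)


class TestGeneFoldChange:
    def test_mean_of_intersecting_peaks(self):
        g = single_exon_gene()
        ps = peakset("m", "c", [("chr1", 10_100, 10_300, 4.0), ("chr1", 12_000, 12_400, 8.0)])
        fc = gene_fold_change(ps, [g])
        assert fc["g1"] == pytest.approx(6.0)

    def test_single_peak_and_absent_gene(self):
        g1 = single_exon_gene(gid="g1")
        g2 = single_exon_gene(50_000, 53_000, gid="g2")
        ps = peakset("m", "c", [("chr1", 11_000, 11_200, 7.0)])
        fc = gene_fold_change(ps, [g1, g2])
        assert fc["g1"] == pytest.approx(7.0)
        assert "g2" not in fc

    def test_flank_only_peak_does_not_count(self):
        g = single_exon_gene()
        ps = peakset("m", "c", [("chr1", 9_000, 9_500, 7.0)])
        assert len(gene_fold_change(ps, [g])) == 0


def test_frame_to_models_roundtrip(tiny_world):
    models = gene_models_from_frame(tiny_world.genes)
    assert len(models) == len(tiny_world.genes)
    g = models[0]
    assert g.mature_length == sum(e - s for s, e in g.exons)
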