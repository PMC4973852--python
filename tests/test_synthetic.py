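"""Synthetic-epigenome generators: determinism, planted structure, rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromstate as cs
from chromstate import synthetic as syn
from chromstate.core_io import GenomeLayout, ValidationError, make_bins


@pytest.fixture(scope="module")
def layout():
    return GenomeLayout([("chr1", 10_000_000)])


@pytest.fixture(scope="module")
def regions(layout):
    return syn.make_region_truth(layout, tp_frac=0.10, gri_frac=0.20)


class TestRegions:
    def test_segments_tile_chromosome_with_tp_at_ends(self, layout, regions):
        r = regions[regions["chrom"] == "chr1"]
        assert r["start"].iloc[0] == 0 and r["end"].iloc[-1] == 10_000_000
        assert (r["start"].iloc[1:].to_numpy() == r["end"].iloc[:-1].to_numpy()).all()
        assert list(r["label"]) == ["TP", "GRI", "LRPC", "GRI", "TP"]

    def test_bad_fractions_rejected(self, layout):
        with pytest.raises(ValidationError):
            syn.make_region_truth(layout, tp_frac=0.3, gri_frac=0.3)


class TestAnnotation:
    def test_zero_ltr_density_gives_empty_set(self, layout, regions):
        _, retros = syn.generate_annotation(
            layout, regions, {"TP": 5, "GRI": 5, "LRPC": 1},
            {"TP": 0, "GRI": 0, "LRPC": 0}, seed=0
        )
        assert len(retros) == 0

    def test_tp_gene_count_within_poisson_bounds(self, layout, regions):
        genes, _ = syn.generate_annotation(
            layout, regions, {"TP": 20, "GRI": 10, "LRPC": 1},
            {"TP": 0, "GRI": 0, "LRPC": 0}, seed=3
        )
        tp_mask = (genes["start"] < 1_000_000) | (genes["start"] >= 9_000_000)
        n = tp_mask.sum()
        lo, hi = stats.poisson.ppf([0.005, 0.995], 20 * 2.0)  # 2 Mbp of TP
        assert lo <= n <= hi

    def test_same_seed_identical(self, layout, regions):
        a = syn.generate_annotation(layout, regions, {"TP": 5, "GRI": 5, "LRPC": 1},
                                    {"TP": 1, "GRI": 3, "LRPC": 8}, seed=11)
        b = syn.generate_annotation(layout, regions, {"TP": 5, "GRI": 5, "LRPC": 1},
                                    {"TP": 1, "GRI": 3, "LRPC": 8}, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_elements_do_not_overlap(self, layout, regions):
        genes, retros = syn.generate_annotation(
            layout, regions, {"TP": 20, "GRI": 15, "LRPC": 2},
            {"TP": 3, "GRI": 10, "LRPC": 25}, seed=5
        )
        spans = pd.concat([genes[["start", "end"]], retros[["start", "end"]]])
        spans = spans.sort_values("start")
        assert (spans["start"].iloc[1:].to_numpy() >= spans["end"].iloc[:-1].to_numpy()).all()

    def test_unplaceable_density_raises(self, layout, regions):
        with pytest.raises(ValidationError, match="without overlap"):
            syn.generate_annotation(layout, regions, {"TP": 400, "GRI": 400, "LRPC": 400},
                                    {"TP": 0, "GRI": 0, "LRPC": 0}, seed=0)


class TestStateChain:
    def test_infinite_persistence_freezes_initial_state(self, layout, regions):
        grid = make_bins(layout, 150)
        states = syn.generate_state_sequence(regions, grid, persistence=1e12, seed=2)
        assert len(np.unique(states)) == 1

    def test_sub_bin_persistence_rejected(self, layout, regions):
        grid = make_bins(layout, 150)
        with pytest.raises(ValidationError):
            syn.generate_state_sequence(regions, grid, persistence=0.5)

    def test_tp_frequencies_converge_to_profile(self):
        # one chromosome that is all TP: 1e5 bins of the TP profile
        layout = GenomeLayout([("c", 15_000_000)])
        grid = make_bins(layout, 150)
        regions = pd.DataFrame(
            [("c", 0, 15_000_000, "TP")], columns=["chrom", "start", "end", "label"]
        )
        profiles = syn.default_region_profiles()
        states = syn.generate_state_sequence(regions, grid, profiles, persistence=8.0, seed=4)
        freq = np.bincount(states, minlength=11) / len(states)
        assert np.abs(freq - profiles["TP"]).max() < 0.02
        # chi-square goodness of fit not rejected at alpha = 0.001 given the
        # chain's positive autocorrelation is accounted for by an effective
        # sample size of n / (2 * persistence - 1)
        n_eff = len(states) / (2 * 8.0 - 1)
        chi2 = n_eff * np.sum(
            (freq - profiles["TP"]) ** 2 / np.maximum(profiles["TP"], 1e-12)
        )
        assert chi2 < stats.chi2.ppf(0.999, df=10)

    def test_same_seed_identical(self, layout, regions):
        grid = make_bins(layout, 150)
        a = syn.generate_state_sequence(regions, grid, seed=9)
        b = syn.generate_state_sequence(regions, grid, seed=9)
        assert (a == b).all()

    def test_gene_overlay_prefers_genic_states(self, layout, regions):
        grid = make_bins(layout, 150)
        genes, retros = syn.generate_annotation(
            layout, regions, {"TP": 20, "GRI": 15, "LRPC": 2},
            {"TP": 3, "GRI": 10, "LRPC": 25}, seed=5
        )
        states = syn.generate_state_sequence(regions, grid, seed=6, genes=genes, retros=retros)
        genic_idx = {syn.STATE_NAMES.index(s) for s in syn.GENIC_STATES}
        w = grid.width
        inside = []
        for r in genes.itertuples(index=False):
            first, last = r.start // w, (r.end - 1) // w
            inside.extend(states[first : last + 1])
        frac_genic = np.mean([s in genic_idx for s in inside])
        assert frac_genic > 0.8


class TestPeakEmission:
    LAYOUT = GenomeLayout([("c", 150_000)])

    def grid(self):
        return make_bins(self.LAYOUT, 150)

    def test_certain_emission_yields_chromosome_spanning_interval(self):
        grid = self.grid()
        em = syn.EmissionMatrix([[1.0]], ("S1",), ("m",))
        states = np.zeros(grid.total_bins, dtype=np.int64)
        tracks = syn.emit_peak_tracks(states, grid, em, replicates=2, concordance=1.0, seed=0)
        for ps in tracks["m"]:
            assert list(map(tuple, ps.df[["start", "end"]].to_numpy())) == [(0, 150_000)]

    def test_zero_emission_yields_empty_tracks(self):
        grid = self.grid()
        em = syn.EmissionMatrix([[0.0]], ("S1",), ("m",))
        states = np.zeros(grid.total_bins, dtype=np.int64)
        tracks = syn.emit_peak_tracks(states, grid, em, seed=0)
        assert all(len(ps) == 0 for ps in tracks["m"])

    def test_full_concordance_gives_identical_replicates(self):
        grid = self.grid()
        em = syn.EmissionMatrix([[0.4]], ("S1",), ("m",))
        states = np.zeros(grid.total_bins, dtype=np.int64)
        tracks = syn.emit_peak_tracks(states, grid, em, replicates=3, concordance=1.0, seed=1)
        r1, r2, r3 = (ps.df[["chrom", "start", "end", "score"]] for ps in tracks["m"])
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(r1, r3)

    def test_bad_concordance_rejected(self):
        grid = self.grid()
        em = syn.EmissionMatrix([[0.4]], ("S1",), ("m",))
        with pytest.raises(ValidationError):
            syn.emit_peak_tracks(np.zeros(grid.total_bins, dtype=np.int64), grid, em,
                                 concordance=1.5)


class TestExpression:
    def _genes(self, n):
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 10_000,
                "end": np.arange(n) * 10_000 + 3000,
                "strand": "+",
                "gene_id": [f"g{i:04d}" for i in range(n)],
                "exons": [[[i * 10_000, i * 10_000 + 3000]] for i in range(n)],
            }
        )

    def test_zero_fraction_zero_means_no_silent_genes(self):
        genes = self._genes(500)
        gs = pd.Series("S5", index=genes["gene_id"])
        t = syn.generate_expression(genes, gs, zero_fraction=0.0, seed=0)
        assert ((t["root_rpkm"] > 0) | (t["leaf_rpkm"] > 0)).all()

    def test_state3_genes_diverge_more_than_state6_genes(self):
        genes = self._genes(2000)
        state = pd.Series(
            ["S3" if i < 1000 else "S6" for i in range(2000)],
            index=genes["gene_id"],
        )
        t = syn.generate_expression(genes, state, zero_fraction=0.0, seed=1)
        lfc = np.abs(np.log2(t["root_rpkm"]) - np.log2(t["leaf_rpkm"]))
        assert lfc[:1000].mean() > 2 * lfc[1000:].mean()

    def test_same_seed_identical(self):
        genes = self._genes(100)
        gs = pd.Series("S4", index=genes["gene_id"])
        a = syn.generate_expression(genes, gs, seed=5)
        b = syn.generate_expression(genes, gs, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestWholeStudy:
    def test_simulation_is_a_pure_function_of_seed(self):
        a = cs.simulate(cs.Scenario.tiny(), seed=3)
        b = cs.simulate(cs.Scenario.tiny(), seed=3)
        assert (a.truth.states == b.truth.states).all()
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(
            a.peak_tracks["H3K27me3"][0].df, b.peak_tracks["H3K27me3"][0].df
        )

    def test_truth_json_roundtrip(self, tmp_path, tiny_world):
        p = tmp_path / "truth.json"
        tiny_world.truth.to_json(p)
        back = syn.SyntheticTruth.from_json(p)
        assert (back.states == tiny_world.truth.states).all()
        np.testing.assert_allclose(back.emissions.probs, tiny_world.truth.emissions.probs)

    def test_observations_follow_planted_emissions(self, tiny_world):
        X = syn.bernoulli_observations(
            tiny_world.truth.states, tiny_world.truth.emissions, tiny_world.truth.grid, seed=0
        )
        for k in range(11):
            mask = tiny_world.truth.states == k
            if mask.sum() < 500:
                continue
            observed = X[mask].mean(axis=0)
            np.testing.assert_allclose(
                observed, tiny_world.truth.emissions.probs[k], atol=0.05
            )
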