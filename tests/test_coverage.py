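"""Coverage-window calling: tiling, normalisation, slope correction, the
log2 >= 2 cut-off cascade, block merging, and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from grcscan import coverage, simulate
from grcscan.simulate import GrcGene, GrcModel


def uniform_pileups(length=12_345, depth=10, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), length))
    ridx = simulate.seq_to_index(seq)
    counts = np.zeros((length, 4), dtype=np.int32)
    counts[np.arange(length), ridx] = depth
    return {"chr1": counts}, {"chr1": counts.copy()}, {"chr1": seq}


class TestWindowDepths:
    def test_uniform_depth_everywhere(self):
        germ, soma, ref = uniform_pileups()
        w = coverage.window_depths(germ, soma, ref, window_size=5000)
        assert (w["depth_germ"] == 10).all() and (w["depth_soma"] == 10).all()

    def test_tiling_with_truncated_terminal_window(self):
        germ, soma, ref = uniform_pileups(length=12_345)
        w = coverage.window_depths(germ, soma, ref, window_size=5000)
        assert list(zip(w["start"], w["end"])) == [(0, 5000), (5000, 10000), (10000, 12345)]

    def test_gc_computed_per_window(self):
        ref = {"chr1": "G" * 5000 + "A" * 5000}
        counts = np.zeros((10_000, 4), dtype=np.int32)
        counts[:, 0] = 5
        w = coverage.window_depths({"chr1": counts}, {"chr1": counts}, ref, 5000)
        assert list(w["gc"]) == [1.0, 0.0]

    def test_raw_ratio_over_grc_gene_matches_dosage(self, demo_dataset):
        ds = demo_dataset
        row = ds.annotation[ds.annotation["gene_id"] == "gene0003"].iloc[0]
        w = coverage.window_depths(ds.germline_pileup, ds.soma_pileup, ds.reference, 1000)
        inside = w[(w["start"] >= row["start"]) & (w["end"] <= row["end"])]
        ratio = (inside["depth_germ"] / inside["depth_soma"]).mean()
        assert ratio == pytest.approx(1 + 0.364 * 9, rel=0.05)


class TestDepthNormalise:
    def test_halves_germline_when_germ_library_doubles(self):
        w = pd.DataFrame(
            {"depth_germ": [40.0, 40.0], "depth_soma": [20.0, 20.0]}
        )
        out = coverage.depth_normalise(w)
        assert list(out["depth_germ"]) == [20.0, 20.0]

    def test_equal_totals_is_identity(self):
        w = pd.DataFrame({"depth_germ": [10.0, 30.0], "depth_soma": [15.0, 25.0]})
        out = coverage.depth_normalise(w)
        assert list(out["depth_germ"]) == [10.0, 30.0]

    def test_zero_total_depth_raises(self):
        w = pd.DataFrame({"depth_germ": [0.0], "depth_soma": [10.0]})
        with pytest.raises(ValueError):
            coverage.depth_normalise(w)


class TestSlopeCorrection:
    def _windows(self, germ, soma):
        return pd.DataFrame({"depth_germ": germ, "depth_soma": soma})

    def test_equal_tissues_slope_one(self):
        rng = np.random.default_rng(0)
        soma = rng.uniform(5, 30, 200)
        w, slope = coverage.remove_outliers_and_fit(self._windows(soma.copy(), soma))
        assert slope == pytest.approx(1.0)
        assert np.allclose(w["depth_germ"], soma)

    def test_constant_excess_corrected_exactly(self):
        rng = np.random.default_rng(1)
        soma = rng.uniform(5, 30, 200)
        w, slope = coverage.remove_outliers_and_fit(self._windows(1.5 * soma, soma))
        assert slope == pytest.approx(1.5)
        assert np.allclose(w["depth_germ"] / w["depth_soma"], 1.0)

    def test_outliers_excluded_from_fit_but_still_corrected(self):
        rng = np.random.default_rng(2)
        soma = rng.uniform(10, 20, 300)
        germ = soma.copy()
        germ[:5] = 500.0  # amplified windows far above mean + 2 SD
        w, slope = coverage.remove_outliers_and_fit(self._windows(germ, soma))
        assert slope == pytest.approx(1.0, rel=0.01)
        assert w["outlier_removed"].sum() == 5
        assert (w.loc[w["outlier_removed"], "depth_germ"] > 400).all()

    def test_constant_soma_depth_is_degenerate(self):
        w = self._windows(np.full(200, 10.0), np.full(200, 10.0))
        with pytest.raises(ValueError, match="degenerate"):
            coverage.remove_outliers_and_fit(w)

    def test_too_few_windows_rejected(self):
        w = self._windows(np.arange(50.0), np.arange(50.0))
        with pytest.raises(ValueError, match="100 windows"):
            coverage.remove_outliers_and_fit(w)

    def test_corrected_tissues_correlate_on_simulated_data(self, demo_dataset):
        ds = demo_dataset
        w = coverage.window_depths(ds.germline_pileup, ds.soma_pileup, ds.reference, 1000)
        w = coverage.depth_normalise(w)
        w, _ = coverage.remove_outliers_and_fit(w)
        grc_spans = ds.annotation[ds.annotation["gene_id"].isin(ds.grc.gene_ids)]
        non_grc = np.ones(len(w), dtype=bool)
        for _, g in grc_spans.iterrows():
            non_grc &= ~((w["start"] < g["end"]) & (w["end"] > g["start"])).to_numpy()
        r = np.corrcoef(w.loc[non_grc, "depth_germ"], w.loc[non_grc, "depth_soma"])[0, 1]
        assert r > 0.95


def _basic_windows(n=200, ratio_at=None, gc=0.45, seed=0):
    """Windows with unit ratio everywhere except chosen indices."""
    rng = np.random.default_rng(seed)
    soma = rng.uniform(18, 22, n)
    germ = soma * rng.uniform(0.98, 1.02, n)
    gcs = np.full(n, gc)
    for idx, (r, g) in (ratio_at or {}).items():
        germ[idx] = soma[idx] * r
        gcs[idx] = g
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 5000,
            "end": (np.arange(n) + 1) * 5000,
            "gc": gcs,
            "depth_germ": germ,
            "depth_soma": soma,
            "outlier_removed": False,
        }
    )


class TestCallAmplified:
    def test_fourfold_ratio_is_called_inclusively(self):
        w = _basic_windows(ratio_at={10: (4.0, 0.45)})
        out, blocks, _ = coverage.call_amplified(w)
        # histogram-mode centring can only nudge the 4.0 window upward of 2.0
        assert bool(out.loc[10, "amplified"])

    def test_gc_outside_bounds_never_called(self):
        w = _basic_windows(ratio_at={10: (10.0, 0.25), 20: (10.0, 0.65), 30: (10.0, 0.45)})
        out, _, _ = coverage.call_amplified(w)
        assert not out.loc[10, "amplified"] and out.loc[10, "gc_fail"]
        assert not out.loc[20, "amplified"] and out.loc[20, "gc_fail"]
        assert bool(out.loc[30, "amplified"])

    def test_adjacent_called_windows_merge_into_block(self):
        w = _basic_windows(ratio_at={10: (8.0, 0.45), 11: (8.0, 0.45), 40: (8.0, 0.45)})
        _, blocks, _ = coverage.call_amplified(w)
        block = blocks[blocks["n_windows"] == 2].iloc[0]
        assert (block["start"], block["end"], bool(block["is_block"])) == (50_000, 60_000, True)
        singleton = blocks[blocks["n_windows"] == 1].iloc[0]
        assert not bool(singleton["is_block"])

    def test_null_simulation_calls_nothing_either_direction(self, null_dataset):
        ds = null_dataset
        res = coverage.scan_coverage(
            ds.germline_pileup, ds.soma_pileup, ds.reference, window_size=1000
        )
        assert int(res.windows["amplified"].sum()) == 0
        assert res.n_soma_excess == 0

    def test_low_coverage_percentile_flagged(self):
        w = _basic_windows(n=100)
        w.loc[5, "depth_germ"] = 0.01
        w.loc[5, "depth_soma"] = 0.0
        out, _, _ = coverage.call_amplified(w)
        assert bool(out.loc[5, "low_coverage"])


class TestIntersectGenes:
    def test_overlap_and_half_open_boundary(self):
        ann = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 5150],
                "end": [200, 5300],
                "gene_id": ["inside", "abutting"],
            }
        )
        called = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [5150]})
        assert coverage.intersect_genes(called, ann) == ["inside"]

    def test_empty_inputs(self):
        assert coverage.intersect_genes(pd.DataFrame(), pd.DataFrame()) == []


class TestRecovery:
    def test_grc_genes_recovered_without_false_positives(self, demo_dataset):
        ds = demo_dataset
        res = coverage.scan_coverage(
            ds.germline_pileup, ds.soma_pileup, ds.reference, ds.annotation, window_size=1000
        )
        assert set(res.genes) == ds.grc.gene_ids
        assert res.n_soma_excess == 0

    def test_calling_invariant_to_global_library_rescaling(self):
        ref, ann = simulate.simulate_genome(1, 150_000, 10, seed=21)
        grc = GrcModel(0.364, (GrcGene("gene0004", 12, 0.0),))
        calls = {}
        for factor in (1.0, 2.5):
            ds = simulate.simulate_pileups(ref, ann, grc, depth_soma=25, seed=22,
                                           germ_depth_factor=factor)
            res = coverage.scan_coverage(
                ds.germline_pileup, ds.soma_pileup, ref, ann, window_size=1000
            )
            calls[factor] = set(res.genes)
        assert calls[1.0] == calls[2.5] == {"gene0004"}

    def test_increasing_copy_number_never_loses_the_gene(self):
        ref, ann = simulate.simulate_genome(1, 150_000, 10, seed=23)
        called = []
        for c in (10, 40, 160):
            grc = GrcModel(0.364, (GrcGene("gene0006", c, 0.0),))
            ds = simulate.simulate_pileups(ref, ann, grc, depth_soma=20, seed=24)
            res = coverage.scan_coverage(
                ds.germline_pileup, ds.soma_pileup, ref, ann, window_size=1000
            )
            called.append("gene0006" in res.genes)
        assert called == sorted(called) and called[0]  # once called, stays called
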