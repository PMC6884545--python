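"""Germline-specific SNV calling, the soma-swap negative control, per-gene
summaries, consensus building and RNA verification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grcscan import simulate, snv
from grcscan.simulate import GrcGene, GrcModel
from conftest import make_pileup_pair

REF = "ACGT" * 25  # 100 bp


class TestCallRule:
    def test_clean_germline_allele_is_called(self):
        germ, soma = make_pileup_pair(REF, {10: {"A": 28, "C": 12}}, {10: {"A": 15}})
        calls = snv.call_specific_snvs(germ, soma, {"chr1": REF})
        assert len(calls) == 1
        call = calls.iloc[0]
        assert (call["pos"], call["ref"], call["alt"]) == (10, "G", "C")
        assert (call["germ_alt_reads"], call["soma_depth"]) == (12, 15)

    def test_nine_supporting_reads_is_below_threshold(self):
        germ, soma = make_pileup_pair(REF, {10: {"A": 31, "C": 9}}, {10: {"A": 15}})
        assert len(snv.call_specific_snvs(germ, soma, {"chr1": REF})) == 0

    def test_single_soma_alt_read_vetoes_the_call(self):
        germ, soma = make_pileup_pair(REF, {10: {"A": 28, "C": 12}}, {10: {"A": 29, "C": 1}})
        assert len(snv.call_specific_snvs(germ, soma, {"chr1": REF})) == 0

    def test_undercovered_soma_site_is_skipped(self):
        germ, soma = make_pileup_pair(REF, {10: {"A": 28, "C": 12}}, {10: {"A": 9}})
        assert len(snv.call_specific_snvs(germ, soma, {"chr1": REF})) == 0

    def test_multiallelic_site_yields_one_call_per_alt(self):
        germ, soma = make_pileup_pair(REF, {10: {"C": 15, "T": 11, "G": 4}}, {10: {"G": 20}})
        calls = snv.call_specific_snvs(germ, soma, {"chr1": REF})
        assert sorted(calls["alt"]) == ["C", "T"]

    def test_site_mode_counts_total_depth(self):
        germ, soma = make_pileup_pair(REF, {10: {"A": 9, "C": 3}}, {10: {"A": 15}})
        allele = snv.call_specific_snvs(germ, soma, {"chr1": REF}, count_mode="allele")
        site = snv.call_specific_snvs(germ, soma, {"chr1": REF}, count_mode="site")
        assert len(allele) == 0 and len(site) == 1

    def test_no_call_ever_has_soma_alt_reads(self, demo_dataset):
        ds = demo_dataset
        calls = snv.call_specific_snvs(ds.germline_pileup, ds.soma_pileup, ds.reference)
        assert (calls["soma_alt_reads"] == 0).all()

    @given(st.integers(min_value=1, max_value=40))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_calls_monotone_nonincreasing_in_min_germ(self, min_germ):
        germ, soma = make_pileup_pair(
            REF, {10: {"A": 20, "C": 12}, 30: {"T": 25, "G": 25}}, {}
        )
        n = len(snv.call_specific_snvs(germ, soma, {"chr1": REF}, min_germ=min_germ))
        n_next = len(snv.call_specific_snvs(germ, soma, {"chr1": REF}, min_germ=min_germ + 1))
        assert n_next <= n


class TestNegativeControl:
    def test_zero_on_clean_simulation(self, demo_dataset):
        ds = demo_dataset
        assert snv.negative_control(ds.germline_pileup, ds.soma_pileup, ds.reference) == 0

    def test_zero_with_sequencing_error_over_seeds(self):
        ref, ann = simulate.simulate_genome(1, 80_000, 4, seed=31)
        grc = GrcModel(0.364, (GrcGene("gene0002", 9, 0.01),))
        for seed in (1, 2, 3):
            ds = simulate.simulate_pileups(ref, ann, grc, depth_soma=20, error_rate=1e-3, seed=seed)
            assert snv.negative_control(ds.germline_pileup, ds.soma_pileup, ds.reference) == 0

    def test_swapping_a_called_site_yields_no_call(self):
        germ, soma = make_pileup_pair(REF, {10: {"A": 28, "C": 12}}, {10: {"A": 15}})
        assert len(snv.call_specific_snvs(germ, soma, {"chr1": REF})) == 1
        assert len(snv.call_specific_snvs(soma, germ, {"chr1": REF})) == 0

    def test_swap_symmetry_on_label_exchanged_data(self, demo_dataset):
        ds = demo_dataset
        n_calls = len(snv.call_specific_snvs(ds.germline_pileup, ds.soma_pileup, ds.reference))
        n_neg_on_swapped = snv.negative_control(ds.soma_pileup, ds.germline_pileup, ds.reference)
        assert n_neg_on_swapped == n_calls


class TestIntersectSamples:
    def _call(self, pos, alt="C"):
        return pd.DataFrame(
            [["chr1", pos, "A", alt, 12, 40, 0, 20]], columns=snv.CALL_COLUMNS
        )

    def test_call_missing_from_one_sample_is_dropped(self):
        a = pd.concat([self._call(10), self._call(20)], ignore_index=True)
        b = pd.concat([self._call(10), self._call(20)], ignore_index=True)
        c = self._call(10)
        out = snv.intersect_samples([a, b, c])
        assert list(out["pos"]) == [10]

    def test_single_sample_is_identity(self):
        a = self._call(10)
        pd.testing.assert_frame_equal(snv.intersect_samples([a]), a)

    def test_replicate_simulations_retain_truth_sites(self):
        ref, ann = simulate.simulate_genome(1, 80_000, 4, seed=41)
        grc = GrcModel(0.364, (GrcGene("gene0003", 50, 0.01),))
        per_sample = []
        for seed in (1, 2, 3):
            ds = simulate.simulate_pileups(ref, ann, grc, depth_soma=30, seed=seed)
            per_sample.append(
                snv.call_specific_snvs(ds.germline_pileup, ds.soma_pileup, ref)
            )
        shared = snv.intersect_samples(per_sample)
        truth = ds.truth_snvs  # same truth positions each seed? positions differ per seed
        # the intersection is a subset of each sample's calls
        for sample in per_sample:
            keys = set(map(tuple, sample[["chrom", "pos", "alt"]].itertuples(index=False)))
            assert set(map(tuple, shared[["chrom", "pos", "alt"]].itertuples(index=False))) <= keys


class TestGeneSummary:
    def _ann(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [50, 100],
             "gene_id": ["gA", "gB"]}
        )

    def _calls(self, positions):
        return pd.DataFrame(
            [["chr1", p, "A", "C", 12, 40, 0, 20] for p in positions],
            columns=snv.CALL_COLUMNS,
        )

    def test_five_snvs_is_high_confidence_four_is_not(self):
        out5 = snv.summarise_genes(self._calls([1, 2, 3, 4, 5]), self._ann())
        out4 = snv.summarise_genes(self._calls([1, 2, 3, 4]), self._ann())
        assert bool(out5.set_index("gene_id").loc["gA", "high_confidence"])
        assert not bool(out4.set_index("gene_id").loc["gA", "high_confidence"])

    def test_amplified_gene_is_high_confidence_without_snvs(self):
        out = snv.summarise_genes(self._calls([]), self._ann(), amplified_genes={"gB"})
        tab = out.set_index("gene_id")
        assert bool(tab.loc["gB", "high_confidence"]) and not bool(tab.loc["gA", "high_confidence"])

    def test_empty_call_list(self):
        out = snv.summarise_genes(pd.DataFrame(columns=snv.CALL_COLUMNS), self._ann())
        assert not out["high_confidence"].any()


class TestConsensus:
    def _ann(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "gene_id": ["gA"]})

    def test_no_calls_alt_equals_ref(self):
        out = snv.build_consensus(pd.DataFrame(columns=snv.CALL_COLUMNS), {"chr1": REF}, self._ann())
        ref_seq, alt_seq = out["gA"]
        assert ref_seq == alt_seq == REF

    def test_three_calls_give_hamming_distance_three(self):
        calls = pd.DataFrame(
            [["chr1", p, REF[p], "C" if REF[p] != "C" else "G", 12, 40, 0, 20] for p in (3, 40, 77)],
            columns=snv.CALL_COLUMNS,
        )
        ref_seq, alt_seq = snv.build_consensus(calls, {"chr1": REF}, self._ann())["gA"]
        assert len(ref_seq) == len(alt_seq)
        assert sum(a != b for a, b in zip(ref_seq, alt_seq)) == 3

    def test_simulated_divergence_recovered_in_consensus(self):
        ref, ann = simulate.simulate_genome(1, 60_000, 2, gene_length=1000, seed=51)
        grc = GrcModel(0.364, (GrcGene("gene0001", 30, 0.01),))
        ds = simulate.simulate_pileups(ref, ann, grc, depth_soma=30, seed=52)
        calls = snv.call_specific_snvs(ds.germline_pileup, ds.soma_pileup, ref)
        cons = snv.build_consensus(calls, ref, ann)
        gene = ann.iloc[0]
        _, alt_seq = cons["gene0001"]
        truth = ds.truth_snvs
        recovered = sum(
            alt_seq[int(t["pos"]) - int(gene["start"])] == t["alt"] for _, t in truth.iterrows()
        )
        assert len(truth) > 0 and recovered / len(truth) >= 0.95


class TestTranscriptionVerification:
    def _ann(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "gene_id": ["gA"]})

    def _rna(self, pos, ref_n, alt_n, ref_base="A", alt_base="C"):
        counts = np.zeros((100, 4), dtype=np.int32)
        counts[pos, simulate.BASE_INDEX[ref_base]] = ref_n
        counts[pos, simulate.BASE_INDEX[alt_base]] = alt_n
        return {"chr1": counts}

    def _call(self, pos=8):  # REF[8] == 'A'
        return pd.DataFrame([["chr1", pos, "A", "C", 12, 40, 0, 20]], columns=snv.CALL_COLUMNS)

    def test_ratio_just_above_one_percent_supported(self):
        out = snv.verify_transcription(self._call(), self._rna(8, 99, 1), self._ann())
        assert bool(out.set_index("gene_id").loc["gA", "expressed"])  # 1/99 > 0.01

    def test_exactly_one_percent_not_supported(self):
        out = snv.verify_transcription(self._call(), self._rna(8, 100, 1), self._ann())
        assert not bool(out.set_index("gene_id").loc["gA", "expressed"])  # 1/100 == 0.01, strict

    def test_under_hundred_reads_not_evaluated(self):
        out = snv.verify_transcription(self._call(), self._rna(8, 95, 4), self._ann())
        assert not bool(out.set_index("gene_id").loc["gA", "expressed"])

    def test_simulated_expressed_genes_all_supported(self):
        ref, ann = simulate.simulate_genome(1, 60_000, 2, gene_length=1000, seed=61)
        grc = GrcModel(0.364, (GrcGene("gene0002", 20, 0.01),))
        ds = simulate.simulate_pileups(ref, ann, grc, depth_soma=30, seed=62)
        rna = simulate.simulate_rna_pileups(ds, depth=300, alt_fraction=0.3, seed=63)
        calls = snv.call_specific_snvs(ds.germline_pileup, ds.soma_pileup, ref)
        out = snv.verify_transcription(calls, rna, ann).set_index("gene_id")
        assert bool(out.loc["gene0002", "expressed"])
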