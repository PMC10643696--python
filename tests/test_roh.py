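import numpy as np
import pandas as pd
import pytest

from kinselect import sim
from kinselect.datamodel import MISSING, make_variant_table
from kinselect.roh import (
    GenerationModel,
    ROHParams,
    bin_length_class,
    bin_length_classes,
    detect_roh,
    f_roh,
    generations_to_ancestor,
    map_extent,
)


def _tract_genotypes(variants, tract):
    """Heterozygous individual with one homozygous tract (chrom, lo, hi)."""
    g = np.ones(len(variants), dtype=np.int8)
    chrom, lo, hi = tract
    inside = (variants["chrom"] == chrom) & variants["pos"].between(lo, hi)
    g[inside.to_numpy()] = 0
    return g[None, :]


class TestDetect:
    def test_fully_heterozygous_no_roh(self, snp_map_10k):
        g = np.ones((1, len(snp_map_10k)), dtype=np.int8)
        assert len(detect_roh(g, snp_map_10k)) == 0

    def test_five_mb_tract_recovered(self, snp_map_10k):
        tract = ("chr1", 20_000_000, 25_000_000)
        g = _tract_genotypes(snp_map_10k, tract)
        seg = detect_roh(g, snp_map_10k)
        assert len(seg) == 1
        window_span = 15 * 10_000
        assert abs(seg["start_pos"].iloc[0] - tract[1]) <= window_span
        assert abs(seg["end_pos"].iloc[0] - tract[2]) <= window_span

    def test_short_tract_rejected_by_min_length(self, snp_map_10k):
        g = _tract_genotypes(snp_map_10k, ("chr1", 30_000_000, 30_200_000))
        assert len(detect_roh(g, snp_map_10k)) == 0

    def test_gap_splits_run(self):
        # homozygous SNPs with a 2-Mb hole in the middle of a tract
        pos = np.concatenate(
            [np.arange(1, 301) * 10_000, 5_000_000 + np.arange(1, 301) * 10_000]
        )
        v = make_variant_table(["chr1"] * 600, pos)
        g = np.zeros((1, 600), dtype=np.int8)
        seg = detect_roh(g, v)
        assert len(seg) == 2
        assert (seg["length_bp"] < 5_000_000).all()

    def test_few_snps_chromosome_warns(self, caplog):
        v = make_variant_table(["chr1"] * 5, np.arange(1, 6) * 1000)
        g = np.zeros((1, 5), dtype=np.int8)
        with caplog.at_level("WARNING"):
            seg = detect_roh(g, v)
        assert len(seg) == 0

    def test_segments_satisfy_all_filters_and_do_not_overlap(self, snp_map_10k):
        rng = np.random.default_rng(33)
        freqs = rng.uniform(0.2, 0.8, len(snp_map_10k))
        segs_in = [("chr1", 10_000_000, 14_000_000), ("chr1", 60_000_000, 61_500_000)]
        g = sim.inject_autozygosity(snp_map_10k, freqs, segs_in, rng, error_rate=0.001)
        params = ROHParams()
        seg = detect_roh(g[None, :], snp_map_10k, params)
        assert len(seg) > 0
        assert (seg["n_snps"] >= params.min_snp).all()
        assert (seg["length_bp"] >= params.min_length_bps).all()
        dens = seg["n_snps"] / (seg["length_bp"] / 1000.0)
        assert (dens >= params.min_density).all()
        seg = seg.sort_values("start_pos")
        assert (seg["start_pos"].to_numpy()[1:] > seg["end_pos"].to_numpy()[:-1]).all()

    def test_monotone_in_threshold_and_opp(self, snp_map_10k):
        rng = np.random.default_rng(44)
        freqs = rng.uniform(0.2, 0.8, len(snp_map_10k))
        g = sim.inject_autozygosity(
            snp_map_10k, freqs, [("chr1", 20_000_000, 30_000_000)], rng, error_rate=0.005
        )[None, :]
        base = detect_roh(g, snp_map_10k, ROHParams())["length_bp"].sum()
        looser_thr = detect_roh(g, snp_map_10k, ROHParams(threshold=0.01))["length_bp"].sum()
        looser_opp = detect_roh(g, snp_map_10k, ROHParams(max_opp_window=2))["length_bp"].sum()
        assert looser_thr >= base
        assert looser_opp >= base

    def test_recovery_rate_with_errors(self, snp_map_10k):
        """>=90% of injected >=1 Mb autozygous length is recovered and <=5%
        of the rest of the genome is falsely covered (0.1% genotype error)."""
        rng = np.random.default_rng(55)
        freqs = rng.uniform(0.2, 0.8, len(snp_map_10k))
        covered_t = total_t = covered_f = total_f = 0
        for rep in range(5):
            tracts = [("chr1", 10_000_000 + 30_000_000 * k, 13_000_000 + 30_000_000 * k)
                      for k in range(2)]
            g = sim.inject_autozygosity(snp_map_10k, freqs, tracts, rng, error_rate=0.001)
            seg = detect_roh(g[None, :], snp_map_10k)
            pos = snp_map_10k["pos"].to_numpy()
            in_truth = np.zeros(len(pos), bool)
            for _, lo, hi in tracts:
                in_truth |= (pos >= lo) & (pos <= hi)
            in_detected = np.zeros(len(pos), bool)
            for _, r in seg.iterrows():
                in_detected |= (pos >= r["start_pos"]) & (pos <= r["end_pos"])
            covered_t += (in_truth & in_detected).sum()
            total_t += in_truth.sum()
            covered_f += (~in_truth & in_detected).sum()
            total_f += (~in_truth).sum()
        assert covered_t / total_t >= 0.90
        assert covered_f / total_f <= 0.05


class TestFroh:
    def test_zero_segments(self, snp_map_10k):
        empty = detect_roh(np.ones((1, len(snp_map_10k)), dtype=np.int8), snp_map_10k)
        assert f_roh(empty, snp_map_10k) == 0.0

    def test_full_span_is_one(self, snp_map_10k):
        seg = pd.DataFrame(
            {"length_bp": [map_extent(snp_map_10k)]}
        )
        assert f_roh(seg, snp_map_10k) == pytest.approx(1.0)

    def test_injected_fraction_recovered(self, snp_map_10k):
        rng = np.random.default_rng(66)
        freqs = rng.uniform(0.2, 0.8, len(snp_map_10k))
        tracts = [("chr1", 10_000_000, 25_000_000), ("chr1", 50_000_000, 60_000_000)]
        g = sim.inject_autozygosity(snp_map_10k, freqs, tracts, rng, error_rate=0.001)
        seg = detect_roh(g[None, :], snp_map_10k)
        truth = 25_000_000 / map_extent(snp_map_10k)
        assert f_roh(seg, snp_map_10k) == pytest.approx(truth, abs=0.03)

    def test_empty_map_fatal(self):
        with pytest.raises(ValueError):
            f_roh(pd.DataFrame({"length_bp": []}), pd.DataFrame({"chrom": [], "pos": []}))


class TestBinning:
    @pytest.mark.parametrize(
        "mb,label",
        [(30, "24-48Mb"), (5.99, "0-6Mb"), (6.0, "6-12Mb"), (48.0, ">48Mb"), (0.3, "0-6Mb")],
    )
    def test_boundaries(self, mb, label):
        assert bin_length_class(mb) == label

    def test_one_segment_per_class(self):
        seg = pd.DataFrame(
            {"length_class": [bin_length_class(x) for x in (1, 7, 13, 30, 60)]}
        )
        counts = bin_length_classes(seg)
        assert counts.tolist() == [1, 1, 1, 1, 1]
        assert len(counts) == 5


class TestGenerations:
    def test_24mb_more_than_two_generations(self):
        assert generations_to_ancestor(24.0) == pytest.approx(2.0032, abs=1e-4)
        assert generations_to_ancestor(24.0) > 2

    def test_algebraic_identity_one_generation(self):
        L = 100.0 / (2.0 * 1.04)
        assert generations_to_ancestor(L) == pytest.approx(1.0, abs=1e-12)

    def test_50mb_under_one_generation(self):
        assert generations_to_ancestor(50.0) == pytest.approx(0.9615, abs=1e-4)
        assert generations_to_ancestor(50.0) < 1

    def test_strictly_decreasing_in_length(self):
        ls = np.linspace(0.5, 60, 100)
        gs = [generations_to_ancestor(l) for l in ls]
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generations_to_ancestor(0.0)
        with pytest.raises(ValueError):
            generations_to_ancestor(10.0, GenerationModel(r=0.0))
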