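import numpy as np
import pandas as pd
import pytest

from kinselect import sim
from kinselect.datamodel import MISSING


class TestFrequencies:
    def test_small_fst_stays_near_ancestral(self):
        cfg = sim.SimConfig(n_variants=5000, fst=0.001, seed=1)
        rng = np.random.default_rng(1)
        anc, freqs = sim.draw_subpop_frequencies(cfg, rng)
        close = np.abs(freqs - anc[None, :]) < 0.05
        assert close.mean() >= 0.99

    def test_seed_reproducible(self):
        cfg = sim.SimConfig(n_variants=1000, fst=0.2, seed=5)
        a1, f1 = sim.draw_subpop_frequencies(cfg)
        a2, f2 = sim.draw_subpop_frequencies(cfg)
        np.testing.assert_array_equal(f1, f2)

    def test_hudson_fst_recovered(self, two_pop_freqs):
        anc, freqs = two_pop_freqs
        p1, p2 = freqs
        # Hudson-style ratio-of-averages on the population frequencies
        num = (p1 - p2) ** 2
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num.sum() / den.sum()
        assert fst == pytest.approx(0.2, abs=0.02)

    def test_degenerate_fst_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(fst=0.0, seed=1).validate()


class TestGeneDrop:
    def test_parent_offspring_realized_ibd_exact(self):
        cfg = sim.SimConfig(n_variants=2000, pedigree=sim.ped_parent_offspring("t"), seed=3)
        g, v, s, truth = sim.gene_drop(cfg)
        po = truth.pairs[(truth.pairs.id1 == "t_f") & (truth.pairs.id2 == "t_c")].iloc[0]
        assert po["z1"] == 1.0 and po["pi_hat"] == 0.5
        assert po["expected_kinship"] == 0.25

    def test_full_sib_mean_ibd(self, sib_cohort):
        g, v, s, truth = sib_cohort
        fam = lambda s: s.str.split("_").str[0]
        sib = truth.pairs[
            truth.pairs.id1.str.endswith("_s1")
            & truth.pairs.id2.str.endswith("_s2")
            & (fam(truth.pairs.id1) == fam(truth.pairs.id2))
        ]
        assert len(sib) == 50
        z = sib[["z0", "z1", "z2"]].mean().to_numpy()
        np.testing.assert_allclose(z, [0.25, 0.50, 0.25], atol=0.03)

    def test_sib_mating_offspring_autozygosity(self):
        """Offspring of a full-sib mating: expected autozygous fraction 1/4."""
        ped = []
        for i in range(40):
            fam = sim.ped_full_sibs(f"q{i}")
            fam.append(
                sim.PedigreeEntry(f"q{i}_in", "male", father=f"q{i}_s1", mother=f"q{i}_s2")
            )
            ped += fam
        chroms = {f"chr{i}": 50_000_000 for i in range(1, 11)}
        cfg = sim.SimConfig(chrom_lengths=chroms, n_variants=5000, pedigree=ped, seed=9)
        g, v, s, truth = sim.gene_drop(cfg)
        inbred = [f"q{i}_in" for i in range(40)]
        assert truth.autozygous_fraction[inbred].mean() == pytest.approx(0.25, abs=0.05)
        assert truth.pairs[["z0", "z1", "z2"]].min().min() >= 0.0

    def test_unknown_parent_fatal(self):
        ped = [sim.PedigreeEntry("kid", father="ghost", mother="ghost2")]
        with pytest.raises(ValueError, match="ghost"):
            sim.gene_drop(sim.SimConfig(n_variants=100, pedigree=ped, seed=1))

    def test_seed_determinism_byte_identical(self):
        cfg = sim.demo_config(seed=4)
        cfg.n_variants = 800
        g1, v1, s1, t1 = sim.gene_drop(cfg)
        g2, v2, s2, t2 = sim.gene_drop(cfg)
        np.testing.assert_array_equal(g1, g2)
        pd.testing.assert_frame_equal(t1.pairs, t2.pairs)
        pd.testing.assert_frame_equal(t1.autozygous, t2.autozygous)

    def test_missingness_rate_applied(self):
        cfg = sim.demo_config(seed=6)
        cfg.n_variants = 2000
        cfg.missing_rate = 0.05
        g, *_ = sim.gene_drop(cfg)
        assert (g == MISSING).mean() == pytest.approx(0.05, abs=0.01)


class TestAdmixed:
    def test_pure_target_all_from_one_pop(self, two_pop_freqs):
        _, freqs = two_pop_freqs
        # make pop freqs disjoint to identify origin: pop A fixed ref, pop B fixed alt
        fr = np.vstack([np.full(500, 1e-6), np.full(500, 1 - 1e-6)])
        cfg = sim.SimConfig(n_variants=500, fst=0.2, seed=2)
        g, v, q = sim.make_admixed(cfg, fr, np.array([[1.0, 0.0]]))
        assert q[0, 0] == 1.0
        assert (g == 0).all()

    def test_half_half_realized_fraction(self, two_pop_freqs):
        _, freqs = two_pop_freqs
        cfg = sim.SimConfig(n_variants=5000, fst=0.2, seed=12)
        g, v, q = sim.make_admixed(cfg, freqs, np.tile([0.5, 0.5], (20, 1)))
        assert q[:, 0].mean() == pytest.approx(0.5, abs=0.03)

    def test_malformed_target_fatal(self, two_pop_freqs):
        _, freqs = two_pop_freqs
        cfg = sim.SimConfig(n_variants=100, fst=0.2, seed=2)
        with pytest.raises(ValueError):
            sim.make_admixed(cfg, freqs, np.array([[0.7, 0.7]]))


class TestTruthExport:
    def test_bed_round_trip(self, tmp_path):
        cfg = sim.SimConfig(
            n_variants=2000, pedigree=sim.ped_first_cousin_offspring("c"), seed=14
        )
        g, v, s, truth = sim.gene_drop(cfg)
        sim.export_truth(truth, str(tmp_path))
        back = sim.read_truth_bed(str(tmp_path / "truth_autozygous.bed"))
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), truth.autozygous.reset_index(drop=True)
        )

    def test_empty_pedigree_truth_files(self, tmp_path):
        truth = sim.TruthSet(
            q=pd.DataFrame(columns=["sample_id", "q_A", "q_B"]),
            pairs=pd.DataFrame(columns=["id1", "id2", "z0", "z1", "z2", "pi_hat", "expected_kinship"]),
            autozygous=pd.DataFrame(columns=["sample_id", "chrom", "start_pos", "end_pos"]),
            autozygous_fraction=pd.Series(dtype=float),
        )
        sim.export_truth(truth, str(tmp_path))
        lines = (tmp_path / "truth_pairs.tsv").read_text().splitlines()
        assert lines[0].startswith("id1\tid2")
        assert len(lines) == 1

    def test_segment_snp_conservation(self):
        """SNPs inside truth segments reproduce the recorded per-locus
        autozygous fraction exactly."""
        cfg = sim.SimConfig(
            n_variants=3000, pedigree=sim.ped_first_cousin_offspring("c"), seed=15
        )
        g, v, s, truth = sim.gene_drop(cfg)
        pos = v["pos"].to_numpy()
        chrom = v["chrom"].to_numpy()
        for sid in ["c_x"]:
            segs = truth.autozygous[truth.autozygous["sample_id"] == sid]
            covered = np.zeros(len(v), bool)
            for _, r in segs.iterrows():
                covered |= (chrom == r["chrom"]) & (pos >= r["start_pos"]) & (pos <= r["end_pos"])
            assert covered.mean() == pytest.approx(truth.autozygous_fraction[sid], abs=1e-12)

    def test_scenario_yaml_round_trip(self, tmp_path):
        cfg = sim.demo_config(seed=3)
        path = tmp_path / "scenario.yaml"
        sim.save_scenario(cfg, str(path))
        cfg2 = sim.load_scenario(str(path))
        assert cfg2.seed == cfg.seed
        assert cfg2.fst == cfg.fst
        assert [e.id for e in cfg2.pedigree] == [e.id for e in cfg.pedigree]
        g1, *_ = sim.gene_drop(cfg)
        g2, *_ = sim.gene_drop(cfg2)
        np.testing.assert_array_equal(g1, g2)
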