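import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinselect import sim
from kinselect.datamodel import MISSING
from kinselect.relatedness import (
    IBDRelatedness,
    RelationshipThresholds,
    classify_relationship,
    ibd_moments,
    ibs_counts,
    mds_embed,
    pair_matrix,
    pairwise_relatedness,
)


class TestIBSCounts:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([0], [2], (1, 0, 0)),
            ([1], [1], (0, 0, 1)),
            ([0], [1], (0, 1, 0)),
            ([0, 1, 2], [2, 1, 0], (2, 0, 1)),
        ],
    )
    def test_enumeration(self, x, y, expected):
        assert ibs_counts(np.array(x), np.array(y)) == expected

    def test_identical_vectors(self):
        x = np.tile([0, 1, 2, 1], 25)
        assert ibs_counts(x, x) == (0, 0, 100)

    def test_missing_excluded(self):
        x = np.array([0, MISSING, 2])
        y = np.array([2, 1, MISSING])
        assert ibs_counts(x, y) == (1, 0, 0)

    def test_no_complete_loci_fatal(self):
        with pytest.raises(ValueError, match="complete"):
            ibs_counts(np.array([MISSING]), np.array([1]))


class TestIBDMoments:
    def test_duplicate_pair_pi_near_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 10_000)
        x = rng.binomial(2, p).astype(np.int8)
        counts = ibs_counts(x, x)
        z0, z1, z2, pi = ibd_moments(counts, p)
        assert pi >= 0.99

    def test_simplex_and_symmetry(self, sib_cohort):
        g, variants, samples, truth = sib_cohort
        pairs, _ = pairwise_relatedness(g[:20], list(samples["sample_id"][:20]))
        z = pairs[["z0", "z1", "z2"]].to_numpy()
        assert np.allclose(z.sum(axis=1), 1.0, atol=1e-9)
        assert ((z >= 0) & (z <= 1)).all()
        assert pairs["pi_hat"].between(0, 1).all()
        # symmetry: reversing sample order gives identical pair values
        rev_pairs, _ = pairwise_relatedness(
            g[:20][::-1].copy(), list(samples["sample_id"][:20])[::-1]
        )
        key = lambda df: df.assign(
            a=np.minimum(df.id1, df.id2), b=np.maximum(df.id1, df.id2)
        ).set_index(["a", "b"])["pi_hat"].sort_index()
        pd.testing.assert_series_equal(key(pairs), key(rev_pairs), atol=1e-12)

    def test_all_monomorphic_fatal(self):
        with pytest.raises(ValueError, match="monomorphic|non-positive"):
            ibd_moments((0, 0, 100), np.zeros(100))


class TestClassifier:
    @pytest.mark.parametrize(
        "pi,expected",
        [
            (0.96, "duplicate_or_twin"),
            (0.95, "first_degree"),  # duplicate boundary is strict
            (0.40, "first_degree"),  # "40% or more" is inclusive
            (0.399, "second_degree"),
            (0.20, "second_degree"),
            (0.10, "third_degree"),
            (0.09, "unrelated"),
            (0.0, "unrelated"),
            (1.0, "duplicate_or_twin"),
        ],
    )
    def test_boundaries(self, pi, expected):
        assert classify_relationship(pi) == expected

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            classify_relationship(1.2)

    def test_thresholds_must_decrease(self):
        with pytest.raises(ValueError):
            RelationshipThresholds(first=0.1, third=0.4).validate()

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1))
    def test_total_and_exclusive(self, pi):
        assert classify_relationship(pi) in (
            "duplicate_or_twin",
            "first_degree",
            "second_degree",
            "third_degree",
            "unrelated",
        )


class TestPedigreeRecovery:
    def test_parent_offspring_and_sibs(self, sib_cohort):
        g, variants, samples, truth = sib_cohort
        pairs, _ = pairwise_relatedness(g, list(samples["sample_id"]))
        fam = lambda s: s.str.split("_").str[0]
        po = pairs[
            pairs.id1.str.endswith("_f") & pairs.id2.str.endswith("_s1")
            & (fam(pairs.id1) == fam(pairs.id2))
        ]
        fs = pairs[
            pairs.id1.str.endswith("_s1") & pairs.id2.str.endswith("_s2")
            & (fam(pairs.id1) == fam(pairs.id2))
        ]
        unrel = pairs[
            pairs.id1.str.endswith("_f") & pairs.id2.str.endswith("_f")
            & (fam(pairs.id1) != fam(pairs.id2))
        ]
        assert len(po) == 50 and len(fs) == 50
        assert 0.45 <= po["pi_hat"].mean() <= 0.55
        assert po["z1"].mean() > 0.8
        assert 0.45 <= fs["pi_hat"].mean() <= 0.55
        assert unrel["pi_hat"].mean() <= 0.05

    def test_estimates_track_realized_truth(self, sib_cohort):
        g, variants, samples, truth = sib_cohort
        pairs, _ = pairwise_relatedness(g, list(samples["sample_id"]))
        merged = pairs.merge(truth.pairs, on=["id1", "id2"], suffixes=("", "_true"))
        fam_pairs = merged[merged["expected_kinship"] > 0]
        err = (fam_pairs["pi_hat"] - fam_pairs["pi_hat_true"]).abs()
        assert err.mean() < 0.05


class TestMDS:
    def test_duplicates_identical_coordinates(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float)
        x = mds_embed(d, 2)
        # second eigenvalue is numerically zero; allow eps-scale noise there
        np.testing.assert_allclose(x[0], x[1], atol=1e-6)

    def test_three_point_metric_exact(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        x = mds_embed(d, 2)
        recon = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_deterministic_sign_convention(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        x1, x2 = mds_embed(d, 2), mds_embed(d, 2)
        np.testing.assert_array_equal(x1, x2)
        nz = x1[np.abs(x1[:, 0]) > 1e-12, 0]
        assert nz[0] > 0

    def test_subspecies_separate_on_dim1(self, two_pop_cohort):
        g, labels = two_pop_cohort
        _, dist = pairwise_relatedness(g)
        coords = mds_embed(dist, 2)
        a = coords[np.array(labels) == "A", 0]
        b = coords[np.array(labels) == "B", 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_asymmetric_fatal(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(d)


def test_bottlenecked_herd_mean_pihat_exceeds_outbred(demo_dataset):
    """Directionally, a herd descended from 3 founders with sib matings has
    far higher mean pairwise Pi-Hat than an outbred 12-founder herd."""
    g, variants, samples, truth = demo_dataset
    pairs, _ = pairwise_relatedness(g, list(samples["sample_id"]))
    sub = samples.set_index("sample_id")["subpopulation"]
    in_ids = set(sub[sub == "HERD-IN"].index)
    out_ids = set(sub[sub == "HERD-OUT"].index)
    mean_in = pairs[pairs.id1.isin(in_ids) & pairs.id2.isin(in_ids)]["pi_hat"].mean()
    mean_out = pairs[pairs.id1.isin(out_ids) & pairs.id2.isin(out_ids)]["pi_hat"].mean()
    assert mean_in > mean_out


def test_pair_matrix_layout():
    pairs = pd.DataFrame(
        {"id1": ["m1", "m1", "m2", "m2"], "id2": ["f1", "f2", "f1", "f2"],
         "pi_hat": [0.5, 0.1, 0.0, 0.25]}
    )
    mat = pair_matrix(pairs, ["m1", "m2"], ["f1", "f2"])
    assert mat.loc["m1", "f1"] == pytest.approx(50.0)
    assert mat.loc["m2", "f2"] == pytest.approx(25.0)
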