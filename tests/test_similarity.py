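"""IBS/IBG/NSG measures, HWE expectations, IBD, exclusion power and MDS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildkin import (
    SimilarityError,
    classical_mds,
    exclusion_probability,
    exclusion_survival,
    expected_similarity,
    flag_outliers,
    ibs_distance_matrix,
    mom_ibd,
    nsg_snp_count,
    pairwise_similarity,
)

from conftest import hwe_matrix, make_matrix


def enumerate_expected(p, f=0.0):
    """Independent oracle: exhaust the 3x3 genotype-pair table at one SNP."""
    q = 1.0 - p
    geno_p = {2: p**2 + f * p * q, 1: 2 * p * q * (1 - f), 0: q**2 + f * p * q}
    share = {(2, 2): 1, (1, 1): 1, (0, 0): 1, (2, 1): 0.5, (1, 2): 0.5,
             (0, 1): 0.5, (1, 0): 0.5, (2, 0): 0.0, (0, 2): 0.0}
    ibs = ibg = nsg = 0.0
    for a, b in itertools.product((0, 1, 2), repeat=2):
        w = geno_p[a] * geno_p[b]
        ibs += w * share[(a, b)]
        ibg += w * (a == b)
        nsg += w * ((a, b) in ((2, 0), (0, 2)))
    return ibs, ibg, nsg


class TestPairwiseSimilarity:
    def test_identical_vectors(self):
        G = make_matrix([[0, 1, 2, 1], [0, 1, 2, 1]])
        row = pairwise_similarity(G).iloc[0]
        assert (row.ibs, row.ibg, row.nsg) == (1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "codes, expected",
        [
            ([[2], [0]], (0.0, 0.0, 1.0)),  # opposing homozygotes
            ([[2], [1]], (0.5, 0.0, 0.0)),  # one shared allele
            ([[1], [1]], (1.0, 1.0, 0.0)),  # both heterozygous
        ],
    )
    def test_single_snp_scores(self, codes, expected):
        row = pairwise_similarity(make_matrix(codes)).iloc[0]
        assert (row.ibs, row.ibg, row.nsg) == expected

    def test_needs_two_samples(self):
        with pytest.raises(SimilarityError):
            pairwise_similarity(make_matrix([[0, 1]]))

    def test_ibs_identity_and_bounds(self, rng):
        # IBS = IBG + (het-vs-hom fraction)/2 exactly; NSG <= 1 - IBG
        G = hwe_matrix(12, rng.uniform(0.1, 0.9, 300), rng, f=0.2)
        sim = pairwise_similarity(G)
        het_hom = 1.0 - sim.ibg - sim.nsg
        np.testing.assert_allclose(sim.ibs, sim.ibg + 0.5 * het_hom, atol=1e-12)
        assert (sim.ibg <= sim.ibs + 1e-12).all()
        assert (sim.nsg <= 1 - sim.ibg + 1e-12).all()


class TestExpectedSimilarity:
    def test_half_frequency_values(self):
        e = expected_similarity(0.5)
        assert e.ibs_e == pytest.approx(0.625)
        assert e.ibg_e == pytest.approx(0.375)
        assert e.nsg_e == pytest.approx(0.125)

    def test_matches_enumeration_oracle(self):
        for p in np.arange(0.05, 0.96, 0.05):
            ibs, ibg, nsg = enumerate_expected(p)
            e = expected_similarity(p)
            assert e.ibs_e == pytest.approx(ibs, abs=1e-12)
            assert e.ibg_e == pytest.approx(ibg, abs=1e-12)
            assert e.nsg_e == pytest.approx(nsg, abs=1e-12)
            for f in (0.09, 0.2, 1.0):
                _, _, nsg_f = enumerate_expected(p, f)
                assert expected_similarity(p, f).nsg_ef == pytest.approx(nsg_f, abs=1e-12)

    def test_no_inbreeding_reduces_to_hwe(self):
        for p in (0.1, 0.5, 0.9):
            e = expected_similarity(p, 0.0)
            assert e.nsg_ef == pytest.approx(e.nsg_e)

    def test_full_inbreeding_at_half(self):
        assert expected_similarity(0.5, 1.0).nsg_ef == pytest.approx(0.5)

    def test_out_of_range_raises(self):
        with pytest.raises(SimilarityError):
            expected_similarity(0.0)
        with pytest.raises(SimilarityError):
            expected_similarity(0.5, 1.5)

    @given(
        st.floats(0.01, 0.99), st.floats(0.0, 0.99), st.floats(0.0, 0.99)
    )
    @settings(max_examples=100, deadline=None)
    def test_nsg_increases_with_inbreeding(self, p, f1, f2):
        lo, hi = sorted((f1, f2))
        if hi - lo < 1e-9:
            return
        assert (
            expected_similarity(p, hi).nsg_ef > expected_similarity(p, lo).nsg_ef - 1e-15
        )

    def test_observed_matches_expectation_for_unrelated(self, rng):
        # mean observed IBS/IBG/NSG over unrelated HWE pairs matches the
        # mean of the per-SNP expectations within 3 SEs
        p = rng.uniform(0.1, 0.9, 4000)
        G = hwe_matrix(40, p, rng)
        sim = pairwise_similarity(G)
        for col, attr in (("ibs", "ibs_e"), ("ibg", "ibg_e"), ("nsg", "nsg_e")):
            exp = np.mean([getattr(expected_similarity(pi), attr) for pi in p])
            se = sim[col].std(ddof=1) / np.sqrt(len(sim))
            assert abs(sim[col].mean() - exp) < 3 * max(se, 1e-4)


class TestMomIbd:
    def test_duplicate_individual(self, rng):
        G = hwe_matrix(6, rng.uniform(0.2, 0.8, 500), rng)
        G.codes[1] = G.codes[0]
        p = np.clip(G.codes.mean(axis=0) / 2.0, 0.01, 0.99)
        row = mom_ibd(G, p).set_index(["id1", "id2"]).loc[("S1", "S2")]
        assert row.z2 == pytest.approx(1.0)
        assert row.pi_hat == pytest.approx(1.0)

    def test_unrelated_pairs_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 10_000)
        G = hwe_matrix(10, p, rng)
        ibd = mom_ibd(G, p)
        assert abs(ibd.pi_hat.mean()) < 0.03

    def test_degenerate_snp_raises(self, rng):
        G = hwe_matrix(4, [0.5, 0.5], rng)
        with pytest.raises(SimilarityError, match="degenerate"):
            mom_ibd(G, np.array([0.5, 1.0]))

    def test_states_sum_to_one(self, rng):
        G = hwe_matrix(8, rng.uniform(0.2, 0.8, 1000), rng, f=0.1)
        ibd = mom_ibd(G, np.clip(G.codes.mean(axis=0) / 2.0, 0.01, 0.99))
        np.testing.assert_allclose(ibd[["z0", "z1", "z2"]].sum(axis=1), 1.0)


class TestExclusionPower:
    def test_single_snp(self):
        assert exclusion_probability([0.017]) == pytest.approx(0.017)

    def test_two_snp_complement_product(self):
        assert exclusion_probability([0.5, 0.5]) == pytest.approx(0.75)

    def test_panel_underflow_handled_in_log_domain(self):
        # 7051 SNPs at the theoretical lower bound 0.017: survival ~ 3e-53,
        # so Q is indistinguishable from 1 in double precision
        qs = [0.017] * 7051
        surv = exclusion_survival(qs)
        assert surv == pytest.approx(0.983**7051)
        assert np.log10(surv) == pytest.approx(7051 * np.log10(0.983))
        assert exclusion_probability(qs) == 1.0

    def test_empty_raises(self):
        with pytest.raises(SimilarityError):
            exclusion_probability([])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotonicity(self, qs):
        q_all = exclusion_probability(qs)
        assert 0.0 <= q_all <= 1.0
        assert q_all >= max(qs) - 1e-12  # adding SNPs never reduces power


class TestNsgSnpCount:
    @pytest.mark.parametrize(
        "m, rate, expected", [(150_025, 0.047, 7051), (100, 0.0, 0), (10, 0.25, 2)]
    )
    def test_floor_counts(self, m, rate, expected):
        assert nsg_snp_count(m, rate) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            nsg_snp_count(-1, 0.5)
        with pytest.raises(ValueError):
            nsg_snp_count(10, 1.5)


class TestFlagOutliers:
    def test_duplicate_pair_flagged_null_cohort_mostly_clean(self, rng):
        p = rng.uniform(0.1, 0.9, 5000)
        G = hwe_matrix(50, p, rng)
        G.codes[1] = G.codes[0]  # near-duplicate sample
        sim = pairwise_similarity(G)
        flagged = flag_outliers(sim, p)
        assert {("S1", "S2")} <= set(zip(flagged.id1, flagged.id2))
        # a clean unrelated cohort yields zero or near-zero flags
        G2 = hwe_matrix(50, p, rng)
        flagged2 = flag_outliers(pairwise_similarity(G2), p)
        assert len(flagged2) <= 0.01 * (50 * 49 // 2)

    def test_values_exactly_at_expectation_not_flagged(self, rng):
        import pandas as pd

        p = rng.uniform(0.2, 0.8, 2000)
        e = {m: np.mean([getattr(expected_similarity(pi), m + "_e") for pi in p])
             for m in ("ibs", "ibg", "nsg")}
        jitter = rng.normal(0, 1e-4, 10)  # tiny spread so the SD is defined
        obs = pd.DataFrame(
            {"id1": [f"a{i}" for i in range(10)], "id2": [f"b{i}" for i in range(10)],
             "ibs": e["ibs"] + jitter, "ibg": e["ibg"] + jitter, "nsg": e["nsg"] + jitter}
        )
        assert len(flag_outliers(obs, p)) == 0


class TestClassicalMds:
    def test_zero_distances_give_zero_coordinates(self):
        np.testing.assert_allclose(classical_mds(np.zeros((4, 4)), 2), 0.0)

    def test_collinear_points_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        d = np.abs(x[:, None] - x[None, :])
        coords = classical_mds(d, 1)
        rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(rec, d, atol=1e-10)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = classical_mds(d, 2)
        rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-10)

    def test_matches_pcoa_oracle(self, rng):
        # independent implementation check against scikit-bio's PCoA
        from skbio.stats.ordination import pcoa

        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = classical_mds(d, 3)
        ref = pcoa(d, number_of_dimensions=3).samples.values
        for axis in range(3):
            r = np.corrcoef(ours[:, axis], ref[:, axis])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_sign_convention_deterministic(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c1 = classical_mds(d, 2)
        c2 = classical_mds(d.copy(), 2)
        np.testing.assert_array_equal(c1, c2)
        for axis in range(2):
            nz = np.flatnonzero(np.abs(c1[:, axis]) > 1e-12)
            assert c1[nz[0], axis] > 0

    def test_asymmetric_raises(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(SimilarityError):
            classical_mds(d, 1)


def test_ibs_distance_matrix_consistent(rng):
    G = hwe_matrix(6, rng.uniform(0.2, 0.8, 200), rng)
    d = ibs_distance_matrix(G)
    sim = pairwise_similarity(G).set_index(["id1", "id2"])
    assert d.loc["S1", "S2"] == pytest.approx(1 - sim.loc[("S1", "S2")].ibs)
    assert np.allclose(d.values, d.values.T)
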