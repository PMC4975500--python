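"""Genomic relationship matrices: definitions, coefficients, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildkin import (
    RelationshipError,
    RelationshipMatrix,
    additive_matrix,
    coancestry_from_offdiagonal,
    dominance_matrix,
    inbreeding_from_diagonal,
    mean_coancestry,
)

from conftest import hwe_matrix, make_matrix


class TestAdditiveDefinitions:
    def test_single_snp_homozygote_diagonal(self):
        # one SNP at p=0.5: a 2-coded individual has z=1, A_jj = 1/(2pq) = 2
        G = make_matrix([[2], [0]])
        A = additive_matrix(G, np.array([0.5]), "IV")
        assert A.values[0, 0] == pytest.approx(2.0)
        assert inbreeding_from_diagonal(A)["S1"] == pytest.approx(1.0)

    def test_single_snp_opposite_offdiagonal(self):
        G = make_matrix([[2], [0]])
        A = additive_matrix(G, np.array([0.5]), "IV")
        assert A.values[0, 1] == pytest.approx(-2.0)
        fjk = coancestry_from_offdiagonal(A)
        assert fjk.f_jk[0] == pytest.approx(-1.0)

    def test_definition_I_equals_IV_at_common_frequency(self, rng):
        # algebraic identity: with one shared p the two standardizations agree
        G = hwe_matrix(12, [0.3] * 40, rng)
        p = np.full(40, 0.3)
        a1 = additive_matrix(G, p, "I").values
        a4 = additive_matrix(G, p, "IV").values
        np.testing.assert_allclose(a1, a4, atol=1e-10)

    def test_definitions_highly_correlated_on_structured_cohort(self):
        # on a cohort with real structure (inbreeding, families, subpops) the
        # across- and within-SNP standardizations give near-identical matrices
        from wildkin import default_scenario, make_dataset, allele_frequencies

        G, _, _ = make_dataset(default_scenario(n_snps=4000, seed=3))
        p = allele_frequencies(G)
        keep = (p > 0) & (p < 1)
        G, p = G.take_snps(np.flatnonzero(keep)), p[keep]
        a1 = additive_matrix(G, p, "I").values
        a4 = additive_matrix(G, p, "IV").values
        iu = np.triu_indices(G.n_samples, 1)
        r = np.corrcoef(a1[iu], a4[iu])[0, 1]
        assert r > 0.99

    def test_ivb_diagonal_fully_homozygous(self):
        # all-homozygous individual scores h=1 everywhere: A_jj = 2, f = 1
        G = make_matrix([[2, 0, 2], [1, 1, 1]])
        p = np.array([0.5, 0.4, 0.6])
        A = additive_matrix(G, p, "IVb")
        assert A.values[0, 0] == pytest.approx(2.0)
        # fully heterozygous individual: h=0, term = -(1-2pq)/2pq
        expected = 1.0 + np.mean(-(1 - 2 * p * (1 - p)) / (2 * p * (1 - p)))
        assert A.values[1, 1] == pytest.approx(expected)

    def test_ivb_offdiagonal_matches_iv(self, rng):
        G = hwe_matrix(8, rng.uniform(0.2, 0.8, 100), rng)
        p = G.codes.mean(axis=0) / 2.0
        p = np.clip(p, 0.01, 0.99)
        a4 = additive_matrix(G, p, "IV").values
        ab = additive_matrix(G, p, "IVb").values
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(a4[off], ab[off], atol=1e-12)

    def test_degenerate_frequency_names_snp(self):
        G = make_matrix([[0, 1], [0, 2]])
        with pytest.raises(RelationshipError, match="chr1:1000"):
            additive_matrix(G, np.array([0.0, 0.5]), "IV")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_allele_swap_invariance(self, seed):
        # recoding x -> 2-x with p -> 1-p leaves every definition unchanged
        rng = np.random.default_rng(seed)
        G = hwe_matrix(6, rng.uniform(0.2, 0.8, 30), rng)
        p = np.clip(G.codes.mean(axis=0) / 2.0, 0.05, 0.95)
        flip = rng.random(30) < 0.5
        codes2 = np.where(flip, 2 - G.codes, G.codes).astype(np.int8)
        G2 = make_matrix(codes2)
        p2 = np.where(flip, 1 - p, p)
        for definition in ("I", "IV", "IVb"):
            np.testing.assert_allclose(
                additive_matrix(G, p, definition).values,
                additive_matrix(G2, p2, definition).values,
                atol=1e-10,
            )
        np.testing.assert_allclose(
            dominance_matrix(G, p, "IV").values,
            dominance_matrix(G2, p2, "IV").values,
            atol=1e-10,
        )


class TestDominance:
    def test_single_heterozygote_diagonal(self):
        # het at p=0.5: w = 2pq = 0.5, D_jj = w^2/(2pq)^2 = 1
        G = make_matrix([[1], [0]])
        D = dominance_matrix(G, np.array([0.5]), "IV")
        assert D.values[0, 0] == pytest.approx(1.0)

    def test_coding_zero_mean_under_hwe(self):
        # q^2*(-2p^2) + 2pq*(2pq) + p^2*(-2q^2) = 0 for any p
        for p in (0.1, 0.37, 0.5, 0.8):
            q = 1 - p
            mean_w = q**2 * (-2 * p**2) + 2 * p * q * (2 * p * q) + p**2 * (-2 * q**2)
            assert mean_w == pytest.approx(0.0, abs=1e-15)

    def test_mean_f_and_coancestry_null_under_hwe(self, rng):
        # frequencies used for both simulation and standardization:
        # mean f and mean off-diagonal coancestry are 0 within 3 SEs
        n, m = 100, 10_000
        p = rng.uniform(0.1, 0.9, m)
        G = hwe_matrix(n, p, rng)
        A = additive_matrix(G, p, "IV")
        f = inbreeding_from_diagonal(A)
        se_f = f.std(ddof=1) / np.sqrt(n)
        assert abs(f.mean()) < 3 * max(se_f, 1e-3)
        iu = np.triu_indices(n, 1)
        fjk = 0.5 * A.values[iu]
        assert abs(fjk.mean()) < 3 * max(fjk.std(ddof=1) / np.sqrt(len(fjk)), 1e-3)
        D = dominance_matrix(G, p, "IV")
        djk = D.values[iu]
        assert abs(djk.mean()) < 3 * max(djk.std(ddof=1) / np.sqrt(len(djk)), 1e-3)

    def test_ivb_request_falls_back_to_iv(self, rng):
        G = hwe_matrix(5, [0.4] * 20, rng)
        p = np.full(20, 0.4)
        np.testing.assert_array_equal(
            dominance_matrix(G, p, "IVb").values, dominance_matrix(G, p, "IV").values
        )


class TestCoefficients:
    @pytest.mark.parametrize("diag, f", [(1.0, 0.0), (2.0, 1.0), (1.201, 0.201)])
    def test_inbreeding_is_diagonal_minus_one(self, diag, f):
        A = RelationshipMatrix("additive", "IV", np.array([[diag]]), ["S1"])
        assert inbreeding_from_diagonal(A)["S1"] == pytest.approx(f)

    @pytest.mark.parametrize("ajk, fjk", [(0.5, 0.25), (0.776, 0.388), (-0.02, -0.01)])
    def test_coancestry_is_half_offdiagonal(self, ajk, fjk):
        vals = np.array([[1.0, ajk], [ajk, 1.0]])
        A = RelationshipMatrix("additive", "IV", vals, ["a", "b"])
        assert coancestry_from_offdiagonal(A).f_jk[0] == pytest.approx(fjk)

    def test_kind_mismatch_raises(self):
        D = RelationshipMatrix("dominance", "IV", np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(RelationshipError):
            inbreeding_from_diagonal(D)
        with pytest.raises(RelationshipError):
            coancestry_from_offdiagonal(D)

    @pytest.mark.parametrize(
        "values, expected",
        [([0.190], 0.190), ([0.1, 0.2, 0.3], 0.2), ([-0.05, 0.05], 0.0)],
    )
    def test_mean_coancestry(self, values, expected):
        assert mean_coancestry(values) == pytest.approx(expected)

    def test_mean_coancestry_empty_raises(self):
        with pytest.raises(ValueError):
            mean_coancestry([])


def test_matrix_io_round_trip(tmp_path, rng):
    G = hwe_matrix(6, rng.uniform(0.2, 0.8, 50), rng)
    p = np.clip(G.codes.mean(axis=0) / 2.0, 0.05, 0.95)
    A = additive_matrix(G, p, "IV")
    path = tmp_path / "grm.tsv"
    A.write_tsv(path)
    back = pd.read_csv(path, sep="\t", index_col=0)
    np.testing.assert_allclose(back.values, A.values, atol=1e-9)
    A.write_grm_text(tmp_path / "grm.txt")
    lines = (tmp_path / "grm.txt").read_text().strip().splitlines()
    assert len(lines) == 6 * 7 // 2
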