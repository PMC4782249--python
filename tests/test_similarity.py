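"""Symmetric KL divergence, KLS kernel, matrix assembly, homotopic
contrast, and intersession matrix correlation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphnet import density, similarity, synthetic
from morphnet.errors import GridAlignmentError
from morphnet.similarity import SimilarityMatrix
from morphnet.synthetic import SyntheticCohortSpec


def random_pmf(rng, n=16):
    p = rng.random(n) + 1e-3
    return p / p.sum()


class TestKLSymmetric:
    def test_two_point_oracle(self):
        """Hand-computed two-term sum: D((.5,.5),(.75,.25)) ~ 0.2747."""
        d = similarity.kl_symmetric(np.array([0.5, 0.5]), np.array([0.75, 0.25]))
        expected = (
            0.5 * np.log(0.5 / 0.75) + 0.5 * np.log(0.5 / 0.25)
            + 0.75 * np.log(0.75 / 0.5) + 0.25 * np.log(0.25 / 0.5)
        )
        assert np.isclose(d, expected, atol=1e-12)
        assert np.isclose(d, 0.2747, atol=5e-5)

    def test_identity_of_indiscernibles(self, rng):
        p = random_pmf(rng)
        assert similarity.kl_symmetric(p, p) == 0.0

    @given(seed=st.integers(0, 100_000))
    def test_symmetry_and_nonnegativity(self, seed):
        g = np.random.default_rng(seed)
        p, q = random_pmf(g), random_pmf(g)
        d_pq = similarity.kl_symmetric(p, q)
        assert d_pq >= 0
        assert np.isclose(d_pq, similarity.kl_symmetric(q, p), atol=1e-12)

    @given(seed=st.integers(0, 100_000))
    def test_equals_sum_of_directed_divergences(self, seed):
        """D(P,Q) must equal D_KL(P||Q) + D_KL(Q||P) computed term by term."""
        g = np.random.default_rng(seed)
        p, q = random_pmf(g), random_pmf(g)
        directed = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
        assert np.isclose(similarity.kl_symmetric(p, q), directed, atol=1e-9)

    def test_mismatched_grids_rejected(self, rng):
        v = rng.normal(0.5, 0.1, 200)
        a = density.estimate_pmf(v, support=(0.0, 1.0))
        b = density.estimate_pmf(v, support=(0.0, 1.1))
        with pytest.raises(GridAlignmentError):
            similarity.kl_symmetric(a, b)


class TestKLS:
    def test_identical_distributions_give_one(self, rng):
        v = rng.normal(0.5, 0.1, 300)
        d = density.estimate_pmf(v, n_grid=128)
        assert abs(similarity.kls(d, d) - 1.0) < 1e-9

    def test_exponential_of_divergence(self):
        s = similarity.kls(np.array([0.5, 0.5]), np.array([0.75, 0.25]))
        assert np.isclose(s, np.exp(-0.2746530721670274), atol=1e-9)
        assert np.isclose(s, 0.7598, atol=5e-5)

    def test_monotone_in_separation(self, rng):
        """KLS strictly decreases as two Gaussian families are pulled apart."""
        base = rng.normal(0.0, 0.1, 2000)
        prev = 1.1
        for delta in (0.05, 0.1, 0.2, 0.4):
            lo = min(base.min(), (base + delta).min()) - 0.3
            hi = max(base.max(), (base + delta).max()) + 0.3
            p = density.estimate_pmf(base, support=(lo, hi))
            q = density.estimate_pmf(base + delta, support=(lo, hi))
            s = similarity.kls(p, q)
            assert s < prev
            prev = s


class TestBuildSimilarityMatrix:
    def test_contract_on_synthetic_cohort(self, small_matrices):
        m = next(iter(small_matrices.values()))
        assert m.kls.shape == (10, 10)
        assert np.array_equal(m.kls, m.kls.T)
        assert np.all(np.diag(m.kls) == 0)
        off = m.upper_values()
        assert np.all((off > 0) & (off <= 1))

    def test_identical_regions_reach_unit_similarity(self, rng):
        values = rng.normal(0.5, 0.08, 400)
        m = similarity.similarity_matrix_from_values({1: values, 2: values.copy()})
        assert abs(m.kls[0, 1] - 1.0) < 1e-9

    def test_invariant_to_region_relabeling(self, rng):
        vals = {r: rng.normal(0.3 + 0.1 * r, 0.05, 200) for r in range(1, 5)}
        m1 = similarity.similarity_matrix_from_values(vals)
        relabeled = {10 - r: v for r, v in vals.items()}  # 9,8,7,6 <- 1,2,3,4
        m2 = similarity.similarity_matrix_from_values(relabeled)
        # region r becomes 10-r, so ordering reverses
        assert np.allclose(m1.kls, m2.kls[::-1, ::-1], atol=1e-12)

    def test_within_family_exceeds_between_family(self, small_cohort, small_matrices):
        spec, atlas, _ = small_cohort
        fa = spec.resolved_family_assignment()
        m = next(iter(small_matrices.values()))
        iu = np.triu_indices(m.n_regions, k=1)
        same = np.array(
            [fa[m.region_ids[i]] == fa[m.region_ids[j]] for i, j in zip(*iu)]
        )
        v = m.upper_values()
        assert np.median(v[same]) > np.median(v[~same])

    def test_global_policy_matches_shape_contract(self, rng):
        vals = {r: rng.normal(0.3 + 0.1 * r, 0.05, 150) for r in range(1, 4)}
        m = similarity.similarity_matrix_from_values(vals, common_support_policy="global")
        assert m.kls.shape == (3, 3)
        assert np.all(m.upper_values() > 0)


@pytest.fixture(scope="module")
def mirrored():
    spec = SyntheticCohortSpec(
        n_regions=12,
        n_subjects=1,
        n_sessions=1,
        image_shape=(48, 32, 32),
        parcel_edge=5,
        homotopic_pairs=tuple((i, i + 6) for i in range(1, 7)),
        seed=11,
    )
    atlas = synthetic.generate_atlas(spec)
    cohort = synthetic.generate_cohort(spec, atlas)
    m = similarity.build_similarity_matrix(cohort[("sub01", "ses1")], atlas)
    return atlas, m


class TestHomotopicContrast:
    def test_mirrored_pairs_are_more_similar(self, mirrored):
        atlas, m = mirrored
        res = similarity.homotopic_contrast(m, atlas, n_perm=2000, seed=0)
        assert res["mean_homotopic"] > res["mean_other"]
        assert res["p"] < 0.05

    def test_flat_matrix_gives_null_result(self):
        n = 8
        kls_mat = np.full((n, n), 0.5)
        np.fill_diagonal(kls_mat, 0.0)
        m = SimilarityMatrix(kls=kls_mat, region_ids=list(range(1, n + 1)))
        spec = SyntheticCohortSpec(
            n_regions=8, image_shape=(30, 24, 24), homotopic_pairs=((1, 2), (3, 4))
        )
        atlas = synthetic.generate_atlas(spec)
        res = similarity.homotopic_contrast(m, atlas, n_perm=200, seed=0)
        assert res["statistic"] == 0.0
        assert res["p"] == 1.0

    def test_single_pair_smallest_input(self, rng):
        k = rng.random((3, 3)) * 0.5 + 0.25
        k = (k + k.T) / 2
        np.fill_diagonal(k, 0.0)
        m = SimilarityMatrix(kls=k, region_ids=[1, 2, 3])
        spec = SyntheticCohortSpec(
            n_regions=3, image_shape=(20, 20, 20), homotopic_pairs=((1, 2),)
        )
        atlas = synthetic.generate_atlas(spec)
        res = similarity.homotopic_contrast(m, atlas, n_perm=100, seed=0)
        assert np.isfinite(res["statistic"])


class TestMatrixCorrelation:
    def _matrix(self, values, ids):
        return SimilarityMatrix(kls=values, region_ids=ids)

    def test_self_correlation_is_one(self, small_matrices):
        m = next(iter(small_matrices.values()))
        assert np.isclose(similarity.matrix_correlation(m, m), 1.0)

    def test_permuted_entries_decorrelate(self, rng):
        n = 40
        iu = np.triu_indices(n, k=1)
        vals = rng.random(iu[0].size) * 0.8 + 0.1
        a = np.zeros((n, n))
        a[iu] = vals
        a = a + a.T
        b = np.zeros((n, n))
        b[iu] = rng.permutation(vals)
        b = b + b.T
        ma = self._matrix(a, list(range(n)))
        mb = self._matrix(b, list(range(n)))
        assert abs(similarity.matrix_correlation(ma, mb)) < 0.15

    def test_anti_ordered_entries_give_minus_one(self):
        n = 5
        iu = np.triu_indices(n, k=1)
        vals = np.linspace(0.1, 0.9, iu[0].size)
        a = np.zeros((n, n))
        a[iu] = vals
        a = a + a.T
        b = np.zeros((n, n))
        b[iu] = 1.0 - vals
        b = b + b.T
        ma = self._matrix(a, list(range(n)))
        mb = self._matrix(b, list(range(n)))
        assert np.isclose(similarity.matrix_correlation(ma, mb), -1.0)

    def test_dimension_mismatch_rejected(self):
        ka = np.full((3, 3), 0.5)
        np.fill_diagonal(ka, 0)
        a = self._matrix(ka, [1, 2, 3])
        kb = np.full((4, 4), 0.5)
        np.fill_diagonal(kb, 0)
        b = self._matrix(kb, [1, 2, 3, 4])
        with pytest.raises(ValueError):
            similarity.matrix_correlation(a, b)
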