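import itertools

import numpy as np
import pytest

from conftest import random_marker_matrix
from provzone import amova
from provzone.datasets import REFERENCE_AMOVA, load_reference_summary
from provzone.io import MarkerMatrix, ValidationError


def centroid_amova(bands: np.ndarray, labels: list[str]):
    """Independent oracle: deviation-from-centroid sums of squares in marker space.

    For squared Euclidean distances, SS_total = sum ||x_i - x_bar||^2 and
    SS_within = sum_k sum_{i in k} ||x_i - x_bar_k||^2; identical quantities to
    the pairwise-distance formulation but computed by a different route.
    """
    x = bands.astype(float)
    labels = np.asarray(labels)
    ss_total = ((x - x.mean(axis=0)) ** 2).sum()
    ss_within = 0.0
    sizes = []
    for pop in np.unique(labels):
        sub = x[labels == pop]
        sizes.append(len(sub))
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    k, n = len(sizes), len(labels)
    sizes = np.asarray(sizes, float)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    ms_w = ss_within / (n - k)
    ms_a = (ss_total - ss_within) / (k - 1)
    s2a = (ms_a - ms_w) / n0
    return ss_total, ss_within, s2a, ms_w, s2a / (s2a + ms_w)


class TestBinaryDistance:
    def test_identical_and_complementary(self):
        a = np.array([1, 0, 1, 0, 1])
        assert amova.binary_squared_distance(a, a) == 0
        assert amova.binary_squared_distance(a, 1 - a) == 5

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        expected = sum(int(x != y) for x, y in zip(a, b))
        assert amova.binary_squared_distance(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            amova.binary_squared_distance(np.array([1, 0]), np.array([1]))


class TestDecomposition:
    def test_published_worked_example(self):
        """Variance components recovered from the published AMOVA sums of squares."""
        sizes = load_reference_summary()["n"]
        res = amova.components_from_sums(
            REFERENCE_AMOVA["ss_among"], REFERENCE_AMOVA["ss_within"],
            REFERENCE_AMOVA["df_among"], REFERENCE_AMOVA["df_within"], sizes,
        )
        assert res.n0 == pytest.approx(32.354, abs=5e-4)
        assert res.sigma2_within == pytest.approx(16.38, abs=5e-3)
        assert res.sigma2_among == pytest.approx(4.80, abs=5e-3)
        assert res.phi_pt == pytest.approx(0.23, abs=5e-3)
        assert res.pct_among == pytest.approx(22.66, abs=5e-3)

    def test_identical_populations_phi_zero(self):
        bands = np.tile([[1, 0, 1, 0], [0, 1, 0, 1]], (4, 1)).astype(np.int8)
        m = MarkerMatrix([f"i{k}" for k in range(8)], ["A"] * 4 + ["B"] * 4,
                         [f"L{j}" for j in range(4)], bands)
        res = amova.amova_decompose(amova.squared_distance_matrix(m), m.population_labels)
        assert res.ss_among == pytest.approx(0.0, abs=1e-9)
        assert res.phi_pt == 0.0  # truncated
        assert res.phi_pt_raw <= 0.0  # raw diagnostic preserved

    def test_matches_centroid_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_pops = rng.integers(2, 5)
            m = random_marker_matrix(rng, n_pops=n_pops,
                                     n_per=int(rng.integers(2, 6)),
                                     n_loci=int(rng.integers(3, 10)))
            res = amova.amova_decompose(amova.squared_distance_matrix(m),
                                        m.population_labels)
            ss_t, ss_w, s2a, ms_w, phi = centroid_amova(m.bands, m.population_labels)
            assert res.ss_total == pytest.approx(ss_t, abs=1e-8)
            assert res.ss_within == pytest.approx(ss_w, abs=1e-8)
            assert res.sigma2_among == pytest.approx(s2a, abs=1e-8)
            assert res.phi_pt_raw == pytest.approx(phi, abs=1e-8)

    def test_invariance_to_relabeling_and_order(self):
        rng = np.random.default_rng(5)
        m = random_marker_matrix(rng, n_pops=3, n_per=4, n_loci=8)
        res1 = amova.amova_decompose(amova.squared_distance_matrix(m), m.population_labels)
        perm = rng.permutation(m.n_individuals)
        relabel = {"P0": "X", "P1": "Y", "P2": "Z"}
        m2 = MarkerMatrix([m.individual_ids[i] for i in perm],
                          [relabel[m.population_labels[i]] for i in perm],
                          m.locus_ids, m.bands[perm])
        res2 = amova.amova_decompose(amova.squared_distance_matrix(m2), m2.population_labels)
        assert res1.phi_pt_raw == pytest.approx(res2.phi_pt_raw, abs=1e-10)

    def test_n0_equals_n_for_equal_sizes(self):
        res = amova.components_from_sums(10.0, 20.0, 2, 9, [4, 4, 4])
        assert res.n0 == pytest.approx(4.0)

    def test_singleton_population_rejected(self):
        bands = np.array([[1, 0], [0, 1], [1, 1], [1, 1], [0, 0]], dtype=np.int8)
        with pytest.raises(ValidationError):
            MarkerMatrix(list("abcde"), ["A", "A", "B", "B", "C"],
                         ["L1", "L2"], bands)


class TestPermutationTest:
    def test_reproducible_given_seed(self, ibd_dataset):
        m = ibd_dataset[0].subset_populations(["P01", "P05", "P08"])
        p1 = amova.phi_pt_test(m, n_perm=99, seed=11).p_value
        p2 = amova.phi_pt_test(m, n_perm=99, seed=11).p_value
        assert p1 == p2

    def test_perfect_differentiation_minimal_p(self):
        bands = np.vstack([np.tile([1, 1, 1, 1, 1, 1], (4, 1)),
                           np.tile([0, 0, 0, 0, 0, 0], (4, 1))]).astype(np.int8)
        m = MarkerMatrix([f"i{k}" for k in range(8)], ["A"] * 4 + ["B"] * 4,
                         [f"L{j}" for j in range(6)], bands)
        res = amova.phi_pt_test(m, n_perm=199, seed=0)
        # only label orderings reproducing the two-block partition (2/70 of them)
        # tie the observed Phi; everything else falls below
        assert res.p_value < 0.08

    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        bands = rng.integers(0, 2, (6, 5)).astype(np.int8)
        labels = ["A"] * 3 + ["B"] * 3
        m = MarkerMatrix([f"i{k}" for k in range(6)], labels, [f"L{j}" for j in range(5)], bands)
        obs = amova.phi_pt_test(m, n_perm=4999, seed=3)
        # exhaustive oracle over all 6! label orderings
        d2 = amova.squared_distance_matrix(m).values
        codes = np.array([0, 0, 0, 1, 1, 1])
        phis = []
        for perm in itertools.permutations(range(6)):
            ss_t, ss_w = amova._sums_of_squares(d2, codes[list(perm)], 2)
            r = amova.components_from_sums(ss_t - ss_w, ss_w, 1, 4, [3, 3])
            phis.append(r.phi_pt_raw)
        exact_p = np.mean(np.asarray(phis) >= obs.phi_pt_raw - 1e-12)
        assert obs.p_value == pytest.approx(exact_p, abs=0.03)


class TestPairwiseAndHelpers:
    def test_pairwise_symmetric_and_complete(self, ibd_dataset):
        m = ibd_dataset[0].subset_populations(["P01", "P04", "P08"])
        pairs = amova.pairwise_phi_pt(m, n_perm=49, seed=2)
        assert len(pairs) == 3
        assert set(zip(pairs["pop_a"], pairs["pop_b"])) == {
            ("P01", "P04"), ("P01", "P08"), ("P04", "P08")}

    def test_pair_of_identical_populations(self):
        bands = np.tile([[1, 0, 1], [0, 1, 0]], (4, 1)).astype(np.int8)
        m = MarkerMatrix([f"i{k}" for k in range(8)], ["A"] * 4 + ["B"] * 4,
                         ["L1", "L2", "L3"], bands)
        pairs = amova.pairwise_phi_pt(m, n_perm=0)
        assert pairs.loc[0, "phi_pt"] == 0.0

    @pytest.mark.parametrize("phi, expected", [(0.0, 0.0), (0.5, 1.0), (0.23, 0.2987)])
    def test_linearize(self, phi, expected):
        assert amova.linearize_phi(phi) == pytest.approx(expected, abs=5e-5)

    def test_linearize_domain(self):
        with pytest.raises(ValidationError):
            amova.linearize_phi(1.0)

    def test_subset_loci(self, toy_matrix):
        assert amova.subset_loci(toy_matrix, toy_matrix.locus_ids) == toy_matrix
        sub = amova.subset_loci(toy_matrix, ["L3", "L1"])
        assert sub.locus_ids == ["L3", "L1"]
        with pytest.raises(ValidationError):
            amova.subset_loci(toy_matrix, [])
        with pytest.raises(ValidationError):
            amova.subset_loci(toy_matrix, ["nope"])
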