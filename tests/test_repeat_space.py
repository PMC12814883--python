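"""Edit distances vs exhaustive oracle, SMACOF MDS, KDE marginals."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casarray import (
    GenomeAnnotation,
    distance_distribution,
    distance_matrix,
    edit_distance,
    kde_marginal,
    mds_embed,
)
from casarray.repeat_space import DistanceMatrix

from conftest import make_array


@lru_cache(maxsize=None)
def recursive_edit_distance(a: str, b: str) -> int:
    """Textbook exponential recursion; the independent oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        recursive_edit_distance(a[1:], b) + 1,
        recursive_edit_distance(a, b[1:]) + 1,
        recursive_edit_distance(a[1:], b[1:]) + (a[0] != b[0]),
    )


def binary_strings(max_len):
    for n in range(max_len + 1):
        for bits in itertools.product("AB", repeat=n):
            yield "".join(bits)


class TestEditDistance:
    def test_worked_examples(self):
        assert edit_distance("GTTTCCC", "GTTTCCC") == 0
        assert edit_distance("ACGT", "") == 4
        assert edit_distance("", "ACGT") == 4
        assert edit_distance("kitten", "sitting") == 3

    def test_matches_oracle_on_all_short_binary_pairs(self):
        strings = list(binary_strings(6))
        for a in strings:
            for b in strings:
                assert edit_distance(a, b) == recursive_edit_distance(a, b), (a, b)

    def test_matches_oracle_on_random_dna_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(500):
            a = "".join(rng.choice(bases, size=rng.integers(0, 9)))
            b = "".join(rng.choice(bases, size=rng.integers(0, 9)))
            assert edit_distance(a, b) == recursive_edit_distance(a, b), (a, b)

    @given(
        st.lists(st.text(alphabet="ACGT", min_size=0, max_size=12), min_size=3, max_size=3)
    )
    @settings(max_examples=300, derandomize=True)
    def test_metric_axioms(self, triple):
        a, b, c = triple
        dab, dba = edit_distance(a, b), edit_distance(b, a)
        assert dab == dba
        assert (dab == 0) == (a == b)
        assert dab <= edit_distance(a, c) + edit_distance(c, b)


class TestDistanceMatrix:
    def _arrays(self, repeats, genome_id="g"):
        return [
            make_array(f"a{i}", genome_id, 1_000 * (i + 1), 1_000 * (i + 1) + 400, r, ["s"])
            for i, r in enumerate(repeats)
        ]

    def test_identical_repeats_all_zero(self):
        dm = distance_matrix(self._arrays(["ACGTACGT"] * 3))
        assert np.all(dm.D == 0)

    def test_per_genome_max_normalization(self):
        # lengths 30 and 36, raw distance known, divided by 36
        a = "A" * 30
        b = "A" * 24 + "C" * 12  # distance: 6 subs + 6 ins = 12
        dm = distance_matrix(self._arrays([a, b]), normalization="per_genome_max")
        assert dm.D[0, 1] == pytest.approx(12 / 36)

    def test_global_max_normalization_uses_whole_scope(self):
        a = "A" * 30
        b = "A" * 24 + "C" * 12
        c = "G" * 40
        dm = distance_matrix(self._arrays([a, b, c]), normalization="global_max")
        assert dm.D[0, 1] == pytest.approx(12 / 40)

    def test_per_genome_requires_single_genome(self):
        arrays = self._arrays(["ACGT"], "g1") + self._arrays(["ACGG"], "g2")
        with pytest.raises(ValueError):
            distance_matrix(arrays, normalization="per_genome_max")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([])


class TestMdsEmbed:
    def embedded_distances(self, emb):
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(emb.coords))

    def test_equilateral_triangle_embeds_exactly(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        emb = mds_embed(D, seed=0, n_init=8, max_iter=2_000, tol=1e-14)
        assert emb.stress < 1e-6

    def test_unit_square_recovers_distances(self):
        s = np.sqrt(2)
        D = np.array(
            [[0, 1, s, 1], [1, 0, 1, s], [s, 1, 0, 1], [1, s, 1, 0]], float
        )
        emb = mds_embed(D, seed=0, n_init=8, max_iter=5_000, tol=1e-14)
        assert emb.stress < 1e-6
        np.testing.assert_allclose(self.embedded_distances(emb), D, atol=1e-3)

    def test_stress_monotone_nonincreasing(self, rng):
        D = np.abs(rng.normal(size=(12, 12)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        emb = mds_embed(D, seed=1, n_init=2, max_iter=200, tol=0.0)
        hist = np.array(emb.stress_history)
        assert np.all(np.diff(hist) <= 1e-9)
        assert hist[-1] <= hist[0]

    def test_single_point_degenerate(self):
        emb = mds_embed(np.zeros((1, 1)), seed=0)
        assert emb.stress == 0.0
        assert np.allclose(emb.coords, 0)

    def test_deterministic_given_seed(self, rng):
        D = np.abs(rng.normal(size=(8, 8)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        e1 = mds_embed(D, seed=5)
        e2 = mds_embed(D, seed=5)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_rejects_non_finite(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            mds_embed(D)

    def test_agrees_with_reference_smacof(self):
        # independent route: scikit-learn's SMACOF on the same dissimilarities
        sklearn = pytest.importorskip("sklearn.manifold")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        ours = mds_embed(D, seed=0, n_init=8, max_iter=2_000, tol=1e-12)
        _, ref_stress = sklearn.smacof(
            D, metric=True, n_components=2, n_init=8, max_iter=2_000,
            eps=1e-12, random_state=0, normalized_stress=False,
        )
        # both should essentially perfectly embed a genuinely 2-D configuration
        assert ours.stress == pytest.approx(ref_stress, abs=1e-4)


class TestKde:
    def test_density_integrates_to_one(self, rng):
        values = rng.normal(size=400)
        grid = np.linspace(-8, 8, 1_000)
        density = kde_marginal(values, grid)
        assert np.all(density >= 0)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=0.01)

    def test_well_separated_clusters_are_bimodal(self, rng):
        values = np.concatenate([rng.normal(0, 0.1, 200), rng.normal(10, 0.1, 200)])
        grid = np.linspace(-2, 12, 2_000)
        density = kde_marginal(values, grid)
        maxima = np.flatnonzero(
            (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
        )
        assert len(maxima) == 2

    def test_identical_values_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="distinct"):
            kde_marginal([1.0, 1.0, 1.0], np.linspace(0, 2, 10))


class TestDistanceDistribution:
    def test_shared_repeat_genomes_put_all_mass_at_zero(self):
        genomes = [
            GenomeAnnotation(
                genome_id=f"g{i}",
                loci=[],
                arrays=[
                    make_array(f"g{i}a{j}", f"g{i}", 1_000 * (j + 1), 1_000 * (j + 1) + 400,
                               "ACGTACGT", ["s"])
                    for j in range(3)
                ],
            )
            for i in range(4)
        ]
        strata = distance_distribution(genomes, bins=np.linspace(0, 1, 11))
        counts, edges = strata[3]
        assert counts[0] == 4 * 3  # 4 genomes x C(3,2) pairs, all distance 0
        assert counts[1:].sum() == 0

    def test_pair_count_per_genome_is_k_choose_2(self, small_cohort):
        cohort, _, _ = small_cohort
        strata = distance_distribution(cohort)
        for k, (counts, _) in strata.items():
            n_genomes_k = sum(1 for g in cohort if len(g.arrays) == k)
            assert counts.sum() == n_genomes_k * k * (k - 1) // 2

    def test_two_ancestral_repeats_give_bimodal_distances(self):
        r1 = "ACGTACGTACGTACGTACGT"
        r2 = "TTTTGGGGCCCCAAAATTTT"
        genomes = [
            GenomeAnnotation(
                genome_id=f"g{i}",
                loci=[],
                arrays=[
                    make_array(f"g{i}a0", f"g{i}", 1_000, 1_400, r1, ["s"]),
                    make_array(f"g{i}a1", f"g{i}", 3_000, 3_400, r1, ["t"]),
                    make_array(f"g{i}a2", f"g{i}", 5_000, 5_400, r2, ["u"]),
                ],
            )
            for i in range(5)
        ]
        strata = distance_distribution(genomes, bins=np.linspace(0, 1, 6))
        counts, edges = strata[3]
        assert counts[0] > 0  # same-repeat pairs at 0
        assert counts[-2:].sum() > 0  # cross-ancestral pairs far from 0
        assert counts[1] == 0  # nothing in between
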