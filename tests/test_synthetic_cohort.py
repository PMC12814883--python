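"""Generator correctness: samplers, dependence injection, determinism, truth."""

import numpy as np
import pytest

from casarray import CohortSpec, PlacementModel, generate_cohort, sample_idm_length, sample_type_presence
from casarray.synthetic_cohort import DEFAULT_TYPE_FREQS


class TestIdmLength:
    def test_zero_insertion_rate_gives_empty_arrays(self, rng):
        assert all(sample_idm_length(0.0, 1.0, rng) == 0 for _ in range(50))

    def test_invalid_deletion_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_idm_length(10.0, 0.0, rng)

    def test_stationary_mean_and_equidispersion(self, rng):
        # stationary array length is Poisson(theta/rho): mean 30, var ~ mean
        draws = np.array([sample_idm_length(30.0, 1.0, rng) for _ in range(10_000)])
        assert abs(draws.mean() - 30.0) < 3 * np.sqrt(30.0 / 10_000)
        se_var = np.sqrt((np.mean((draws - draws.mean()) ** 4) - draws.var() ** 2) / len(draws))
        assert abs(draws.var(ddof=1) - draws.mean()) < 3 * se_var


class TestTypePresence:
    def test_independent_marginal_recovered(self, rng):
        spec = CohortSpec(n_genomes=1, type_freqs={"A": 0.5}, theta_per_type={"A": 10.0})
        hits = sum("A" in sample_type_presence(spec, rng) for _ in range(10_000))
        assert abs(hits / 10_000 - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_zero_multiplier_excludes_joint_presence(self, rng):
        spec = CohortSpec(
            n_genomes=1,
            type_freqs={"A": 0.4, "B": 0.4},
            theta_per_type={"A": 10.0, "B": 10.0},
            pair_enrichment={("A", "B"): 0.0},
        )
        for _ in range(2_000):
            present = sample_type_presence(spec, rng)
            assert not ({"A", "B"} <= present)

    def test_enrichment_scales_joint_count(self, rng):
        spec = CohortSpec(
            n_genomes=1,
            type_freqs={"A": 0.05, "B": 0.05},
            theta_per_type={"A": 10.0, "B": 10.0},
            pair_enrichment={("A", "B"): 5.0},
        )
        n = 20_000
        joint = sum({"A", "B"} <= sample_type_presence(spec, rng) for _ in range(n))
        target = 5 * 0.05 * 0.05 * n  # 25
        assert abs(joint - target) < 3 * np.sqrt(target)

    def test_enrichment_preserves_marginals(self, rng):
        spec = CohortSpec(
            n_genomes=1,
            type_freqs={"A": 0.2, "B": 0.3},
            theta_per_type={"A": 10.0, "B": 10.0},
            pair_enrichment={("A", "B"): 2.0},
        )
        n = 20_000
        a = b = 0
        for _ in range(n):
            present = sample_type_presence(spec, rng)
            a += "A" in present
            b += "B" in present
        assert abs(a / n - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)
        assert abs(b / n - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_infeasible_enrichment_names_pair(self, rng):
        spec = CohortSpec(
            n_genomes=1,
            type_freqs={"A": 0.5, "B": 0.5},
            theta_per_type={"A": 10.0, "B": 10.0},
            pair_enrichment={("A", "B"): 10.0},
        )
        with pytest.raises(ValueError, match="A.*B"):
            sample_type_presence(spec, rng)


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        spec = CohortSpec(n_genomes=30, seed=7)
        c1, t1 = generate_cohort(spec)
        c2, t2 = generate_cohort(spec)
        assert [g.arrays for g in c1] == [g.arrays for g in c2]
        assert [g.loci for g in c1] == [g.loci for g in c2]
        assert t1.type_sets == t2.type_sets

    def test_truth_is_consistent_with_cohort(self, small_cohort):
        cohort, truth, _ = small_cohort
        by_genome = truth.arrays_by_genome()
        for genome in cohort:
            recs = by_genome.get(genome.genome_id, [])
            assert {r.array_id for r in recs} == {a.array_id for a in genome.arrays}
            assert truth.type_sets[genome.genome_id] == genome.cas_types

    def test_duplications_share_repeat_and_last_spacer(self):
        spec = CohortSpec(
            n_genomes=50,
            seed=5,
            duplication_prob=1.0,
            repeat_substitution_rate=0.0,
            orphan_rate=0.0,
        )
        cohort, truth = generate_cohort(spec)
        dups = [r for r in truth.arrays if r.duplicate_of is not None]
        assert dups, "duplication_prob=1 must produce duplicates"
        for genome in cohort:
            arrays = {a.array_id: a for a in genome.arrays}
            for rec in truth.arrays_by_genome().get(genome.genome_id, []):
                if rec.duplicate_of is None:
                    continue
                child = arrays[rec.array_id]
                parent = arrays[rec.duplicate_of]
                assert child.consensus_repeat == parent.consensus_repeat
                assert child.spacers[-1] == parent.spacers[-1]
                assert child.spacers == parent.spacers[-len(child.spacers):]

    def test_unbiased_close_and_far_lengths_match(self):
        # acquisition_bias = 1: both Poisson with the same mean
        spec = CohortSpec(
            n_genomes=1500,
            seed=9,
            type_freqs={"I-E": 1.0},
            theta_per_type={"I-E": 20.0},
            arrays_per_locus_dist={2: 1.0},
            placement={"I-E": PlacementModel(p_near=0.5)},
            duplication_prob=0.0,
            orphan_rate=0.0,
            acquisition_bias=1.0,
        )
        cohort, truth = generate_cohort(spec)
        lengths = {a.array_id: a.n_spacers for g in cohort for a in g.arrays}
        close = np.array([lengths[r.array_id] for r in truth.arrays if r.placed_close])
        far = np.array([lengths[r.array_id] for r in truth.arrays if not r.placed_close])
        assert len(close) + len(far) >= 5_000 * 0.5  # 3000 arrays total
        se = np.sqrt(close.var(ddof=1) / len(close) + far.var(ddof=1) / len(far))
        assert abs(close.mean() - far.mean()) < 3 * se

    def test_zero_substitution_rate_gives_type_pure_repeats(self):
        spec = CohortSpec(n_genomes=60, seed=3, repeat_substitution_rate=0.0, orphan_rate=0.0)
        cohort, truth = generate_cohort(spec)
        by_genome = {g.genome_id: g for g in cohort}
        for rec in truth.arrays:
            if rec.cas_type is None or rec.duplicate_of is not None:
                continue
            arr = next(
                a for a in by_genome[rec.genome_id].arrays if a.array_id == rec.array_id
            )
            # all non-duplicate arrays of one type share the ancestral repeat
            spec_repeat = spec.repeat_for(rec.cas_type, None)
            assert arr.consensus_repeat == spec_repeat

    def test_marginal_type_frequencies_recovered(self):
        spec = CohortSpec(n_genomes=10_000, seed=21)
        _, truth = generate_cohort(spec)
        n = spec.n_genomes
        for t, f in DEFAULT_TYPE_FREQS.items():
            hits = sum(t in s for s in truth.type_sets.values())
            assert abs(hits / n - f) < 3 * np.sqrt(f * (1 - f) / n), t
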