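"""Shared fixtures: hand-built micro-cohorts and generated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from casarray import CasLocus, CohortSpec, GenomeAnnotation, SpacerArray, generate_cohort
from casarray.pipeline import assign_cohort


def make_array(
    array_id,
    genome_id,
    start,
    end,
    repeat,
    spacers,
    orientation="forward",
    confidence="bona-fide",
    seq_id="chr",
):
    return SpacerArray(
        array_id=array_id,
        genome_id=genome_id,
        seq_id=seq_id,
        start=start,
        end=end,
        orientation=orientation,
        confidence=confidence,
        consensus_repeat=repeat,
        spacers=tuple(spacers),
    )


def make_locus(locus_id, genome_id, cas_type, start, end, seq_id="chr"):
    return CasLocus(
        locus_id=locus_id, genome_id=genome_id, seq_id=seq_id,
        cas_type=cas_type, start=start, end=end,
    )


@pytest.fixture(scope="session")
def census_fixture():
    """Five genomes with hand-countable redundancy structure.

    Hand counts (8 arrays, 4 loci):
      same-repeat co-occurrence: a1,a2 + b1,b2 + d1,d2       -> 6/8
      any spacer overlap among those: a1,a2 + d1,d2          -> 4/8
      identical spacer multisets: d1,d2                      -> 2/8
      same last spacer: a1,a2 (s3) + d1,d2 (w2)              -> 4/8
      loci with >=2 same-repeat arrays: L1, L2, L4 (not L5)  -> 3/4
      arrays per locus: L1=3, L2=2, L4=2, L5=0 (c1 orphan)
    """
    g1 = GenomeAnnotation(
        genome_id="g1",
        loci=[make_locus("L1", "g1", "I-E", 100_000, 108_000)],
        arrays=[
            make_array("a1", "g1", 108_500, 109_000, "AAAA", ["s1", "s2", "s3"]),
            make_array("a2", "g1", 98_000, 99_000, "AAAA", ["s2", "s3"]),
            make_array("a3", "g1", 300_000, 300_500, "CCCC", ["s9"]),
        ],
    )
    g2 = GenomeAnnotation(
        genome_id="g2",
        loci=[make_locus("L2", "g2", "I-F", 50_000, 58_000)],
        arrays=[
            make_array("b1", "g2", 60_000, 60_400, "GGGG", ["t1", "t2"]),
            make_array("b2", "g2", 40_000, 40_400, "GGGG", ["u1", "u2"]),
        ],
    )
    g3 = GenomeAnnotation(
        genome_id="g3",
        loci=[],
        arrays=[make_array("c1", "g3", 10_000, 10_300, "TTTT", ["v1"])],
    )
    g4 = GenomeAnnotation(
        genome_id="g4",
        loci=[make_locus("L4", "g4", "I-E", 200_000, 208_000)],
        arrays=[
            make_array("d1", "g4", 209_000, 209_400, "ACGT", ["w1", "w2"]),
            make_array("d2", "g4", 195_000, 195_400, "ACGT", ["w1", "w2"]),
        ],
    )
    g5 = GenomeAnnotation(
        genome_id="g5",
        loci=[make_locus("L5", "g5", "II-C", 400_000, 408_000)],
        arrays=[],
    )
    cohort = [g1, g2, g3, g4, g5]
    return cohort, assign_cohort(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-genome default-parameter cohort plus its truth and assignments."""
    spec = CohortSpec(n_genomes=200, seed=11)
    cohort, truth = generate_cohort(spec)
    return cohort, truth, assign_cohort(cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
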