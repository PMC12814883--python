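"""Synthetic annotation cohorts with the statistical structure the analyses assume.

The generator emulates the annotation tables produced by CRISPR detection
pipelines on large genome collections: per-genome Cas-type presence with
configurable marginal frequencies and pairwise dependence, one Cas locus per
present type, a configurable arrays-per-locus distribution, array lengths
drawn from the stationary law of the independent-deletion spacer-turnover
model (Poisson with mean theta/rho), type-specific placement and orientation
biases around the locus, type-specific ancestral consensus repeats diverged
by per-site substitution, occasional array duplications that copy the repeat
and a leader-distal spacer suffix, and orphan arrays unattached to any Cas.

Every draw comes from a single :class:`numpy.random.Generator` seeded from
``CohortSpec.seed``, so a spec reproduces its cohort bit-for-bit.  Alongside
the cohort a :class:`CohortTruth` records the realised latent variables
(type sets, per-array insertion rates, duplication lineage) for parameter
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotations_io import CasLocus, GenomeAnnotation, SpacerArray

__all__ = [
    "PlacementModel",
    "CohortSpec",
    "ArrayTruth",
    "CohortTruth",
    "sample_idm_length",
    "sample_type_presence",
    "generate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _indexed_spacer(index: int, rng: np.random.Generator, length: int = 32) -> str:
    """Random spacer with the index base-4 encoded in a prefix.

    The 8-nt prefix encodes a per-genome running index, which makes spacers
    collision-free within a genome by construction; the remaining sites are
    random so spacer content still looks sequence-like.
    """
    prefix = []
    x = index
    for _ in range(8):
        prefix.append("ACGT"[x % 4])
        x //= 4
    return "".join(prefix) + random_dna(rng, length - 8)


@dataclass(frozen=True)
class PlacementModel:
    """Where and how a type places its arrays relative to the Cas locus.

    ``p_after`` is the probability of the array landing downstream (right) of
    the locus, ``p_forward`` of forward orientation, ``p_near`` of drawing
    from the near-gap sampler.  Near gaps are exponential with the given mean
    (truncated below the close threshold, matching the observed concentration
    of close arrays under ~500 bp); far gaps are uniform on the far window.
    """

    p_after: float = 0.7
    p_forward: float = 0.8
    p_near: float = 0.8
    near_gap_mean: float = 800.0
    near_gap_max: int = 9_999
    far_gap_min: int = 100_000
    far_gap_max: int = 500_000
    p_unknown_orientation: float = 0.05

    def sample_gap(self, rng: np.random.Generator) -> tuple[int, bool]:
        if rng.random() < self.p_near:
            gap = int(min(rng.exponential(self.near_gap_mean), self.near_gap_max))
            return gap, True
        return int(rng.integers(self.far_gap_min, self.far_gap_max + 1)), False

    def sample_orientation(self, rng: np.random.Generator) -> str:
        if rng.random() < self.p_unknown_orientation:
            return "unknown"
        return "forward" if rng.random() < self.p_forward else "reverse"


# Defaults reflect the census structure of large GenBank CRISPR surveys:
# a handful of dominant types, ~1.5 arrays per locus, per-type mean array
# lengths between ~8 and ~25 spacers.
DEFAULT_TYPE_FREQS = {
    "I-E": 0.30,
    "I-F": 0.20,
    "III-A": 0.10,
    "II-C": 0.08,
    "V-A": 0.06,
    "II-A": 0.05,
}
DEFAULT_THETA = {
    "I-E": 20.0,
    "I-F": 25.0,
    "III-A": 20.0,
    "II-C": 12.0,
    "V-A": 8.0,
    "II-A": 15.0,
}
DEFAULT_ARRAYS_PER_LOCUS = {1: 0.65, 2: 0.25, 3: 0.08, 4: 0.02}  # mean 1.47

DEFAULT_ANCESTRAL_REPEATS = {
    "I-E": "GTGTTCCCCGCGCCAGCGGGGATAAACCG",
    "I-F": "GTTCACTGCCGTATAGGCAGCTAAGAAA",
    "III-A": "GATCGATACCCACCCCGAAGAAAAGGGGACGAGAAC",
    "II-C": "GTTTTAGAAGGTTGTTAGTTCCCTAAAAC",
    "V-A": "AATTTCTACTGTTGTAGAT",
    "II-A": "GTTTTAGAGCTGTGTTGTTTCGAATGGTTCCAAAAC",
}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``theta_per_type`` and ``rho`` are the insertion and deletion rates of
    the spacer-turnover model; stationary array length is Poisson(theta/rho).
    ``acquisition_bias`` multiplies theta for arrays placed close (< close
    threshold) to their locus; 1 means proximity does not affect acquisition.
    ``pair_enrichment`` maps unordered type pairs to a multiplier on the
    independent joint presence probability (1 = independent).
    """

    n_genomes: int = 1000
    type_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_FREQS))
    pair_enrichment: Mapping[tuple[str, str], float] = field(default_factory=dict)
    arrays_per_locus_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ARRAYS_PER_LOCUS)
    )
    theta_per_type: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA))
    rho: float = 1.0
    placement: Mapping[str, PlacementModel] = field(default_factory=dict)
    ancestral_repeats: Mapping[str, str] = field(default_factory=dict)
    repeat_substitution_rate: float = 0.02
    duplication_prob: float = 0.15
    orphan_rate: float = 0.10
    acquisition_bias: float = 1.0
    close_threshold_bp: int = 10_000
    genome_length: int = 4_000_000
    min_locus_spacing: int = 50_000
    locus_length: int = 8_000
    repeat_length: int = 30
    spacer_length: int = 32
    p_possible_confidence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.type_freqs:
            raise ValueError("type_freqs must name at least one Cas type")
        for t, f in self.type_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"type frequency for {t} outside [0,1]: {f}")
        if self.rho <= 0:
            raise ValueError(f"deletion rate rho must be > 0, got {self.rho}")
        for t, th in self.theta_per_type.items():
            if th <= 0:
                raise ValueError(f"insertion rate theta for {t} must be > 0, got {th}")
        total = sum(self.arrays_per_locus_dist.values())
        if not np.isclose(total, 1.0):
            raise ValueError("arrays_per_locus_dist probabilities must sum to 1")
        if any(k < 1 for k in self.arrays_per_locus_dist):
            raise ValueError("arrays_per_locus_dist is over positive integers")

    def placement_for(self, cas_type: str) -> PlacementModel:
        return self.placement.get(cas_type, PlacementModel())

    def repeat_for(self, cas_type: str, rng: np.random.Generator) -> str:
        if cas_type in self.ancestral_repeats:
            return self.ancestral_repeats[cas_type]
        if cas_type in DEFAULT_ANCESTRAL_REPEATS:
            return DEFAULT_ANCESTRAL_REPEATS[cas_type]
        # unseen type: derive a reproducible ancestral repeat from the type name
        sub = np.random.default_rng(abs(hash(cas_type)) % 2**31)
        return random_dna(sub, self.repeat_length)

    def theta_for(self, cas_type: str) -> float:
        if cas_type in self.theta_per_type:
            return self.theta_per_type[cas_type]
        return float(np.mean(list(self.theta_per_type.values() or [15.0])))


@dataclass(frozen=True)
class ArrayTruth:
    array_id: str
    genome_id: str
    cas_type: str | None  # None for orphan arrays
    theta: float
    source_locus: str | None
    duplicate_of: str | None  # parent array_id if this is a duplication copy
    placed_close: bool
    resampled_zero_length: bool


@dataclass
class CohortTruth:
    """Realised latent state of a generated cohort."""

    type_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    arrays: list[ArrayTruth] = field(default_factory=list)

    def arrays_by_genome(self) -> dict[str, list[ArrayTruth]]:
        out: dict[str, list[ArrayTruth]] = {}
        for rec in self.arrays:
            out.setdefault(rec.genome_id, []).append(rec)
        return out


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def sample_idm_length(theta: float, rho: float, rng: np.random.Generator) -> int:
    """One stationary array length of the independent-deletion model.

    With insertion rate ``theta`` and per-spacer deletion rate ``rho`` the
    stationary number of spacers is Poisson distributed with mean theta/rho.
    """
    if rho <= 0:
        raise ValueError(f"deletion rate rho must be > 0, got {rho}")
    if theta < 0:
        raise ValueError(f"insertion rate theta must be >= 0, got {theta}")
    return int(rng.poisson(theta / rho))


def _pair_joint_probability(fa: float, fb: float, multiplier: float, pair) -> float:
    target = multiplier * fa * fb
    lower = max(0.0, fa + fb - 1.0)
    if target > min(fa, fb) + 1e-12:
        raise ValueError(
            f"infeasible enrichment for pair {pair}: joint probability "
            f"{target:.6g} exceeds min marginal {min(fa, fb):.6g}"
        )
    return max(target, lower)


def sample_type_presence(spec: CohortSpec, rng: np.random.Generator) -> frozenset[str]:
    """Sample the set of Cas types present in one genome.

    With all enrichment multipliers at 1 every type is an independent
    Bernoulli draw at its marginal frequency.  A multiplier ``m`` on (A, B)
    moves the joint presence probability to ``m * f_A * f_B`` (clipped to the
    Frechet-feasible range) while preserving both marginals, by sampling A
    first and B conditionally.  Types involved in several enriched pairs are
    handled sequentially pair by pair.
    """
    freqs = dict(spec.type_freqs)
    enriched: dict[frozenset[str], float] = {}
    for (a, b), m in spec.pair_enrichment.items():
        if m == 1.0:
            continue
        if a not in freqs or b not in freqs:
            raise ValueError(f"enrichment names unknown type in pair ({a}, {b})")
        enriched[frozenset((a, b))] = m

    present: dict[str, bool] = {}
    # deterministic iteration order
    for pair in sorted(enriched, key=sorted):
        a, b = sorted(pair)
        m = enriched[pair]
        fa, fb = freqs[a], freqs[b]
        p_ab = _pair_joint_probability(fa, fb, m, (a, b))
        if a not in present:
            present[a] = rng.random() < fa
        if b not in present:
            if present[a]:
                p_b = p_ab / fa if fa > 0 else 0.0
            else:
                p_b = (fb - p_ab) / (1.0 - fa) if fa < 1 else fb
            present[b] = rng.random() < min(max(p_b, 0.0), 1.0)
    for t in sorted(freqs):
        if t not in present:
            present[t] = rng.random() < freqs[t]
    return frozenset(t for t, on in present.items() if on)


def _sample_arrays_per_locus(spec: CohortSpec, rng: np.random.Generator) -> int:
    counts = sorted(spec.arrays_per_locus_dist)
    probs = np.array([spec.arrays_per_locus_dist[c] for c in counts], dtype=float)
    return int(rng.choice(counts, p=probs / probs.sum()))


def _mutate_repeat(repeat: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return repeat
    chars = list(repeat)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

class _IntervalRegistry:
    """Tracks occupied genomic intervals to avoid overlapping placements."""

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int]] = []

    def collides(self, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in self.intervals)

    def add(self, start: int, end: int) -> None:
        self.intervals.append((start, end))


def _place_array(
    locus: CasLocus,
    gap: int,
    near: bool,
    placement: PlacementModel,
    length_bp: int,
    side_after: bool,
    registry: _IntervalRegistry,
    genome_length: int,
    rng: np.random.Generator,
    retries: int = 100,
) -> tuple[int, int]:
    """Place an array at ``gap`` bp from the locus; on collision redraw the
    gap within the same near/far window so the close/far truth label holds."""
    for attempt in range(retries):
        if attempt == 0:
            g = gap
        elif near:
            g = int(rng.integers(0, placement.near_gap_max + 1))
        else:
            g = int(rng.integers(placement.far_gap_min, placement.far_gap_max + 1))
        if side_after:
            start = locus.end + g
        else:
            start = locus.start - g - length_bp
        end = start + length_bp
        if start < 0 or end > genome_length:
            side_after = not side_after
            continue
        if not registry.collides(start, end):
            registry.add(start, end)
            return start, end
    raise RuntimeError(
        f"could not place array near locus {locus.locus_id} after {retries} retries"
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[GenomeAnnotation], CohortTruth]:
    """Generate a cohort and its ground truth. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cohort: list[GenomeAnnotation] = []
    truth = CohortTruth()

    width = max(5, len(str(spec.n_genomes)))
    for g in range(spec.n_genomes):
        genome_id = f"G{g:0{width}d}"
        types = sample_type_presence(spec, rng)
        truth.type_sets[genome_id] = types

        registry = _IntervalRegistry()
        loci: list[CasLocus] = []
        # one locus per present type, spaced across the genome
        for t in sorted(types):
            for _ in range(100):
                start = int(rng.integers(0, spec.genome_length - spec.locus_length))
                lo = start - spec.min_locus_spacing
                hi = start + spec.locus_length + spec.min_locus_spacing
                if not any(lo < e and s < hi for s, e in registry.intervals):
                    break
            else:
                raise RuntimeError(f"could not place locus for type {t} in {genome_id}")
            end = start + spec.locus_length
            registry.add(start, end)
            loci.append(
                CasLocus(
                    locus_id=f"{genome_id}_L{len(loci)}",
                    genome_id=genome_id,
                    cas_type=t,
                    start=start,
                    end=end,
                )
            )

        arrays: list[SpacerArray] = []
        genome_truth: list[ArrayTruth] = []
        spacer_counter = 0

        def new_spacers(n: int) -> tuple[str, ...]:
            nonlocal spacer_counter
            out = tuple(
                _indexed_spacer(spacer_counter + i, rng, spec.spacer_length) for i in range(n)
            )
            spacer_counter += n
            return out

        def make_array(
            cas_type: str | None,
            locus: CasLocus | None,
            repeat: str,
            spacers: tuple[str, ...],
            start: int,
            end: int,
            placed_close: bool,
            theta: float,
            duplicate_of: str | None,
            resampled: bool,
        ) -> None:
            array_id = f"{genome_id}_A{len(arrays)}"
            orientation = (
                spec.placement_for(cas_type).sample_orientation(rng)
                if cas_type is not None
                else ("forward" if rng.random() < 0.5 else "reverse")
            )
            confidence = "possible" if rng.random() < spec.p_possible_confidence else "bona-fide"
            arrays.append(
                SpacerArray(
                    array_id=array_id,
                    genome_id=genome_id,
                    start=start,
                    end=end,
                    orientation=orientation,
                    confidence=confidence,
                    consensus_repeat=repeat,
                    spacers=spacers,
                )
            )
            rec = ArrayTruth(
                array_id=array_id,
                genome_id=genome_id,
                cas_type=cas_type,
                theta=theta,
                source_locus=locus.locus_id if locus else None,
                duplicate_of=duplicate_of,
                placed_close=placed_close,
                resampled_zero_length=resampled,
            )
            genome_truth.append(rec)
            truth.arrays.append(rec)

        for locus in loci:
            t = locus.cas_type
            placement = spec.placement_for(t)
            ancestral = spec.repeat_for(t, rng)
            n_arrays = _sample_arrays_per_locus(spec, rng)
            locus_arrays: list[int] = []  # indices into `arrays`
            for _ in range(n_arrays):
                gap, near = placement.sample_gap(rng)
                theta = spec.theta_for(t)
                close = near and gap < spec.close_threshold_bp
                if close:
                    theta = theta * spec.acquisition_bias
                n_spacers = sample_idm_length(theta, spec.rho, rng)
                resampled = n_spacers == 0
                while n_spacers == 0:  # arrays must hold >= 1 spacer
                    n_spacers = sample_idm_length(theta, spec.rho, rng)
                length_bp = n_spacers * (spec.spacer_length + spec.repeat_length) + spec.repeat_length
                side_after = rng.random() < placement.p_after
                start, end = _place_array(
                    locus, gap, near, placement, length_bp, side_after, registry,
                    spec.genome_length, rng,
                )
                repeat = _mutate_repeat(ancestral, spec.repeat_substitution_rate, rng)
                locus_arrays.append(len(arrays))
                make_array(t, locus, repeat, new_spacers(n_spacers), start, end, close, theta, None, resampled)

            if locus_arrays and rng.random() < spec.duplication_prob:
                # duplication: copy repeat and a leader-distal spacer suffix
                parent = arrays[locus_arrays[0]]
                parent_truth = genome_truth[locus_arrays[0]]
                keep = int(rng.integers(1, parent.n_spacers + 1))
                dup_spacers = parent.spacers[-keep:]
                length_bp = len(dup_spacers) * (spec.spacer_length + spec.repeat_length) + spec.repeat_length
                gap, near = placement.sample_gap(rng)
                side_after = rng.random() < placement.p_after
                start, end = _place_array(
                    locus, gap, near, placement, length_bp, side_after, registry,
                    spec.genome_length, rng,
                )
                make_array(
                    t,
                    locus,
                    parent.consensus_repeat,
                    dup_spacers,
                    start,
                    end,
                    near and gap < spec.close_threshold_bp,
                    parent_truth.theta,
                    parent.array_id,
                    False,
                )

        if rng.random() < spec.orphan_rate:
            n_spacers = max(1, int(rng.poisson(5)))
            length_bp = n_spacers * (spec.spacer_length + spec.repeat_length) + spec.repeat_length
            for _ in range(100):
                start = int(rng.integers(0, spec.genome_length - length_bp))
                if not registry.collides(start, start + length_bp):
                    registry.add(start, start + length_bp)
                    break
            else:
                raise RuntimeError(f"could not place orphan array in {genome_id}")
            make_array(
                None,
                None,
                random_dna(rng, spec.repeat_length),
                new_spacers(n_spacers),
                start,
                start + length_bp,
                False,
                0.0,
                None,
                False,
            )

        cohort.append(GenomeAnnotation(genome_id=genome_id, loci=loci, arrays=arrays,
                                       sequence_length=spec.genome_length))
    return cohort, truth
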