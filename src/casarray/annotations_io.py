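"""Domain types and TSV I/O for CRISPR array / Cas locus annotation cohorts.

The unit of analysis is one genome (:class:`GenomeAnnotation`): the Cas loci
detected in it and the spacer arrays detected in it.  Coordinates are 0-based
half-open ``[start, end)`` throughout, both in memory and in the TSV files.

Arrays are related to Cas loci by :func:`assign_arrays`, which implements the
closest-locus rule used in comparative CRISPR surveys: each array is assigned
to the Cas locus minimising the gap between the nearest feature ends, is
labelled ``before``/``after``/``overlap`` relative to that locus, and is
``close`` when the gap is below a threshold (10 kb by default).  Genomes
without any Cas locus yield *orphan* arrays carrying the type label
``"no cas type"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ORPHAN_TYPE",
    "DEFAULT_CLOSE_THRESHOLD_BP",
    "CasLocus",
    "SpacerArray",
    "GenomeAnnotation",
    "ArrayAssignment",
    "read_cohort",
    "write_cohort",
    "assign_arrays",
    "interval_gap",
]

ORPHAN_TYPE = "no cas type"

#: Arrays closer than this many bp to their assigned Cas locus are "close".
DEFAULT_CLOSE_THRESHOLD_BP = 10_000

ORIENTATIONS = ("forward", "reverse", "unknown")
CONFIDENCES = ("bona-fide", "possible")

ARRAYS_COLUMNS = [
    "genome_id",
    "seq_id",
    "array_id",
    "start",
    "end",
    "orientation",
    "confidence",
    "consensus_repeat",
    "spacers",
]
LOCI_COLUMNS = ["genome_id", "seq_id", "locus_id", "cas_type", "start", "end"]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation records."""


@dataclass(frozen=True)
class CasLocus:
    """A Cas gene cluster with a subtype label such as ``"I-E"`` or ``"II-C"``."""

    locus_id: str
    genome_id: str
    cas_type: str
    start: int
    end: int
    seq_id: str = "chr"

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise AnnotationError(
                f"locus {self.locus_id}: start ({self.start}) must be < end ({self.end})"
            )
        if not self.cas_type:
            raise AnnotationError(f"locus {self.locus_id}: empty cas_type")


@dataclass(frozen=True)
class SpacerArray:
    """One CRISPR array: consensus repeat plus ordered spacers.

    ``spacers[0]`` is leader-proximal (newest acquisition), ``spacers[-1]``
    leader-distal (oldest).  The array length in the turnover-model sense is
    ``len(spacers)``.
    """

    array_id: str
    genome_id: str
    start: int
    end: int
    orientation: str
    confidence: str
    consensus_repeat: str
    spacers: tuple[str, ...]
    seq_id: str = "chr"

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise AnnotationError(
                f"array {self.array_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.orientation not in ORIENTATIONS:
            raise AnnotationError(
                f"array {self.array_id}: orientation {self.orientation!r} not one of {ORIENTATIONS}"
            )
        if self.confidence not in CONFIDENCES:
            raise AnnotationError(
                f"array {self.array_id}: confidence {self.confidence!r} not one of {CONFIDENCES}"
            )
        if len(self.consensus_repeat) < 1:
            raise AnnotationError(f"array {self.array_id}: empty consensus_repeat")
        if len(self.spacers) < 1:
            raise AnnotationError(f"array {self.array_id}: arrays must contain >= 1 spacer")
        object.__setattr__(self, "spacers", tuple(self.spacers))

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


@dataclass
class GenomeAnnotation:
    """All Cas loci and spacer arrays annotated in one genome."""

    genome_id: str
    loci: list[CasLocus] = field(default_factory=list)
    arrays: list[SpacerArray] = field(default_factory=list)
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus.genome_id != self.genome_id:
                raise AnnotationError(
                    f"locus {locus.locus_id} carries genome_id {locus.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )
        for arr in self.arrays:
            if arr.genome_id != self.genome_id:
                raise AnnotationError(
                    f"array {arr.array_id} carries genome_id {arr.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )
        locus_ids = [l.locus_id for l in self.loci]
        if len(set(locus_ids)) != len(locus_ids):
            raise AnnotationError(f"genome {self.genome_id}: duplicate locus_id")
        array_ids = [a.array_id for a in self.arrays]
        if len(set(array_ids)) != len(array_ids):
            raise AnnotationError(f"genome {self.genome_id}: duplicate array_id")

    @property
    def cas_types(self) -> set[str]:
        return {l.cas_type for l in self.loci}


@dataclass(frozen=True)
class ArrayAssignment:
    """An array's relation to its nearest Cas locus (or orphan status).

    ``signed_distance`` is negative for arrays before (left of) the locus,
    positive after it, and 0 for interval overlap.  ``side == "orphan"`` iff
    ``locus_id is None`` iff ``assigned_type == "no cas type"``.
    """

    array_id: str
    locus_id: str | None
    signed_distance: int
    side: str  # before | after | overlap | orphan
    is_close: bool
    assigned_type: str

    def __post_init__(self) -> None:
        orphanish = (self.side == "orphan", self.locus_id is None, self.assigned_type == ORPHAN_TYPE)
        if len(set(orphanish)) != 1:
            raise AnnotationError(
                f"array {self.array_id}: inconsistent orphan marking {orphanish}"
            )
        if self.side == "before" and self.signed_distance >= 0:
            raise AnnotationError(f"array {self.array_id}: side=before needs negative distance")
        if self.side == "after" and self.signed_distance <= 0:
            raise AnnotationError(f"array {self.array_id}: side=after needs positive distance")
        if self.side == "overlap" and self.signed_distance != 0:
            raise AnnotationError(f"array {self.array_id}: side=overlap needs distance 0")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing column(s) {missing}")


def _parse_int(value: object, path: str, line: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise AnnotationError(
            f"{path}, line {line}, field {column!r}: not an integer: {value!r}"
        ) from None


def read_cohort(arrays_path, loci_path) -> list[GenomeAnnotation]:
    """Read a cohort from ``arrays.tsv`` + ``loci.tsv``.

    Returns one :class:`GenomeAnnotation` per distinct ``genome_id`` seen in
    either file; genomes present only in the loci file are emitted with zero
    arrays, genomes present only in the arrays file with zero loci (their
    arrays will be orphans).  Spacer order in the file is preserved.
    """
    arrays_df = pd.read_csv(arrays_path, sep="\t", dtype=str, keep_default_na=False)
    loci_df = pd.read_csv(loci_path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(arrays_df, ARRAYS_COLUMNS, str(arrays_path))
    _require_columns(loci_df, LOCI_COLUMNS, str(loci_path))

    arrays_by_genome: dict[str, list[SpacerArray]] = {}
    seen_array_ids: set[str] = set()
    for idx, row in enumerate(arrays_df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        if row.array_id in seen_array_ids:
            raise AnnotationError(
                f"{arrays_path}, line {line}: duplicate array_id {row.array_id!r}"
            )
        seen_array_ids.add(row.array_id)
        spacers = tuple(s for s in row.spacers.split(",") if s != "")
        if not spacers:
            raise AnnotationError(
                f"{arrays_path}, line {line}, field 'spacers': no spacers listed"
            )
        try:
            arr = SpacerArray(
                array_id=row.array_id,
                genome_id=row.genome_id,
                seq_id=row.seq_id,
                start=_parse_int(row.start, str(arrays_path), line, "start"),
                end=_parse_int(row.end, str(arrays_path), line, "end"),
                orientation=row.orientation,
                confidence=row.confidence,
                consensus_repeat=row.consensus_repeat,
                spacers=spacers,
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{arrays_path}, line {line}: {exc}") from None
        arrays_by_genome.setdefault(row.genome_id, []).append(arr)

    loci_by_genome: dict[str, list[CasLocus]] = {}
    for idx, row in enumerate(loci_df.itertuples(index=False)):
        line = idx + 2
        try:
            locus = CasLocus(
                locus_id=row.locus_id,
                genome_id=row.genome_id,
                seq_id=row.seq_id,
                cas_type=row.cas_type,
                start=_parse_int(row.start, str(loci_path), line, "start"),
                end=_parse_int(row.end, str(loci_path), line, "end"),
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{loci_path}, line {line}: {exc}") from None
        loci_by_genome.setdefault(row.genome_id, []).append(locus)

    genome_ids = sorted(set(arrays_by_genome) | set(loci_by_genome))
    return [
        GenomeAnnotation(
            genome_id=gid,
            loci=loci_by_genome.get(gid, []),
            arrays=arrays_by_genome.get(gid, []),
        )
        for gid in genome_ids
    ]


def cohort_to_frames(cohort: Iterable[GenomeAnnotation]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (arrays, loci) DataFrames matching the TSV schemas."""
    array_rows = []
    locus_rows = []
    for genome in cohort:
        for arr in genome.arrays:
            array_rows.append(
                {
                    "genome_id": arr.genome_id,
                    "seq_id": arr.seq_id,
                    "array_id": arr.array_id,
                    "start": arr.start,
                    "end": arr.end,
                    "orientation": arr.orientation,
                    "confidence": arr.confidence,
                    "consensus_repeat": arr.consensus_repeat,
                    "spacers": ",".join(arr.spacers),
                }
            )
        for locus in genome.loci:
            locus_rows.append(
                {
                    "genome_id": locus.genome_id,
                    "seq_id": locus.seq_id,
                    "locus_id": locus.locus_id,
                    "cas_type": locus.cas_type,
                    "start": locus.start,
                    "end": locus.end,
                }
            )
    arrays_df = pd.DataFrame(array_rows, columns=ARRAYS_COLUMNS)
    loci_df = pd.DataFrame(locus_rows, columns=LOCI_COLUMNS)
    return arrays_df, loci_df


def write_cohort(cohort: Iterable[GenomeAnnotation], arrays_path, loci_path) -> None:
    """Write a cohort back to the two TSV files (UTF-8, header row)."""
    arrays_df, loci_df = cohort_to_frames(cohort)
    arrays_df.to_csv(arrays_path, sep="\t", index=False)
    loci_df.to_csv(loci_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Array-to-locus assignment
# ---------------------------------------------------------------------------

def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between nearest ends of two half-open intervals (0 if they overlap)."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def assign_arrays(
    genome: GenomeAnnotation,
    close_threshold_bp: int = DEFAULT_CLOSE_THRESHOLD_BP,
) -> list[ArrayAssignment]:
    """Assign every array in ``genome`` to its nearest Cas locus.

    Distances are computed only between features on the same ``seq_id``;
    ties (two loci at the same gap) go to the locus with the smaller start
    coordinate, then the smaller locus_id, for determinism.  Arrays with no
    candidate locus are orphans.
    """
    assignments: list[ArrayAssignment] = []
    loci_by_seq: dict[str, list[CasLocus]] = {}
    for locus in genome.loci:
        loci_by_seq.setdefault(locus.seq_id, []).append(locus)

    for arr in genome.arrays:
        candidates = loci_by_seq.get(arr.seq_id, [])
        if not candidates:
            assignments.append(
                ArrayAssignment(
                    array_id=arr.array_id,
                    locus_id=None,
                    signed_distance=0,
                    side="orphan",
                    is_close=False,
                    assigned_type=ORPHAN_TYPE,
                )
            )
            continue
        best = min(
            candidates,
            key=lambda l: (interval_gap(arr.start, arr.end, l.start, l.end), l.start, l.locus_id),
        )
        gap = interval_gap(arr.start, arr.end, best.start, best.end)
        if gap == 0:
            side, signed = "overlap", 0
        elif arr.end <= best.start:
            side, signed = "before", -gap
        else:
            side, signed = "after", gap
        assignments.append(
            ArrayAssignment(
                array_id=arr.array_id,
                locus_id=best.locus_id,
                signed_distance=signed,
                side=side,
                is_close=gap < close_threshold_bp,
                assigned_type=best.cas_type,
            )
        )
    return assignments


def filter_confidence(genome: GenomeAnnotation, exclude_possible: bool) -> GenomeAnnotation:
    """Optionally drop "possible"-confidence arrays (keeps bona-fide only)."""
    if not exclude_possible:
        return genome
    kept = [a for a in genome.arrays if a.confidence == "bona-fide"]
    return GenomeAnnotation(
        genome_id=genome.genome_id,
        loci=list(genome.loci),
        arrays=kept,
        sequence_length=genome.sequence_length,
    )
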