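"""Distance and orientation of arrays around their Cas loci.

Per-array geometry records (side, signed distance, orientation, closeness)
feed binned distance/orientation distributions per Cas type, and a dedicated
classifier for the two-array configurations of genomes carrying exactly one
Cas type and exactly two arrays (flanking vs same-side, joint orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations_io import ArrayAssignment, GenomeAnnotation

__all__ = [
    "GeometryRecord",
    "PairConfiguration",
    "geometry_table",
    "pair_configurations",
    "distance_histogram",
    "DEFAULT_BIN_EDGES",
]

#: Distance bin edges in bp, mirroring the visual scale used for close arrays.
DEFAULT_BIN_EDGES = (0, 500, 2500, 5000, 10_000)


@dataclass(frozen=True)
class GeometryRecord:
    array_id: str
    genome_id: str
    assigned_type: str
    side: str  # before | after | overlap
    signed_distance: int
    orientation: str
    is_close: bool


@dataclass(frozen=True)
class PairConfiguration:
    genome_id: str
    cas_type: str
    side_pattern: str  # flanking | both_before | both_after
    orientation_pattern: str  # both_forward | both_reverse | mixed | unknown


def geometry_table(
    cohort: Iterable[GenomeAnnotation],
    assignments: Mapping[str, list[ArrayAssignment]],
) -> list[GeometryRecord]:
    """One record per non-orphan array; orphans are excluded."""
    records = []
    for genome in cohort:
        by_id = {a.array_id: a for a in assignments.get(genome.genome_id, [])}
        for arr in genome.arrays:
            asn = by_id.get(arr.array_id)
            if asn is None or asn.side == "orphan":
                continue
            records.append(
                GeometryRecord(
                    array_id=arr.array_id,
                    genome_id=genome.genome_id,
                    assigned_type=asn.assigned_type,
                    side=asn.side,
                    signed_distance=asn.signed_distance,
                    orientation=arr.orientation,
                    is_close=asn.is_close,
                )
            )
    return records


def _resolve_side(asn: ArrayAssignment, arr_start: int, arr_end: int, locus) -> str:
    if asn.side != "overlap":
        return asn.side
    # overlap resolved to the side holding the array midpoint
    arr_mid = (arr_start + arr_end) / 2
    locus_mid = (locus.start + locus.end) / 2
    return "before" if arr_mid < locus_mid else "after"


def pair_configurations(
    cohort: Iterable[GenomeAnnotation],
    assignments: Mapping[str, list[ArrayAssignment]],
) -> list[PairConfiguration]:
    """Side/orientation patterns for single-type, two-array genomes.

    Only genomes with exactly one distinct Cas type and exactly two arrays
    (both non-orphan) are classified.  Overlapping arrays are attributed to
    the side holding the array midpoint.
    """
    out = []
    for genome in cohort:
        if len(genome.cas_types) != 1 or len(genome.arrays) != 2:
            continue
        (cas_type,) = genome.cas_types
        by_id = {a.array_id: a for a in assignments.get(genome.genome_id, [])}
        loci_by_id = {l.locus_id: l for l in genome.loci}
        sides = []
        orientations = []
        skip = False
        for arr in genome.arrays:
            asn = by_id.get(arr.array_id)
            if asn is None or asn.side == "orphan":
                skip = True
                break
            locus = loci_by_id[asn.locus_id]
            sides.append(_resolve_side(asn, arr.start, arr.end, locus))
            orientations.append(arr.orientation)
        if skip:
            continue
        if sides[0] != sides[1]:
            side_pattern = "flanking"
        else:
            side_pattern = "both_before" if sides[0] == "before" else "both_after"
        if "unknown" in orientations:
            orientation_pattern = "unknown"
        elif orientations[0] != orientations[1]:
            orientation_pattern = "mixed"
        else:
            orientation_pattern = f"both_{orientations[0]}"
        out.append(PairConfiguration(genome.genome_id, cas_type, side_pattern, orientation_pattern))
    return out


def distance_histogram(
    records: Sequence[GeometryRecord],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Counts per (type, side+distance bin, orientation).

    ``bin_edges`` apply to the absolute distance on each side; overlap gets
    its own bin, as does everything beyond the last edge.  Total counts
    conserve the number of input records.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(hi <= lo for lo, hi in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing (>= 2 edges)")

    def bin_label(record: GeometryRecord) -> str:
        if record.side == "overlap":
            return "overlap"
        d = abs(record.signed_distance)
        for lo, hi in zip(edges, edges[1:]):
            if lo <= d < hi:
                return f"{record.side}:[{lo},{hi})"
        return f"{record.side}:[{edges[-1]},inf)"

    rows = [
        {
            "assigned_type": r.assigned_type,
            "bin": bin_label(r),
            "orientation": r.orientation,
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["assigned_type", "bin", "orientation", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["assigned_type", "bin", "orientation"], sort=True)
        .size()
        .reset_index(name="count")
    )
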