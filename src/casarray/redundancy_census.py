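"""Redundancy census: arrays per locus, repeat/spacer sharing, length by proximity.

Quantifies how often Cas loci serve multiple arrays and how much those arrays
share.  Sharing an identical consensus repeat flags likely duplication or
common acquisition machinery; among such same-repeat co-occurring arrays the
census further distinguishes any spacer overlap, identical spacer content
(recent complete duplication), and an identical leader-distal (last) spacer —
the spacer least likely to be deleted, hence the most durable mark of common
ancestry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .annotations_io import ArrayAssignment, GenomeAnnotation

__all__ = [
    "CensusReport",
    "arrays_per_locus",
    "repeat_spacer_census",
    "length_by_proximity",
]


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def _repeat_key(repeat: str, fold_reverse_complement: bool) -> str:
    if not fold_reverse_complement:
        return repeat
    rc = _revcomp(repeat)
    return min(repeat, rc)


@dataclass
class CensusReport:
    """Cohort-level redundancy fractions and per-(type, proximity) summaries."""

    n_arrays: int
    n_loci: int
    fraction_arrays_with_cooccurring_identical_repeat: float
    fraction_loci_with_multiple_same_repeat_arrays: float
    fraction_arrays_any_spacer_overlap: float
    fraction_arrays_identical_spacer_sets: float
    fraction_arrays_same_last_spacer: float
    arrays_per_locus_summary: pd.DataFrame = field(repr=False, default=None)
    length_summary: pd.DataFrame = field(repr=False, default=None)

    def fractions(self) -> dict[str, float]:
        return {
            "fraction_arrays_with_cooccurring_identical_repeat":
                self.fraction_arrays_with_cooccurring_identical_repeat,
            "fraction_loci_with_multiple_same_repeat_arrays":
                self.fraction_loci_with_multiple_same_repeat_arrays,
            "fraction_arrays_any_spacer_overlap": self.fraction_arrays_any_spacer_overlap,
            "fraction_arrays_identical_spacer_sets": self.fraction_arrays_identical_spacer_sets,
            "fraction_arrays_same_last_spacer": self.fraction_arrays_same_last_spacer,
        }


def arrays_per_locus(
    cohort: Iterable[GenomeAnnotation],
    assignments: Mapping[str, list[ArrayAssignment]],
    include_empty_loci: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus assigned-array counts plus per-type/overall summaries.

    Orphan arrays count toward no locus.  Loci with zero assigned arrays
    contribute a count of 0 unless ``include_empty_loci`` is False.
    Returns ``(per_locus, summary)`` DataFrames.
    """
    per_locus_rows = []
    for genome in cohort:
        counts = Counter(
            a.locus_id for a in assignments.get(genome.genome_id, []) if a.locus_id is not None
        )
        for locus in genome.loci:
            c = counts.get(locus.locus_id, 0)
            if c == 0 and not include_empty_loci:
                continue
            per_locus_rows.append(
                {
                    "genome_id": genome.genome_id,
                    "locus_id": locus.locus_id,
                    "cas_type": locus.cas_type,
                    "n_arrays": c,
                }
            )
    per_locus = pd.DataFrame(per_locus_rows, columns=["genome_id", "locus_id", "cas_type", "n_arrays"])
    if per_locus.empty:
        return per_locus, pd.DataFrame(columns=["cas_type", "mean", "median", "max", "n_loci"])

    def summarize(df: pd.DataFrame, label: str) -> dict:
        return {
            "cas_type": label,
            "mean": df["n_arrays"].mean(),
            "median": df["n_arrays"].median(),
            "max": df["n_arrays"].max(),
            "n_loci": len(df),
        }

    summary_rows = [summarize(g, t) for t, g in per_locus.groupby("cas_type", sort=True)]
    summary_rows.append(summarize(per_locus, "overall"))
    return per_locus, pd.DataFrame(summary_rows)


def repeat_spacer_census(
    cohort: Iterable[GenomeAnnotation],
    assignments: Mapping[str, list[ArrayAssignment]],
    fold_reverse_complement: bool = False,
) -> CensusReport:
    """Compute the redundancy fractions of :class:`CensusReport`.

    All array-level fractions use the total number of arrays in the cohort as
    denominator.  An array counts toward a sharing fraction when at least one
    *other* array in the same genome has a byte-identical consensus repeat
    (optionally folding reverse complements) and the stated sharing property
    with it.  The locus-level fraction uses all loci as denominator and flags
    loci with >= 2 assigned arrays sharing one identical repeat.
    """
    n_arrays = 0
    n_loci = 0
    n_cooccurring_repeat = 0
    n_any_overlap = 0
    n_identical_sets = 0
    n_same_last = 0
    n_multi_same_repeat_loci = 0

    for genome in cohort:
        n_arrays += len(genome.arrays)
        n_loci += len(genome.loci)
        keys = [_repeat_key(a.consensus_repeat, fold_reverse_complement) for a in genome.arrays]
        by_repeat: dict[str, list[int]] = {}
        for i, key in enumerate(keys):
            by_repeat.setdefault(key, []).append(i)

        for key, members in by_repeat.items():
            if len(members) < 2:
                continue
            n_cooccurring_repeat += len(members)
            for i in members:
                a = genome.arrays[i]
                spacers_i = Counter(a.spacers)
                any_overlap = False
                identical = False
                same_last = False
                for j in members:
                    if j == i:
                        continue
                    b = genome.arrays[j]
                    spacers_j = Counter(b.spacers)
                    if spacers_i & spacers_j:
                        any_overlap = True
                    if spacers_i == spacers_j:
                        identical = True
                    if a.spacers[-1] == b.spacers[-1]:
                        same_last = True
                n_any_overlap += any_overlap
                n_identical_sets += identical
                n_same_last += same_last

        # locus-level: >= 2 assigned arrays with identical repeat at one locus
        arrays_by_id = {a.array_id: a for a in genome.arrays}
        locus_repeats: dict[str, Counter] = {}
        for asn in assignments.get(genome.genome_id, []):
            if asn.locus_id is None:
                continue
            arr = arrays_by_id[asn.array_id]
            locus_repeats.setdefault(asn.locus_id, Counter())[
                _repeat_key(arr.consensus_repeat, fold_reverse_complement)
            ] += 1
        for locus_counter in locus_repeats.values():
            if any(c >= 2 for c in locus_counter.values()):
                n_multi_same_repeat_loci += 1

    def frac(num: int, den: int) -> float:
        return num / den if den else 0.0

    per_locus, locus_summary = arrays_per_locus(cohort, assignments)
    length_summary = length_by_proximity(cohort, assignments)
    return CensusReport(
        n_arrays=n_arrays,
        n_loci=n_loci,
        fraction_arrays_with_cooccurring_identical_repeat=frac(n_cooccurring_repeat, n_arrays),
        fraction_loci_with_multiple_same_repeat_arrays=frac(n_multi_same_repeat_loci, n_loci),
        fraction_arrays_any_spacer_overlap=frac(n_any_overlap, n_arrays),
        fraction_arrays_identical_spacer_sets=frac(n_identical_sets, n_arrays),
        fraction_arrays_same_last_spacer=frac(n_same_last, n_arrays),
        arrays_per_locus_summary=locus_summary,
        length_summary=length_summary,
    )


def length_by_proximity(
    cohort: Iterable[GenomeAnnotation],
    assignments: Mapping[str, list[ArrayAssignment]],
    same_repeat_as_close_only: bool = False,
) -> pd.DataFrame:
    """Array-length (spacer count) summaries per (assigned type, is_close).

    With ``same_repeat_as_close_only`` the census is restricted to arrays
    whose consensus repeat matches that of at least one close array in the
    same genome — the conditioning that isolates same-repeat array families.
    Orphan arrays are excluded.
    """
    rows = []
    for genome in cohort:
        by_id = {a.array_id: a for a in assignments.get(genome.genome_id, [])}
        close_repeats = {
            genome.arrays[i].consensus_repeat
            for i, arr in enumerate(genome.arrays)
            if (asn := by_id.get(arr.array_id)) is not None
            and asn.side != "orphan"
            and asn.is_close
        }
        for arr in genome.arrays:
            asn = by_id.get(arr.array_id)
            if asn is None or asn.side == "orphan":
                continue
            if same_repeat_as_close_only and arr.consensus_repeat not in close_repeats:
                continue
            rows.append(
                {
                    "assigned_type": asn.assigned_type,
                    "is_close": asn.is_close,
                    "n_spacers": arr.n_spacers,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["assigned_type", "is_close", "mean", "median", "max", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["assigned_type", "is_close"], sort=True)["n_spacers"]
        .agg(mean="mean", median="median", max="max", count="count")
        .reset_index()
    )
    overall = (
        df.groupby("is_close", sort=True)["n_spacers"]
        .agg(mean="mean", median="median", max="max", count="count")
        .reset_index()
    )
    overall.insert(0, "assigned_type", "overall")
    return pd.concat([out, overall], ignore_index=True)
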