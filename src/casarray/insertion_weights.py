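"""Relative spacer insertion-rate weights and their neutral multinomial null.

Under the independent-deletion spacer-turnover model the stationary length of
an array with insertion rate theta_i and (genome-wide constant) deletion rate
rho is Poisson with mean theta_i/rho, so within one genome the share of the
total insertion rate captured by array i — the *insertion rate weight*
w_i = theta_i / (theta_1 + ... + theta_k) — reduces to the length proportion
w_i = n_i / n, with n = n_1 + ... + n_k spacers in the genome's k arrays.
No numeric value of rho is ever needed: it cancels.

The neutral comparison distribution assumes every array is equally likely to
receive each new spacer: for a genome with k arrays and n spacers the lengths
are one Multinomial(n, (1/k, ..., 1/k)) draw, divided by n.  One null sample
is drawn per observed genome, matched on (k, n), so the null distribution has
exactly the same sample size as the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import ArrayAssignment, GenomeAnnotation

__all__ = [
    "WeightRecord",
    "NullSample",
    "insertion_rate_weights",
    "select_weight_genomes",
    "neutral_weight_sample",
    "neutral_distribution",
    "weight_summary",
]

DEFAULT_K_VALUES = frozenset({2, 3, 4})


@dataclass(frozen=True)
class WeightRecord:
    """Insertion-rate weights for the in-scope arrays of one genome."""

    genome_id: str
    k: int
    array_ids: tuple[str, ...]
    lengths: tuple[int, ...]
    n_total: int
    weights: tuple[float, ...]
    close_flags: tuple[bool, ...]
    same_repeat_scope: bool

    def __post_init__(self) -> None:
        assert abs(sum(self.weights) - 1.0) < 1e-12


@dataclass(frozen=True)
class NullSample:
    genome_id: str
    k: int
    n_total: int
    weights: tuple[float, ...]


def insertion_rate_weights(lengths: Sequence[int]) -> tuple[float, ...]:
    """w_i = n_i / sum(n), order preserved. Requires k >= 2 arrays, lengths >= 1."""
    if len(lengths) < 2:
        raise ValueError(f"need >= 2 arrays, got {len(lengths)}")
    if any(l < 1 for l in lengths):
        raise ValueError(f"array lengths must be >= 1 spacer, got {list(lengths)}")
    total = sum(lengths)
    return tuple(l / total for l in lengths)


def select_weight_genomes(
    cohort: Iterable[GenomeAnnotation],
    assignments: Mapping[str, list[ArrayAssignment]],
    k_values: frozenset[int] | set[int] = DEFAULT_K_VALUES,
    same_repeat_only: bool = False,
) -> list[WeightRecord]:
    """Build weight records for genomes with an in-scope array count in ``k_values``.

    Genomes containing any orphan array are excluded entirely.  By default
    all arrays of a genome are in scope; with ``same_repeat_only`` the scope
    is the largest group of arrays sharing one consensus repeat (ties broken
    by the largest total spacer count, then lexicographic repeat).
    """
    records = []
    for genome in cohort:
        asns = assignments.get(genome.genome_id, [])
        if any(a.side == "orphan" for a in asns):
            continue
        by_id = {a.array_id: a for a in asns}
        arrays = list(genome.arrays)
        if same_repeat_only:
            groups: dict[str, list] = {}
            for arr in arrays:
                groups.setdefault(arr.consensus_repeat, []).append(arr)
            if not groups:
                continue
            arrays = max(
                groups.values(),
                key=lambda g: (len(g), sum(a.n_spacers for a in g), g[0].consensus_repeat),
            )
        k = len(arrays)
        if k not in k_values:
            continue
        lengths = tuple(a.n_spacers for a in arrays)
        records.append(
            WeightRecord(
                genome_id=genome.genome_id,
                k=k,
                array_ids=tuple(a.array_id for a in arrays),
                lengths=lengths,
                n_total=sum(lengths),
                weights=insertion_rate_weights(lengths),
                close_flags=tuple(by_id[a.array_id].is_close for a in arrays),
                same_repeat_scope=same_repeat_only,
            )
        )
    return records


def neutral_weight_sample(n_total: int, k: int, rng: np.random.Generator) -> tuple[float, ...]:
    """One Multinomial(n_total, 1/k) draw divided by n_total."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = rng.multinomial(n_total, np.full(k, 1.0 / k))
    return tuple(counts / n_total)


def neutral_distribution(
    records: Sequence[WeightRecord], rng: np.random.Generator
) -> list[NullSample]:
    """Exactly one matched null sample per observed record (same k and n)."""
    return [
        NullSample(
            genome_id=rec.genome_id,
            k=rec.k,
            n_total=rec.n_total,
            weights=neutral_weight_sample(rec.n_total, rec.k, rng),
        )
        for rec in records
    ]


def weight_summary(
    records: Sequence[WeightRecord], null: Sequence[NullSample] | None = None
) -> pd.DataFrame:
    """Per-k summary: overall/close/far mean weights, variances, null comparison.

    The overall mean weight is 1/k by construction (weights sum to 1 per
    genome) and is reported as a bookkeeping check.  The variance ratio
    observed/null quantifies over-dispersion relative to neutral allocation.
    """
    rows = []
    for k in sorted({r.k for r in records}):
        recs = [r for r in records if r.k == k]
        w = np.array([wi for r in recs for wi in r.weights])
        close = np.array([c for r in recs for c in r.close_flags], dtype=bool)
        row = {
            "k": k,
            "n_genomes": len(recs),
            "mean_weight": float(w.mean()),
            "mean_weight_close": float(w[close].mean()) if close.any() else np.nan,
            "mean_weight_far": float(w[~close].mean()) if (~close).any() else np.nan,
            "n_close": int(close.sum()),
            "n_far": int((~close).sum()),
            "var_weight": float(w.var(ddof=1)) if len(w) > 1 else np.nan,
        }
        if null is not None:
            nw = np.array([wi for s in null if s.k == k for wi in s.weights])
            row["var_null"] = float(nw.var(ddof=1)) if len(nw) > 1 else np.nan
            row["var_ratio"] = (
                row["var_weight"] / row["var_null"] if row.get("var_null") else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[WeightRecord]) -> pd.DataFrame:
    """Tidy per-array view: genome_id, k, scope, array_id, length, weight, is_close."""
    rows = []
    for rec in records:
        scope = "same_repeat" if rec.same_repeat_scope else "all"
        for aid, length, weight, close in zip(
            rec.array_ids, rec.lengths, rec.weights, rec.close_flags
        ):
            rows.append(
                {
                    "genome_id": rec.genome_id,
                    "k": rec.k,
                    "scope": scope,
                    "array_id": aid,
                    "length": length,
                    "weight": weight,
                    "is_close": close,
                }
            )
    return pd.DataFrame(
        rows, columns=["genome_id", "k", "scope", "array_id", "length", "weight", "is_close"]
    )


def null_to_frame(null: Sequence[NullSample]) -> pd.DataFrame:
    rows = []
    for s in null:
        for i, w in enumerate(s.weights):
            rows.append(
                {"genome_id": s.genome_id, "k": s.k, "slot": i, "n_total": s.n_total, "weight": w}
            )
    return pd.DataFrame(rows, columns=["genome_id", "k", "slot", "n_total", "weight"])
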