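"""Observed vs expected occurrence of Cas types, alone and in pairs.

Under the null that presence/absence of Cas types is reshuffled independently
across genomes at the observed marginal frequencies, a type seen in ``j`` of
``n`` genomes and another seen in ``k`` co-occur in ``j*k/n`` genomes in
expectation, and a type occurs *solo* (no other type present) in
``j_t * prod_{s != t} (1 - j_s/n)`` genomes.  Observed counts are compared to
these expectations through a signed fold-change (magnitude always >= 1) and
an exact two-sided binomial test for the solo cells.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binomtest

from .annotations_io import GenomeAnnotation

__all__ = [
    "type_presence",
    "expected_pair_count",
    "expected_solo_count",
    "fold_change",
    "binomial_solo_test",
    "cooccurrence_table",
    "CooccurrenceTable",
]

DEFAULT_MIN_COUNT = 50
DEFAULT_ALPHA = 1e-4


def type_presence(cohort: Iterable[GenomeAnnotation]) -> pd.DataFrame:
    """Genome x type boolean presence table.

    A type is present in a genome iff at least one Cas locus of that type is
    annotated there; orphan arrays contribute no type.
    """
    rows = {}
    types: set[str] = set()
    for genome in cohort:
        present = genome.cas_types
        types |= present
        rows[genome.genome_id] = present
    columns = sorted(types)
    data = [[t in rows[gid] for t in columns] for gid in rows]
    return pd.DataFrame(data, index=list(rows), columns=columns, dtype=bool)


def expected_pair_count(j: int, k: int, n: int) -> float:
    """Expected number of genomes containing both types under reshuffling.

    The joint probability is (j/n)(k/n); over n genomes the expected count is
    j*k/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= j <= n and 0 <= k <= n):
        raise ValueError(f"type counts j={j}, k={k} must lie in [0, n={n}]")
    return j * k / n


def expected_solo_count(counts: Mapping[str, int], t: str, n: int) -> float:
    """Expected number of genomes containing type ``t`` and no other type."""
    if t not in counts:
        raise ValueError(f"unknown type {t!r}")
    if any(j > n for j in counts.values()):
        raise ValueError("a type count exceeds the number of genomes")
    prod = 1.0
    for s, j in counts.items():
        if s != t:
            prod *= 1.0 - j / n
    return counts[t] * prod


def fold_change(observed: float, expected: float) -> float:
    """Signed ratio of observed to expected counts.

    Positive when observed >= expected (observed/expected), negative
    otherwise (-expected/observed), so the magnitude is always >= 1 and the
    sign gives the direction.  ``observed == 0`` returns ``-inf``; tables
    report such cells as the lower bound ``-expected`` with a censored flag.
    """
    if expected <= 0:
        raise ValueError(f"expected must be > 0, got {expected}")
    if observed < 0:
        raise ValueError(f"observed must be >= 0, got {observed}")
    if observed == 0:
        return -math.inf
    if observed >= expected:
        return observed / expected
    return -expected / observed


def binomial_solo_test(observed_solo: int, n: int, p_solo: float) -> float:
    """Exact two-sided binomial p-value for a solo-occurrence count.

    Tests ``observed_solo`` successes in ``n`` genomes against success
    probability ``p_solo`` (= expected_solo / n), two-sided with the
    minimum-likelihood rule for the opposite tail.
    """
    if not 0 <= observed_solo <= n:
        raise ValueError("observed_solo must lie in [0, n]")
    p_solo = min(max(p_solo, 0.0), 1.0)
    if p_solo in (0.0, 1.0):
        # degenerate null: any deviation is impossible under it
        at_null = observed_solo == round(n * p_solo)
        return 1.0 if at_null else 0.0
    return float(binomtest(observed_solo, n, p_solo, alternative="two-sided").pvalue)


@dataclass
class CooccurrenceTable:
    """Tidy co-occurrence statistics: one row per solo type or type pair."""

    n_genomes: int
    type_counts: dict[str, int]
    table: pd.DataFrame  # kind, type_a, type_b, observed, expected, fold_change, p_value, censored, reported

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def pair_row(self, a: str, b: str) -> pd.Series:
        a, b = sorted((a, b))
        rows = self.table[
            (self.table["kind"] == "pair")
            & (self.table["type_a"] == a)
            & (self.table["type_b"] == b)
        ]
        if rows.empty:
            raise KeyError(f"no pair row for ({a}, {b})")
        return rows.iloc[0]

    def solo_row(self, t: str) -> pd.Series:
        rows = self.table[(self.table["kind"] == "solo") & (self.table["type_a"] == t)]
        if rows.empty:
            raise KeyError(f"no solo row for {t}")
        return rows.iloc[0]


def _table_fold_change(observed: float, expected: float) -> tuple[float, bool]:
    fc = fold_change(observed, expected)
    if math.isinf(fc):
        # observed 0: the true fold-change is below -expected; report the bound
        return -expected, True
    return fc, False


def cooccurrence_table(
    cohort: Iterable[GenomeAnnotation],
    min_count: int = DEFAULT_MIN_COUNT,
    alpha: float = DEFAULT_ALPHA,
) -> CooccurrenceTable:
    """Assemble solo and pairwise co-occurrence statistics for a cohort.

    A pair cell is *reported* when observed or expected reaches ``min_count``;
    a solo (diagonal) cell additionally requires binomial p < ``alpha``.
    """
    presence = type_presence(cohort)
    n = len(presence)
    if n == 0:
        return CooccurrenceTable(0, {}, pd.DataFrame(
            columns=["kind", "type_a", "type_b", "observed", "expected",
                     "fold_change", "p_value", "censored", "reported"]))
    counts = {t: int(presence[t].sum()) for t in presence.columns}
    only_one = presence.sum(axis=1) == 1

    rows = []
    for t in presence.columns:
        observed_solo = int((presence[t] & only_one).sum())
        expected_solo = expected_solo_count(counts, t, n)
        if expected_solo > 0:
            fc, censored = _table_fold_change(observed_solo, expected_solo)
            p = binomial_solo_test(observed_solo, n, expected_solo / n)
        else:
            fc, censored, p = math.nan, False, math.nan
        reported = (
            max(observed_solo, expected_solo) >= min_count
            and not math.isnan(p)
            and p < alpha
        )
        rows.append(
            {
                "kind": "solo",
                "type_a": t,
                "type_b": t,
                "observed": observed_solo,
                "expected": expected_solo,
                "fold_change": fc,
                "p_value": p,
                "censored": censored,
                "reported": reported,
            }
        )

    for a, b in itertools.combinations(presence.columns, 2):
        observed = int((presence[a] & presence[b]).sum())
        expected = expected_pair_count(counts[a], counts[b], n)
        if expected > 0:
            fc, censored = _table_fold_change(observed, expected)
            # pair p-values are informational; pair cells gate on count only
            p = binomial_solo_test(observed, n, expected / n)
        else:
            fc, censored, p = math.nan, False, math.nan
        rows.append(
            {
                "kind": "pair",
                "type_a": a,
                "type_b": b,
                "observed": observed,
                "expected": expected,
                "fold_change": fc,
                "p_value": p,
                "censored": censored,
                "reported": max(observed, expected) >= min_count,
            }
        )

    return CooccurrenceTable(n, counts, pd.DataFrame(rows))
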