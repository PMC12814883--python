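"""Consensus-repeat similarity: edit distances, metric MDS, KDE marginals.

Repeats are compared by Levenshtein (edit) distance, optionally normalized by
the maximum repeat length within a genome or across the whole input.  The
distance matrix is projected to two dimensions by metric MDS via the SMACOF
majorization algorithm (Guttman transform), which monotonically decreases the
raw stress — the residual sum of squares between input dissimilarities and
embedded Euclidean distances.  Marginal densities of the embedding axes use
Gaussian-kernel KDE with Scott's-rule bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

from .annotations_io import GenomeAnnotation, SpacerArray

__all__ = [
    "edit_distance",
    "DistanceMatrix",
    "distance_matrix",
    "RepeatEmbedding",
    "mds_embed",
    "kde_marginal",
    "distance_distribution",
]

NORMALIZATIONS = ("none", "per_genome_max", "global_max")


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance: minimum single-character edits turning a into b."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    D: np.ndarray
    normalization: str

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


def distance_matrix(
    arrays: Sequence[SpacerArray],
    normalization: str = "none",
    uppercase: bool = True,
) -> DistanceMatrix:
    """Pairwise consensus-repeat distances for a set of arrays.

    Normalization divides every distance by the maximum repeat length L in
    scope: the genome for ``per_genome_max`` (all arrays must then share one
    genome_id), all input arrays for ``global_max``, or L = 1 for ``none``.
    """
    arrays = list(arrays)
    if not arrays:
        raise ValueError("distance_matrix needs at least one array")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    if normalization == "per_genome_max":
        genomes = {a.genome_id for a in arrays}
        if len(genomes) != 1:
            raise ValueError("per_genome_max normalization requires arrays from one genome")
    repeats = [a.consensus_repeat.upper() if uppercase else a.consensus_repeat for a in arrays]
    n = len(repeats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = edit_distance(repeats[i], repeats[j])
    if normalization != "none":
        L = max(len(r) for r in repeats)
        D = D / L
    return DistanceMatrix(tuple(a.array_id for a in arrays), D, normalization)


@dataclass
class RepeatEmbedding:
    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    stress: float
    seed: int
    stress_history: tuple[float, ...] = ()


def _stress(D: np.ndarray, X: np.ndarray) -> float:
    d = squareform(pdist(X), checks=False)
    diff = squareform(D, checks=False) - squareform(d, checks=False)
    return float(np.sum(diff**2))


def _smacof_single(
    D: np.ndarray, X: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    """One SMACOF run from initialization X; returns (coords, stress, history)."""
    n = D.shape[0]
    history = [_stress(D, X)]
    for _ in range(max_iter):
        dist = squareform(pdist(X), checks=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / dist, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n  # Guttman transform
        history.append(_stress(D, X))
        if history[-2] - history[-1] < tol:
            break
    return X, history[-1], history


def mds_embed(
    D: DistanceMatrix | np.ndarray,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 300,
    tol: float = 1e-4,
    n_components: int = 2,
) -> RepeatEmbedding:
    """Metric MDS via SMACOF: best of ``n_init`` random starts by final stress.

    Deterministic given ``seed``.  Stress is the raw residual sum of squares
    and is non-increasing over the iterations of each run.
    """
    if isinstance(D, DistanceMatrix):
        labels, mat = D.labels, D.D
    else:
        mat = np.asarray(D, dtype=float)
        labels = tuple(str(i) for i in range(mat.shape[0]))
    if not np.all(np.isfinite(mat)):
        raise ValueError("distance matrix contains non-finite entries")
    n = mat.shape[0]
    if n == 1:
        return RepeatEmbedding(labels, np.zeros((1, n_components)), 0.0, seed, (0.0,))
    rng = np.random.default_rng(seed)
    scale = mat.max() or 1.0
    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(n_init):
        X0 = rng.uniform(-scale, scale, size=(n, n_components))
        X, stress, history = _smacof_single(mat, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history)
    X, stress, history = best
    return RepeatEmbedding(labels, X - X.mean(axis=0), stress, seed, tuple(history))


def kde_marginal(values: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Gaussian-kernel density (Scott's-rule bandwidth) evaluated on ``grid``."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError(
            "KDE needs >= 2 distinct values (all-identical input has zero bandwidth); "
            "jitter the input or plot a point mass instead"
        )
    kde = gaussian_kde(values, bw_method="scott")
    return kde(np.asarray(grid, dtype=float))


def distance_distribution(
    cohort: Iterable[GenomeAnnotation],
    normalization: str = "per_genome_max",
    bins: Sequence[float] | int = 20,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Within-genome pairwise repeat distances, stratified by arrays per genome.

    Returns ``{k_arrays: (histogram_counts, bin_edges)}`` pooled over all
    genomes with ``k_arrays`` arrays; each genome contributes k(k-1)/2 pairs.
    """
    pooled: dict[int, list[float]] = {}
    for genome in cohort:
        k = len(genome.arrays)
        if k < 2:
            continue
        dm = distance_matrix(genome.arrays, normalization=normalization)
        pooled.setdefault(k, []).extend(dm.condensed().tolist())
    out = {}
    for k, values in sorted(pooled.items()):
        counts, edges = np.histogram(np.asarray(values), bins=bins)
        out[k] = (counts, edges)
    return out
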