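"""End-to-end orchestration: generate/load → assign → analyze → report.

``run_pipeline`` produces a report directory containing the eight analysis
tables (co-occurrence, geometry, pair configurations, census, observed and
null weights, distances, embedding) plus a run manifest echoing the
configuration and seed.  All stochastic stages draw from generators seeded
from the single global seed, so identical configurations yield byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations_io import (
    DEFAULT_CLOSE_THRESHOLD_BP,
    ArrayAssignment,
    GenomeAnnotation,
    assign_arrays,
    filter_confidence,
    read_cohort,
    write_cohort,
)
from .cooccurrence import DEFAULT_ALPHA, DEFAULT_MIN_COUNT, cooccurrence_table
from .insertion_weights import (
    DEFAULT_K_VALUES,
    neutral_distribution,
    null_to_frame,
    records_to_frame,
    select_weight_genomes,
)
from .locus_geometry import (
    DEFAULT_BIN_EDGES,
    distance_histogram,
    geometry_table,
    pair_configurations,
)
from .redundancy_census import repeat_spacer_census
from .repeat_space import distance_matrix, mds_embed
from .synthetic_cohort import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "assign_cohort"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``arrays_path``/``loci_path`` (analyze existing TSVs) or
    ``generator_spec`` (generate a synthetic cohort first) must be set.
    """

    arrays_path: str | None = None
    loci_path: str | None = None
    generator_spec: CohortSpec | None = None
    output_dir: str = "casarray_report"
    close_threshold_bp: int = DEFAULT_CLOSE_THRESHOLD_BP
    min_count: int = DEFAULT_MIN_COUNT
    alpha: float = DEFAULT_ALPHA
    k_values: frozenset[int] = DEFAULT_K_VALUES
    normalization: str = "global_max"
    mds_n_init: int = 4
    mds_max_iter: int = 300
    mds_tol: float = 1e-4
    subsample_cap: int = 2000
    exclude_possible: bool = False
    include_orphans_in_repeat_space: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        have_paths = self.arrays_path is not None and self.loci_path is not None
        have_spec = self.generator_spec is not None
        if have_paths == have_spec:
            raise ValueError("set exactly one of (arrays_path, loci_path) or generator_spec")
        if self.close_threshold_bp <= 0 or self.min_count <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")


def assign_cohort(
    cohort: list[GenomeAnnotation], close_threshold_bp: int = DEFAULT_CLOSE_THRESHOLD_BP
) -> dict[str, list[ArrayAssignment]]:
    """Per-genome array-to-locus assignments keyed by genome_id."""
    return {g.genome_id: assign_arrays(g, close_threshold_bp) for g in cohort}


def _subsample_arrays(cohort, assignments, cap, include_orphans, rng):
    """Seeded subsample for the quadratic repeat-space stage, stratified by type."""
    pool = []
    for genome in cohort:
        by_id = {a.array_id: a for a in assignments[genome.genome_id]}
        for arr in genome.arrays:
            asn = by_id[arr.array_id]
            if asn.side == "orphan" and not include_orphans:
                continue
            pool.append((asn.assigned_type, arr))
    if len(pool) <= cap:
        return [arr for _, arr in pool]
    by_type: dict[str, list] = {}
    for t, arr in pool:
        by_type.setdefault(t, []).append(arr)
    frac = cap / len(pool)
    chosen = []
    for t in sorted(by_type):
        members = by_type[t]
        take = max(1, int(round(frac * len(members))))
        idx = rng.choice(len(members), size=min(take, len(members)), replace=False)
        chosen.extend(members[i] for i in sorted(idx))
    return chosen[:cap]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every analysis stage and write the report directory."""
    out = Path(config.output_dir)
    if config.generator_spec is not None:
        cohort, _truth = generate_cohort(config.generator_spec)
    else:
        for p in (config.arrays_path, config.loci_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        cohort = read_cohort(config.arrays_path, config.loci_path)
    out.mkdir(parents=True, exist_ok=True)

    if config.exclude_possible:
        cohort = [filter_confidence(g, exclude_possible=True) for g in cohort]
        cohort = [g for g in cohort if g.arrays or g.loci]

    assignments = assign_cohort(cohort, config.close_threshold_bp)
    stage_counts = {
        "genomes": len(cohort),
        "arrays": sum(len(g.arrays) for g in cohort),
        "loci": sum(len(g.loci) for g in cohort),
        "orphan_arrays": sum(
            1 for asns in assignments.values() for a in asns if a.side == "orphan"
        ),
    }

    if config.generator_spec is not None:
        write_cohort(cohort, out / "arrays.tsv", out / "loci.tsv")

    # co-occurrence (orphans contribute no type by construction)
    cooc = cooccurrence_table(cohort, min_count=config.min_count, alpha=config.alpha)
    cooc.to_tsv(out / "cooccurrence.tsv")

    # geometry
    geo = geometry_table(cohort, assignments)
    pd.DataFrame([dataclasses.asdict(r) for r in geo]).to_csv(
        out / "geometry.tsv", sep="\t", index=False
    )
    distance_histogram(geo, DEFAULT_BIN_EDGES).to_csv(
        out / "geometry_histogram.tsv", sep="\t", index=False
    )
    pairs = pair_configurations(cohort, assignments)
    pd.DataFrame([dataclasses.asdict(r) for r in pairs]).to_csv(
        out / "pair_config.tsv", sep="\t", index=False
    )

    # census
    census = repeat_spacer_census(cohort, assignments)
    census_rows = [{"statistic": k, "value": v} for k, v in census.fractions().items()]
    census_rows.append({"statistic": "n_arrays", "value": census.n_arrays})
    census_rows.append({"statistic": "n_loci", "value": census.n_loci})
    pd.DataFrame(census_rows).to_csv(out / "census.tsv", sep="\t", index=False)
    census.arrays_per_locus_summary.to_csv(out / "arrays_per_locus.tsv", sep="\t", index=False)
    census.length_summary.to_csv(out / "length_by_proximity.tsv", sep="\t", index=False)

    # insertion-rate weights and matched null
    null_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = select_weight_genomes(cohort, assignments, config.k_values, same_repeat_only=False)
    records_to_frame(records).to_csv(out / "weights.tsv", sep="\t", index=False)
    null = neutral_distribution(records, null_rng)
    null_to_frame(null).to_csv(out / "null_weights.tsv", sep="\t", index=False)
    same_repeat = select_weight_genomes(
        cohort, assignments, config.k_values, same_repeat_only=True
    )
    records_to_frame(same_repeat).to_csv(out / "weights_same_repeat.tsv", sep="\t", index=False)

    # repeat space
    sub_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    subset = _subsample_arrays(
        cohort, assignments, config.subsample_cap, config.include_orphans_in_repeat_space, sub_rng
    )
    if len(subset) >= 2:
        dm = distance_matrix(subset, normalization=config.normalization)
        labels = dm.labels
        tri = [
            {"array_a": labels[i], "array_b": labels[j], "distance": dm.D[i, j]}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        pd.DataFrame(tri).to_csv(out / "distances.tsv", sep="\t", index=False)
        emb = mds_embed(
            dm,
            seed=config.seed,
            n_init=config.mds_n_init,
            max_iter=config.mds_max_iter,
            tol=config.mds_tol,
        )
        emb_df = pd.DataFrame(
            {"array_id": emb.labels, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
        )
        emb_df.attrs["stress"] = emb.stress
        with open(out / "embedding.tsv", "w") as fh:
            fh.write(f"# stress={emb.stress:.6g}\n")
            emb_df.to_csv(fh, sep="\t", index=False)
    else:
        (out / "distances.tsv").write_text("array_a\tarray_b\tdistance\n")
        (out / "embedding.tsv").write_text("# stress=0\narray_id\tx\ty\n")

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "stage_counts": stage_counts,
        "config": {
            k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(sorted(v)) if isinstance(v, frozenset) else repr(v))
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
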