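# Methods

This note documents the statistical procedures implemented in `casarray`,
the defaults they use, the design choices that were genuinely open, and what
the synthetic-data tests do and do not establish about real data.

## Annotation model and array-to-locus assignment

The unit of analysis is a genome: a set of Cas loci (subtype-labelled
intervals) and CRISPR arrays (intervals with a consensus repeat and an
ordered spacer list, leader-proximal first). Coordinates are 0-based
half-open everywhere; the distance between an array and a locus is the gap
between their nearest ends, `max(0, max(starts) - min(ends))`, so touching
or overlapping intervals are at distance 0 and are labelled `overlap`.

Each array is assigned to the locus with the smallest gap **on the same
sequence record** (cross-contig distances are meaningless); equidistant loci
are broken by smaller start coordinate, then lexicographic locus id, so
assignment is deterministic. Arrays in genomes without any Cas locus are
*orphans* with type `"no cas type"`; an array on a contig without loci while
the genome has Cas elsewhere is likewise treated as an orphan, since no
within-contig distance exists. Arrays with gap < 10 000 bp (default,
configurable) are *close*. Orphans are excluded from co-occurrence,
geometry, and weight analyses; they can optionally be included in the
repeat-space embedding.

Both `bona-fide` and `possible` confidence arrays are analysed by default;
`exclude_possible` restricts every denominator to `bona-fide`.

## Cas-type co-occurrence

With type counts $j_t$ over $n$ genomes, the independence null reshuffles
presence labels per type. Expected co-occurrence of two types is
$n\cdot(j/n)(k/n) = jk/n$ (the product $jkn^{-2}$ is the per-genome
probability; multiplying by $n$ converts it to a count, which a reshuffling
simulation confirms). Expected solo occurrence of $t$ is
$j_t \prod_{s\ne t}(1-j_s/n)$.

Observed/expected is reported as a signed fold-change: $+o/e$ when $o\ge e$,
$-e/o$ otherwise, so $|f|\ge 1$ and $f=+1$ at parity. An observed count of 0
makes the ratio undefined; the table then reports the lower bound $-e$ with
a `censored` flag. Solo cells are tested with an exact two-sided binomial
test (`scipy.stats.binomtest`, minimum-likelihood opposite tail) of the solo
count against $\mathrm{Binomial}(n, e_{\text{solo}}/n)$; sidedness is a
package choice. Cells are *reported* when observed or expected reaches 50
genomes (default), solo cells additionally when $p < 10^{-4}$ (default).
Pair p-values are computed the same way and exposed but do not gate pair
cells. No multiple-testing correction is applied — the gate is a fixed
alpha, not an FDR procedure.

## Locus geometry

Per non-orphan array: side (`before`/`after`/`overlap`), signed distance
(negative before, positive after, 0 overlap) and orientation. Histograms bin
absolute distance per side with default edges (0, 500, 2500, 5000,
10 000 bp) plus an open top bin and a dedicated overlap bin; `unknown`
orientation is kept as its own category, never merged.

Two-array configurations are classified only for genomes with exactly one
distinct Cas type and exactly two arrays: `flanking` / `both_before` /
`both_after`, with joint orientation `both_forward` / `both_reverse` /
`mixed` / `unknown`. For overlapping arrays the side is resolved by
comparing the array midpoint with the locus midpoint — an arbitrary but
stated tie-break for a case the data leave ambiguous.

## Redundancy census

Array-level fractions use all arrays as denominator: (a) having at least one
other array in the same genome with a byte-identical consensus repeat; and,
via same-repeat partners only, (b) sharing at least one spacer string, (c)
identical spacer *multisets* (duplicated spacers count), (d) identical
leader-distal (last) spacer — the spacer least likely to be deleted, hence
the most durable signal of common ancestry. Genome-wide (a) and the
locus-level fraction (loci with ≥ 2 assigned same-repeat arrays) are
deliberately separate statistics with different denominators. Repeats are
compared as exact strings; an optional flag folds reverse complements
(off by default, since consensus repeats are compared as reported).

Arrays-per-locus counts include zero-array loci by default (flag to
exclude). Length-by-proximity summarises spacer counts per (type, close)
cell, optionally restricted to arrays whose repeat matches a close array of
the same genome — the conditioning that isolates same-repeat families.

## Insertion-rate weights

See the README for the IDM derivation of $w_i = n_i/n$; the deletion rate
$\rho$ cancels and never needs a numeric value outside the generator. The
analysis keeps genomes with $k\in\{2,3,4\}$ in-scope arrays and excludes any
genome containing an orphan array. In the same-repeat scope the in-scope set
is the **largest** group of arrays sharing one consensus repeat (ties:
larger total spacer count, then lexicographic repeat) — the data do not
dictate a rule for multi-group genomes, so one is fixed for determinism.
Genomes whose arrays span several Cas types are pooled.

The neutral null draws one $\mathrm{Multinomial}(n,(1/k,\dots,1/k))/n$
sample per observed genome, matched on $(k,n)$, giving a null with exactly
the data's sample size. The per-$k$ summary reports the overall mean weight
(identically $1/k$; a bookkeeping check), close- and far-array mean weights,
and the observed/null variance ratio. Under the null the variance of one
weight is $(1/k)(1-1/k)/n$; heterogeneous per-array insertion rates inflate
the observed variance above it.

## Repeat space

Levenshtein distances between consensus repeats (uppercased; non-ACGT
symbols kept — edit distance is alphabet-agnostic) are computed with the
`edlib` C library and optionally normalized by the maximum repeat length in
the genome (`per_genome_max`) or in the full input scope (`global_max`).
Raw Levenshtein is a metric; normalized variants are used for comparability
of distributions, which are pooled within genomes and stratified by
arrays-per-genome.

Metric MDS uses an in-package SMACOF implementation (Guttman transform from
random initializations, best of `n_init` by final stress), which exposes the
per-iteration stress trajectory — raw stress, the residual sum of squares
between input dissimilarities and embedded Euclidean distances, is
guaranteed non-increasing per iteration and this is asserted in tests
against scikit-learn's `smacof` as an independent reference. Defaults:
`n_init = 4`, `max_iter = 300`, `tol = 1e-4` (absolute stress decrease);
exactly 2-D-embeddable configurations reach numerically zero stress with a
tighter tolerance. A single point embeds at the origin with stress 0;
non-finite dissimilarities are rejected.

The full pairwise problem is quadratic in the number of arrays, so the
pipeline embeds a seeded, type-stratified subsample (default cap 2000
arrays); the cap and seed are configuration. KDE marginals of embedding
coordinates use `scipy.stats.gaussian_kde` with Scott's-rule bandwidth;
all-identical inputs are rejected (zero bandwidth) with guidance.

## Synthetic cohort generator

The generator emulates annotation tables of large genome surveys, with
ground truth for recovery tests. Per genome: a Cas-type set, one locus per
present type, arrays per locus, placements, lengths, repeats, duplications,
orphans. Defaults encode a realistic study condition:

- **type frequencies** `I-E 0.30, I-F 0.20, III-A 0.10, II-C 0.08, V-A 0.06,
  II-A 0.05` — the dominant types in large surveys, in their observed
  ranking;
- **arrays per locus** `{1: .65, 2: .25, 3: .08, 4: .02}` (mean 1.47,
  matching the ~1.5 arrays/locus regime);
- **lengths** Poisson($\theta/\rho$) with per-type $\theta$ between 8
  (V-A) and 25 (I-F) at $\rho=1$, spanning the reported per-type means;
  zero draws are resampled to ≥ 1 spacer (arrays must contain a spacer)
  and flagged in the truth record;
- **placement**: 80 % near (exponential gap, mean 800 bp, < 10 kb), else
  far (uniform 100–500 kb); `p_after = 0.7`, `p_forward = 0.8`, 5 %
  unknown orientation — close-and-forward bias with a far reverse tail;
- **repeats**: a fixed type-specific ancestral repeat mutated per site at
  2 % per array; **duplications** (15 % per locus) copy the repeat and a
  leader-distal spacer suffix; **orphans** at 10 % per genome;
- genome length 4 Mb, loci ≥ 50 kb apart, collisions re-drawn within the
  same near/far window (cap 100, then error).

Pairwise type dependence is injected by conditional Bernoulli sampling: a
multiplier $m$ on (A, B) sets the joint probability to $m f_A f_B$ (clipped
to the Fréchet-feasible range, error if above the smaller marginal) while
preserving both marginals. Spacers are 32-nt strings whose 8-nt prefix
encodes a per-genome counter — collision-free by construction; the analyses
use string identity only.

**What the generator does not emulate:** phylogenetic correlation between
genomes, taxonomy-specific repeat/leader structure, PAM or secondary
structure in spacers, plasmid dynamics, detection-tool error modes, or
misclassified CRISPR-like elements. Passing recovery tests therefore shows
the estimators are correct under the stated model, not that real annotation
pipelines are unbiased.

## Problem sizes and numerics

Tests and reference checks use cohorts of 150–20 000 genomes chosen so each
statistic has the power its check needs: 20 000 genomes for co-occurrence
fold-change recovery (expected pair counts ≥ 50 under 5 % frequencies),
2 500 single-type genomes for acquisition-bias detection, 10 000 draws for
sampler moments, 200-genome cohorts for exact brute-force cross-checks.
Monte-Carlo assertions use 3-standard-error bands throughout. Weight vectors
are validated to sum to 1 within 1e-12; exact embeddings are accepted below
stress 1e-6 and distance error 1e-3.

## Known limitations

- The co-occurrence null ignores phylogeny: closely related genomes are not
  independent draws, so real-data fold-changes conflate ecology and shared
  ancestry.
- The IDM weight estimate is a point estimate per genome; no uncertainty is
  propagated to the weight distributions beyond the matched null.
- Same-repeat grouping uses exact string identity; near-identical repeats
  (1–2 substitutions) form separate groups, understating redundancy.
- The SMACOF embedding is a local optimum; multiple initializations reduce
  but do not eliminate sensitivity for large, high-stress inputs.
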