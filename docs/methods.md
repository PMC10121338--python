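# Methods

This note records the statistical model, the algorithmic choices, and the
places where the design was genuinely open, in the order the pipeline runs.

## Per-individual association statistics

Expression values are standardized per gene with the sample mean and sample
standard deviation (ddof = 1) estimated on the **pooled** population (both
classes together, the default; a per-class option exists via subsetting).
Pooled moments keep the two network collections on a common scale — a gene
pair scored in a case and in a control individual is judged against the same
reference distribution, which is what makes the two network sets comparable.
Zero-variance genes are flagged and excluded from network construction.

**Strength.** The observed standardized pair (z_i, z_j) is modeled as a
single draw from a standard bivariate normal with unknown correlation ρ; the
strength is the ρ maximizing the density at the observation. Differentiating
the log-density and clearing denominators gives the cubic

ρ³ − z_i z_j ρ² + (z_i² + z_j² − 1) ρ − z_i z_j = 0,

which has at least one root in (−1, 1) whenever z_i ≠ ±z_j (the cubic is
−(z_i+z_j)² at ρ = −1 and +(z_i−z_j)² at ρ = +1). The implementation solves
the cubic in closed form (vectorized trigonometric/Cardano method) and picks
the real root with maximal log-density. Degenerate cases, handled exactly:

* z_i = z_j ≠ 0 → the density diverges as ρ → 1; strength 1. Mirror case
  z_i = −z_j ≠ 0 → −1.
* z_i = z_j = 0 → the density diverges at both boundaries; strength 0 by
  convention (no information).
* z_i z_j = 0 with 0 < |z| < 1 → two maximizers ±√(1−z²) with equal density;
  the non-negative root is returned. The sign-flip identity
  strength(z_i, −z_j) = −strength(z_i, z_j) therefore holds everywhere except
  on this measure-zero tie family, and the test suite asserts exactly that.

Near-degenerate pairs push the maximizer within floating-point distance of
±1; roots are clipped into [−1+10⁻¹², 1−10⁻¹²] before density rating so the
returned strength degrades continuously instead of falling to a wrong root.

**Relevance.** The null model draws the other gene's value Z from its
standard-normal marginal, conditioning on the fixed margin:
tail(z, ρ̃) = P(strength(z, Z) < ρ̃), and relevance = min of the two tails
with ρ̃ the pair's strength. strength(z, ·) is *not* monotone — it rises to
+1 at Z = z, falls toward 0 like z/Z in both tails, and passes through −1 at
Z = −z — so the tail is computed by locating every level crossing of
strength(z, ·) = ρ̃ on a dense grid (2001 points over ±9, plus the exact
peaks ±z), refining each crossing by bisection to 10⁻⁸, and summing the
Gaussian measure of the sub-level intervals. A Monte-Carlo estimator over
i.i.d. null draws is kept as the independent oracle; the two agree within
three MC standard errors at 10⁵ draws in the acceptance checks.

For all-pairs network construction the same quantity is evaluated through a
stratified-quantile quadrature (`TailTable`): the null margin is represented
by 20 001 equal-probability-mass points, each gene's strength row is sorted
once, and a tail becomes a binary search — exact to ~5·10⁻⁵ in probability
and orders of magnitude faster than per-pair bisection. Both routes are
exposed (`relevance_method="quadrature" | "bisection"`) and agree in tests.

## Networks, patterns, incidence

An individual's network keeps the edges with relevance strictly greater than
τ_r (default 0.9) over the shared gene universe. Edge weights must lie in
[0, 1] for match values to do so; the mapping from strength is configurable:
`clamp` (max(ρ̃, 0), the default — negative associations carry no weight),
`abs`, or `affine` ((ρ̃+1)/2). Under the null about 10% of pairs pass
τ_r = 0.9, so individual networks are sparse but not empty; this background
rate is what the discriminative scoring must overcome.

Incidence at x% uses n_x = ⌈x/100 · n⌉ (ceiling, so n_x ≥ 1), taken of each
population's own size when per-population incidences feed the entropy
formulas. A null incidence is represented as 0 with an explicit flag so the
downstream arithmetic always receives a number. Ties among match values are
broken by sample identifier; since only the top-n_x *sum* is used, the
tie-break affects nothing but determinism of the bookkeeping.

## Scoring

Entropies default to base 2 (bits); rankings are base-invariant (verified on
random instances). Power comparisons use an equality tolerance of 10⁻¹² for
the tie branch of the discriminative test; the tie-break incidence ŝ(P) is
the total over both populations (a guiding-only variant is configurable).
The discriminative test enumerates all proper connected subpatterns
exhaustively up to 12 edges (≤ 4096 subsets, connectivity-filtered), beyond
which only single-edge-removal subpatterns are checked.

**Direction.** The conditional entropy H(N | P) is exactly invariant under
simultaneously swapping the two populations together with their incidences
(q₁ ↦ 1−q₁ and q₂ ↦ 1−q₂ leave the binary entropies unchanged), so the gain
alone cannot distinguish a case-characterizing pattern from a
control-characterizing one. The package therefore makes the direction
explicit in two places: seeds come only from edges of the guiding
population's networks, and a pattern enters the result set only when its
incidence *rate* at x% in the guiding population is at least the other's
(ŝ₁/|N₁| ≥ ŝ₂/|N₂|). The search itself is not restricted by the second
condition — a superpattern of a non-enriched pattern can become enriched when
the added edge kills the other population's support. With both in place,
mining "cases guide" and "controls guide" return genuinely different,
population-specific result sets.

**Upper bound.** Branch pruning needs U(P) ≥ pow(P′) for every superpattern
P′. Support is anti-monotone under extension, so per population a
superpattern's incidence at x% lies in [0, n_x] when P's support reaches n_x
and is identically 0 otherwise; match values never exceed 1. U is H(N) minus
the minimum conditional entropy over that feasible box, found by a vectorized
grid (step 0.01 · max(c₁, c₂, 1)) with two zoom rounds; the box corners and
P's own profile are always evaluated exactly, which guarantees U ≥ pow(P).
Admissibility is not proven for the grid minimum in general, so it is
*verified*: exhaustive superpattern enumeration on small instances, and exact
equality of pruned and unpruned mining with the brute-force reference.

## Search

Depth-first from every seed edge, extensions ranked by decreasing raw
incidence over all networks (configurable to guiding-only or ŝ-at-x%), ties
by canonical key — the canonical key of a pattern being its sorted,
endpoint-sorted edge list. A global visited set prevents combinatorial
re-expansion of patterns reachable by multiple extension orders; this is
sound because a branch is only cut when an ancestor's power exceeds the
bound, a certificate independent of the path taken.

Two pruning rules:

* **Bound gate** (default on): an extension whose upper bound is below the
  power of the pattern it extends is not recursed into — any deeper pattern
  would fail the discriminative test against that ancestor.
* **Null-branch cut**: a pattern whose support is below n_x in *both*
  populations is never extended. Every superpattern then has ŝ₁ = ŝ₂ = 0,
  hence power 0 and a total-incidence tie it cannot win against its own
  subpatterns, so none can be discriminative. This cut is what keeps the
  search tractable on dense chance background.

`cascade_prune` (skip all lower-ranked siblings once one fails the bound
gate) assumes the bound is monotone in the ranking metric; that assumption
failed on 1 of 100 random instances, so the flag is off by default and
documented as a heuristic.

Determinism: with a fixed input and configuration, two runs produce
byte-identical outputs (sorted seeds, sorted extensions, canonical keys,
12-significant-digit serialization).

## Synthetic data

The generator draws each population from a multivariate normal whose
correlation matrix is block-structured: planted modules get a
population-specific within-module correlation on top of a background
correlation (0 by default); per-gene means (uniform 6–10) and SDs (uniform
0.8–1.6) are drawn once and shared by both populations, so the planted signal
is purely co-expressional. Covariance positive-definiteness is validated at
build time, naming the offending module. The master seed spawns independent
substreams for gene parameters and for each population, so resizing one
population leaves the other's draws unchanged.

The standard scenario — 30 genes, one 4-gene module at ρ = 0.9 vs 0.0,
40 + 40 samples, τ_r = 0.9, x = 20, k = 20 — is the package's end-to-end
benchmark: across 10 replicates the case-guided direction recovers ≥ 80% of
planted pairs in at least 9, while the control-guided direction recovers at
most 20%. What the generator does *not* emulate: count noise (RNA-seq
negative binomial), batch effects, outlier samples, correlated background
blocks, or realistic gene numbers — passing recovery here shows the chain of
definitions works end to end at desk scale, not that the method's operating
characteristics transfer to any particular real dataset.

## Problem sizes and other numerical choices

Oracle-equivalence checks run on random instances with ≤ 8 nodes,
≤ 10 networks and patterns capped at 4 nodes, where exhaustive enumeration is
exact and fast; the recovery benchmark runs the full 30-gene scenario. These
sizes make the whole verification suite run in minutes on a single core while
exercising every code path; larger runs change cost, not logic. Bisection
tolerances are 10⁻⁸ in z, quadrature resolution 5·10⁻⁵ in probability,
bound-grid step 1% of the box, all per above.

## Known limitations

* The strength/relevance statistics are bivariate-normal likelihood
  constructions; heavy-tailed or rank-based alternatives are out of scope.
* The null model for relevance (standard-normal draw for the free margin,
  fixed margin conditioned on) is one defensible reading of "not due to
  chance given an expression level"; others (e.g. joint nulls) would change
  edge densities.
* The guiding-enrichment rule is this package's resolution of the direction
  semantics (see Scoring); disable `require_guiding_enrichment` to get the
  purely gain-ranked, direction-symmetric behaviour.
* Exactly two populations; multi-class extensions would need a different
  entropy decomposition.
* All-pairs network construction is O(genes² · samples); use the gene
  sub-listing / top-variance pre-filter for large matrices.
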