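"""Entropy-based discriminative scoring of patterns.

A pattern discriminates between the two populations to the extent that its
per-population incidences at x% induce an information gain over the class
entropy of the pooled network collection:

    pow(P) = H(N) - H(N | P)

with H(N) the binary entropy of the population split and H(N | P) the
incidence-weighted mixture of the entropies of the "contains P" and "does not
contain P" parts.  The mixture weights are real-valued because incidences are
sums of match values, not counts.  The definition is asymmetric: the first
population guides, and the reverse direction is obtained by swapping the two
populations.

A pattern is *discriminative* when its power strictly exceeds that of every
proper connected subpattern (with an incidence tie-break), and *maximal* when
no other discriminative pattern strictly contains it.

For search-space pruning an admissible upper bound on the power of all
superpatterns of P is computed from a feasible box of their reachable
incidence-at-x% values: a superpattern's support can only shrink, so its
incidence at x% lies in [0, n_x] per population (and is identically 0 where
P's own support is already below n_x).  The bound is H(N) minus the minimum
conditional entropy over that box, located by a vectorized grid search with
iterative zoom plus the box corners and P's own profile.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .wiga import (
    IncidenceProfile,
    NetworkSet,
    Pattern,
    connected_subpatterns,
    incidence_profile,
    is_subpattern,
)

__all__ = [
    "ScoredPattern",
    "population_entropy",
    "conditional_entropy",
    "discriminative_power",
    "power_upper_bound",
    "is_discriminative",
    "is_maximal",
    "score_pattern",
]

POW_TOL = 1e-12  # equality tolerance for power comparisons (floating-point ties)


def _binary_entropy(p: np.ndarray, base: float) -> np.ndarray:
    """-(p log p + (1-p) log(1-p)) with 0 log 0 = 0, in the given base."""
    p = np.asarray(p, float)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        out = out - np.where(mask, q * np.log(np.where(mask, q, 1.0)), 0.0)
    return out / np.log(base)


def population_entropy(n1: int, n2: int, base: float = 2.0) -> float:
    """Class entropy of the two-population split (bits by default)."""
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise ValueError(f"invalid population sizes: {n1}, {n2}")
    return float(_binary_entropy(n1 / (n1 + n2), base))


def conditional_entropy(s1_hat, s2_hat, n1: int, n2: int, base: float = 2.0):
    """Entropy of the class split given a pattern with incidences (s1_hat, s2_hat).

    q  = (s1 + s2) / n        weight of the "contains the pattern" part
    q1 = s1 / (s1 + s2)       class-1 share inside that part
    q2 = (n1 - s1) / ((n1 - s1) + (n2 - s2))   class-1 share outside

    Accepts scalars or arrays (vectorized over the incidence box).  The s=0
    and s=n corner cases contribute zero through their vanishing weights.
    """
    s1 = np.asarray(s1_hat, float)
    s2 = np.asarray(s2_hat, float)
    if np.any(s1 < -1e-9) or np.any(s2 < -1e-9) or np.any(s1 > n1 + 1e-9) or np.any(s2 > n2 + 1e-9):
        raise ValueError("incidence outside [0, population size]")
    s1 = np.clip(s1, 0.0, n1)
    s2 = np.clip(s2, 0.0, n2)
    n = n1 + n2
    tot = s1 + s2
    rest = (n1 - s1) + (n2 - s2)
    q = tot / n
    with np.errstate(divide="ignore", invalid="ignore"):
        q1 = np.where(tot > 0, s1 / np.where(tot > 0, tot, 1.0), 0.0)
        q2 = np.where(rest > 0, (n1 - s1) / np.where(rest > 0, rest, 1.0), 0.0)
    h_in = np.where(tot > 0, _binary_entropy(q1, base), 0.0)
    h_out = np.where(rest > 0, _binary_entropy(q2, base), 0.0)
    out = h_in * q + h_out * (1.0 - q)
    return float(out) if np.isscalar(s1_hat) and np.isscalar(s2_hat) else out


def _oriented(profile: IncidenceProfile, networkset: NetworkSet, direction: str):
    if direction == "forward":
        return profile.s_hat1, profile.s_hat2, len(networkset.n1), len(networkset.n2)
    if direction == "reverse":
        return profile.s_hat2, profile.s_hat1, len(networkset.n2), len(networkset.n1)
    raise ValueError(f"direction must be 'forward' or 'reverse': {direction!r}")


def discriminative_power(
    pattern: Pattern,
    networkset: NetworkSet,
    x: float = 20.0,
    direction: str = "forward",
    base: float = 2.0,
    profile: IncidenceProfile | None = None,
) -> float:
    """Information gain H(N) - H(N|P); ``direction='reverse'`` swaps the populations."""
    if profile is None:
        profile = incidence_profile(pattern, networkset, x)
    s1, s2, n1, n2 = _oriented(profile, networkset, direction)
    return population_entropy(n1, n2, base) - conditional_entropy(s1, s2, n1, n2, base)


def _min_conditional_entropy(
    c1: float, c2: float, n1: int, n2: int, base: float,
    grid_step: float = 0.01, extra_points=(),
) -> float:
    """Minimum of the conditional entropy over the box [0, c1] x [0, c2].

    Vectorized grid (step <= grid_step * max(c1, c2, 1)) with two zoom
    rounds; corners and any ``extra_points`` are always evaluated exactly.
    """
    corners1 = np.array([0.0, c1])
    corners2 = np.array([0.0, c2])
    g1, g2 = np.meshgrid(corners1, corners2)
    best = float(np.min(conditional_entropy(g1, g2, n1, n2, base)))
    for s1, s2 in extra_points:
        best = min(best, float(conditional_entropy(s1, s2, n1, n2, base)))

    step = grid_step * max(c1, c2, 1.0)
    lo1, hi1, lo2, hi2 = 0.0, c1, 0.0, c2
    for _ in range(3):
        a1 = np.linspace(lo1, hi1, max(int(round((hi1 - lo1) / step)) + 1, 2)) if hi1 > lo1 else np.array([lo1])
        a2 = np.linspace(lo2, hi2, max(int(round((hi2 - lo2) / step)) + 1, 2)) if hi2 > lo2 else np.array([lo2])
        g1, g2 = np.meshgrid(a1, a2, indexing="ij")
        vals = conditional_entropy(g1, g2, n1, n2, base)
        k = int(np.argmin(vals))
        i, j = np.unravel_index(k, vals.shape)
        best = min(best, float(vals[i, j]))
        # zoom around the best grid point
        lo1 = max(0.0, float(a1[max(i - 1, 0)]))
        hi1 = min(c1, float(a1[min(i + 1, len(a1) - 1)]))
        lo2 = max(0.0, float(a2[max(j - 1, 0)]))
        hi2 = min(c2, float(a2[min(j + 1, len(a2) - 1)]))
        step /= 10.0
    return best


def power_upper_bound(
    pattern: Pattern,
    networkset: NetworkSet,
    x: float = 20.0,
    direction: str = "forward",
    base: float = 2.0,
    profile: IncidenceProfile | None = None,
    grid_step: float = 0.01,
) -> float:
    """Admissible upper bound on pow(P') over all superpatterns P' of P.

    A superpattern occurs in a subset of P's networks (support anti-monotone),
    so per population its incidence at x% is either null (when P's support is
    already below n_x) or at most n_x (match values are bounded by 1).  The
    bound maximizes the gain over that feasible box; P's own profile sits in
    the box, so U(P) >= pow(P) holds by construction.
    """
    if profile is None:
        profile = incidence_profile(pattern, networkset, x)
    s1, s2, n1, n2 = _oriented(profile, networkset, direction)
    if direction == "forward":
        sup1, sup2 = profile.support1, profile.support2
        nx1, nx2 = profile.n_x1, profile.n_x2
    else:
        sup1, sup2 = profile.support2, profile.support1
        nx1, nx2 = profile.n_x2, profile.n_x1
    c1 = float(min(nx1, sup1)) if sup1 >= nx1 else 0.0
    c2 = float(min(nx2, sup2)) if sup2 >= nx2 else 0.0
    h_min = _min_conditional_entropy(
        c1, c2, n1, n2, base, grid_step=grid_step, extra_points=[(s1, s2)]
    )
    return population_entropy(n1, n2, base) - h_min


def is_discriminative(
    pattern: Pattern,
    networkset: NetworkSet,
    x: float = 20.0,
    direction: str = "forward",
    base: float = 2.0,
    exhaustive_limit: int = 12,
    profile_cache: dict | None = None,
    profiler=None,
) -> bool:
    """Power strictly exceeds (or ties with larger total incidence-at-x%) every
    proper connected subpattern's.

    Subpatterns are enumerated exhaustively up to ``exhaustive_limit`` edges;
    beyond that only single-edge-removal subpatterns are checked (logged
    caveat in the caller).  Single-edge patterns are vacuously discriminative.
    """
    if len(pattern.edges) == 1:
        return True
    pow_p, prof_p = _cached_pow(pattern, networkset, x, direction, base, profile_cache, profiler)
    if len(pattern.edges) <= exhaustive_limit:
        subs = connected_subpatterns(pattern, proper=True)
    else:
        subs = []
        for e in pattern.edges:
            rest = tuple(se for se in pattern.edges if se != e)
            try:
                subs.append(Pattern(edges=rest))
            except ValueError:
                continue  # removal disconnects; not a pattern
    for sub in subs:
        pow_s, prof_s = _cached_pow(sub, networkset, x, direction, base, profile_cache, profiler)
        if pow_p > pow_s + POW_TOL:
            continue
        if abs(pow_p - pow_s) <= POW_TOL and prof_p.s_hat_total > prof_s.s_hat_total:
            continue
        return False
    return True


def _cached_pow(pattern, networkset, x, direction, base, cache, profiler=None):
    key = (pattern.key, direction)
    if cache is not None and key in cache:
        return cache[key]
    prof = profiler(pattern) if profiler is not None else incidence_profile(pattern, networkset, x)
    powv = discriminative_power(pattern, networkset, x, direction, base, profile=prof)
    if cache is not None:
        cache[key] = (powv, prof)
    return powv, prof


def is_maximal(pattern: Pattern, patterns) -> bool:
    """No strict superpattern of ``pattern`` inside the collection."""
    return not any(
        other.edges != pattern.edges and is_subpattern(pattern, other, strict=True)
        for other in patterns
    )


@dataclasses.dataclass(frozen=True)
class ScoredPattern:
    """A pattern with its incidence profile, power and pruning bound."""

    pattern: Pattern
    profile: IncidenceProfile
    pow: float
    upper_bound: float
    direction: str

    def __post_init__(self) -> None:
        if self.upper_bound < self.pow - 1e-9:
            raise ValueError(
                f"upper bound {self.upper_bound} below the pattern's own power {self.pow}"
            )


def score_pattern(
    pattern: Pattern,
    networkset: NetworkSet,
    x: float = 20.0,
    direction: str = "forward",
    base: float = 2.0,
    grid_step: float = 0.01,
    profile: IncidenceProfile | None = None,
) -> ScoredPattern:
    if profile is None:
        profile = incidence_profile(pattern, networkset, x)
    powv = discriminative_power(pattern, networkset, x, direction, base, profile=profile)
    upper = power_upper_bound(
        pattern, networkset, x, direction, base, profile=profile, grid_step=grid_step
    )
    return ScoredPattern(
        pattern=pattern, profile=profile, pow=powv,
        upper_bound=max(upper, powv), direction=direction,
    )
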