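"""Per-pair, per-individual association statistics.

For one individual, the observed expression pair of two genes is a *single*
draw from a bivariate normal whose margins are the genes' population
distributions.  The **strength** of the association is the correlation value
that maximizes the bivariate-normal density at that single standardized
observation (a single-observation MLE of the correlation).  Its **relevance**
is a per-edge significance: the probability, under a standard-normal null for
the other gene, of observing a smaller strength, minimized over the two
conditioning directions.

Writing z_i, z_j for the standardized pair, the log-density as a function of
the correlation rho is

    l(rho) = -1/2 log(1 - rho^2) - (z_i^2 - 2 rho z_i z_j + z_j^2) / (2 (1 - rho^2))

up to constants.  Setting dl/drho = 0 and clearing denominators yields the
cubic stationarity condition

    rho^3 - z_i z_j rho^2 + (z_i^2 + z_j^2 - 1) rho - z_i z_j = 0 ,

which always has a real root in (-1, 1) when z_i != +/- z_j (the cubic is
negative at -1 and positive at +1).  When z_i = z_j != 0 the density diverges
as rho -> 1 (strength 1); when z_i = -z_j != 0 it diverges as rho -> -1
(strength -1); at (0, 0) the density diverges at both boundaries and the
strength is 0 by convention.  A second degenerate family is z_i z_j = 0 with
0 < |z| < 1, where +sqrt(1 - z^2) and -sqrt(1 - z^2) attain equal density:
the non-negative root is returned.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset

__all__ = [
    "GeneStats",
    "AssociationScore",
    "estimate_gene_stats",
    "strength",
    "strength_vec",
    "strength_grid_oracle",
    "strength_tail_given_margin",
    "relevance",
    "TailTable",
]

_EQ_TOL = 0.0  # z_i == z_j is an exact comparison: the boundary cases are exact identities


@dataclasses.dataclass(frozen=True)
class GeneStats:
    """Per-gene mean and standard deviation plus the retained gene list.

    Genes with zero variance (or all-equal values) are listed in
    ``zero_variance`` and must be excluded from network construction.
    """

    genes: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if np.any(self.sd[np.isin(self.genes, self.zero_variance, invert=True)] <= 0):
            raise ValueError("retained genes must have positive standard deviation")

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if g not in self.zero_variance)

    def standardize(self, values: pd.Series | Mapping, genes: tuple[str, ...]) -> np.ndarray:
        """Standardize one sample's expression tuple over ``genes``."""
        idx = {g: i for i, g in enumerate(self.genes)}
        pos = np.array([idx[g] for g in genes])
        x = np.array([float(values[g]) for g in genes])
        return (x - self.mean[pos]) / self.sd[pos]


@dataclasses.dataclass(frozen=True)
class AssociationScore:
    """Strength and relevance of one gene pair for one individual."""

    strength: float
    relevance: float
    z_i: float
    z_j: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.strength <= 1.0:
            raise ValueError(f"strength out of [-1, 1]: {self.strength}")
        if not 0.0 <= self.relevance <= 1.0:
            raise ValueError(f"relevance out of [0, 1]: {self.relevance}")


def estimate_gene_stats(dataset: ExpressionDataset, moments: str = "pooled") -> GeneStats:
    """Per-gene sample mean and SD (ddof=1).

    ``moments='pooled'`` (default) estimates on all samples of both classes so
    the two network sets are standardized identically; ``'per-class'`` is not
    handled here — callers wanting per-class moments estimate on a class subset.
    Constant genes are flagged in ``zero_variance``, not dropped from the record.
    """
    if moments != "pooled":
        raise ValueError("estimate_gene_stats computes pooled moments; subset the dataset for per-class")
    vals = dataset.values.to_numpy(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero = tuple(g for g, s in zip(dataset.genes, sd) if not s > 0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return GeneStats(genes=tuple(dataset.genes), mean=mean, sd=sd_safe, zero_variance=zero)


# ---------------------------------------------------------------------------
# strength


def strength_vec(z_i, z_j) -> np.ndarray:
    """Vectorized strength: MLE correlation for standardized pairs.

    Solves the stationarity cubic with the trigonometric/Cardano method and
    picks, among real roots in (-1, 1), the one with maximal log-density;
    exact boundary identities (z_i = +/- z_j) are handled first.
    """
    z_i = np.asarray(z_i, float)
    z_j = np.asarray(z_j, float)
    z_i, z_j = np.broadcast_arrays(z_i, z_j)
    if not (np.all(np.isfinite(z_i)) and np.all(np.isfinite(z_j))):
        raise ValueError("non-finite standardized value")
    m = z_i * z_j
    s = z_i * z_i + z_j * z_j

    # cubic rho^3 + b rho^2 + c rho + d with b = -m, c = s - 1, d = -m
    b = -m
    c = s - 1.0
    d = -m
    # depressed cubic t^3 + p t + q, rho = t - b/3
    p = c - b * b / 3.0
    q = 2.0 * b**3 / 27.0 - b * c / 3.0 + d
    shift = -b / 3.0

    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    roots = np.full(z_i.shape + (3,), np.nan)

    one = disc > 0
    if np.any(one):
        sq = np.sqrt(disc[one])
        u = np.cbrt(-q[one] / 2.0 + sq)
        v = np.cbrt(-q[one] / 2.0 - sq)
        roots[one, 0] = u + v + shift[one]

    three = ~one
    if np.any(three):
        pp = p[three]
        qq = q[three]
        r = np.sqrt(np.maximum(-pp / 3.0, 0.0))
        # theta in [0, pi]; clip guards rounding at disc ~ 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cosarg = np.where(r > 0, -qq / (2.0 * r**3), 1.0)
        theta = np.arccos(np.clip(cosarg, -1.0, 1.0))
        for k in range(3):
            roots[three, k] = 2.0 * r * np.cos((theta - 2.0 * np.pi * k) / 3.0) + shift[three]

    # rate real roots by log-density; near-degenerate pairs (z_i ~ +/- z_j) push the
    # maximizer arbitrarily close to +/-1, so roots are clipped into the open
    # interval rather than discarded
    finite = np.isfinite(roots)
    clipped = np.clip(roots, -1.0 + 1e-12, 1.0 - 1e-12)
    ld = np.full_like(roots, -np.inf)
    if np.any(finite):
        rr = clipped[finite]
        om = 1.0 - rr * rr
        zi3 = np.broadcast_to(z_i[..., None], roots.shape)[finite]
        zj3 = np.broadcast_to(z_j[..., None], roots.shape)[finite]
        ld[finite] = -0.5 * np.log(om) - (zi3 * zi3 - 2.0 * rr * zi3 * zj3 + zj3 * zj3) / (2.0 * om)
    best = np.take_along_axis(clipped, np.argmax(ld, axis=-1)[..., None], axis=-1)[..., 0]
    any_finite = finite.any(axis=-1)
    best = np.where(any_finite, best, 0.0)

    # degenerate tie z_i z_j = 0: the +/- roots have equal density; take the non-negative one
    tie = (m == 0) & any_finite
    best = np.where(tie, np.abs(best), best)

    # exact boundary identities override
    best = np.where((z_i == z_j) & (z_i != 0), 1.0, best)
    best = np.where((z_i == -z_j) & (z_i != 0), -1.0, best)
    best = np.where((z_i == 0) & (z_j == 0), 0.0, best)
    return best


def strength(z_i: float, z_j: float) -> float:
    """Strength of the association for one standardized pair; in [-1, 1]."""
    return float(strength_vec(float(z_i), float(z_j)))


def strength_grid_oracle(z_i: float, z_j: float, step: float = 1e-4) -> float:
    """Dense-grid maximization of the log-density over rho (test oracle)."""
    if z_i == z_j:
        return 1.0 if z_i != 0 else 0.0
    if z_i == -z_j:
        return -1.0 if z_i != 0 else 0.0
    rho = np.arange(-1.0 + step, 1.0, step)
    om = 1.0 - rho * rho
    ld = -0.5 * np.log(om) - (z_i * z_i - 2.0 * rho * z_i * z_j + z_j * z_j) / (2.0 * om)
    r = float(rho[int(np.argmax(ld))])
    if z_i * z_j == 0 and r < 0:
        r = -r  # symmetric tie; same convention as strength()
    return r


# ---------------------------------------------------------------------------
# relevance


def strength_tail_given_margin(
    z_fixed: float,
    rho_hat: float,
    method: str = "root_inversion",
    mc_draws: int = 10_000,
    seed: int | None = None,
    z_span: float = 9.0,
    grid_points: int = 2001,
    tol: float = 1e-8,
) -> float:
    """P(strength(z_fixed, Z) < rho_hat) with Z a standard-normal null draw.

    ``root_inversion`` locates every level crossing of
    strength(z_fixed, .) = rho_hat on a dense z-grid (the function is
    piecewise monotone with at most a handful of crossings), refines each by
    bisection to ``tol``, and sums the Gaussian measure of the sub-level
    intervals.  ``monte_carlo`` averages the indicator over ``mc_draws``
    i.i.d. draws and serves as the independent oracle.
    """
    if not np.isfinite(z_fixed) or not np.isfinite(rho_hat):
        raise ValueError("non-finite input")
    if not -1.0 <= rho_hat <= 1.0:
        raise ValueError(f"rho_hat out of [-1, 1]: {rho_hat}")
    if rho_hat <= -1.0:
        return 0.0
    if rho_hat >= 1.0:
        return 1.0

    if method == "monte_carlo":
        if mc_draws < 100:
            raise ValueError("mc_draws must be >= 100")
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(mc_draws)
        return float(np.mean(strength_vec(z_fixed, z) < rho_hat))
    if method != "root_inversion":
        raise ValueError(f"unknown method: {method!r}")

    # include the exact peaks +/- z_fixed so the boundary identities anchor the grid
    grid = np.linspace(-z_span, z_span, grid_points)
    extra = np.array([z_fixed, -z_fixed, 0.0])
    grid = np.unique(np.concatenate([grid, extra[np.abs(extra) <= z_span]]))
    f = strength_vec(np.full_like(grid, z_fixed), grid) - rho_hat

    below = f < 0
    # crossings between consecutive grid points with opposite strict signs
    change = np.nonzero(below[:-1] != below[1:])[0]
    lo = grid[change].copy()
    hi = grid[change + 1].copy()
    lo_below = below[change].copy()
    for _ in range(64):
        if lo.size == 0 or np.all(hi - lo < tol):
            break
        mid = 0.5 * (lo + hi)
        fm = strength_vec(np.full_like(mid, z_fixed), mid) - rho_hat
        mid_below = fm < 0
        same = mid_below == lo_below
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)

    cuts = np.sort(0.5 * (lo + hi))
    # measure of {z : f(z) < 0}: walk the intervals delimited by the refined
    # cuts, classifying each by the grid signs already computed (f has constant
    # sign between consecutive refined crossings)
    bounds = np.concatenate([[-np.inf], cuts, [np.inf]])
    total = 0.0
    for a, b2 in zip(bounds[:-1], bounds[1:]):
        interior = below[(grid > a + tol) & (grid < b2 - tol)]
        if interior.size == 0:
            continue  # sliver narrower than the grid step: negligible measure
        if interior[interior.size // 2]:
            total += stats.norm.cdf(b2) - stats.norm.cdf(a)
    return float(min(max(total, 0.0), 1.0))


def relevance(
    z_i: float,
    z_j: float,
    method: str = "root_inversion",
    mc_draws: int = 10_000,
    seed: int | None = None,
) -> AssociationScore:
    """Strength plus relevance (min of the two conditional tail probabilities)."""
    rho = strength(z_i, z_j)
    t_i = strength_tail_given_margin(z_i, rho, method=method, mc_draws=mc_draws, seed=seed)
    t_j = strength_tail_given_margin(z_j, rho, method=method, mc_draws=mc_draws,
                                     seed=None if seed is None else seed + 1)
    return AssociationScore(strength=rho, relevance=min(t_i, t_j), z_i=z_i, z_j=z_j)


class TailTable:
    """Batch tail probabilities for a fixed set of standardized values.

    Stratified-quantile quadrature: the null margin is represented by ``cells``
    equal-probability-mass points z_k = Phi^-1((k + 1/2)/cells); for each fixed
    value the row strength(z_fixed, z_k) is sorted once, after which
    P(strength(z_fixed, Z) < rho) is a binary search, exact to ~1/cells in
    probability.  This is the workhorse behind all-pairs network construction.
    """

    def __init__(self, z_values: np.ndarray, cells: int = 20001):
        if cells < 100:
            raise ValueError("cells must be >= 100")
        self.z_values = np.asarray(z_values, float)
        self.cells = int(cells)
        zk = stats.norm.ppf((np.arange(cells) + 0.5) / cells)
        rows = strength_vec(self.z_values[:, None], zk[None, :])
        rows.sort(axis=1)
        self._sorted = rows

    def tail(self, i: int, rho_hat) -> np.ndarray:
        """P(strength(z_values[i], Z) < rho_hat); ``rho_hat`` may be an array."""
        pos = np.searchsorted(self._sorted[i], np.asarray(rho_hat, float), side="left")
        return pos / self.cells
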