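"""Two-phenotype binomial mixture exclusion model.

A cohort of ``N`` nominally phenotype-I embryos (anomalously reprogrammed,
term-development rate ``q1``) may hide an unknown fraction ``rho`` of
phenotype-II embryos (normally reprogrammed, rate ``q2``).  ``T`` of the
``N`` embryos developed to term.  The model bounds, for every admixture
fraction ``rho``, the probability that at least ``n`` of those ``T`` term
offspring derive from the hidden phenotype-II subpopulation, combined with
the evidence that ``k`` independently assayed embryos all showed the
phenotype-I modification state (probability ``(1 - rho)**k``).  The
exclusion bound is the worst case (maximum) of that product over
``rho in [0, 1]``.

Two interpretation strategies of the marginalization over the unknown
phenotype-II count ``m`` are provided (see :data:`STRATEGIES`); the default
``"total-conditioned"`` strategy treats the observed term total ``T`` as
given, so the phenotype-II-derived count follows the normalized marginal
distribution on ``0..T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

__all__ = [
    "RateEstimate",
    "MixtureQuery",
    "RhoProfile",
    "ExclusionResult",
    "NotExcludable",
    "estimate_rate",
    "concordance_evidence",
    "term_origin_pmf",
    "term_origin_tail",
    "combined_probability",
    "worst_case",
    "min_excludable_n",
    "rho_profile",
    "STRATEGIES",
]

STRATEGIES = ("total-conditioned", "literal-prose")
DEFAULT_STRATEGY = "total-conditioned"

#: grid resolution used by :func:`worst_case` before local refinement
DEFAULT_GRID_SIZE = 2001
#: absolute rho tolerance of the local refinement step
RHO_REFINE_TOL = 1e-6


class NotExcludable(Exception):
    """No candidate count ``n`` within ``[0, T]`` achieves exclusion."""


@dataclass(frozen=True)
class RateEstimate:
    """A term-development probability with its underlying counts."""

    developed: int
    transferred: int

    def __post_init__(self) -> None:
        if self.transferred <= 0:
            raise ValueError("transferred must be a positive count")
        if not 0 <= self.developed <= self.transferred:
            raise ValueError(
                f"developed must lie in [0, transferred]; "
                f"got {self.developed}/{self.transferred}"
            )

    @property
    def rate(self) -> float:
        """Exact ratio developed/transferred (rounding only at display)."""
        return self.developed / self.transferred

    def display(self, digits: int = 3) -> float:
        return round(self.rate, digits)


def estimate_rate(developed: int, transferred: int) -> RateEstimate:
    """Estimate a term-development rate from developed/transferred counts."""
    return RateEstimate(int(developed), int(transferred))


@dataclass(frozen=True)
class MixtureQuery:
    """Full parameterization of one exclusion computation.

    Parameters
    ----------
    N : cohort size (embryos transferred).
    T : total number developed to term.
    q1, q2 : phenotype-I and phenotype-II term rates.
    k_list : concordant phenotype-I observation counts, one per independent
        line of evidence (each contributes an ``(1-rho)**k`` factor).
    n : candidate count of phenotype-II-derived term offspring.
    alpha : significance level for the exclusion verdict.
    strategy : marginalization interpretation, one of :data:`STRATEGIES`.
    """

    N: int
    T: int
    q1: RateEstimate
    q2: RateEstimate
    k_list: tuple[int, ...] = ()
    n: int = 0
    alpha: float = 0.05
    strategy: str = DEFAULT_STRATEGY

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_list", tuple(int(k) for k in self.k_list))
        if not 0 <= self.n <= self.T <= self.N:
            raise ValueError("require 0 <= n <= T <= N")
        if any(k < 1 for k in self.k_list):
            raise ValueError("every k in k_list must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class RhoProfile:
    """Combined probability evaluated on a rho grid, plus its maximum."""

    rho_grid: np.ndarray
    p_values: np.ndarray
    p_max: float
    rho_argmax: float


@dataclass(frozen=True)
class ExclusionResult:
    query: MixtureQuery
    profile: RhoProfile
    excluded: bool
    strategy: str
    n_threshold: int | None = field(default=None)

    @property
    def p_max(self) -> float:
        return self.profile.p_max

    @property
    def rho_argmax(self) -> float:
        return self.profile.rho_argmax


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    return rho


def concordance_evidence(k: int, rho: float) -> float:
    """Probability of k phenotype-I states in k assays: ``(1 - rho)**k``.

    Computed in log space so that large ``k`` cannot underflow prematurely.
    """
    rho = _check_rho(rho)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 1.0
    if rho == 1.0:
        return 0.0
    return math.exp(k * math.log1p(-rho))


def _log_binom_pmf(x: np.ndarray, size: np.ndarray, p: float) -> np.ndarray:
    """Elementwise log Binomial(size, p) pmf; -inf for infeasible arguments.

    Infeasible (x < 0, x > size) configurations silently contribute zero
    probability, as the marginalization over m requires.
    """
    x = np.asarray(x, dtype=float)
    size = np.asarray(size, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = gammaln(size + 1.0) - gammaln(x + 1.0) - gammaln(size - x + 1.0)
        if p > 0.0:
            out = out + np.where(x == 0.0, 0.0, x * math.log(p))
        else:
            out = np.where(x == 0.0, out, -np.inf)
        if p < 1.0:
            out = out + np.where(size - x == 0.0, 0.0, (size - x) * math.log1p(-p))
        else:
            out = np.where(size - x == 0.0, out, -np.inf)
    return np.where((x >= 0.0) & (x <= size) & (size >= 0.0), out, -np.inf)


@lru_cache(maxsize=32)
def _rho_free_tables(
    N: int, T: int, q1: float, q2: float, strategy: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute the rho-independent parts of the marginalization over m.

    Returns ``(m, log_choose_Nm, A)`` where ``A[n, m]`` collects
    ``log p(n|m, q2) + log p(base-n|N-m, q1)`` for n = 0..T;  ``base`` is ``T``
    under the total-conditioned strategy and ``N`` under literal-prose.
    """
    base = T if strategy == "total-conditioned" else N
    m = np.arange(N + 1, dtype=float)
    n_col = np.arange(T + 1, dtype=float)[:, None]
    A = _log_binom_pmf(n_col, m[None, :], q2) + _log_binom_pmf(
        base - n_col, N - m[None, :], q1
    )
    log_choose = gammaln(N + 1.0) - gammaln(m + 1.0) - gammaln(N - m + 1.0)
    return m, log_choose, A


def _log_joint_over_m(query: MixtureQuery, rho: float) -> np.ndarray:
    """log of sum_m p(m|N,rho) p(n|m,q2) p(base-n|N-m,q1) for n = 0..T.

    Log-sum-exp over m keeps values at the 1e-300 scale representable.
    """
    N = query.N
    m, log_choose, A = _rho_free_tables(
        query.N, query.T, query.q1.rate, query.q2.rate, query.strategy
    )
    if rho == 0.0:
        lpm = np.where(m == 0.0, 0.0, -np.inf)
    elif rho == 1.0:
        lpm = np.where(m == N, 0.0, -np.inf)
    else:
        lpm = log_choose + m * math.log(rho) + (N - m) * math.log1p(-rho)
    return logsumexp(lpm[None, :] + A, axis=1)


def _log_pmf_vector(query: MixtureQuery, rho: float) -> np.ndarray:
    """Normalized log pmf over n = 0..T of the phenotype-II-derived count."""
    lj = _log_joint_over_m(query, rho)
    lz = logsumexp(lj)
    if lz == -np.inf:
        # degenerate: the observed total is impossible under (rho, q1, q2)
        return np.full(query.T + 1, -np.inf)
    return lj - lz


def term_origin_pmf(query: MixtureQuery, rho: float, n: int | None = None) -> float:
    """Marginal-over-m probability that exactly n term offspring are phenotype-II."""
    rho = _check_rho(rho)
    n = query.n if n is None else int(n)
    if not 0 <= n <= query.T:
        raise ValueError(f"n must lie in [0, T], got {n}")
    return float(np.exp(_log_pmf_vector(query, rho)[n]))


def _log_tail(query: MixtureQuery, rho: float) -> float:
    if query.n == 0:
        return 0.0
    lp = _log_pmf_vector(query, rho)
    return float(logsumexp(lp[query.n:]))


def term_origin_tail(query: MixtureQuery, rho: float) -> float:
    """P(at least query.n of the T term offspring derive from phenotype-II)."""
    rho = _check_rho(rho)
    return math.exp(_log_tail(query, rho))


def _log_combined(query: MixtureQuery, rho: float) -> float:
    le = 0.0
    for k in query.k_list:
        if rho == 1.0:
            return -np.inf
        le += k * math.log1p(-rho)
    return _log_tail(query, rho) + le


def combined_probability(query: MixtureQuery, rho: float) -> float:
    """Mixture tail times the product of all concordance-evidence factors."""
    rho = _check_rho(rho)
    return math.exp(_log_combined(query, rho))


def rho_profile(query: MixtureQuery, grid_size: int = DEFAULT_GRID_SIZE) -> RhoProfile:
    """Evaluate the combined probability on an evenly spaced rho grid.

    The returned maximum is refined locally (bounded scalar minimization of
    the negative log around the grid argmax) to |drho| <= 1e-6.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    logp = np.array([_log_combined(query, r) for r in grid])
    with np.errstate(over="ignore"):
        pvals = np.exp(logp)
    i = int(np.argmax(logp))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if hi > lo and np.isfinite(logp[i]):
        res = minimize_scalar(
            lambda r: -_log_combined(query, float(np.clip(r, 0.0, 1.0))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": RHO_REFINE_TOL},
        )
        rho_star, best = float(res.x), -float(res.fun)
        if best < logp[i]:  # keep the grid point if refinement regressed
            rho_star, best = float(grid[i]), float(logp[i])
    else:
        rho_star, best = float(grid[i]), float(logp[i])
    return RhoProfile(
        rho_grid=grid,
        p_values=pvals,
        p_max=float(np.exp(best)),
        rho_argmax=rho_star,
    )


def worst_case(query: MixtureQuery, grid_size: int = DEFAULT_GRID_SIZE) -> ExclusionResult:
    """Maximize the combined probability over rho and render the verdict."""
    profile = rho_profile(query, grid_size)
    return ExclusionResult(
        query=query,
        profile=profile,
        excluded=bool(profile.p_max <= query.alpha),
        strategy=query.strategy,
    )


def min_excludable_n(query: MixtureQuery, grid_size: int = DEFAULT_GRID_SIZE) -> int:
    """Smallest n in [0, T] whose worst-case bound falls at or below alpha.

    The worst case is non-increasing in n, so a bisection over n suffices.
    Raises :class:`NotExcludable` when even n = T is not excludable.
    """

    def p_max(n: int) -> float:
        return worst_case(replace(query, n=n), grid_size).p_max

    if p_max(query.T) > query.alpha:
        raise NotExcludable(
            f"no n in [0, {query.T}] achieves p_max <= alpha={query.alpha}"
        )
    lo, hi = 0, query.T  # invariant: p_max(hi) <= alpha
    if p_max(0) <= query.alpha:
        return 0
    while hi - lo > 1:  # p_max(lo) > alpha
        mid = (lo + hi) // 2
        if p_max(mid) <= query.alpha:
            hi = mid
        else:
            lo = mid
    return hi
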