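"""Storage-capacity theory for one-step retrieval in diluted Willshaw networks.

Two analysis paths:

* an asymptotic path built on the memory load
  ``p1 = 1 - (1 - k*l/(m*n))**M`` (the probability that a synapse is
  potentiated after storing M random memories), the binomial low-unit error
  probability, and the classic capacity definitions — pattern capacity
  (memories storable at output noise <= eps), weight capacity (stored bits
  per anatomical synapse, bounded by ln 2 ~ 0.693 for noiseless queries) and
  total capacity (stored bits per *consolidated* synapse, which diverges with
  network size for fixed sparse assemblies, the central gain from structural
  plasticity);

* a finite-network path that approximates the dendritic-potential
  distributions of "high" units (members of the retrieved assembly) and
  "low" units (all others) by Gaussians with exactly computed means and
  variances, optimises an integer firing threshold, and binary-searches the
  largest admissible number of memories.  An exact potential distribution
  (inclusion–exclusion over assembly overlaps, mixed over binomial dilution)
  is provided for validation on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CapacityQuery",
    "CapacityResult",
    "PotentialMoments",
    "ThresholdResult",
    "memory_load",
    "low_unit_error",
    "predicted_output_noise",
    "max_matrix_load",
    "pattern_capacity",
    "transinformation",
    "weight_capacity",
    "total_capacity",
    "gaussian_moments",
    "exact_potential_pmf",
    "optimal_threshold_gaussian",
    "pattern_capacity_finite",
    "capacity_surface",
]


@dataclass(frozen=True)
class CapacityQuery:
    """Parameter set of a capacity analysis.

    ``P`` is the connectivity entering retrieval — anatomical c_a for a
    static network, effectual c_e for a consolidated structurally plastic
    one.  ``eps`` is the tolerated output-noise level.
    """

    m: int
    n: int
    k: int
    l: int
    eps: float
    P: float = 1.0
    lambda_: float = 1.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if not 0.0 < self.P <= 1.0:
            raise ValueError("P must lie in (0, 1]")
        if not (0 < self.k <= self.m and 0 < self.l <= self.n):
            raise ValueError("activities must satisfy 0 < k <= m, 0 < l <= n")

    @property
    def zk(self) -> int:
        """Number of correct active query units."""
        return int(round(self.lambda_ * self.k))

    @property
    def zf(self) -> int:
        """Number of false active query units."""
        return int(round(self.kappa * self.k))


@dataclass(frozen=True)
class CapacityResult:
    p1: float          # memory load at M_eps
    p1max: float       # maximal admissible matrix load
    M_eps: int         # pattern capacity
    C_weight: float    # bits per anatomical synapse
    C_total: float     # bits per consolidated synapse
    theta_opt: int | None = None


@dataclass(frozen=True)
class PotentialMoments:
    """Mean/variance of low- and high-unit dendritic potentials."""

    mu_lo: float
    var_lo: float
    mu_hi: float
    var_hi: float


@dataclass(frozen=True)
class ThresholdResult:
    theta: int
    eps_hat: float
    p01: float
    p10: float


# ---------------------------------------------------------------------------
# asymptotic one-step analysis
# ---------------------------------------------------------------------------

def memory_load(M: int, k: int, l: int, m: int, n: int) -> float:
    """p1 = 1 - (1 - k*l/(m*n))**M, the potentiation probability of a synapse."""
    if M < 0:
        raise ValueError("M must be nonnegative")
    frac = k * l / (m * n)
    if frac >= 1.0:
        return 1.0 if M > 0 else 0.0
    return -math.expm1(M * math.log1p(-frac))


def low_unit_error(p1: float, k: int, lambda_: float, P: float) -> float:
    """False-positive probability of a low unit under connected-count thresholds.

    A low unit fires only if every one of its synapses from the c connected
    correct query units is potentiated, c ~ Binom(round(lambda*k), P); the sum
    over c collapses to the closed form (1 - P + P*p1)**(lambda*k).  Both are
    computed and checked against each other.
    """
    zk = int(round(lambda_ * k))
    if zk < 1:
        raise ValueError("lambda_*k rounds to zero")
    c = np.arange(zk + 1)
    total = float(stats.binom.pmf(c, zk, P) @ np.power(p1, c))
    closed = float((1.0 - P + P * p1) ** zk)
    if not math.isclose(total, closed, rel_tol=1e-10, abs_tol=1e-14):
        raise AssertionError("binomial sum and closed form disagree")
    return closed


def predicted_output_noise(p01: float, p10: float, l: int, n: int) -> float:
    """eps_hat = ((n - l) * p01 + l * p10) / l."""
    if l <= 0 or n <= l:
        raise ValueError("need 0 < l < n")
    return ((n - l) * p01 + l * p10) / l


def max_matrix_load(q: CapacityQuery) -> float:
    """Largest memory load p1 whose predicted output noise stays at eps.

    Solves ((n-l)/l) * (1 - P + P*p1)**(lambda*k) = eps for p1 by bisection
    (Brent) to 1e-10.  For P = 1 the closed form
    p1max = (eps*l/(n-l))**(1/(lambda*k)) is available and cross-checked.
    """
    from scipy.optimize import brentq

    target = q.eps * q.l / (q.n - q.l)
    if target >= 1.0:
        return 1.0
    zk = q.zk

    def f(p1: float) -> float:
        return (1.0 - q.P + q.P * p1) ** zk - target

    if f(0.0) > 0:
        raise ValueError(
            "no admissible load: even an empty network exceeds the noise level "
            f"(P={q.P}, lambda*k={zk}, eps={q.eps}); raise eps, lambda*k or P"
        )
    p1max = float(brentq(f, 0.0, 1.0, xtol=1e-12, rtol=1e-12))
    if q.P == 1.0:
        closed = target ** (1.0 / zk)
        if not math.isclose(p1max, closed, rel_tol=1e-8, abs_tol=1e-10):
            raise AssertionError("bisection disagrees with the P=1 closed form")
    return p1max


def pattern_capacity(q: CapacityQuery) -> int:
    """M_eps = floor( ln(1 - p1max) / ln(1 - k*l/(m*n)) )."""
    p1max = max_matrix_load(q)
    frac = q.k * q.l / (q.m * q.n)
    if p1max >= 1.0:
        raise ValueError("p1max = 1: pattern capacity unbounded at this eps")
    return int(math.floor(math.log1p(-p1max) / math.log1p(-frac)))


def _h2(p: float) -> float:
    """Binary entropy in bits."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def transinformation(p: float, p01: float, p10: float) -> float:
    """Mutual information (bits) across a binary asymmetric channel.

    Source emits 1 with probability p; a 0 flips to 1 with probability p01,
    a 1 flips to 0 with probability p10.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    p_out = p * (1.0 - p10) + (1.0 - p) * p01
    return _h2(p_out) - p * _h2(p10) - (1.0 - p) * _h2(p01)


def weight_capacity(q: CapacityQuery) -> float:
    """Stored bits per anatomical synapse at the admissible noise level.

    C = M_eps * n * T(l/n; p01, p10=0) / (m * n * P), with p01 at the eps
    level.  Bounded by ln 2 ~ 0.693 bits for complete noiseless queries.
    """
    M_eps = pattern_capacity(q)
    p01 = q.eps * q.l / (q.n - q.l)
    T = transinformation(q.l / q.n, min(p01, 1.0), 0.0)
    return M_eps * q.n * T / (q.m * q.n * q.P)


def total_capacity(q: CapacityQuery, c_e: float | None = None) -> float:
    """Stored bits per consolidated synapse (structural plasticity included).

    Normalises the stored information by the number of consolidated (state-1)
    synapses m*n*c_e*p1max instead of all anatomical synapses m*n*P.  With
    effectual connectivity at the anatomical level and p1max = 1 this
    coincides with the weight capacity; for sparse assemblies it diverges
    with network size.
    """
    if c_e is None:
        c_e = q.P
    if not 0.0 < c_e <= 1.0:
        raise ValueError("c_e must lie in (0, 1]")
    p1max = max_matrix_load(q)
    M_eps = pattern_capacity(q)
    p01 = q.eps * q.l / (q.n - q.l)
    T = transinformation(q.l / q.n, min(p01, 1.0), 0.0)
    return M_eps * q.n * T / (q.m * q.n * c_e * p1max)


# ---------------------------------------------------------------------------
# finite-network Gaussian analysis
# ---------------------------------------------------------------------------

def _pair_nonpot_prob(M: int, k: int, l: int, m: int, n: int, s: int) -> float:
    """P(all of s synapses sharing a content unit stay unpotentiated after M memories).

    Per memory, the content unit joins its assembly with probability l/n and
    the address assembly hits at least one of the s designated units with
    probability 1 - C(m-s, k)/C(m, k).
    """
    if s == 0:
        return 1.0
    if s > m - k:
        miss = 0.0
    else:
        j = np.arange(s)
        miss = float(np.prod((m - k - j) / (m - j)))
    per_memory = 1.0 - (l / n) * (1.0 - miss)
    return per_memory ** M


def _willshaw_cov(M: int, k: int, l: int, m: int, n: int) -> float:
    """Covariance of two Willshaw weights onto the same content unit."""
    p0 = _pair_nonpot_prob(M, k, l, m, n, 1)
    p00 = _pair_nonpot_prob(M, k, l, m, n, 2)
    return p00 - p0 * p0


def gaussian_moments(
    M: int, k: int, l: int, m: int, n: int,
    lambda_: float = 1.0, kappa: float = 0.0, P: float = 1.0,
) -> PotentialMoments:
    """Means and variances of low/high-unit dendritic potentials.

    Low units receive all round(lambda*k) + round(kappa*k) active query units
    as random inputs: each contributes through an existing (prob P)
    potentiated (prob p1) synapse; weights sharing the target unit are
    positively correlated across inputs, which is accounted for exactly.
    High units additionally receive their round(lambda*k) correct inputs
    through surely potentiated synapses (contributing P-thinned counts), and
    the false inputs see the load of the remaining M-1 memories.
    """
    if M < 0:
        raise ValueError("M must be nonnegative")
    if not 0.0 < P <= 1.0:
        raise ValueError("P must lie in (0, 1]")
    zk = int(round(lambda_ * k))
    zf = int(round(kappa * k))

    def random_input_moments(z: int, M_eff: int) -> tuple[float, float]:
        if z == 0:
            return 0.0, 0.0
        p1 = memory_load(M_eff, k, l, m, n)
        cov = _willshaw_cov(M_eff, k, l, m, n)
        mu = z * P * p1
        var = z * P * p1 * (1.0 - P * p1) + z * (z - 1) * P * P * cov
        return mu, max(var, 0.0)

    mu_lo, var_lo = random_input_moments(zk + zf, M)
    mu_f, var_f = random_input_moments(zf, max(M - 1, 0))
    mu_hi = zk * P + mu_f
    var_hi = zk * P * (1.0 - P) + var_f
    return PotentialMoments(mu_lo=mu_lo, var_lo=var_lo, mu_hi=mu_hi, var_hi=var_hi)


def exact_potential_pmf(
    M: int, k: int, l: int, m: int, n: int, active_inputs: int, P: float = 1.0,
) -> np.ndarray:
    """Exact pmf of a low unit's dendritic potential (small instances).

    For a fully connected network the probability that a random content unit
    receives potential x0 from z active random query units follows by
    inclusion–exclusion over which inputs' synapses stayed unpotentiated;
    dilution mixes this over the binomially distributed number of connected
    inputs.  Returns probabilities for x = 0..active_inputs.
    """
    z = int(active_inputs)
    if z < 0:
        raise ValueError("active_inputs must be nonnegative")
    if z > 40:
        raise ValueError("exact pmf is intended for small instances (z <= 40)")
    q = np.array([_pair_nonpot_prob(M, k, l, m, n, s) for s in range(z + 1)])

    def pmf_full(x0: int, c: int) -> float:
        s = np.arange(x0 + 1)
        signs = (-1.0) ** s
        combs = np.array([math.comb(x0, int(si)) for si in s], dtype=float)
        return math.comb(c, x0) * float(np.sum(signs * combs * q[c - x0 + s]))

    pmf = np.zeros(z + 1)
    cs = np.arange(z + 1)
    wc = stats.binom.pmf(cs, z, P)
    for c in cs:
        if wc[c] < 1e-300:
            continue
        for x0 in range(c + 1):
            pmf[x0] += wc[c] * pmf_full(x0, int(c))
    pmf = np.clip(pmf, 0.0, None)
    total = pmf.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise AssertionError(f"pmf does not sum to 1 (sum={total})")
    return pmf / total


def _tail_ge(theta: float, mu: float, var: float) -> float:
    """Gaussian P[X >= theta] with continuity correction; degenerate -> step."""
    if var <= 0.0:
        return 1.0 if mu >= theta else 0.0
    return float(stats.norm.sf(theta - 0.5, loc=mu, scale=math.sqrt(var)))


def optimal_threshold_gaussian(
    moments: PotentialMoments, l: int, n: int, theta_max: int | None = None,
) -> ThresholdResult:
    """Integer firing threshold minimising predicted output noise.

    Scans all integer thresholds in [0, theta_max] evaluating
    eps(theta) = ((n - l) * P[lo >= theta] + l * P[hi < theta]) / l
    under the Gaussian tail approximation (continuity-corrected); ties go to
    the lowest threshold.
    """
    if theta_max is None:
        theta_max = int(math.ceil(moments.mu_hi + 8.0 * math.sqrt(moments.var_hi + 1.0)))
    best = None
    for theta in range(0, theta_max + 1):
        p01 = _tail_ge(theta, moments.mu_lo, moments.var_lo)
        p10 = 1.0 - _tail_ge(theta, moments.mu_hi, moments.var_hi)
        eps = ((n - l) * p01 + l * p10) / l
        if best is None or eps < best.eps_hat - 1e-15:
            best = ThresholdResult(theta=theta, eps_hat=eps, p01=p01, p10=p10)
    return best


def pattern_capacity_finite(q: CapacityQuery) -> CapacityResult:
    """Largest M whose Gaussian-predicted minimal output noise stays at eps.

    Binary search over M, valid because the minimal predicted noise is
    non-decreasing in M (checked at the bracket).  Returns the full capacity
    summary at the optimum.
    """
    theta_max = q.zk + q.zf

    def eps_min(M: int) -> ThresholdResult:
        mom = gaussian_moments(M, q.k, q.l, q.m, q.n, q.lambda_, q.kappa, q.P)
        return optimal_threshold_gaussian(mom, q.l, q.n, theta_max=theta_max)

    if eps_min(0).eps_hat > q.eps:
        raise ValueError("even an empty network exceeds the noise level")
    # expand upper bracket until failure or the load saturates
    M_lo, M_hi = 0, 1
    while eps_min(M_hi).eps_hat <= q.eps:
        if memory_load(M_hi, q.k, q.l, q.m, q.n) > 1.0 - 1e-9:
            M_lo = M_hi
            break
        M_lo = M_hi
        M_hi *= 2
    else:
        while M_hi - M_lo > 1:
            mid = (M_lo + M_hi) // 2
            if eps_min(mid).eps_hat <= q.eps:
                M_lo = mid
            else:
                M_hi = mid
    M_eps = M_lo
    res = eps_min(M_eps)
    p1 = memory_load(M_eps, q.k, q.l, q.m, q.n)
    T = transinformation(q.l / q.n, res.p01, res.p10)
    C_weight = M_eps * q.n * T / (q.m * q.n * q.P)
    denom = q.m * q.n * q.P * max(p1, 1e-300)
    C_total = M_eps * q.n * T / denom
    return CapacityResult(p1=p1, p1max=p1, M_eps=M_eps,
                          C_weight=C_weight, C_total=C_total, theta_opt=res.theta)


def capacity_surface(
    n: int, k_grid, ce_grid, eps: float,
    lambda_: float = 1.0, kappa: float = 0.0, m: int | None = None,
) -> pd.DataFrame:
    """Pattern/weight/total capacity over an (assembly size, connectivity) grid.

    Long-format table with one row per (k, c_e) cell, computed via the
    finite-network Gaussian path with k = l and m = n by default.
    """
    if m is None:
        m = n
    rows = []
    for k in k_grid:
        for ce in ce_grid:
            q = CapacityQuery(m=m, n=n, k=int(k), l=int(k), eps=eps,
                              P=float(ce), lambda_=lambda_, kappa=kappa)
            try:
                r = pattern_capacity_finite(q)
            except ValueError:
                rows.append({"k": int(k), "c_e": float(ce), "M_eps": 0,
                             "C_weight": 0.0, "C_total": 0.0, "theta_opt": None})
                continue
            rows.append({"k": int(k), "c_e": float(ce), "M_eps": r.M_eps,
                         "C_weight": r.C_weight, "C_total": r.C_total,
                         "theta_opt": r.theta_opt})
    return pd.DataFrame(rows)
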