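"""Single-pathway counting model of chiasma interference.

Chiasma events along a bivalent are modelled as every (i+1)-th point of a
point process in which chiasmata are interleaved with unobserved "dummy"
events: the number of dummy events falling between two successive chiasmata
is drawn independently from a law ``gamma`` with support 0..m.  Because
events (dummy + chiasma) form a homogeneous Poisson stream on the genetic
map, the genetic distance between chiasmata is a mixture of Erlang
distributions and interference strength is controlled entirely by
``gamma`` — the classical counting (chi-square) model of crossover
interference.

The *phase* at a chromosomal location is the number of dummy events between
that location and the next chiasma in the direction of travel.  Multilocus
recombination-pattern probabilities follow from a Markov chain on phases:
per-interval transition matrices ``H`` (no chiasma in the interval) and
``G`` (at least one chiasma), combined with the no-chromatid-interference
thinning factor 1/2, are multiplied along the chain and summed over
terminal phases.

This module is pure numerics: distributions, renewal coefficients, the
H/G/M matrices and pattern probabilities.  Chromosome structure, viability
and inference live elsewhere.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "InterferenceDistribution",
    "PhaseDistribution",
    "RenewalCoefficients",
    "IntervalRate",
    "TruncationError",
    "gamma_from_strength",
    "stationary_phase",
    "renewal_coefficients",
    "interval_rate",
    "h_matrix",
    "g_matrix",
    "transition_matrices",
    "pattern_probability",
    "chain_pattern_distribution",
]

#: tolerance on probability-vector normalisation
_SUM_TOL = 1e-12


class TruncationError(RuntimeError):
    """The infinite renewal sum failed to converge within the hard cap."""


def _as_prob_vector(values, name: str) -> np.ndarray:
    vec = np.asarray(values, dtype=float)
    if vec.ndim != 1 or vec.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d vector")
    if np.any(vec < 0):
        raise ValueError(f"{name} entries must be non-negative")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} entries must sum to 1 (got {vec.sum()!r})")
    return vec


@dataclasses.dataclass(frozen=True)
class InterferenceDistribution:
    """Law of the dummy-event count between successive chiasmata.

    Parameters
    ----------
    gamma
        Probabilities indexed 0..m; non-negative, summing to 1.
    q
        Optional interference-strength parameter when the distribution is
        the single-parameter gamma-model law: all mass on ``floor(q)`` and
        ``floor(q) + 1`` with weights ``1 - frac(q)`` and ``frac(q)``.
    """

    gamma: np.ndarray
    q: float | None = None

    def __post_init__(self) -> None:
        vec = _as_prob_vector(self.gamma, "gamma")
        object.__setattr__(self, "gamma", vec)
        if self.q is not None:
            if self.q < 0:
                raise ValueError("interference strength q must be >= 0")
            ref = _gamma_model_vector(float(self.q), self.m)
            if not np.allclose(vec, ref, atol=1e-9):
                raise ValueError("gamma does not match its declared strength q")

    @property
    def m(self) -> int:
        """Largest index of the support (length of ``gamma`` minus one)."""
        return self.gamma.size - 1

    @property
    def mean_spacing(self) -> float:
        """Expected events (dummy + chiasma) per chiasma, sum (s+1)*gamma_s."""
        s = np.arange(self.gamma.size)
        return float(np.dot(s + 1.0, self.gamma))

    def padded(self, m: int) -> "InterferenceDistribution":
        """Return a copy zero-padded to support 0..m."""
        if m < self.m:
            raise ValueError("cannot pad to a smaller support")
        vec = np.zeros(m + 1)
        vec[: self.gamma.size] = self.gamma
        return InterferenceDistribution(vec, q=self.q)


@dataclasses.dataclass(frozen=True)
class PhaseDistribution:
    """Law of the phase (dummy events until the next chiasma) at a point."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega", _as_prob_vector(self.omega, "omega"))

    @property
    def m(self) -> int:
        return self.omega.size - 1

    def padded(self, m: int) -> "PhaseDistribution":
        if m < self.m:
            raise ValueError("cannot pad to a smaller support")
        vec = np.zeros(m + 1)
        vec[: self.omega.size] = self.omega
        return PhaseDistribution(vec)


@dataclasses.dataclass(frozen=True)
class RenewalCoefficients:
    """Coefficients b_t of the phase-renewal expansion.

    ``b_t`` is the probability that some chiasma renewal lands exactly t
    events after a chiasma; it satisfies ``b_0 = 1`` and
    ``b_t = sum_{a<t} b_a * gamma_{t-1-a}``.
    """

    b: np.ndarray
    tmax: int

    def __post_init__(self) -> None:
        vec = np.asarray(self.b, dtype=float)
        if vec.size != self.tmax + 1:
            raise ValueError("b must have tmax + 1 entries")
        if vec[0] != 1.0:
            raise ValueError("b_0 must equal 1")
        if np.any((vec < -1e-12) | (vec > 1.0 + 1e-12)):
            raise ValueError("renewal coefficients must lie in [0, 1]")
        object.__setattr__(self, "b", vec)


@dataclasses.dataclass(frozen=True)
class IntervalRate:
    """Event intensity of one interval.

    ``lam`` is the expected number of events (dummy + chiasma) in an
    interval of heterokaryotype genetic length ``l_prime`` Morgans:
    ``lam = 2 * l_prime * sum_s (s+1) * gamma_s``.
    """

    l_prime: float
    lam: float

    def __post_init__(self) -> None:
        if self.l_prime < 0 or self.lam < 0:
            raise ValueError("interval length and rate must be non-negative")


def _gamma_model_vector(q: float, m: int) -> np.ndarray:
    base = int(math.floor(q))
    frac = q - base
    need = base if frac == 0.0 else base + 1
    if m < need:
        raise ValueError(f"m={m} too small to hold the support of q={q}")
    vec = np.zeros(m + 1)
    vec[base] = 1.0 - frac
    if frac > 0.0:
        vec[base + 1] = frac
    return vec


def gamma_from_strength(q: float, m: int | None = None) -> InterferenceDistribution:
    """Gamma-model interference law for strength ``q``.

    Mass ``1 - frac(q)`` at ``floor(q)`` and ``frac(q)`` at ``floor(q)+1``;
    an integer ``q`` puts all mass at index ``q``.  ``q = 0`` is the
    no-interference (Haldane) limit.
    """
    if q < 0:
        raise ValueError("interference strength q must be >= 0")
    if m is None:
        base = int(math.floor(q))
        m = base if q == base else base + 1
    return InterferenceDistribution(_gamma_model_vector(float(q), m), q=float(q))


def stationary_phase(gamma: InterferenceDistribution) -> PhaseDistribution:
    """Stationary phase law pi of the equilibrium renewal process.

    ``pi_i = sum_{s>=i} gamma_s / sum_s (s+1) gamma_s``.
    """
    tail = np.cumsum(gamma.gamma[::-1])[::-1]
    return PhaseDistribution(tail / gamma.mean_spacing)


def renewal_coefficients(gamma: InterferenceDistribution, tmax: int) -> RenewalCoefficients:
    """Renewal coefficients b_0..b_tmax for the law ``gamma``."""
    if tmax < 0:
        raise ValueError("tmax must be >= 0")
    return RenewalCoefficients(_renewal_b(gamma.gamma, tmax), tmax)


def interval_rate(l_prime: float, gamma: InterferenceDistribution) -> IntervalRate:
    """Event rate of an interval of heterokaryotype length ``l_prime`` Morgans."""
    if l_prime < 0:
        raise ValueError("interval length must be >= 0")
    return IntervalRate(float(l_prime), 2.0 * l_prime * gamma.mean_spacing)


def _lam(rate) -> float:
    return float(rate.lam) if isinstance(rate, IntervalRate) else float(rate)


_LGAMMA_TABLE = special.gammaln(np.arange(1, 2048 + 2))  # lgamma(k+1), k = 0..2048


def _poisson_pmf_vec(lam: float, cmax: int) -> np.ndarray:
    """pmf of Poisson(lam) at counts 0..cmax (fast path, cached lgamma)."""
    if cmax >= _LGAMMA_TABLE.size:
        return stats.poisson.pmf(np.arange(cmax + 1), lam)
    if lam == 0.0:
        out = np.zeros(cmax + 1)
        out[0] = 1.0
        return out
    k = np.arange(cmax + 1)
    return np.exp(k * math.log(lam) - lam - _LGAMMA_TABLE[: cmax + 1])


def _renewal_b(gamma_vec: np.ndarray, tmax: int) -> np.ndarray:
    """Raw b_0..b_tmax recursion for a gamma probability vector."""
    mg = gamma_vec.size - 1
    b = np.zeros(tmax + 1)
    b[0] = 1.0
    for t in range(1, tmax + 1):
        lo = max(0, t - 1 - mg)
        idx = t - 1 - np.arange(lo, t)
        b[t] = float(np.dot(b[lo:t], gamma_vec[idx]))
    return b


def truncation_length(lam: float, m: int, tol: float = 1e-12) -> int:
    """Number of renewal terms needed so the neglected Poisson tail < tol.

    At step t of the renewal sum the smallest Poisson count still to be
    added is t + 1, and every coefficient multiplying the Poisson mass is
    at most 1, so the neglected mass is bounded by ``P(Poisson(lam) > t)``.
    A hard cap of ``10 (m+1) + lam + 10 sqrt(lam)`` guards against a
    tolerance that can never be met.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if lam == 0.0:
        return 0
    cap = int(math.ceil(10.0 * (m + 1) + lam + 10.0 * math.sqrt(lam)))
    pmf = _poisson_pmf_vec(lam, cap + 1)
    # reverse cumsum avoids the cancellation of 1 - cumsum for tiny tails
    rev = np.cumsum(pmf[::-1])[::-1]
    tail = rev[1:]  # tail[t] = P(X > t), up to pmf truncation beyond cap
    ok = np.nonzero(tail < tol)[0]
    if ok.size == 0:
        raise TruncationError(
            f"renewal sum for lam={lam} did not reach tolerance {tol} within t <= {cap}"
        )
    return int(ok[0])


def _hg_matrices(lam: float, gamma: InterferenceDistribution,
                 b: np.ndarray | None = None,
                 tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """H and G for one interval, sharing a single Poisson pmf evaluation."""
    m = gamma.m
    g = gamma.gamma
    tmax = truncation_length(lam, m, tol)
    if b is None:
        b = _renewal_b(g, tmax)
    elif b.size < tmax + 1:
        raise ValueError(f"b too short: need tmax >= {tmax}, got {b.size - 1}")
    cmax = 2 * m + 1 + tmax
    pmf = _poisson_pmf_vec(lam, cmax)
    i = np.arange(m + 1)
    diff = i[:, None] - i[None, :]
    H = np.where(diff >= 0, pmf[np.clip(diff, 0, None)], 0.0)
    # W[c] = sum_t b_t * pmf[c + t] for c = 0 .. 2m+1
    windows = np.lib.stride_tricks.sliding_window_view(pmf, tmax + 1)
    W = windows[: 2 * m + 2] @ b[: tmax + 1]
    G = np.zeros((m + 1, m + 1))
    for j in range(m + 1):
        col = np.zeros(m + 1)
        for s in range(j, m + 1):
            if g[s] != 0.0:
                col += g[s] * W[i + 1 + s - j]
        G[:, j] = col
    return H, G


def h_matrix(rate, m: int) -> np.ndarray:
    """Phase-transition matrix for an interval containing no chiasma.

    Entry (i, j) is the probability of i - j events, all dummy, taking the
    phase from i down to j: ``lam^(i-j) e^-lam / (i-j)!`` for i >= j.
    """
    lam = _lam(rate)
    pmf = _poisson_pmf_vec(lam, m)
    i = np.arange(m + 1)
    diff = i[:, None] - i[None, :]
    return np.where(diff >= 0, pmf[np.clip(diff, 0, None)], 0.0)


def g_matrix(rate, gamma: InterferenceDistribution,
             b: RenewalCoefficients | None = None, tol: float = 1e-12) -> np.ndarray:
    """Phase-transition matrix for an interval with at least one chiasma.

    Entry (i, j) sums, over renewal paths, the probability that the interval
    holds ``i + 1 + t + s - j`` events: i dummies then the first chiasma,
    t further events up to the last chiasma, and s - j of the s dummies
    following it (j remain as the outgoing phase).  The infinite t-sum is
    truncated by :func:`truncation_length`.
    """
    bvec = b.b if b is not None else None
    _, G = _hg_matrices(_lam(rate), gamma, b=bvec, tol=tol)
    return G


def transition_matrices(rate, gamma: InterferenceDistribution,
                        b: RenewalCoefficients | None = None,
                        tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Return (M_r0, M_r1): matrices for a non-recombinant / recombinant interval.

    A chiasma is transmitted to the sampled chromatid with probability 1/2
    (no chromatid interference), so an interval with >= 1 chiasma shows
    recombination with probability exactly 1/2: ``M_r1 = G/2`` and
    ``M_r0 = G/2 + H``.
    """
    bvec = b.b if b is not None else None
    H, G = _hg_matrices(_lam(rate), gamma, b=bvec, tol=tol)
    return 0.5 * G + H, 0.5 * G


def pattern_probability(omega: PhaseDistribution, rates: Sequence,
                        pattern: Sequence[int], gamma: InterferenceDistribution,
                        tol: float = 1e-12) -> float:
    """Probability of one recombination pattern along a chain of intervals.

    Row vector ``omega`` times the ordered product of per-interval
    transition matrices, summed over terminal phases.  An empty chain has
    probability 1.
    """
    rates = list(rates)
    pattern = list(pattern)
    if len(rates) != len(pattern):
        raise ValueError("rates and pattern must have equal length")
    if omega.m < gamma.m:
        omega = omega.padded(gamma.m)
    elif omega.m > gamma.m:
        raise ValueError("omega support exceeds gamma support")
    v = omega.omega.copy()
    for rate, r in zip(rates, pattern):
        M0, M1 = transition_matrices(rate, gamma, tol=tol)
        v = v @ (M1 if r else M0)
    return float(v.sum())


def chain_pattern_distribution(omega: PhaseDistribution, lams: Sequence[float],
                               gamma: InterferenceDistribution,
                               tol: float = 1e-12) -> np.ndarray:
    """Probabilities of all 2^n recombination patterns of a chain.

    Returns an array indexed by pattern code, where bit k of the code is
    the recombination indicator of interval k (interval 0 is the least
    significant bit).  Computed by propagating all partial phase vectors at
    once, doubling the stack at each interval.
    """
    lams = [float(x) for x in lams]
    m = gamma.m
    om = omega.padded(m) if omega.m < m else omega
    if om.m != m:
        raise ValueError("omega support exceeds gamma support")
    tmaxes = [truncation_length(lam, m, tol) for lam in lams]
    b = _renewal_b(gamma.gamma, max(tmaxes, default=0))
    V = om.omega[None, :].copy()
    for lam in lams:
        H, G = _hg_matrices(lam, gamma, b=b, tol=tol)
        V = np.vstack([V @ (0.5 * G + H), V @ (0.5 * G)])
    return V.sum(axis=1)
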