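"""Sterility of pericentric inversion heterokaryotypes.

A recombinant chromatid inside the inverted region is unbalanced unless it
recombines in *both* inner regions (breakpoint-to-centromere segments), so
the sterility — the proportion of unbalanced gametes — of an inversion of
heterokaryotype genetic length I' (Morgans) with the centromere at relative
position rho is

    zeta = p1 (1 - p2) + p2 (1 - p1),

where p_k is the recombination probability of inner region k, with region
lengths I' rho and I' (1 - rho).  Each p_k has the closed form

    p_k = (1/2) (1 - sum_s Omega_s P(Poisson(lam_k) <= s)),

with lam_k = 2 l'_k sum_s (s+1) gamma_s, i.e. the probability that at
least one chiasma lands in the region, halved by chromatid thinning; the
start phase Omega encodes the breakpoint-interference hypothesis.

The module also fits (qc[, qb], d_I) to observed sterilities of a panel of
inversions by unweighted least squares, sharing the chiasma-suppression
factor d_I = I'/I across inversions.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .counting import InterferenceDistribution, PhaseDistribution, gamma_from_strength
from .karyotype import HypothesisSpec, start_phase

__all__ = [
    "SterilityRecord",
    "SterilityParams",
    "inner_recombination_probability",
    "sterility",
    "three_locus_recombination",
    "sterility_curve",
    "fit_sterility",
    "SterilityModel",
    "SterilityResults",
]


@dataclasses.dataclass(frozen=True)
class SterilityRecord:
    """Observed sterility of one inversion.

    ``I`` is the homokaryotype genetic length of the inverted region in
    Morgans and ``rho`` the relative centromere position inside it.
    """

    inversion_id: str
    I: float
    rho: float
    observed: float

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("inversion length I must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.observed <= 1.0:
            raise ValueError("observed sterility must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SterilityParams:
    """Shared sterility-model parameters: a hypothesis plus d_I = I'/I."""

    spec: HypothesisSpec
    d_I: float

    def __post_init__(self) -> None:
        if not 0.0 < self.d_I:
            raise ValueError("d_I must be > 0")


def inner_recombination_probability(omega: PhaseDistribution, lam: float) -> float:
    """Recombination probability of an inner region with event rate ``lam``.

    Equals half the probability that at least one chiasma falls in the
    region given start phase ``omega``; lies in [0, 1/2].
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    s = np.arange(omega.omega.size)
    return 0.5 * (1.0 - float(np.dot(omega.omega, stats.poisson.cdf(s, lam))))


def _inner_probs(I_prime: float, rho: float, gamma: InterferenceDistribution,
                 omega: PhaseDistribution) -> tuple[float, float]:
    mult = gamma.mean_spacing
    lam1 = 2.0 * I_prime * rho * mult
    lam2 = 2.0 * I_prime * (1.0 - rho) * mult
    return (inner_recombination_probability(omega, lam1),
            inner_recombination_probability(omega, lam2))


def sterility(I_prime: float, rho: float, gamma: InterferenceDistribution,
              omega: PhaseDistribution) -> float:
    """Proportion of unbalanced gametes, zeta = p1(1-p2) + p2(1-p1)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    p1, p2 = _inner_probs(I_prime, rho, gamma, omega)
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


def three_locus_recombination(I_prime: float, rho: float,
                              gamma: InterferenceDistribution,
                              omega: PhaseDistribution) -> float:
    """Probability that both inner regions recombine (p1 * p2).

    With one locus at each breakpoint and one at the centromere this is the
    only viable way of separating the three loci, so it is the effective
    three-locus recombination rate of the inversion.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    p1, p2 = _inner_probs(I_prime, rho, gamma, omega)
    return p1 * p2


def _phase_for(hypothesis: str, q: float, qb: float | None, m: int) -> tuple:
    if hypothesis == "none":
        # independent chiasmata: q = 0, where gamma = pi = delta_0
        gamma = gamma_from_strength(0.0, m)
        return gamma, start_phase(HypothesisSpec("H0", 0.0), m)
    spec = HypothesisSpec(hypothesis, q, qb if hypothesis == "H2" else None)
    return gamma_from_strength(spec.qc, m), start_phase(spec, m)


def sterility_curve(hypothesis: str, I_prime_grid: Sequence[float],
                    rho_grid: Sequence[float], q: float = 4.0,
                    qb: float | None = None, quantity: str = "sterility",
                    m: int | None = None) -> pd.DataFrame:
    """Tabulate sterility or three-locus recombination over an (I', rho) grid.

    ``hypothesis`` is ``"none"`` (independent chiasmata), ``"H0"`` or
    ``"H1"`` (or ``"H2"`` with ``qb``).  Returns a tidy frame with columns
    I_prime, rho, value — the numerical content of the classic surface
    plots contrasting the interference regimes.
    """
    if quantity not in ("sterility", "three_locus"):
        raise ValueError("quantity must be 'sterility' or 'three_locus'")
    if m is None:
        m = int(np.ceil(max(q, qb or 0.0))) + 1 if max(q, qb or 0.0) > 0 else 1
    gamma, omega = _phase_for(hypothesis, q, qb, m)
    func = sterility if quantity == "sterility" else three_locus_recombination
    rows = [
        (ip, rho, func(float(ip), float(rho), gamma, omega))
        for ip in I_prime_grid
        for rho in rho_grid
    ]
    return pd.DataFrame(rows, columns=["I_prime", "rho", "value"])


# ---------------------------------------------------------------------------
# least-squares fitting


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame(
            [(r.inversion_id, r.I, r.rho, r.observed) for r in records],
            columns=["inversion_id", "I_morgans", "rho", "observed_sterility"],
        )
    if frame.empty:
        raise ValueError("no sterility records supplied")
    return frame


def _expected_sterility_vec(I: np.ndarray, rho: np.ndarray, d_I: float,
                            hypothesis: str, q: float, qb: float | None,
                            m: int) -> np.ndarray:
    gamma = gamma_from_strength(q, m)
    if hypothesis == "H0":
        omega = start_phase(HypothesisSpec("H0", q), m)
    elif hypothesis == "H1":
        omega = PhaseDistribution(gamma.gamma)
    else:
        omega = PhaseDistribution(gamma_from_strength(qb, m).gamma)
    mult = gamma.mean_spacing
    I_prime = d_I * I
    lam1 = 2.0 * I_prime * rho * mult
    lam2 = 2.0 * I_prime * (1.0 - rho) * mult
    s = np.arange(m + 1)
    # sum_s omega_s P(Pois(lam) <= s), vectorised over inversions
    cdf1 = stats.poisson.cdf(s[:, None], lam1[None, :])
    cdf2 = stats.poisson.cdf(s[:, None], lam2[None, :])
    p1 = 0.5 * (1.0 - omega.omega @ cdf1)
    p2 = 0.5 * (1.0 - omega.omega @ cdf2)
    return p1 + p2 - 2.0 * p1 * p2


class SterilityModel:
    """Least-squares sterility model over a panel of inversions.

    The free parameters are the interference strength(s) — ``qc`` (H0, H1)
    plus ``qb`` (H2) — and a single chiasma-suppression factor ``d_I``
    shared by every inversion; the objective is the unweighted sum of
    squared deviations between expected and observed sterilities.
    """

    def __init__(self, records, q_max: float = 30.0):
        self.data = _records_frame(records)
        self.q_max = float(q_max)
        self.m = int(np.ceil(self.q_max)) + 1
        self._I = self.data["I_morgans"].to_numpy(dtype=float)
        self._rho = self.data["rho"].to_numpy(dtype=float)
        self._obs = self.data["observed_sterility"].to_numpy(dtype=float)

    def expected(self, hypothesis: str, q: float, d_I: float,
                 qb: float | None = None) -> np.ndarray:
        return _expected_sterility_vec(self._I, self._rho, d_I, hypothesis, q, qb, self.m)

    def objective(self, hypothesis: str, q: float, d_I: float,
                  qb: float | None = None) -> float:
        resid = self.expected(hypothesis, q, d_I, qb) - self._obs
        return float(np.dot(resid, resid))

    def _unpack(self, x: np.ndarray, hypothesis: str):
        q = self.q_max * special.expit(x[0])
        d_I = special.expit(x[1])
        qb = self.q_max * special.expit(x[2]) if hypothesis == "H2" else None
        return q, d_I, qb

    def fit(self, hypothesis: str = "H1", n_restarts: int = 20,
            seed: int | None = None, fatol: float = 1e-12) -> "SterilityResults":
        """Multi-start Nelder-Mead minimisation of the squared deviations."""
        if hypothesis not in ("H0", "H1", "H2"):
            raise ValueError("hypothesis must be H0, H1 or H2")
        rng = np.random.default_rng(seed)
        n_par = 3 if hypothesis == "H2" else 2

        def neg(x):
            q, d_I, qb = self._unpack(x, hypothesis)
            return self.objective(hypothesis, q, d_I, qb)

        best, best_idx = None, -1
        for i in range(n_restarts):
            q0 = rng.uniform(0.2, 10.0)
            d0 = rng.uniform(0.2, 0.95)
            x0 = [special.logit(q0 / self.q_max), special.logit(d0)]
            if hypothesis == "H2":
                x0.append(special.logit(rng.uniform(0.2, 10.0) / self.q_max))
            res = optimize.minimize(
                neg, np.asarray(x0), method="Nelder-Mead",
                options={"fatol": fatol, "xatol": 1e-8, "maxiter": 4000 * n_par},
            )
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:  # ties keep the first occurrence
                best, best_idx = res, i
        if best is None:
            raise RuntimeError("all sterility-fit restarts failed")
        q, d_I, qb = self._unpack(best.x, hypothesis)
        spec = HypothesisSpec(hypothesis, q, qb if hypothesis == "H2" else None)
        return SterilityResults(
            model=self,
            params=SterilityParams(spec=spec, d_I=d_I),
            ls=float(best.fun),
            n_restarts=n_restarts,
            restart_best=best_idx,
            nfev=int(best.nfev),
            converged=bool(best.success),
        )


@dataclasses.dataclass
class SterilityResults:
    """Fitted sterility parameters with the least-squares value."""

    model: SterilityModel
    params: SterilityParams
    ls: float
    n_restarts: int
    restart_best: int
    nfev: int
    converged: bool

    @property
    def hypothesis(self) -> str:
        return self.params.spec.name

    @property
    def qc(self) -> float:
        return self.params.spec.qc

    @property
    def qb(self) -> float | None:
        return self.params.spec.qb

    @property
    def d_I(self) -> float:
        return self.params.d_I

    @property
    def at_q_bound(self) -> bool:
        """True when qc is pinned at the upper search bound."""
        return self.qc > 0.99 * self.model.q_max

    def fittedvalues(self) -> pd.DataFrame:
        exp = self.model.expected(self.hypothesis, self.qc, self.d_I, self.qb)
        out = self.model.data.copy()
        out["expected_sterility"] = exp
        out["residual"] = out["observed_sterility"] - exp
        return out

    def summary(self) -> str:
        lines = [
            f"Sterility least-squares fit ({self.hypothesis})",
            f"  inversions: {len(self.model.data)}",
            f"  qc  = {self.qc:.4g}" + ("  [at upper bound]" if self.at_q_bound else ""),
        ]
        if self.qb is not None:
            lines.append(f"  qb  = {self.qb:.4g}")
        lines += [
            f"  d_I = {self.d_I:.4g}",
            f"  LS  = {self.ls:.6g}",
            f"  restarts: {self.n_restarts} (best at {self.restart_best}, nfev {self.nfev})",
        ]
        if self.hypothesis == "H2":
            lines.append(
                "  note: H2 sterility optima are non-unique; qb is not separately"
                " identified by the two-region sterility curve"
            )
        return "\n".join(lines)


def fit_sterility(records, hypothesis_name: str = "H1", n_restarts: int = 20,
                  seed: int | None = None, q_max: float = 30.0
                  ) -> tuple[SterilityParams, float]:
    """Functional wrapper: fit and return (params, least-squares value)."""
    res = SterilityModel(records, q_max=q_max).fit(
        hypothesis_name, n_restarts=n_restarts, seed=seed
    )
    if hypothesis_name == "H2":
        warnings.warn("H2 sterility fit has multiple global optima (LS ties H1)")
    return res.params, res.ls
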