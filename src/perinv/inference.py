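"""Maximum-likelihood inference for recombination pattern counts.

Observed offspring of a heterokaryotype cross are tabulated by marker
recombination pattern; under the model the counts are multinomial with
cell probabilities given by the viable-conditioned pattern law of the
layout.  ``RecombinationModel`` fits the interference strength(s) and the
per-interval heterokaryotype lengths by multi-start Nelder-Mead, and the
results object carries lnL, AIC, the likelihood-ratio test between the
nested H1/H2 hypotheses and a parametric bootstrap for confidence
intervals.  The multinomial coefficient is omitted from lnL throughout
(it is constant in the parameters).
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .karyotype import ChromosomeLayout, HypothesisSpec, PatternDistributionEngine, map_ratio

__all__ = [
    "PatternDataset",
    "RecombinationModel",
    "RecombinationResults",
    "BootstrapSummary",
    "log_likelihood",
    "fit",
    "compare_aic",
    "likelihood_ratio_test",
    "parametric_bootstrap",
]

_LOG_FLOOR = 1e-300


@dataclasses.dataclass(frozen=True)
class PatternDataset:
    """Counts of offspring per marker recombination pattern.

    ``counts`` is indexed by pattern code: bit k of the code is the
    recombination indicator of interval k, interval 0 being the least
    significant bit.  Pattern strings (e.g. ``"0100110"``) list interval 0
    first.
    """

    marker_names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.marker_names)
        object.__setattr__(self, "marker_names", names)
        counts = np.asarray(self.counts)
        n = len(names) - 1
        if n < 1:
            raise ValueError("need at least two markers")
        if counts.shape != (2**n,):
            raise ValueError(f"counts must have 2^{n} entries")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.floor(counts)) or np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_intervals(self) -> int:
        return len(self.marker_names) - 1

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    def pattern_string(self, code: int) -> str:
        return "".join(str((code >> k) & 1) for k in range(self.n_intervals))

    @classmethod
    def from_counts_dict(cls, marker_names: Sequence[str], counts: dict[str, int]
                         ) -> "PatternDataset":
        n = len(marker_names) - 1
        arr = np.zeros(2**n, dtype=np.int64)
        for pattern, count in counts.items():
            if len(pattern) != n or set(pattern) - {"0", "1"}:
                raise ValueError(f"malformed pattern string {pattern!r}")
            code = sum(int(c) << k for k, c in enumerate(pattern))
            arr[code] += int(count)
        return cls(tuple(marker_names), arr)

    def marginal_recombinant_fractions(self) -> np.ndarray:
        """Observed per-interval recombinant fraction among viable offspring."""
        n = self.n_intervals
        codes = np.arange(2**n)
        frac = np.empty(n)
        for k in range(n):
            frac[k] = self.counts[(codes >> k) & 1 == 1].sum() / max(self.N, 1)
        return frac

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern": [self.pattern_string(c) for c in range(self.counts.size)],
                "count": self.counts,
            }
        )


def log_likelihood(dataset: PatternDataset, layout: ChromosomeLayout,
                   spec: HypothesisSpec, lengths: Sequence[float],
                   m: int | None = None, tol: float = 1e-12) -> float:
    """Multinomial log-likelihood (without the multinomial coefficient)."""
    model = RecombinationModel(dataset, layout, tol=tol, m=m)
    return model.loglike(spec, lengths)


class RecombinationModel:
    """Multinomial likelihood of pattern counts under the counting model.

    Parameters
    ----------
    dataset
        Observed pattern counts.
    layout
        Chromosome layout (hetero- or homokaryotype).  The layout's own
        length entries, if any, are ignored by fitting: lengths are free
        parameters.
    q_max
        Upper bound of the interference-strength search, default 30; the
        phase support is fixed at m = ceil(q_max) + 1 so matrices stay
        conformable across hypotheses.
    """

    def __init__(self, dataset: PatternDataset, layout: ChromosomeLayout,
                 q_max: float = 30.0, tol: float = 1e-12, m: int | None = None):
        if dataset.n_intervals != layout.n_intervals:
            raise ValueError("dataset and layout disagree on the interval count")
        self.dataset = dataset
        self.layout = layout
        self.q_max = float(q_max)
        self.m = int(m) if m is not None else int(np.ceil(self.q_max)) + 1
        self.tol = float(tol)
        self.engine = PatternDistributionEngine(layout, m=self.m, tol=self.tol)

    @property
    def n_intervals(self) -> int:
        return self.layout.n_intervals

    def distribution(self, spec: HypothesisSpec, lengths: Sequence[float]) -> np.ndarray:
        return self.engine.distribution(spec, lengths)

    def loglike(self, spec: HypothesisSpec, lengths: Sequence[float]) -> float:
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths <= 0):
            raise ValueError("interval lengths must be strictly positive")
        probs = self.distribution(spec, lengths)
        mask = self.dataset.counts > 0
        if np.any(probs[mask] <= 0):
            warnings.warn("observed pattern with zero model probability; lnL = -inf")
            return -np.inf
        return float(self.dataset.counts[mask]
                     @ np.log(np.maximum(probs[mask], _LOG_FLOOR)))

    # -- parameter packing ---------------------------------------------------

    def _n_params(self, hypothesis: str) -> int:
        return self.n_intervals + (2 if hypothesis == "H2" else 1)

    def _unpack(self, x: np.ndarray, hypothesis: str):
        n = self.n_intervals
        lengths = np.exp(x[:n])
        qc = self.q_max * special.expit(x[n])
        qb = self.q_max * special.expit(x[n + 1]) if hypothesis == "H2" else None
        spec = HypothesisSpec(hypothesis, qc, qb)
        return spec, lengths

    def _start_point(self, hypothesis: str, rng: np.random.Generator) -> np.ndarray:
        # lengths: Haldane-inverted observed recombinant fractions, jittered
        frac = np.clip(self.dataset.marginal_recombinant_fractions(), 5e-3, 0.45)
        l0 = -0.5 * np.log(1.0 - 2.0 * frac) * rng.uniform(0.5, 2.0, size=frac.size)
        x = list(np.log(l0))
        qs = 1 if hypothesis != "H2" else 2
        for _ in range(qs):
            q0 = rng.uniform(0.05, 10.0)
            x.append(special.logit(q0 / self.q_max))
        return np.asarray(x)

    def fit(self, hypothesis: str = "H1", n_restarts: int = 100,
            seed: int | None = None, fatol: float = 1e-8,
            maxiter: int | None = None) -> "RecombinationResults":
        """Best-of-restarts Nelder-Mead maximisation of the log-likelihood.

        The simplex runs unconstrained on transformed parameters (log
        lengths; logistic map of strengths onto [0, q_max]); ties between
        restarts keep the first occurrence.
        """
        if hypothesis not in ("H0", "H1", "H2"):
            raise ValueError("hypothesis must be H0, H1 or H2")
        rng = np.random.default_rng(seed)
        n_par = self._n_params(hypothesis)
        if maxiter is None:
            maxiter = 400 * n_par

        def neg(x):
            spec, lengths = self._unpack(x, hypothesis)
            if np.any(lengths > 5.0):  # > 500 cM per interval: out of domain
                return np.inf
            ll = self.loglike(spec, lengths)
            return np.inf if not np.isfinite(ll) else -ll

        best, best_idx, failures = None, -1, 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n_restarts):
                x0 = self._start_point(hypothesis, rng)
                res = optimize.minimize(
                    neg, x0, method="Nelder-Mead",
                    options={"fatol": fatol, "xatol": 1e-8, "maxiter": maxiter},
                )
                if not np.isfinite(res.fun):
                    failures += 1
                    continue
                if best is None or res.fun < best.fun:
                    best, best_idx = res, i
        if best is None:
            raise RuntimeError(f"all {n_restarts} restarts failed to converge")
        spec, lengths = self._unpack(best.x, hypothesis)
        lnL = -float(best.fun)
        k = n_par
        return RecombinationResults(
            model=self,
            spec=spec,
            lengths=lengths,
            lnL=lnL,
            k_params=k,
            aic=2.0 * k - 2.0 * lnL,
            n_restarts=n_restarts,
            restart_best=best_idx,
            nfev=int(best.nfev),
            n_failed_restarts=failures,
            converged=bool(best.success),
        )


@dataclasses.dataclass
class RecombinationResults:
    """Maximum-likelihood fit of one hypothesis to one dataset."""

    model: RecombinationModel
    spec: HypothesisSpec
    lengths: np.ndarray
    lnL: float
    k_params: int
    aic: float
    n_restarts: int
    restart_best: int
    nfev: int
    n_failed_restarts: int
    converged: bool

    @property
    def hypothesis(self) -> str:
        return self.spec.name

    @property
    def qc(self) -> float:
        return self.spec.qc

    @property
    def qb(self) -> float | None:
        return self.spec.qb

    @property
    def at_q_bound(self) -> bool:
        qs = [self.qc] + ([self.qb] if self.qb is not None else [])
        return any(q > 0.99 * self.model.q_max for q in qs)

    def params_dict(self) -> dict[str, float]:
        names = self.model.layout.interval_names()
        out = {f"l_{name}": float(v) for name, v in zip(names, self.lengths)}
        out["qc"] = self.qc
        if self.hypothesis == "H2":
            out["qb"] = self.qb
        return out

    def fitted_distribution(self) -> np.ndarray:
        return self.model.distribution(self.spec, self.lengths)

    def expected_counts(self) -> np.ndarray:
        return self.model.dataset.N * self.fitted_distribution()

    def residuals(self) -> np.ndarray:
        """Observed minus expected counts per pattern."""
        return self.model.dataset.counts - self.expected_counts()

    def map_table(self, l_homo: Sequence[float] | None = None) -> pd.DataFrame:
        """Genetic map in cM with d_k = l'_k / l_k where control lengths exist."""
        if l_homo is None:
            l_homo = self.model.layout.l_homo
        names = self.model.layout.interval_names()
        out = pd.DataFrame({"interval": names, "l_prime_cM": 100.0 * self.lengths})
        if l_homo is not None:
            l_homo = np.asarray(l_homo, dtype=float)
            out["l_homo_cM"] = 100.0 * l_homo
            out["d_k"] = [map_ratio(lp, lh) for lp, lh in zip(self.lengths, l_homo)]
        return out

    def simulate(self, seed: int | None = None, N: int | None = None) -> PatternDataset:
        """Draw a multinomial replicate dataset from the fitted pattern law."""
        rng = np.random.default_rng(seed)
        N = self.model.dataset.N if N is None else int(N)
        counts = rng.multinomial(N, self.fitted_distribution())
        return PatternDataset(self.model.dataset.marker_names, counts)

    def bootstrap(self, n_boot: int = 99, n_restarts: int = 100,
                  seed: int | None = None) -> "BootstrapSummary":
        return parametric_bootstrap(self, n_boot=n_boot, n_restarts=n_restarts, seed=seed)

    def summary(self) -> str:
        names = self.model.layout.interval_names()
        lines = [
            f"Recombination-pattern ML fit ({self.hypothesis})",
            f"  N = {self.model.dataset.N} offspring over {2**self.model.n_intervals}"
            f" patterns ({self.model.n_intervals} intervals)",
            f"  parameters: {self.k_params}",
            f"  qc  = {self.qc:.4g}" + ("  [near q bound]" if self.at_q_bound else ""),
        ]
        if self.hypothesis == "H2":
            lines.append(f"  qb  = {self.qb:.4g}")
        lines.append(f"  lnL = {self.lnL:.2f}   AIC = {self.aic:.2f}")
        for name, l in zip(names, self.lengths):
            lines.append(f"  l'({name}) = {100.0 * l:.2f} cM")
        lines.append(
            f"  restarts: {self.n_restarts} (best at {self.restart_best},"
            f" nfev {self.nfev}, failed {self.n_failed_restarts})"
        )
        return "\n".join(lines)


def fit(dataset: PatternDataset, layout: ChromosomeLayout, hypothesis_name: str,
        n_restarts: int = 100, seed: int | None = None,
        q_max: float = 30.0) -> RecombinationResults:
    """Functional wrapper around :meth:`RecombinationModel.fit`."""
    return RecombinationModel(dataset, layout, q_max=q_max).fit(
        hypothesis_name, n_restarts=n_restarts, seed=seed
    )


def compare_aic(fits: Sequence[RecombinationResults | object]) -> pd.DataFrame:
    """Delta-AIC table across fits of the same dataset (minimum gets 0)."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = [
        {
            "hypothesis": f.hypothesis,
            "k": getattr(f, "k_params", None),
            "lnL": f.lnL,
            "AIC": f.aic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows)
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    return table


def likelihood_ratio_test(fit_null: RecombinationResults,
                          fit_alt: RecombinationResults) -> tuple[float, float]:
    """Chi-square LRT of H1 (null) against H2 (alternative), df = 1."""
    if fit_alt.k_params != fit_null.k_params + 1:
        raise ValueError("alternative must have exactly one extra parameter")
    if fit_null.model.dataset is not fit_alt.model.dataset and not np.array_equal(
        fit_null.model.dataset.counts, fit_alt.model.dataset.counts
    ):
        raise ValueError("fits are not on the same dataset")
    chi2 = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclasses.dataclass
class BootstrapSummary:
    """Parametric-bootstrap point estimates and 95% intervals."""

    point: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_boot: int
    n_failed: int
    samples: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Parametric bootstrap ({self.n_boot} resamples, {self.n_failed} failed)"]
        lines.append("  95% intervals (2.5%/97.5% resample quantiles, two-sided"
                     " reading of 'most extreme 5% discarded'):")
        for name, est in self.point.items():
            lo, hi = self.ci[name]
            lines.append(f"  {name:>12s} = {est:9.4f}  ({lo:.4f} - {hi:.4f})")
        return "\n".join(lines)


def parametric_bootstrap(result: RecombinationResults, n_boot: int = 99,
                         n_restarts: int = 100, seed: int | None = None
                         ) -> BootstrapSummary:
    """Refit multinomial resamples drawn from the fitted pattern law.

    Resample b is generated and refitted with seed ``seed + b``; fits that
    raise or return non-finite lnL are excluded (with a warning if more
    than 5% are lost).  Intervals are the 2.5%/97.5% quantiles of the
    retained resample estimates.
    """
    if seed is None:
        seed = 0
    rows = []
    n_failed = 0
    for b in range(n_boot):
        replicate = result.simulate(seed=seed + b)
        try:
            refit = result.model.__class__(
                replicate, result.model.layout, q_max=result.model.q_max,
                tol=result.model.tol, m=result.model.m,
            ).fit(result.hypothesis, n_restarts=n_restarts, seed=seed + b)
        except RuntimeError:
            n_failed += 1
            continue
        if not np.isfinite(refit.lnL):
            n_failed += 1
            continue
        rows.append(refit.params_dict())
    if n_failed > 0.05 * n_boot:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap refits failed")
    if not rows:
        raise RuntimeError("all bootstrap refits failed")
    samples = pd.DataFrame(rows)
    point = result.params_dict()
    ci = {
        name: (float(np.quantile(samples[name], 0.025)),
               float(np.quantile(samples[name], 0.975)))
        for name in samples.columns
    }
    return BootstrapSummary(point=point, ci=ci, n_boot=n_boot,
                            n_failed=n_failed, samples=samples)
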