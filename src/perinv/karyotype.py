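"""Chromosome structure of a pericentric inversion heterokaryotype.

A chromosome carrying a heterozygous pericentric inversion is split by the
two breakpoints and the centromere into four regions — inner-left and
inner-right (between a breakpoint and the centromere) and outer-left and
outer-right (distal to the breakpoints).  Interference is blocked by the
centromere and does not cross the breakpoints, so the chiasma process runs
independently in each region, starting from the adjoining breakpoint with
a phase law that encodes the breakpoint-interference hypothesis:

* H0 — breakpoints do not interfere: start phase is the stationary law pi;
* H1 — breakpoints interfere exactly like chiasmata: start phase is gamma;
* H2 — breakpoints interfere with their own strength qb: start phase is
  the gamma-model law built from qb.

A gamete is *balanced* (viable) iff the transmitted chromatid shows equal
recombination parity in the two inner regions; observed marker patterns are
conditioned on balance.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

from .counting import (
    InterferenceDistribution,
    PhaseDistribution,
    chain_pattern_distribution,
    gamma_from_strength,
    stationary_phase,
)

__all__ = [
    "Placement",
    "ChromosomeLayout",
    "RegionDecomposition",
    "HypothesisSpec",
    "start_phase",
    "decompose",
    "subpattern_probability",
    "is_balanced",
    "marker_pattern_distribution",
    "map_ratio",
    "PatternDistributionEngine",
]

REGION_NAMES = ("inner_left", "inner_right", "outer_left", "outer_right")

#: more subintervals than this and exhaustive pattern enumeration is refused
MAX_SUBINTERVALS = 24


@dataclasses.dataclass(frozen=True)
class Placement:
    """A point on the marker map: interval index plus fraction of its length."""

    interval: int
    fraction: float

    def __post_init__(self) -> None:
        if self.interval < 0:
            raise ValueError("interval index must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("placement fraction must lie in [0, 1]")

    @property
    def position(self) -> float:
        """Map position in interval units (interval + fraction)."""
        return self.interval + self.fraction


@dataclasses.dataclass(frozen=True)
class ChromosomeLayout:
    """Marker map plus breakpoint/centromere placements.

    ``marker_names`` has n+1 entries bounding n intervals.  ``l_prime``
    (heterokaryotype) and ``l_homo`` (homokaryotype) per-interval genetic
    lengths are in Morgans and optional: fitting treats lengths as free
    parameters and supplies them separately.  A homokaryotype layout has no
    placements.
    """

    marker_names: tuple[str, ...]
    karyotype: str = "hetero"
    left_bp: Placement | None = None
    centromere: Placement | None = None
    right_bp: Placement | None = None
    l_prime: np.ndarray | None = None
    l_homo: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = tuple(self.marker_names)
        object.__setattr__(self, "marker_names", names)
        if len(names) < 2:
            raise ValueError("need at least two markers")
        if self.karyotype not in ("hetero", "homo"):
            raise ValueError("karyotype must be 'hetero' or 'homo'")
        n = self.n_intervals
        for field in ("l_prime", "l_homo"):
            val = getattr(self, field)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{field} must have one entry per interval")
                if np.any(arr < 0):
                    raise ValueError(f"{field} entries must be >= 0")
                object.__setattr__(self, field, arr)
        if self.karyotype == "homo":
            if any(p is not None for p in (self.left_bp, self.centromere, self.right_bp)):
                raise ValueError("homokaryotype layouts carry no placements")
            return
        if any(p is None for p in (self.left_bp, self.centromere, self.right_bp)):
            raise ValueError("heterokaryotype layouts need both breakpoints and the centromere")
        for p in (self.left_bp, self.centromere, self.right_bp):
            if p.interval >= n:
                raise ValueError("placement interval index out of range")
        if not (self.left_bp.position < self.centromere.position < self.right_bp.position):
            raise ValueError(
                "pericentric ordering violated: need left breakpoint < centromere < right breakpoint"
            )

    @property
    def n_intervals(self) -> int:
        return len(self.marker_names) - 1

    def interval_names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in itertools.pairwise(self.marker_names)]


@dataclasses.dataclass(frozen=True)
class RegionDecomposition:
    """The four independent region chains of a heterokaryotype.

    Each chain is an ordered tuple of ``(parent_interval, share)`` pairs —
    the share being the fraction of the parent marker interval's genetic
    length carried by that subinterval.  Chains are oriented starting from
    the adjoining breakpoint: the inner chains run toward the centromere,
    the outer chains toward the terminal markers.
    """

    inner_left: tuple[tuple[int, float], ...]
    inner_right: tuple[tuple[int, float], ...]
    outer_left: tuple[tuple[int, float], ...]
    outer_right: tuple[tuple[int, float], ...]

    @property
    def chains(self) -> tuple[tuple[tuple[int, float], ...], ...]:
        return (self.inner_left, self.inner_right, self.outer_left, self.outer_right)

    @property
    def subintervals(self) -> list[tuple[int, float]]:
        """Global subinterval order: inner-left, inner-right, outer-left, outer-right."""
        return [piece for chain in self.chains for piece in chain]

    @property
    def n_sub(self) -> int:
        return len(self.subintervals)

    def region_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, chain in zip(REGION_NAMES, self.chains):
            out[name] = slice(start, start + len(chain))
            start += len(chain)
        return out

    def chain_lengths(self, lengths: Sequence[float]) -> list[np.ndarray]:
        """Morgan lengths of each chain's subintervals given per-interval lengths."""
        lengths = np.asarray(lengths, dtype=float)
        return [
            np.array([lengths[parent] * share for parent, share in chain])
            for chain in self.chains
        ]


@dataclasses.dataclass(frozen=True)
class HypothesisSpec:
    """One of the three breakpoint-interference hypotheses.

    ``qc`` is the chiasma-chiasma interference strength; ``qb`` the
    breakpoint-chiasma strength (H2 only — under H1 it equals ``qc`` and
    under H0 the breakpoints do not interfere at all).
    """

    name: str
    qc: float
    qb: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("H0", "H1", "H2"):
            raise ValueError("hypothesis name must be H0, H1 or H2")
        if self.qc < 0:
            raise ValueError("qc must be >= 0")
        if self.name == "H1":
            object.__setattr__(self, "qb", float(self.qc))
        elif self.name == "H0":
            object.__setattr__(self, "qb", None)
        elif self.qb is None or self.qb < 0:
            raise ValueError("H2 requires qb >= 0")


def start_phase(spec: HypothesisSpec, m: int) -> PhaseDistribution:
    """Phase law at a breakpoint under the given hypothesis (support 0..m)."""
    gamma = gamma_from_strength(spec.qc, m)
    if spec.name == "H0":
        return stationary_phase(gamma)
    if spec.name == "H1":
        return PhaseDistribution(gamma.gamma)
    return PhaseDistribution(gamma_from_strength(spec.qb, m).gamma)


def decompose(layout: ChromosomeLayout) -> RegionDecomposition:
    """Cut the marker map at the breakpoints and centromere into four chains.

    Marker intervals containing a cut point are split at the placement
    fraction; zero-length pieces are dropped.  Within each parent interval
    the retained shares sum to 1.
    """
    if layout.karyotype != "hetero":
        raise ValueError("decompose applies to heterokaryotype layouts")
    cuts = (layout.left_bp, layout.centromere, layout.right_bp)
    pieces: list[tuple[float, int, float]] = []  # (genomic start pos, parent, share)
    for k in range(layout.n_intervals):
        fracs = sorted({0.0, 1.0} | {c.fraction for c in cuts if c.interval == k})
        for lo, hi in itertools.pairwise(fracs):
            if hi > lo:
                pieces.append((k + lo, k, hi - lo))
    p_l, p_c, p_r = (c.position for c in cuts)
    regions: dict[str, list[tuple[int, float]]] = {name: [] for name in REGION_NAMES}
    for start, parent, share in pieces:
        mid = start + share * 0.5  # midpoints never coincide with a cut
        if mid < p_l:
            regions["outer_left"].append((parent, share))
        elif mid < p_c:
            regions["inner_left"].append((parent, share))
        elif mid < p_r:
            regions["inner_right"].append((parent, share))
        else:
            regions["outer_right"].append((parent, share))
    return RegionDecomposition(
        inner_left=tuple(regions["inner_left"]),
        inner_right=tuple(reversed(regions["inner_right"])),
        outer_left=tuple(reversed(regions["outer_left"])),
        outer_right=tuple(regions["outer_right"]),
    )


def is_balanced(decomp: RegionDecomposition, subpattern: Sequence[int]) -> bool:
    """Viability of a gamete with the given global subinterval pattern.

    Balanced iff the recombination parity of the inner-left chain equals
    that of the inner-right chain; recombination in exactly one inner
    region leaves the gamete with an incomplete gene set.
    """
    subpattern = np.asarray(subpattern, dtype=int)
    if subpattern.size != decomp.n_sub:
        raise ValueError("subpattern length must equal the subinterval count")
    sl = decomp.region_slices()
    par_left = int(subpattern[sl["inner_left"]].sum()) % 2
    par_right = int(subpattern[sl["inner_right"]].sum()) % 2
    return par_left == par_right


def subpattern_probability(decomp: RegionDecomposition, spec: HypothesisSpec,
                           gamma: InterferenceDistribution,
                           lengths: Sequence[float],
                           subpattern: Sequence[int],
                           tol: float = 1e-12) -> float:
    """Joint probability of a full subinterval pattern (regions independent)."""
    subpattern = list(subpattern)
    if len(subpattern) != decomp.n_sub:
        raise ValueError("subpattern length must equal the subinterval count")
    omega = start_phase(spec, gamma.m)
    prob = 1.0
    pos = 0
    for chain, chain_l in zip(decomp.chains, decomp.chain_lengths(lengths)):
        lams = 2.0 * chain_l * gamma.mean_spacing
        bits = subpattern[pos : pos + len(chain)]
        pos += len(chain)
        dist = chain_pattern_distribution(omega, lams, gamma, tol=tol)
        code = sum(b << k for k, b in enumerate(bits))
        prob *= float(dist[code])
    return prob


def map_ratio(l_prime: float, l_homo: float) -> float:
    """d_k = l'_k / l_k: inversion-induced change in an interval's map length."""
    if l_homo <= 0:
        raise ValueError("homokaryotype length must be > 0")
    return float(l_prime) / float(l_homo)


class PatternDistributionEngine:
    """Precomputed machinery for marker-pattern distributions of one layout.

    The decomposition, the XOR tables mapping region patterns onto marker
    intervals and the viability mask depend only on the layout, so they are
    built once; :meth:`distribution` then evaluates the viable-conditioned
    marker-pattern law for any hypothesis and length vector.  This is the
    hot path of maximum-likelihood fitting.
    """

    def __init__(self, layout: ChromosomeLayout, m: int, tol: float = 1e-12):
        self.layout = layout
        self.m = int(m)
        self.tol = float(tol)
        self.n = layout.n_intervals
        if layout.karyotype == "hetero":
            self.decomp = decompose(layout)
            if self.decomp.n_sub > MAX_SUBINTERVALS:
                raise ValueError(
                    f"{self.decomp.n_sub} subintervals exceed the enumeration guard "
                    f"({MAX_SUBINTERVALS})"
                )
            self._build_tables()
        else:
            self.decomp = None

    def _build_tables(self) -> None:
        codes, parities = [], []
        for chain in self.decomp.chains:
            c = np.zeros(1, dtype=np.int64)
            p = np.zeros(1, dtype=np.int64)
            for parent, _share in chain:
                c = np.concatenate([c, c ^ (1 << parent)])
                p = np.concatenate([p, p ^ 1])
            codes.append(c)
            parities.append(p)
        cA, cB, cC, cD = codes
        code4 = (
            cA[:, None, None, None]
            ^ cB[None, :, None, None]
            ^ cC[None, None, :, None]
            ^ cD[None, None, None, :]
        )
        bal4 = np.broadcast_to(
            (parities[0][:, None] == parities[1][None, :])[:, :, None, None], code4.shape
        )
        self._code_flat = np.ascontiguousarray(code4).ravel()
        self._bal_flat = np.ascontiguousarray(bal4).ravel().astype(float)

    def _region_probs(self, spec: HypothesisSpec, lengths: np.ndarray) -> list[np.ndarray]:
        """Per-region pattern distributions, caching matrices by rate.

        Subintervals split 50/50 share identical rates, so H/G pairs are
        memoised per lambda within one evaluation.
        """
        from .counting import _hg_matrices, _renewal_b, truncation_length

        gamma = gamma_from_strength(spec.qc, self.m)
        omega = start_phase(spec, self.m)
        mult = gamma.mean_spacing
        chain_lams = [2.0 * cl * mult for cl in self.decomp.chain_lengths(lengths)]
        all_lams = np.concatenate([cl for cl in chain_lams if cl.size])
        tmax = max(
            (truncation_length(lam, self.m, self.tol) for lam in all_lams), default=0
        )
        b = _renewal_b(gamma.gamma, tmax)
        cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

        def matrices(lam: float):
            if lam not in cache:
                H, G = _hg_matrices(lam, gamma, b=b, tol=self.tol)
                cache[lam] = (0.5 * G + H, 0.5 * G)
            return cache[lam]

        region_probs = []
        for lams in chain_lams:
            V = omega.omega[None, :]
            for lam in lams:
                M0, M1 = matrices(float(lam))
                V = np.vstack([V @ M0, V @ M1])
            region_probs.append(V.sum(axis=1))
        return region_probs

    def distribution(self, spec: HypothesisSpec, lengths: Sequence[float],
                     conditioned: bool = True) -> np.ndarray:
        """Marker-pattern law (length 2^n) for one hypothesis and length vector.

        For heterokaryotypes the law is conditioned on gamete balance unless
        ``conditioned=False``; homokaryotypes use the unconditioned chain
        with the stationary start phase.
        """
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n,):
            raise ValueError("lengths must have one entry per marker interval")
        if self.layout.karyotype == "homo":
            gamma = gamma_from_strength(spec.qc, self.m)
            lams = 2.0 * lengths * gamma.mean_spacing
            return chain_pattern_distribution(stationary_phase(gamma), lams, gamma, tol=self.tol)
        pA, pB, pC, pD = self._region_probs(spec, lengths)
        prob4 = np.einsum("i,j,k,l->ijkl", pA, pB, pC, pD).ravel()
        if conditioned:
            weights = prob4 * self._bal_flat
            total = weights.sum()
            if total <= 0:
                raise ZeroDivisionError("no balanced probability mass")
            dist = np.bincount(self._code_flat, weights=weights, minlength=2**self.n)
            return dist / total
        return np.bincount(self._code_flat, weights=prob4, minlength=2**self.n)

    def balanced_probability(self, spec: HypothesisSpec, lengths: Sequence[float]) -> float:
        """Probability that a gamete is balanced (viable), i.e. 1 - sterility."""
        lengths = np.asarray(lengths, dtype=float)
        pA, pB, pC, pD = self._region_probs(spec, lengths)
        prob4 = np.einsum("i,j,k,l->ijkl", pA, pB, pC, pD).ravel()
        return float(np.dot(prob4, self._bal_flat))


def marker_pattern_distribution(layout: ChromosomeLayout, spec: HypothesisSpec,
                                lengths: Sequence[float] | None = None,
                                m: int | None = None,
                                tol: float = 1e-12) -> np.ndarray:
    """Viable-conditioned marker recombination-pattern law of a layout.

    Convenience wrapper building a :class:`PatternDistributionEngine` for a
    single evaluation.  ``lengths`` defaults to the layout's ``l_prime``.
    ``m`` defaults to the smallest support holding both strengths.
    """
    if lengths is None:
        if layout.l_prime is None:
            raise ValueError("no lengths supplied and layout carries none")
        lengths = layout.l_prime
    if m is None:
        qs = [spec.qc] + ([spec.qb] if spec.qb is not None else [])
        m = max(int(np.ceil(q)) + 1 for q in qs) if max(qs) > 0 else 1
    return PatternDistributionEngine(layout, m=m, tol=tol).distribution(spec, lengths)
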