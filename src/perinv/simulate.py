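"""Monte-Carlo realisation of the chiasma counting process.

Events (dummy + chiasma) form a unit-rate Poisson stream on the cumulative
event-rate (lambda) axis of a region chain, so the simulator works
directly in event space: the first chiasma arrives after an Omega-drawn
number of dummy events — an Erlang(omega+1) gap — and each later chiasma
after a gamma-drawn number.  Chiasmata are binned by subinterval; each is
then transmitted to the sampled chromatid independently with probability
1/2 (no chromatid interference).

The simulator is the brute-force oracle for every analytic probability in
the package, and the generator of synthetic pattern datasets and sterility
records.  All routines are vectorised across gametes.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .counting import InterferenceDistribution, PhaseDistribution, gamma_from_strength, stationary_phase
from .inference import PatternDataset
from .karyotype import ChromosomeLayout, HypothesisSpec, decompose, start_phase
from .sterility import SterilityParams, SterilityRecord, sterility

__all__ = [
    "SimulatedGamete",
    "simulate_region",
    "simulate_gamete",
    "simulate_gametes",
    "synthesize_pattern_dataset",
    "synthesize_sterility_records",
]


@dataclasses.dataclass(frozen=True)
class SimulatedGamete:
    """One sampled chromatid: crossover counts, marker pattern, viability."""

    crossovers: np.ndarray  # thinned crossover count per global subinterval
    marker_pattern: np.ndarray  # recombination indicator per marker interval
    balanced: bool


def _chain_chiasma_counts(boundaries: np.ndarray, omega_p: np.ndarray,
                          gamma_p: np.ndarray, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Chiasma counts per subinterval for n independent chains.

    ``boundaries`` are cumulative lambda positions (leading 0); returns an
    (n, n_sub) integer array.
    """
    n_sub = boundaries.size - 1
    counts = np.zeros((n, n_sub), dtype=np.int64)
    total = float(boundaries[-1])
    if total == 0.0 or n == 0:
        return counts
    draws = rng.choice(omega_p.size, size=n, p=omega_p)
    pos = rng.gamma(shape=draws + 1.0)  # Erlang gap to the first chiasma
    active = pos < total
    while active.any():
        rows = np.nonzero(active)[0]
        idx = np.searchsorted(boundaries, pos[rows], side="right") - 1
        counts[rows, idx] += 1
        gaps = rng.gamma(shape=rng.choice(gamma_p.size, size=rows.size, p=gamma_p) + 1.0)
        pos[rows] += gaps
        active[rows] = pos[rows] < total
    return counts


def simulate_region(chain_lams: Sequence[float], gamma: InterferenceDistribution,
                    omega: PhaseDistribution, rng: np.random.Generator,
                    n: int = 1) -> np.ndarray:
    """Chiasma counts per subinterval of one region chain ((n, n_sub) array)."""
    lams = np.asarray(chain_lams, dtype=float)
    if np.any(lams < 0):
        raise ValueError("subinterval rates must be >= 0")
    boundaries = np.concatenate([[0.0], np.cumsum(lams)])
    om = omega.padded(gamma.m) if omega.m < gamma.m else omega
    return _chain_chiasma_counts(boundaries, om.omega, gamma.gamma, n, rng)


def simulate_gametes(layout: ChromosomeLayout, spec: HypothesisSpec,
                     lengths: Sequence[float], n: int,
                     rng: np.random.Generator, m: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate n gametes; returns (marker_codes, balanced, crossovers).

    ``marker_codes`` are pattern codes (bit k = interval k); ``balanced``
    is the viability flag; ``crossovers`` the thinned per-subinterval
    counts (homokaryotypes: one subinterval per marker interval).
    """
    lengths = np.asarray(lengths, dtype=float)
    if m is None:
        qs = [spec.qc] + ([spec.qb] if spec.qb is not None else [])
        m = max(int(np.ceil(q)) + 1 for q in qs) if max(qs) > 0 else 1
    gamma = gamma_from_strength(spec.qc, m)
    mult = gamma.mean_spacing
    n_int = layout.n_intervals

    if layout.karyotype == "homo":
        omega = stationary_phase(gamma)
        lams = 2.0 * lengths * mult
        chiasmata = simulate_region(lams, gamma, omega, rng, n=n)
        thinned = rng.binomial(chiasmata, 0.5)
        codes = ((thinned % 2) << np.arange(n_int)[None, :]).sum(axis=1)
        return codes, np.ones(n, dtype=bool), thinned

    omega = start_phase(spec, m)
    decomp = decompose(layout)
    all_thinned = []
    codes = np.zeros(n, dtype=np.int64)
    inner_parity = {}
    for name_idx, (chain, chain_l) in enumerate(
        zip(decomp.chains, decomp.chain_lengths(lengths))
    ):
        lams = 2.0 * chain_l * mult
        chiasmata = simulate_region(lams, gamma, omega, rng, n=n)
        thinned = rng.binomial(chiasmata, 0.5)
        all_thinned.append(thinned)
        parents = np.array([p for p, _ in chain], dtype=np.int64)
        if parents.size:
            bits = thinned % 2
            # XOR subinterval parities onto their parent marker intervals
            for col, parent in enumerate(parents):
                codes ^= bits[:, col].astype(np.int64) << int(parent)
        if name_idx in (0, 1):
            inner_parity[name_idx] = thinned.sum(axis=1) % 2
    balanced = inner_parity[0] == inner_parity[1]
    crossovers = np.concatenate(all_thinned, axis=1)
    return codes, balanced, crossovers


def simulate_gamete(layout: ChromosomeLayout, spec: HypothesisSpec,
                    lengths: Sequence[float], rng: np.random.Generator,
                    m: int | None = None) -> SimulatedGamete:
    """Single-gamete convenience wrapper around :func:`simulate_gametes`."""
    codes, balanced, crossovers = simulate_gametes(layout, spec, lengths, 1, rng, m=m)
    n_int = layout.n_intervals
    pattern = np.array([(int(codes[0]) >> k) & 1 for k in range(n_int)], dtype=np.int64)
    return SimulatedGamete(crossovers[0], pattern, bool(balanced[0]))


def synthesize_pattern_dataset(layout: ChromosomeLayout, spec: HypothesisSpec,
                               lengths: Sequence[float], N: int,
                               rng: np.random.Generator,
                               m: int | None = None,
                               return_acceptance: bool = False):
    """Tabulate N viable gametes into a PatternDataset (rejection sampling).

    Unbalanced gametes are discarded and re-drawn; the acceptance
    probability equals 1 minus the sterility of the layout's inner
    regions, available via ``return_acceptance``.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    n_int = layout.n_intervals
    kept = np.zeros(2**n_int, dtype=np.int64)
    n_drawn = n_balanced = 0
    remaining = N
    while remaining > 0:
        batch = max(int(1.5 * remaining), 1000)
        codes, balanced, _ = simulate_gametes(layout, spec, lengths, batch, rng, m=m)
        n_drawn += batch
        n_balanced += int(balanced.sum())
        good = codes[balanced][:remaining]
        kept += np.bincount(good, minlength=2**n_int)
        remaining = N - int(kept.sum())
    dataset = PatternDataset(layout.marker_names, kept)
    if return_acceptance:
        return dataset, n_balanced / n_drawn
    return dataset


def synthesize_sterility_records(params: SterilityParams,
                                 inversions: Sequence[tuple[float, float]],
                                 noise_sd: float,
                                 rng: np.random.Generator,
                                 m: int | None = None) -> list[SterilityRecord]:
    """Sterility records on the model surface, plus truncated Gaussian noise.

    ``inversions`` is a sequence of (I, rho) pairs in homokaryotype
    Morgans; the expected sterility is evaluated at I' = d_I * I.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spec = params.spec
    if m is None:
        qs = [spec.qc] + ([spec.qb] if spec.qb is not None else [])
        m = max(int(np.ceil(q)) + 1 for q in qs) if max(qs) > 0 else 1
    gamma = gamma_from_strength(spec.qc, m)
    omega = start_phase(spec, m)
    records = []
    for i, (I, rho) in enumerate(inversions):
        zeta = sterility(params.d_I * I, rho, gamma, omega)
        obs = zeta if noise_sd == 0 else float(
            np.clip(zeta + rng.normal(0.0, noise_sd), 0.0, 1.0)
        )
        records.append(SterilityRecord(f"inv{i:02d}", float(I), float(rho), obs))
    return records
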