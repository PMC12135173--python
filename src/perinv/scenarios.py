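"""Built-in study scenarios: the D. melanogaster In(3LR) inversion system.

Three pericentric inversions on chromosome 3 — In(3LR)165, In(3LR)190 and
In(3LR)269 — were scored for recombination against the marker map
ve-h-th-cu-bx-e-ro-ca, whose centromere sits in the th-cu interval.  This
module encodes their layouts (which marker intervals hold the breakpoints
and the centromere), the published H1-model parameter estimates
(interference strength q and heterokaryotype map), and sample sizes
implied by the reported log-likelihood magnitudes.  The scenarios drive
simulation studies: synthetic datasets generated here have the size,
marker geometry and parameter regime of the real crosses.

Split fractions follow the package convention: 0.5 for a single interior
placement, thirds when an interval holds both a breakpoint and the
centromere (as th-cu does for inversions 165 and 269).
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .karyotype import ChromosomeLayout, HypothesisSpec, Placement
from .sterility import SterilityParams

__all__ = ["Scenario", "MARKERS", "CONTROL_CM", "SCENARIOS",
           "STERILITY_H1_PARAMS", "STERILITY_NOISE_SD", "sterility_panel"]

MARKERS = ("ve", "h", "th", "cu", "bx", "e", "ro", "ca")

#: homokaryotype control map (cM) for the seven marker intervals
CONTROL_CM = (27.6, 18.4, 4.5, 9.0, 15.8, 23.0, 11.4)


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One inversion cross: layout, H1 parameter regime and sample size."""

    name: str
    layout: ChromosomeLayout
    q_h1: float
    lengths_cm: tuple[float, ...]  # heterokaryotype H1 map estimates, cM
    n_offspring: int
    q_ci_95: tuple[float, float]  # published 95% bootstrap interval for q

    @property
    def lengths(self) -> np.ndarray:
        """Heterokaryotype interval lengths in Morgans."""
        return np.asarray(self.lengths_cm, dtype=float) / 100.0

    @property
    def spec(self) -> HypothesisSpec:
        return HypothesisSpec("H1", self.q_h1)

    @property
    def control_lengths(self) -> np.ndarray:
        return np.asarray(CONTROL_CM, dtype=float) / 100.0


def _layout(left: tuple[int, float], cen: tuple[int, float],
            right: tuple[int, float]) -> ChromosomeLayout:
    return ChromosomeLayout(
        marker_names=MARKERS,
        karyotype="hetero",
        left_bp=Placement(*left),
        centromere=Placement(*cen),
        right_bp=Placement(*right),
        l_homo=np.asarray(CONTROL_CM) / 100.0,
    )


SCENARIOS: dict[str, Scenario] = {
    # breakpoints in ve-h and th-cu; th-cu also holds the centromere
    "In(3LR)165": Scenario(
        name="In(3LR)165",
        layout=_layout((0, 0.5), (2, 1.0 / 3.0), (2, 2.0 / 3.0)),
        q_h1=2.92,
        lengths_cm=(25.4, 19.8, 24.5, 15.5, 15.4, 28.0, 14.0),
        n_offspring=3100,
        q_ci_95=(2.53, 3.77),
    ),
    # breakpoints in h-th and cu-bx, centromere alone in th-cu
    "In(3LR)190": Scenario(
        name="In(3LR)190",
        layout=_layout((1, 0.5), (2, 0.5), (3, 0.5)),
        q_h1=8.57,
        lengths_cm=(16.2, 21.4, 1.0, 0.7, 21.5, 21.0, 11.3),
        n_offspring=4100,
        q_ci_95=(6.92, 10.15),
    ),
    # breakpoints in th-cu (with the centromere) and ro-ca
    "In(3LR)269": Scenario(
        name="In(3LR)269",
        layout=_layout((2, 1.0 / 3.0), (2, 2.0 / 3.0), (6, 0.5)),
        q_h1=3.92,
        lengths_cm=(27.1, 24.5, 37.3, 16.2, 11.8, 12.1, 17.6),
        n_offspring=5300,
        q_ci_95=(2.95, 4.91),
    ),
}

#: published H1 sterility-fit regime for the chromosome-3 inversion panel
STERILITY_H1_PARAMS = SterilityParams(spec=HypothesisSpec("H1", 3.72), d_I=0.78)

#: residual scale matching the H1 least-squares value of ~0.096 over 30
#: inversions (RMS deviation sqrt(0.096 / 30) ~ 0.057)
STERILITY_NOISE_SD = 0.056


def sterility_panel(rng: np.random.Generator, n_inversions: int = 30
                    ) -> list[tuple[float, float]]:
    """Draw (I, rho) geometries for a panel of pericentric inversions.

    Homokaryotype lengths I are uniform on 0.1-1.1 Morgans and centromere
    positions rho uniform on 0.15-0.85 — the span of medium-to-large
    pericentric inversions on a Drosophila autosome.
    """
    I = rng.uniform(0.1, 1.1, size=n_inversions)
    rho = rng.uniform(0.15, 0.85, size=n_inversions)
    return list(zip(I.tolist(), rho.tolist()))
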