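from pathlib import Path

import numpy as np
import pytest

import perinv as pv

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def toy_layout() -> pv.ChromosomeLayout:
    """Four marker intervals; breakpoints and centromere mid-interval."""
    return pv.ChromosomeLayout(
        marker_names=("a", "b", "c", "d", "e"),
        karyotype="hetero",
        left_bp=pv.Placement(0, 0.5),
        centromere=pv.Placement(1, 0.5),
        right_bp=pv.Placement(2, 0.5),
    )


@pytest.fixture(scope="session")
def toy_lengths() -> np.ndarray:
    return np.array([0.15, 0.10, 0.20, 0.25])


@pytest.fixture(scope="session")
def small_layout() -> pv.ChromosomeLayout:
    """Three intervals with placements at boundaries or midpoints (4 subintervals)."""
    return pv.ChromosomeLayout(
        marker_names=("a", "b", "c", "d"),
        karyotype="hetero",
        left_bp=pv.Placement(1, 0.0),
        centromere=pv.Placement(1, 0.5),
        right_bp=pv.Placement(2, 0.0),
    )


@pytest.fixture(scope="session")
def small_lengths() -> np.ndarray:
    return np.array([0.20, 0.12, 0.18])


@pytest.fixture(scope="session")
def spec_h1_q4() -> pv.HypothesisSpec:
    return pv.HypothesisSpec("H1", 4.0)
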