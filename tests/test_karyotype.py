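"""Region decomposition, start phases, viability and pattern distributions."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perinv as pv
from perinv.karyotype import PatternDistributionEngine


# -- start phases ------------------------------------------------------------


def test_start_phase_per_hypothesis():
    m = 5
    h1 = pv.start_phase(pv.HypothesisSpec("H1", 4.0), m)
    assert np.allclose(h1.omega, [0, 0, 0, 0, 1, 0])
    h0 = pv.start_phase(pv.HypothesisSpec("H0", 4.0), m)
    assert np.allclose(h0.omega, [0.2] * 5 + [0.0])
    h2 = pv.start_phase(pv.HypothesisSpec("H2", 4.0, 2.5), m)
    assert np.allclose(h2.omega, [0, 0, 0.5, 0.5, 0, 0])


def test_hypothesis_spec_constraints():
    spec = pv.HypothesisSpec("H1", 3.0)
    assert spec.qb == 3.0  # H1 forces equal strengths
    assert pv.HypothesisSpec("H0", 3.0).qb is None
    with pytest.raises(ValueError):
        pv.HypothesisSpec("H3", 1.0)
    with pytest.raises(ValueError):
        pv.HypothesisSpec("H2", 1.0)  # qb missing


# -- layout validation -------------------------------------------------------


def test_layout_rejects_misordered_placements():
    with pytest.raises(ValueError):
        pv.ChromosomeLayout(
            marker_names=("a", "b", "c"),
            left_bp=pv.Placement(1, 0.5),
            centromere=pv.Placement(0, 0.5),
            right_bp=pv.Placement(1, 0.8),
        )


def test_layout_rejects_bad_fraction():
    with pytest.raises(ValueError):
        pv.Placement(0, 1.5)


# -- decomposition -----------------------------------------------------------


def test_decompose_at_boundaries_no_splits():
    layout = pv.ChromosomeLayout(
        marker_names=("a", "b", "c", "d", "e"),
        left_bp=pv.Placement(1, 0.0),
        centromere=pv.Placement(2, 0.0),
        right_bp=pv.Placement(3, 0.0),
    )
    d = pv.decompose(layout)
    assert d.outer_left == ((0, 1.0),)
    assert d.inner_left == ((1, 1.0),)
    assert d.inner_right == ((2, 1.0),)
    assert d.outer_right == ((3, 1.0),)


def test_decompose_triple_split_interval():
    # one interval holds the centromere and the right breakpoint
    layout = pv.ChromosomeLayout(
        marker_names=("a", "b", "c"),
        left_bp=pv.Placement(0, 0.5),
        centromere=pv.Placement(1, 1 / 3),
        right_bp=pv.Placement(1, 2 / 3),
    )
    d = pv.decompose(layout)
    assert d.inner_left == ((0, 0.5), (1, pytest.approx(1 / 3)))
    assert d.inner_right == ((1, pytest.approx(1 / 3)),)
    assert d.outer_left == ((0, 0.5),)
    assert d.outer_right == ((1, pytest.approx(1 / 3)),)


def test_inner_right_chain_starts_at_breakpoint(toy_layout):
    # orientation: inner-right runs from the right breakpoint toward the
    # centromere, i.e. reversed genomic order
    d = pv.decompose(toy_layout)
    assert [p for p, _ in d.inner_right] == [2, 1]
    assert [p for p, _ in d.outer_left] == [0]


@given(
    fl=st.floats(0.0, 1.0),
    fc=st.floats(0.01, 0.99),
    fr=st.floats(0.0, 1.0),
)
@settings(max_examples=40, derandomize=True, deadline=None)
def test_decompose_conserves_interval_shares(fl, fc, fr):
    layout = pv.ChromosomeLayout(
        marker_names=("a", "b", "c", "d", "e", "f"),
        left_bp=pv.Placement(1, fl),
        centromere=pv.Placement(2, fc),
        right_bp=pv.Placement(3, fr),
    )
    d = pv.decompose(layout)
    shares = np.zeros(layout.n_intervals)
    for parent, share in d.subintervals:
        shares[parent] += share
    assert np.allclose(shares, 1.0)


# -- viability ---------------------------------------------------------------


def test_balance_rule(toy_layout):
    d = pv.decompose(toy_layout)
    n = d.n_sub
    assert pv.is_balanced(d, [0] * n)
    sl = d.region_slices()
    one_inner_left = [0] * n
    one_inner_left[sl["inner_left"].start] = 1
    assert not pv.is_balanced(d, one_inner_left)
    both_inner = list(one_inner_left)
    both_inner[sl["inner_right"].start] = 1
    assert pv.is_balanced(d, both_inner)
    outer_only = [0] * n
    outer_only[sl["outer_left"].start] = 1
    assert pv.is_balanced(d, outer_only)


# -- subpattern probabilities ------------------------------------------------


def test_subpattern_probability_degenerate(toy_layout):
    d = pv.decompose(toy_layout)
    gamma = pv.gamma_from_strength(4.0, 5)
    spec = pv.HypothesisSpec("H1", 4.0)
    p = pv.subpattern_probability(d, spec, gamma, [0.0] * 4, [0] * d.n_sub)
    assert p == pytest.approx(1.0)


def test_subpattern_probability_haldane_product(toy_layout, toy_lengths):
    d = pv.decompose(toy_layout)
    gamma = pv.gamma_from_strength(0.0)
    spec = pv.HypothesisSpec("H1", 0.0)
    sub_l = np.concatenate(d.chain_lengths(toy_lengths))
    pattern = [(i * 5 + 3) % 2 for i in range(d.n_sub)]  # alternating bits
    expected = 1.0
    for bit, l in zip(pattern, sub_l):
        p = 0.5 * (1 - math.exp(-2 * l))
        expected *= p if bit else 1 - p
    got = pv.subpattern_probability(d, spec, gamma, toy_lengths, pattern)
    assert got == pytest.approx(expected, abs=1e-10)


# -- marker pattern distribution ---------------------------------------------


def _brute_marker_distribution(layout, spec, gamma, lengths):
    """Independent oracle: loop subpatterns, apply parity rule explicitly."""
    d = pv.decompose(layout)
    n = layout.n_intervals
    dist = np.zeros(2**n)
    total = 0.0
    parents = [p for p, _ in d.subintervals]
    for bits in itertools.product((0, 1), repeat=d.n_sub):
        p = pv.subpattern_probability(d, spec, gamma, lengths, list(bits))
        if not pv.is_balanced(d, list(bits)):
            continue
        total += p
        code = 0
        for bit, parent in zip(bits, parents):
            code ^= bit << parent
        dist[code] += p
    return dist / total


def test_marker_distribution_matches_enumeration(small_layout, small_lengths):
    spec = pv.HypothesisSpec("H1", 2.5)
    gamma = pv.gamma_from_strength(2.5, 4)
    dist = pv.marker_pattern_distribution(small_layout, spec, small_lengths, m=4)
    brute = _brute_marker_distribution(small_layout, spec, gamma, small_lengths)
    assert np.allclose(dist, brute, atol=1e-9)
    assert dist.sum() == pytest.approx(1.0)


def test_marker_distribution_no_interference_enumeration(toy_layout, toy_lengths):
    spec = pv.HypothesisSpec("H1", 0.0)
    gamma = pv.gamma_from_strength(0.0)
    dist = pv.marker_pattern_distribution(toy_layout, spec, toy_lengths, m=1)
    brute = _brute_marker_distribution(toy_layout, spec, gamma, toy_lengths)
    assert np.allclose(dist, brute, atol=1e-9)


@given(q=st.floats(0.0, 6.0), scale=st.floats(0.2, 2.0))
@settings(max_examples=15, derandomize=True, deadline=None)
def test_marker_distribution_normalises(toy_layout, toy_lengths, q, scale):
    for name in ("H0", "H1"):
        spec = pv.HypothesisSpec(name, q)
        dist = pv.marker_pattern_distribution(toy_layout, spec, scale * toy_lengths)
        assert np.all(dist >= -1e-12)
        assert abs(dist.sum() - 1.0) < 1e-9


def test_vacuous_conditioning_with_empty_inner_regions():
    # breakpoints coincide with the centromere interval boundaries: the two
    # inner regions have zero length and conditioning changes nothing
    layout = pv.ChromosomeLayout(
        marker_names=("a", "b", "c"),
        left_bp=pv.Placement(1, 0.0),
        centromere=pv.Placement(1, 0.5),
        right_bp=pv.Placement(1, 1.0),
    )
    lengths = np.array([0.3, 0.0])
    spec = pv.HypothesisSpec("H1", 3.0)
    eng = PatternDistributionEngine(layout, m=4)
    cond = eng.distribution(spec, lengths)
    uncond = eng.distribution(spec, lengths, conditioned=False)
    assert np.allclose(cond, uncond, atol=1e-12)


def test_breakpoint_interference_lowers_double_inner_recombination():
    # loci at the breakpoints and centromere: P(both inner regions
    # recombinant) drops when breakpoints interfere (H1 vs H0)
    layout = pv.ChromosomeLayout(
        marker_names=("a", "b", "c"),
        left_bp=pv.Placement(0, 0.0),
        centromere=pv.Placement(1, 0.0),
        right_bp=pv.Placement(1, 1.0),
    )
    lengths = np.array([0.35, 0.35])
    eng = PatternDistributionEngine(layout, m=5)
    both = {}
    for name in ("H0", "H1"):
        spec = pv.HypothesisSpec(name, 4.0)
        dist = eng.distribution(spec, lengths, conditioned=False)
        both[name] = dist[0b11]
    assert both["H1"] < both["H0"]


def test_homokaryotype_distribution_is_plain_chain():
    layout = pv.ChromosomeLayout(marker_names=("a", "b", "c"), karyotype="homo")
    lengths = np.array([0.2, 0.3])
    spec = pv.HypothesisSpec("H0", 3.0)
    dist = pv.marker_pattern_distribution(layout, spec, lengths, m=4)
    gamma = pv.gamma_from_strength(3.0, 4)
    direct = pv.chain_pattern_distribution(
        pv.stationary_phase(gamma), 2.0 * lengths * gamma.mean_spacing, gamma
    )
    assert np.allclose(dist, direct, atol=1e-12)


# -- map ratios --------------------------------------------------------------


def test_map_ratio_values():
    assert pv.map_ratio(0.1, 0.1) == pytest.approx(1.0)
    assert pv.map_ratio(0.245, 0.045) == pytest.approx(5.4, abs=0.05)
    assert pv.map_ratio(0.373, 0.045) == pytest.approx(8.3, abs=0.05)
    with pytest.raises(ValueError):
        pv.map_ratio(0.1, 0.0)
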