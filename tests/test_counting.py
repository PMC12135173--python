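"""Counting-core unit and property tests: distributions, matrices, patterns."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perinv as pv
from perinv.counting import truncation_length


# -- interference / phase distributions -------------------------------------


@pytest.mark.parametrize(
    "q, m, expected",
    [
        (4.0, 5, [0, 0, 0, 0, 1, 0]),
        (3.72, 5, [0, 0, 0, 0.28, 0.72, 0]),
        (0.0, 0, [1.0]),
    ],
)
def test_gamma_model_mass(q, m, expected):
    dist = pv.gamma_from_strength(q, m)
    assert np.allclose(dist.gamma, expected)
    assert dist.q == q
    assert abs(dist.gamma.sum() - 1.0) < 1e-12


def test_gamma_model_rejects_bad_input():
    with pytest.raises(ValueError):
        pv.gamma_from_strength(-0.1)
    with pytest.raises(ValueError):
        pv.gamma_from_strength(3.5, m=3)  # support needs index 4
    with pytest.raises(ValueError):
        pv.InterferenceDistribution(np.array([0.5, 0.6]))  # not normalised


@pytest.mark.parametrize(
    "q, expected",
    [
        (0.0, [1.0]),
        (1.0, [0.5, 0.5]),
        (4.0, [0.2] * 5),
    ],
)
def test_stationary_phase_closed_forms(q, expected):
    pi = pv.stationary_phase(pv.gamma_from_strength(q))
    assert np.allclose(pi.omega, expected)


@given(q=st.floats(0.0, 8.0), m_extra=st.integers(0, 3))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_stationary_phase_is_a_distribution(q, m_extra):
    gamma = pv.gamma_from_strength(q, int(math.ceil(q)) + 1 + m_extra)
    pi = pv.stationary_phase(gamma)
    assert pi.omega.size == gamma.gamma.size
    assert abs(pi.omega.sum() - 1.0) < 1e-12


# -- renewal coefficients ----------------------------------------------------


def _brute_renewal(gamma_vec, tmax):
    # independent direct recursion, scalar arithmetic only
    b = [1.0]
    for t in range(1, tmax + 1):
        total = 0.0
        for a in range(t):
            idx = t - 1 - a
            if idx < len(gamma_vec):
                total += b[a] * gamma_vec[idx]
        b.append(total)
    return b


def test_renewal_no_interference_is_all_ones():
    b = pv.renewal_coefficients(pv.gamma_from_strength(0.0), 10)
    assert np.allclose(b.b, 1.0)


def test_renewal_alternates_for_unit_strength():
    b = pv.renewal_coefficients(pv.gamma_from_strength(1.0), 6)
    assert np.allclose(b.b, [1, 0, 1, 0, 1, 0, 1])


@given(q=st.floats(0.0, 6.0))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_renewal_matches_direct_recursion(q):
    gamma = pv.gamma_from_strength(q)
    b = pv.renewal_coefficients(gamma, 12)
    assert np.allclose(b.b, _brute_renewal(list(gamma.gamma), 12), atol=1e-14)


# -- interval rates ----------------------------------------------------------


@pytest.mark.parametrize(
    "l_prime, q, expected_lam",
    [(0.5, 0.0, 1.0), (0.5, 4.0, 5.0), (0.0, 4.0, 0.0)],
)
def test_interval_rate(l_prime, q, expected_lam):
    rate = pv.interval_rate(l_prime, pv.gamma_from_strength(q))
    assert rate.lam == pytest.approx(expected_lam)


def test_interval_rate_rejects_negative_length():
    with pytest.raises(ValueError):
        pv.interval_rate(-0.1, pv.gamma_from_strength(0.0))


# -- H and G matrices --------------------------------------------------------


def test_h_matrix_zero_rate_is_identity():
    gamma = pv.gamma_from_strength(2.0)
    H = pv.h_matrix(pv.interval_rate(0.0, gamma), gamma.m)
    assert np.allclose(H, np.eye(gamma.m + 1))


def test_h_matrix_structure():
    gamma = pv.gamma_from_strength(3.0)
    rate = pv.interval_rate(0.3, gamma)
    H = pv.h_matrix(rate, gamma.m)
    assert H[0, 0] == pytest.approx(math.exp(-rate.lam))
    assert np.all(H[np.triu_indices(gamma.m + 1, k=1)] == 0.0)
    assert np.all((H >= 0) & (H <= 1))


def test_g_matrix_zero_rate_is_zero():
    gamma = pv.gamma_from_strength(2.5)
    G = pv.g_matrix(pv.interval_rate(0.0, gamma), gamma)
    assert np.allclose(G, 0.0)


def test_g_matrix_haldane_limit():
    # m = 0: single entry, probability of at least one event
    gamma = pv.gamma_from_strength(0.0)
    rate = pv.interval_rate(0.7, gamma)
    G = pv.g_matrix(rate, gamma)
    assert G.shape == (1, 1)
    assert G[0, 0] == pytest.approx(1.0 - math.exp(-rate.lam), abs=1e-10)


def _simulate_phase_transition(lam, gamma_vec, enter_phase, n, seed):
    """MC tally of (exit phase | >=1 chiasma) for a single interval."""
    rng = np.random.default_rng(seed)
    m = len(gamma_vec) - 1
    exit_counts = np.zeros(m + 1)
    n_events = rng.poisson(lam, size=n)
    for ev in n_events:
        phase = enter_phase
        had_chiasma = False
        remaining = ev
        while remaining > phase:
            remaining -= phase + 1  # phase dummies then the chiasma itself
            had_chiasma = True
            phase = rng.choice(m + 1, p=gamma_vec)
        if had_chiasma:
            exit_counts[phase - remaining] += 1
    return exit_counts / n


def test_g_matrix_against_monte_carlo():
    gamma = pv.gamma_from_strength(2.5)
    lam = 3.0
    G = pv.g_matrix(pv.IntervalRate(lam / (2 * gamma.mean_spacing), lam), gamma)
    n = 200_000
    for enter in (0, 2):
        emp = _simulate_phase_transition(lam, list(gamma.gamma), enter, n, seed=enter)
        se = np.sqrt(np.maximum(G[enter] * (1 - G[enter]), 1e-12) / n)
        assert np.all(np.abs(emp - G[enter]) < 4 * se + 1e-4)


@given(q=st.floats(0.0, 8.0), l=st.floats(0.0, 1.5))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_row_stochasticity(q, l):
    gamma = pv.gamma_from_strength(q)
    rate = pv.interval_rate(l, gamma)
    H = pv.h_matrix(rate, gamma.m)
    G = pv.g_matrix(rate, gamma)
    assert np.allclose((H + G).sum(axis=1), 1.0, atol=1e-9)


def test_transition_matrices_limits():
    gamma = pv.gamma_from_strength(3.0)
    M0, M1 = pv.transition_matrices(pv.interval_rate(0.0, gamma), gamma)
    assert np.allclose(M1, 0.0)
    assert np.allclose(M0, np.eye(gamma.m + 1))
    # m = 0 recovers the two Haldane components
    g0 = pv.gamma_from_strength(0.0)
    rate = pv.interval_rate(0.4, g0)
    M0, M1 = pv.transition_matrices(rate, g0)
    assert M1[0, 0] == pytest.approx((1 - math.exp(-rate.lam)) / 2)
    assert M0[0, 0] == pytest.approx((1 + math.exp(-rate.lam)) / 2)


def test_truncation_rule_converges_and_caps():
    assert truncation_length(0.0, 3) == 0
    t = truncation_length(5.0, 3, tol=1e-12)
    assert t > 5
    with pytest.raises(ValueError):
        truncation_length(1.0, 3, tol=-1.0)


# -- pattern probabilities ---------------------------------------------------


def _haldane(l):
    return 0.5 * (1.0 - math.exp(-2.0 * l))


def test_empty_chain_probability_is_one():
    gamma = pv.gamma_from_strength(2.0)
    omega = pv.stationary_phase(gamma)
    assert pv.pattern_probability(omega, [], [], gamma) == pytest.approx(1.0)


def test_single_interval_haldane_mapping():
    gamma = pv.gamma_from_strength(0.0)
    omega = pv.stationary_phase(gamma)
    for l in (0.1, 0.5, 1.0):
        p = pv.pattern_probability(omega, [pv.interval_rate(l, gamma)], [1], gamma)
        assert p == pytest.approx(_haldane(l), abs=1e-10)


@given(
    q=st.floats(0.0, 6.0),
    lengths=st.lists(st.floats(0.01, 0.8), min_size=1, max_size=4),
)
@settings(max_examples=25, derandomize=True, deadline=None)
def test_pattern_distribution_normalises(q, lengths):
    gamma = pv.gamma_from_strength(q)
    omega = pv.stationary_phase(gamma)
    lams = [2.0 * l * gamma.mean_spacing for l in lengths]
    dist = pv.chain_pattern_distribution(omega, lams, gamma)
    assert dist.size == 2 ** len(lengths)
    assert np.all(dist >= -1e-12)
    assert abs(dist.sum() - 1.0) < 1e-9


@given(lengths=st.lists(st.floats(0.01, 0.8), min_size=1, max_size=4))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_haldane_reduction_without_interference(lengths):
    # gamma_0 = 1: the joint law factorises into per-interval Haldane terms
    gamma = pv.gamma_from_strength(0.0)
    omega = pv.stationary_phase(gamma)
    lams = [2.0 * l for l in lengths]
    dist = pv.chain_pattern_distribution(omega, lams, gamma)
    for code in range(dist.size):
        expected = 1.0
        for k, l in enumerate(lengths):
            p = _haldane(l)
            expected *= p if (code >> k) & 1 else 1.0 - p
        assert dist[code] == pytest.approx(expected, abs=1e-10)


@given(q=st.floats(0.0, 6.0), l1=st.floats(0.01, 0.8), l2=st.floats(0.01, 0.8))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_merge_consistency_of_adjacent_intervals(q, l1, l2):
    # odd parity over two adjacent intervals == recombination of the merged one
    gamma = pv.gamma_from_strength(q)
    omega = pv.stationary_phase(gamma)
    mult = gamma.mean_spacing
    pair = pv.chain_pattern_distribution(omega, [2 * l1 * mult, 2 * l2 * mult], gamma)
    merged = pv.chain_pattern_distribution(omega, [2 * (l1 + l2) * mult], gamma)
    assert pair[1] + pair[2] == pytest.approx(merged[1], abs=1e-9)


def test_stationary_marginal_is_position_independent():
    gamma = pv.gamma_from_strength(4.0)
    omega = pv.stationary_phase(gamma)
    mult = gamma.mean_spacing
    lam_target = 2 * 0.25 * mult
    other = [2 * 0.4 * mult, 2 * 0.1 * mult]
    # target interval first, middle, last
    arrangements = [
        ([lam_target] + other, 0),
        ([other[0], lam_target, other[1]], 1),
        (other + [lam_target], 2),
    ]
    marginals = []
    for lams, pos in arrangements:
        dist = pv.chain_pattern_distribution(omega, lams, gamma)
        codes = np.arange(dist.size)
        marginals.append(dist[(codes >> pos) & 1 == 1].sum())
    assert np.allclose(marginals, marginals[0], atol=1e-10)


@given(
    q=st.floats(0.0, 6.0),
    l=st.floats(0.0, 1.0),
    omega_seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=30, derandomize=True, deadline=None)
def test_single_interval_agrees_with_closed_form(q, l, omega_seed):
    # matrix chain of length 1 vs the inner-region closed form, arbitrary omega
    gamma = pv.gamma_from_strength(q)
    rng = np.random.default_rng(omega_seed)
    w = rng.dirichlet(np.ones(gamma.m + 1))
    omega = pv.PhaseDistribution(w / w.sum())
    lam = 2.0 * l * gamma.mean_spacing
    via_chain = pv.chain_pattern_distribution(omega, [lam], gamma)[1]
    closed = pv.inner_recombination_probability(omega, lam)
    assert via_chain == pytest.approx(closed, abs=1e-9)
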