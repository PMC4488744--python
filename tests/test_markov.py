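"""Transition estimation and chain diagnostics (pi, rho, H(P))."""

import math
import warnings

import numpy as np
import pytest

from fragscape.landscape import ALL_LABELS
from fragscape.markov import (
    STATES,
    conversion_sources,
    convergence_rate,
    estimate_transitions,
    model_from_counts,
    model_from_probabilities,
    normalized_entropy,
    project,
    read_matrix_csv,
    stationary_distribution,
    subdominant_modulus,
    write_matrix_csv,
)


def code(label):
    return ALL_LABELS.index(label)


P2 = np.array([[0.9, 0.1], [0.2, 0.8]])


def two_state(P=P2):
    return model_from_probabilities(P, states=("a", "b"))


# --- estimation ------------------------------------------------------------


def test_identical_maps_give_identity_matrix(rng):
    grid = rng.integers(0, 8, size=(30, 30))
    model = estimate_transitions(grid, grid)
    diag_states = np.unique(grid)
    for i in range(8):
        assert model.probabilities[i, i] == 1.0
    assert model.counts.sum() == 900
    assert model.n_pixels == 900
    assert diag_states.size > 1


def test_two_by_two_toy_tally():
    t1 = np.array([[code("core"), code("core")], [code("edge"), code("background")]])
    t2 = np.array([[code("core"), code("edge")], [code("edge"), code("background")]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent states become absorbing rows
        model = estimate_transitions(t1, t2)
    i_core, i_edge, i_nf = STATES.index("core"), STATES.index("edge"), STATES.index("non_farmland")
    assert model.probabilities[i_core, i_core] == 0.5
    assert model.probabilities[i_core, i_edge] == 0.5
    assert model.probabilities[i_edge, i_edge] == 1.0
    assert model.probabilities[i_nf, i_nf] == 1.0


def test_row_sums_equal_t1_state_counts(rng):
    t1 = rng.integers(0, 8, size=(40, 40))
    t2 = rng.integers(0, 8, size=(40, 40))
    model = estimate_transitions(t1, t2)
    # rows of C conserve the t1 state counts (after label->state reordering)
    lut = {l: STATES.index("non_farmland" if l == "background" else l) for l in ALL_LABELS}
    expected = np.zeros(8, dtype=int)
    for label_code in range(8):
        expected[lut[ALL_LABELS[label_code]]] += (t1 == label_code).sum()
    np.testing.assert_array_equal(model.counts.sum(axis=1), expected)


def test_shape_mismatch_errors(rng):
    with pytest.raises(ValueError, match="shapes"):
        estimate_transitions(np.zeros((3, 3), dtype=int), np.zeros((3, 4), dtype=int))


def test_unknown_code_errors():
    with pytest.raises(ValueError, match="state code"):
        estimate_transitions(np.full((2, 2), 9), np.zeros((2, 2), dtype=int))


def test_zero_count_rows_become_absorbing():
    counts = np.zeros((8, 8), dtype=int)
    counts[0, 0] = 10
    with pytest.warns(UserWarning, match="absorbing"):
        model = model_from_counts(counts)
    np.testing.assert_allclose(model.probabilities.sum(axis=1), 1.0)
    assert model.probabilities[3, 3] == 1.0


# --- stationary distribution ----------------------------------------------


def test_stationary_uniform_for_doubly_stochastic():
    model = two_state(np.array([[0.5, 0.5], [0.5, 0.5]]))
    np.testing.assert_allclose(stationary_distribution(model), [0.5, 0.5])


def test_stationary_identity_warns_reducible():
    model = two_state(np.eye(2))
    with pytest.warns(UserWarning, match="reducible"):
        pi = stationary_distribution(model)
    np.testing.assert_allclose(pi @ model.probabilities, pi, atol=1e-10)
    assert pi.sum() == pytest.approx(1.0)


def test_stationary_two_state_hand_solution():
    # balance: 0.1 pi_1 = 0.2 pi_2  ->  pi = (2/3, 1/3)
    pi = stationary_distribution(two_state())
    np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-10)
    np.testing.assert_allclose(pi @ P2, pi, atol=1e-10)


# --- convergence rate ------------------------------------------------------


def test_rho_two_state_equals_trace_minus_one_reciprocal():
    # for 2-state chains lambda_2 = trace - 1 = 0.7
    assert subdominant_modulus(two_state()) == pytest.approx(0.7, abs=1e-12)
    assert convergence_rate(two_state()) == pytest.approx(1 / 0.7)


def test_rho_uniform_rows_is_infinite():
    model = two_state(np.array([[0.3, 0.7], [0.3, 0.7]]))
    assert convergence_rate(model) == math.inf


def test_rho_periodic_chain_warns():
    model = two_state(np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.warns(UserWarning, match="modulus 1"):
        assert convergence_rate(model) == 1.0


def test_spectral_quantities_reproducible():
    rng = np.random.default_rng(5)
    P = rng.random((8, 8))
    P /= P.sum(axis=1, keepdims=True)
    model = model_from_probabilities(P)
    vals = {(convergence_rate(model), normalized_entropy(model)) for _ in range(5)}
    assert len(vals) == 1


# --- entropy ---------------------------------------------------------------


def test_entropy_identity_is_zero():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert normalized_entropy(two_state(np.eye(2))) == pytest.approx(0.0, abs=1e-12)


def test_entropy_uniform_chain_is_one():
    for s in (2, 5, 8):
        P = np.full((s, s), 1.0 / s)
        model = model_from_probabilities(P, states=tuple(f"s{i}" for i in range(s)))
        assert normalized_entropy(model) == pytest.approx(1.0)
        assert normalized_entropy(model, weights="uniform") == pytest.approx(1.0)


def test_entropy_two_state_hand_evaluation():
    # independent arithmetic: H = -[pi1*(0.9 ln 0.9 + 0.1 ln 0.1)
    #                              + pi2*(0.2 ln 0.2 + 0.8 ln 0.8)] / ln 2
    h1 = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
    h2 = -(0.2 * math.log(0.2) + 0.8 * math.log(0.8))
    expected = (2 / 3 * h1 + 1 / 3 * h2) / math.log(2)
    assert normalized_entropy(two_state()) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.5533, abs=5e-5)


def test_entropy_weighting_both_directions():
    # a random (noisy) row raises the stationary-weighted H only when the
    # stationary mass actually sits on it; both directions constructed
    states = ("a", "b", "c")
    # noisy state recurrent and dominant: pi = (0.6, 0.2, 0.2)
    P_dom = np.array([[1 / 3, 1 / 3, 1 / 3], [1, 0, 0], [1, 0, 0]])
    m_dom = model_from_probabilities(P_dom, states=states)
    assert normalized_entropy(m_dom) > normalized_entropy(m_dom, weights="uniform")
    # same noisy row but transient: pi = (0, 0.5, 0.5) sits on quiet states
    P_tr = np.array([[1 / 3, 1 / 3, 1 / 3], [0, 0.02, 0.98], [0, 0.98, 0.02]])
    m_tr = model_from_probabilities(P_tr, states=states)
    assert normalized_entropy(m_tr) < normalized_entropy(m_tr, weights="uniform")


# --- conversion sources ----------------------------------------------------


def test_conversion_sources_arithmetic():
    counts = np.zeros((8, 8), dtype=int)
    nf = STATES.index("non_farmland")
    counts[STATES.index("islet"), nf] = 30
    counts[STATES.index("branch"), nf] = 45
    counts[STATES.index("core"), nf] = 25
    counts[nf, nf] = 1000  # persistence must be excluded
    np.fill_diagonal(counts, counts.diagonal() + 10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = model_from_counts(counts)
    shares = conversion_sources(model, "non_farmland")
    assert shares["islet"] + shares["branch"] == pytest.approx(0.75)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)


def test_conversion_single_source():
    counts = np.zeros((8, 8), dtype=int)
    counts[0, 7] = 5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = model_from_counts(counts)
    shares = conversion_sources(model, STATES[7])
    assert shares[STATES[0]] == 1.0


def test_conversion_no_flow_errors():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = model_from_counts(np.eye(8, dtype=int) * 5)
    with pytest.raises(ValueError, match="no transitions"):
        conversion_sources(model, "core")


# --- projection ------------------------------------------------------------


def test_project_zero_steps():
    model = two_state()
    out = project(model, np.array([1.0, 0.0]), 0)
    np.testing.assert_array_equal(out, [[1.0, 0.0]])


def test_project_uniform_converges_in_one_step():
    model = two_state(np.array([[0.3, 0.7], [0.3, 0.7]]))
    out = project(model, np.array([1.0, 0.0]), 3)
    np.testing.assert_allclose(out[1], [0.3, 0.7])
    np.testing.assert_allclose(out[2], out[1])


def test_project_distance_decays_at_lambda2():
    model = two_state()
    pi = stationary_distribution(model)
    out = project(model, np.array([1.0, 0.0]), 25)
    dists = np.abs(out - pi).sum(axis=1)
    ratios = dists[1:20] / dists[0:19]
    np.testing.assert_allclose(ratios, 0.7, atol=1e-6)


def test_project_validation():
    model = two_state()
    with pytest.raises(ValueError):
        project(model, np.array([1.0, 0.0]), -1)
    with pytest.raises(ValueError):
        project(model, np.array([0.6, 0.6]), 2)


# --- round trip ------------------------------------------------------------


def test_matrix_csv_round_trip(tmp_path, rng):
    P = rng.random((8, 8))
    P /= P.sum(axis=1, keepdims=True)
    model = model_from_probabilities(P)
    path = tmp_path / "P.csv"
    write_matrix_csv(model, path)
    back = read_matrix_csv(path)
    np.testing.assert_allclose(back.probabilities, P, atol=1e-12)
    assert back.states == STATES


def test_restrict_to_observed_drops_padding_states():
    from fragscape.markov import restrict_to_observed

    counts = np.zeros((8, 8), dtype=int)
    counts[0, 0] = 80
    counts[0, 7] = 20
    counts[7, 7] = 100
    with pytest.warns(UserWarning, match="absorbing"):
        full = model_from_counts(counts)
    # six synthetic identity rows force |lambda_2| = 1
    with pytest.warns(UserWarning, match="modulus 1"):
        assert convergence_rate(full) == 1.0
    sub = restrict_to_observed(full)
    assert sub.states == (STATES[0], STATES[7])
    assert convergence_rate(sub) == pytest.approx(1 / 0.8)


def test_restrict_to_observed_refuses_lost_flow():
    from fragscape.markov import restrict_to_observed

    counts = np.zeros((8, 8), dtype=int)
    counts[0, 1] = 10  # flow into a state with no outgoing observations
    with pytest.warns(UserWarning, match="absorbing"):
        model = model_from_counts(counts)
    with pytest.raises(ValueError, match="absent at t1"):
        restrict_to_observed(model)
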