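import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwta import (
    BooleanMap,
    NetworkParameters,
    NetworkState,
    classify_outcome,
    jacobian_at,
    predict_fixed_point,
    predict_inhibitory,
    predict_nonwinners,
    predict_winner,
    quenching_threshold,
    read_boolean_map,
    simulate,
)
from fwta.core import _core_rhs


# ------------------------------------------------------- closed-form formulas

def test_predict_winner(params):
    assert predict_winner(2.0, params) == pytest.approx(3.0)
    assert predict_winner(1.0, params) == pytest.approx(2.0)
    assert predict_winner(1.0, params.replace(alpha=0.0)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        predict_winner(0.0, params)


def test_predict_inhibitory(params):
    assert predict_inhibitory(3.0, 4, params) == pytest.approx(40 * 2.9 / 41)
    assert predict_inhibitory(3.0, 10**6, params) == pytest.approx(2.9, abs=1e-4)
    assert predict_inhibitory(params.T_x, 5, params) == 0.0
    with pytest.raises(ValueError):
        predict_inhibitory(3.0, 0, params)


@given(st.integers(1, 500), st.integers(1, 500))
@settings(deadline=None)
def test_inhibitory_increasing_in_k_and_bounded(k1, k2):
    p = NetworkParameters()
    y1, y2 = predict_inhibitory(3.0, k1, p), predict_inhibitory(3.0, k2, p)
    if k1 < k2:
        assert y1 < y2
    assert y1 < 3.0 - p.T_x and y2 < 3.0 - p.T_x


def test_quenching_threshold(params):
    assert quenching_threshold(3.0, params) == pytest.approx(2.8)
    assert quenching_threshold(2.0, params) == pytest.approx(1.8)
    p0 = params.replace(T_x=1e-12, T_y=1e-12)
    assert quenching_threshold(3.0, p0) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        quenching_threshold(0.1, params)


def test_predict_nonwinners_dichotomy(params):
    # 0.2 + 1 < 2.8: silenced; 1.9 + 1 >= 2.8: survives at its own level
    out = predict_nonwinners(np.array([0.2, 1.9]), 2.8, params)
    assert np.allclose(out, [0.0, 2.9])
    everything = predict_nonwinners(np.array([0.2, 1.9]), 0.0, params)
    assert np.all(everything > 0)


def test_predict_fixed_point_consistency(params):
    I = np.full(20, 0.2)
    I[3:6] = 2.0
    fp = predict_fixed_point(I, params)
    assert fp.k == 3
    assert fp.qt == fp.x_winner - params.T_x - params.T_y
    assert fp.y_star < fp.x_winner and fp.qt < fp.x_winner


# ------------------------------------------------------------------ Jacobian

@pytest.fixture(scope="module")
def converged_three_node():
    """A 2-excitatory + 1-inhibitory system driven to its WTA fixed point."""
    p = NetworkParameters(n_units=2)
    I = np.array([2.0, 1.0])
    traj = simulate(p, I, horizon=400.0)
    state = NetworkState(x=traj.x[-1], y=float(traj.y[-1]), t=traj.horizon)
    return p, I, state


def test_jacobian_diagonal_with_time_constant_eigenvalues(converged_three_node):
    p, I, state = converged_three_node
    res = jacobian_at(state, I, p)
    assert res.is_fixed_point
    assert res.offdiagonal_max() < 1e-9
    eig = np.sort(res.eigenvalues.real)
    assert np.allclose(np.sort(np.unique(np.round(eig, 12))),
                       sorted({-1 / p.tau_x, -1 / p.tau_y}))
    assert res.stable


def test_jacobian_matches_finite_differences(converged_three_node):
    p, I, state = converged_three_node
    J = jacobian_at(state, I, p, convention="exact").matrix
    z0 = np.concatenate([state.x, [state.y]])
    h = 1e-7

    def rhs(z):
        dx, dy = _core_rhs(z[:-1], z[-1], I, p)
        return np.concatenate([dx, [dy]])

    J_fd = np.column_stack([
        (rhs(z0 + h * e) - rhs(z0 - h * e)) / (2 * h)
        for e in np.eye(z0.size)
    ])
    assert np.abs(J - J_fd).max() < 1e-5


def test_jacobian_two_winner_fixed_point_also_diagonal():
    p = NetworkParameters(n_units=3)
    I = np.array([2.0, 2.0, 0.5])
    traj = simulate(p, I, horizon=400.0)
    state = NetworkState(x=traj.x[-1], y=float(traj.y[-1]))
    res = jacobian_at(state, I, p)
    assert res.is_fixed_point and res.offdiagonal_max() < 1e-9


def test_jacobian_warns_away_from_fixed_point(params):
    p = NetworkParameters(n_units=2)
    state = NetworkState(x=np.array([1.0, 0.0]), y=0.0)
    with pytest.warns(UserWarning):
        res = jacobian_at(state, np.array([2.0, 1.0]), p)
    assert not res.is_fixed_point


# ------------------------------------------------------------------- readout

def test_boolean_map_all_quiet(params):
    traj = simulate(params, np.zeros(params.n_units), horizon=10.0)
    bm = read_boolean_map(traj, 10.0)
    assert not bm.selected.any()


def test_boolean_map_half_max_and_qt_modes(params):
    I = np.full(params.n_units, 0.2)
    I[10:20] = 2.0
    traj = simulate(params, I, horizon=250.0)
    for mode in ("half_max", "qt"):
        bm = read_boolean_map(traj, 250.0, mode=mode)
        assert np.array_equal(bm.indices(), np.arange(10, 20))


def test_classify_outcome_definitions():
    s1, s2 = [1, 2, 3], [3, 4]

    def bm(idx):
        sel = np.zeros(10, bool)
        sel[idx] = True
        return BooleanMap(selected=sel, threshold_used=1.0)

    assert classify_outcome(s1, s2, bm([3])) == "intersection"
    assert classify_outcome(s1, s2, bm([1, 2, 3, 4])) == "union"
    assert classify_outcome(s1, s2, bm([3, 4])) == "override"
    assert classify_outcome(s1, s2, bm([1, 2, 3])) == "first_map_only"
    assert classify_outcome(s1, s2, bm([])) == "none"
    assert classify_outcome(s1, s2, bm([7])) == "other"
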