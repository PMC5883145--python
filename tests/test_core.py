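import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwta import (
    NetworkParameters,
    NetworkState,
    Trajectory,
    dendritic_output,
    derivatives,
    neighbor_sum,
    predict_inhibitory,
    predict_winner,
    rectify,
    simulate,
)


# ---------------------------------------------------------------- nonlinearities

@pytest.mark.parametrize("u, expected", [(-1.0, 0.0), (0.0, 0.0), (0.5, 0.5)])
def test_rectify_scalar(u, expected):
    assert rectify(u) == expected


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
@settings(deadline=None)
def test_rectify_elementwise_nonnegative_and_idempotent(vals):
    r = rectify(np.asarray(vals))
    assert np.all(r >= 0)
    assert np.array_equal(rectify(r), r)


def test_dendritic_output_midpoint_and_tails(params):
    # sigmoid midpoint sits at the dendritic threshold
    assert dendritic_output(params.T_d, params) == pytest.approx(0.5 * params.S_d)
    assert dendritic_output(0.2, params) == pytest.approx(1 / (1 + np.exp(-10)))
    assert dendritic_output(0.0, params) == pytest.approx(1 / (1 + np.exp(10)))


def test_dendritic_output_extreme_arguments_saturate_without_nan(params):
    lo = dendritic_output(-1e4, params)
    hi = dendritic_output(1e4, params)
    assert lo == 0.0 and hi == params.S_d
    assert np.isfinite([lo, hi]).all()


@given(st.floats(-5, 5), st.floats(-5, 5))
@settings(deadline=None)
def test_dendritic_output_monotone(u1, u2):
    p = NetworkParameters()
    if u1 < u2:
        assert dendritic_output(u1, p) <= dendritic_output(u2, p)


def test_neighbor_sum_open_boundary():
    x = np.array([1.0, 2.0, 3.0])
    # edge nodes see a single neighbor only
    assert np.array_equal(neighbor_sum(x), [3.0, 6.0, 5.0])
    assert np.array_equal(neighbor_sum(x, wraparound=True), [6.0, 6.0, 6.0])


# ---------------------------------------------------------------- derivatives

def test_derivatives_at_rest_only_residual_dendritic_drive(small_params):
    p = small_params
    state = NetworkState.resting(p)
    dx, dy = derivatives(state, np.zeros(p.n_units), p)
    # f(0) is tiny but positive; no other drive at rest
    f0 = float(dendritic_output(0.0, p))
    assert np.allclose(dx, p.alpha * f0 / p.tau_x)
    assert dy == 0.0


def test_derivatives_inhibitory_pure_decay_when_terminals_shut(small_params):
    p = small_params
    x = np.full(p.n_units, 0.5)
    y = float(x.max() + p.T_x + 1.0)  # above every terminal threshold
    dx, dy = derivatives(NetworkState(x=x, y=y), np.zeros(p.n_units), p)
    assert dy == pytest.approx(-y / p.tau_y)


def test_derivatives_strong_node_escapes_inhibition(small_params):
    p = small_params
    x = np.zeros(p.n_units)
    x[3] = 5.0
    I = np.zeros(p.n_units)
    dx, _ = derivatives(NetworkState(x=x, y=0.0), I, p)
    # rectification kills the inhibitory term for y < x + T_y
    expected = (-5.0 + rectify(p.alpha * dendritic_output(5.0, p))) / p.tau_x
    assert dx[3] == pytest.approx(expected)


def test_derivatives_shape_mismatch_raises(small_params):
    state = NetworkState.resting(small_params)
    with pytest.raises(ValueError):
        derivatives(state, np.zeros(small_params.n_units + 1), small_params)


# ---------------------------------------------------------------- simulate

def test_zero_stimulus_stays_subthreshold(params):
    traj = simulate(params, np.zeros(params.n_units), horizon=250.0)
    assert traj.x[-1].max() < params.T_d


def test_constant_block_winner_matches_closed_form(params):
    I = np.full(params.n_units, 0.2)
    I[95:105] = 2.0
    traj = simulate(params, I, horizon=250.0)
    xw = traj.x[-1, 95:105]
    assert np.abs(xw - predict_winner(2.0, params)).max() < 0.05
    # losers are quenched
    assert traj.x[-1, :90].max() == pytest.approx(0.0, abs=1e-6)


def test_trajectory_invariants_and_bounds(params):
    I = np.full(params.n_units, 0.2)
    I[50:60] = 1.0
    I[120:130] = 2.0
    traj = simulate(params, I, horizon=250.0)
    assert traj.times[0] == 0.0 and traj.times[-1] == 250.0
    assert np.all(np.diff(traj.times) > 0)
    assert np.all(traj.x >= 0) and np.all(traj.y >= 0)
    # the interneuron computes a MAX: bounded by the strongest unit + T_x
    assert np.all(traj.y <= traj.x.max(axis=1) + params.T_x + 1e-6)


@pytest.mark.parametrize("k", [1, 4, 16])
def test_steady_state_matches_fixed_point_formulas(params, k):
    I = np.full(params.n_units, 0.2)
    I[:k] = 2.0
    traj = simulate(params, I, horizon=250.0)
    x_pred = predict_winner(2.0, params)
    y_pred = predict_inhibitory(x_pred, k, params)
    assert traj.x[-1, :k].mean() == pytest.approx(x_pred, rel=0.02)
    assert traj.y[-1] == pytest.approx(y_pred, rel=0.02)


def test_winner_activity_invariant_to_winner_count(params):
    results = []
    for k in (4, 40):
        I = np.full(params.n_units, 0.2)
        I[:k] = 2.0
        traj = simulate(params, I, horizon=250.0)
        results.append(traj.x[-1, :k].mean())
    assert abs(results[0] - results[1]) / results[0] < 0.01


def test_memory_state_persists_after_input_removal(params):
    from fwta.stimuli import GainSchedule, Item, StimulusSpec

    spec = StimulusSpec.from_items([Item(96, 105, "m", 2.0)], ["m"],
                                   background_level=0.2,
                                   gain_schedule=GainSchedule(
                                       intervals=[(100.0, 250.0, "m", 1e-9)]))
    traj = simulate(params, spec, horizon=250.0)
    # after the input is removed the winners settle at the recurrent
    # drive alone, alpha * S_d
    assert traj.x[-1, 95:105].mean() == pytest.approx(
        params.alpha * params.S_d, rel=0.01)


def test_simulation_is_deterministic(params):
    I = np.full(params.n_units, 0.2)
    I[30:40] = 1.5
    a = simulate(params, I, horizon=100.0)
    b = simulate(params, I, horizon=100.0)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


def test_constant_input_shape_checked(params):
    with pytest.raises(ValueError):
        simulate(params, np.zeros(params.n_units - 1))


def test_state_and_trajectory_validation(params):
    with pytest.raises(ValueError):
        NetworkState(x=np.array([-1.0]), y=0.0)
    with pytest.raises(ValueError):
        Trajectory(times=[0.0, 0.0], x=np.zeros((2, params.n_units)),
                   y=np.zeros(2), params=params)
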