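"""State, nonlinearities, right-hand side and integrator of the F-WTA network.

The network is a 1-D chain of ``n_units`` excitatory rate units coupled to a
single inhibitory interneuron.  Excitatory unit ``i`` obeys

    tau_x dx_i/dt + x_i = [ I_i(t) + alpha * f(x_i + x_{i+1} + x_{i-1})
                            - beta1 * g(y - x_i - T_y) ]+

and the interneuron obeys

    tau_y dy/dt + y = [ beta2 * sum_i g(x_i - y - T_x) ]+

where ``[u]+ = max(u, 0)`` is the non-saturating rectifier, ``g`` is the same
rectifier acting on the presynaptic terminals (implementing retrograde
suppression of transmission), and ``f`` is a steep sigmoid modelling the
all-or-none output of the dendritic compartment that carries the
self-recurrent and nearest-neighbor collaterals.  Edge nodes receive
excitation from their single existing neighbor (open boundary).

The system is stiff (the dendritic sigmoid is nearly a step), so it is
integrated with an implicit BDF solver and an analytic Jacobian, restarting
at every stimulus breakpoint because piecewise-constant cue schedules make
the right-hand side discontinuous in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .params import NetworkParameters

__all__ = [
    "NetworkState",
    "Trajectory",
    "SimulationError",
    "rectify",
    "dendritic_output",
    "neighbor_sum",
    "derivatives",
    "simulate",
]


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure time."""

    def __init__(self, message: str, t: float):
        super().__init__(message)
        self.t = t


def rectify(u):
    """Non-saturating rectifier ``[u]+ = max(u, 0)``, elementwise."""
    return np.maximum(u, 0.0)


def dendritic_output(u, params: NetworkParameters):
    """Sigmoid output of the dendritic compartment.

    ``f(u) = S_d / (1 + exp(-lambda * (u - T_d)))``: bounded in
    ``(0, S_d)``, midpoint ``S_d/2`` at the dendritic threshold ``T_d``.
    Evaluated through :func:`scipy.special.expit`, which saturates to the
    exact asymptotes instead of overflowing for extreme arguments (with
    the default steepness ``lambda = 100`` a naive ``exp`` overflows for
    moderate inputs already).
    """
    return params.S_d * expit(params.lambda_ * (np.asarray(u, dtype=float) - params.T_d))


def _dendritic_slope(u, params: NetworkParameters):
    """Derivative of :func:`dendritic_output` with respect to its input."""
    sig = expit(params.lambda_ * (np.asarray(u, dtype=float) - params.T_d))
    return params.S_d * params.lambda_ * sig * (1.0 - sig)


def neighbor_sum(x: np.ndarray, wraparound: bool = False) -> np.ndarray:
    """Dendritic input ``x_i + x_{i+1} + x_{i-1}`` with open boundary.

    Edge nodes only have one neighbor unless ``wraparound`` closes the
    chain into a ring.
    """
    s = x.copy()
    s[:-1] += x[1:]
    s[1:] += x[:-1]
    if wraparound and x.size > 1:
        s[0] += x[-1]
        s[-1] += x[0]
    return s


@dataclass
class NetworkState:
    """Activity of the network at one time point."""

    x: np.ndarray
    y: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ValueError("x must be a 1-D activity vector")
        if np.any(self.x < 0) or self.y < 0:
            raise ValueError("activities must be nonnegative")

    @classmethod
    def resting(cls, params: NetworkParameters, t: float = 0.0) -> "NetworkState":
        """The resting state of the network with no input: all zeros."""
        return cls(x=np.zeros(params.n_units), y=0.0, t=t)


def _core_rhs(x, y, I, p: NetworkParameters):
    inhib = rectify(y - x - p.T_y)
    drive = rectify(I + p.alpha * dendritic_output(neighbor_sum(x, p.wraparound), p)
                    - p.beta1 * inhib)
    dx = (-x + drive) / p.tau_x
    dy = (-y + rectify(p.beta2 * np.sum(rectify(x - y - p.T_x)))) / p.tau_y
    return dx, dy


def _core_jac(x, y, I, p: NetworkParameters):
    n = x.size
    s = neighbor_sum(x, p.wraparound)
    phi = ((y - x - p.T_y) > 0).astype(float)
    bracket = I + p.alpha * dendritic_output(s, p) - p.beta1 * rectify(y - x - p.T_y)
    theta = (bracket > 0).astype(float)
    fprime = _dendritic_slope(s, p)

    J = np.zeros((n + 1, n + 1))
    diag = np.arange(n)
    # excitatory rows: -x_i term, dendritic coupling, presynaptic inhibition
    coup = theta * p.alpha * fprime
    J[diag, diag] = -1.0 + coup + theta * p.beta1 * phi
    J[diag[:-1], diag[:-1] + 1] = coup[:-1]
    J[diag[1:], diag[1:] - 1] = coup[1:]
    if p.wraparound and n > 1:
        J[0, n - 1] += coup[0]
        J[n - 1, 0] += coup[n - 1]
    J[:n, n] = -theta * p.beta1 * phi
    J[:n, :] /= p.tau_x
    # inhibitory row
    psi = ((x - y - p.T_x) > 0).astype(float)
    J[n, :n] = p.beta2 * psi / p.tau_y
    J[n, n] = (-1.0 - p.beta2 * np.sum(psi)) / p.tau_y
    return J


def derivatives(state: NetworkState, I: np.ndarray, params: NetworkParameters):
    """Right-hand side of the network equations at one state.

    Returns ``(dx, dy)``: the time derivatives of the excitatory vector
    and of the inhibitory scalar.  Raises ``ValueError`` if the input
    vector does not match the network size.
    """
    I = np.asarray(I, dtype=float)
    if I.shape != (params.n_units,) or state.x.shape != (params.n_units,):
        raise ValueError(
            f"shape mismatch: n_units={params.n_units}, "
            f"I.shape={I.shape}, x.shape={state.x.shape}"
        )
    return _core_rhs(state.x, state.y, I, params)


@dataclass
class Trajectory:
    """Dense space-time record of one simulation run.

    ``x`` has shape ``(len(times), n_units)``; ``y`` has shape
    ``(len(times),)``.  Sample times are strictly increasing, starting at
    0 and ending at the simulation horizon.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    params: NetworkParameters
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.x.shape != (self.times.size, self.params.n_units):
            raise ValueError("x must have shape (n_times, n_units)")

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def index_at(self, t: float) -> int:
        """Index of the sample closest to ``t`` (must be within range)."""
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"t={t} outside trajectory [{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))

    def state_at(self, t: float) -> NetworkState:
        i = self.index_at(t)
        return NetworkState(x=self.x[i].copy(), y=float(self.y[i]), t=float(self.times[i]))

    @property
    def states(self) -> list:
        """Snapshots aligned with ``times`` (built on demand)."""
        return [NetworkState(x=self.x[i].copy(), y=float(self.y[i]), t=float(t))
                for i, t in enumerate(self.times)]


def _resolve_input(stimulus, n_units: int):
    """Turn a stimulus argument into ``(input_at(t), breakpoints)``.

    Accepts a :class:`~fwta.stimuli.StimulusSpec`-like object (anything
    with ``input_at`` and ``breakpoints``), a constant input vector, or a
    callable ``t -> vector``.
    """
    if hasattr(stimulus, "input_at") and hasattr(stimulus, "breakpoints"):
        return stimulus.input_at, list(stimulus.breakpoints()), getattr(stimulus, "stimulus_id", "")
    if callable(stimulus):
        return stimulus, [], ""
    I = np.asarray(stimulus, dtype=float)
    if I.shape != (n_units,):
        raise ValueError(f"constant input must have shape ({n_units},), got {I.shape}")
    return (lambda t: I), [], "constant"


def simulate(
    params: NetworkParameters,
    stimulus,
    horizon: float = 250.0,
    initial: Optional[NetworkState] = None,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    sample_dt: float = 1.0,
    method: str = "BDF",
    model: str = "auto",
) -> Trajectory:
    """Integrate the network over ``[0, horizon]`` under a stimulus.

    The stimulus may be a :class:`~fwta.stimuli.StimulusSpec`, a constant
    input vector of length ``n_units`` or a callable ``t -> vector``.
    Integration restarts at every stimulus breakpoint (cue onset/offset)
    because the implicit solver assumes a smooth right-hand side between
    events.  The trajectory is sampled every ``sample_dt`` time units plus
    at all breakpoints.

    ``model`` selects the nonlinearity family: ``"core"`` (rectifier soma
    + sigmoid dendrite), ``"pwl"`` (piecewise-linear saturating outputs,
    requires :class:`~fwta.params.PWLParameters`), or ``"auto"`` which
    infers it from the parameter type.
    """
    from .params import PWLParameters

    if model == "auto":
        model = "pwl" if isinstance(params, PWLParameters) else "core"
    if model == "core":
        rhs_xy, jac_xy = _core_rhs, _core_jac
    elif model == "pwl":
        from .variants import _pwl_rhs, _pwl_jac

        if not isinstance(params, PWLParameters):
            raise TypeError("model='pwl' requires PWLParameters")
        rhs_xy, jac_xy = _pwl_rhs, _pwl_jac
    else:
        raise ValueError(f"unknown model {model!r}")

    n = params.n_units
    input_at, breaks, stim_id = _resolve_input(stimulus, n)
    if initial is None:
        initial = NetworkState.resting(params)
    if initial.x.shape != (n,):
        raise ValueError("initial state size does not match n_units")

    edges = sorted({0.0, float(horizon), *[float(b) for b in breaks if 0.0 < b < horizon]})
    samples = np.unique(np.concatenate([
        np.arange(0.0, horizon + 0.5 * sample_dt, sample_dt), np.asarray(edges)
    ]))
    samples = samples[(samples >= 0.0) & (samples <= horizon)]

    z0 = np.concatenate([initial.x, [initial.y]])
    times_out: list = []
    z_out: list = []

    for a, b in zip(edges[:-1], edges[1:]):
        # input is constant on the open segment; evaluate just inside
        I_seg = np.asarray(input_at(a + 1e-9 * max(1.0, b - a)), dtype=float)

        def rhs(t, z, I=I_seg):
            dx, dy = rhs_xy(z[:-1], z[-1], I, params)
            return np.concatenate([dx, [dy]])

        def jac(t, z, I=I_seg):
            return jac_xy(z[:-1], z[-1], I, params)

        t_eval = samples[(samples >= a) & (samples <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(rhs, (a, b), z0, method=method, jac=jac,
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else a
            raise SimulationError(
                f"ODE solver failed at t={t_fail:g}: {sol.message}", t=t_fail)
        keep = slice(1, None) if times_out else slice(None)
        times_out.append(sol.t[keep])
        z_out.append(sol.y[:, keep].T)
        z0 = sol.y[:, -1]

    times = np.concatenate(times_out)
    Z = np.concatenate(z_out, axis=0)
    # clip solver noise: the dynamics preserve nonnegativity exactly
    Z = np.maximum(Z, 0.0)
    return Trajectory(times=times, x=Z[:, :-1], y=Z[:, -1],
                      params=params, stimulus_id=stim_id)
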