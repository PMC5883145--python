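"""Piecewise-linear saturating variant of the network.

Replaces the non-saturating somatic rectifier, the sigmoid dendrite and
the rectifying presynaptic terminals with one family of piecewise-linear
clamps ``s_q(u) = clip(u, 0, S_q)`` with separate saturation points for
the soma (``S_c``), dendrite (``S_d``) and presynaptic terminals
(``S_p``):

    tau_x dx_i/dt + x_i = s_c[ I_i(t) + alpha * s_d(x_i + x_{i+1} + x_{i-1} - T_d)
                               - beta1 * s_p(y - x_i - T_y) ]
    tau_y dy/dt  + y    = s_c[ beta2 * sum_i s_p(x_i - y - T_x) ]

With the soma and terminals kept far from saturation (``S_c = S_p = 10``
by default) and the dendrite saturating early (``S_d = 1 < S_c``), this
variant reproduces the selection behavior of the core model; letting the
dendrite saturate at the somatic level instead makes the recurrent drive
overshadow the feedforward input and the network stops responding to new
cues.
"""

from __future__ import annotations

import numpy as np

from .core import neighbor_sum
from .params import PWLParameters

__all__ = ["pwl_output", "derivatives_pwl"]


def pwl_output(u, S_q: float):
    """Piecewise-linear saturating output ``clip(u, 0, S_q)``."""
    if S_q <= 0:
        raise ValueError("saturation point S_q must be positive")
    return np.clip(u, 0.0, S_q)


def _pwl_rhs(x, y, I, p: PWLParameters):
    dend = pwl_output(neighbor_sum(x, p.wraparound) - p.T_d, p.S_d)
    inhib = pwl_output(y - x - p.T_y, p.S_p)
    dx = (-x + pwl_output(I + p.alpha * dend - p.beta1 * inhib, p.S_c)) / p.tau_x
    exc = p.beta2 * np.sum(pwl_output(x - y - p.T_x, p.S_p))
    dy = (-y + pwl_output(exc, p.S_c)) / p.tau_y
    return dx, dy


def _pwl_jac(x, y, I, p: PWLParameters):
    n = x.size
    s = neighbor_sum(x, p.wraparound) - p.T_d
    d_dend = ((s > 0) & (s < p.S_d)).astype(float)   # dendritic clamp linear region
    u_in = y - x - p.T_y
    d_inh = ((u_in > 0) & (u_in < p.S_p)).astype(float)
    bracket = I + p.alpha * pwl_output(s, p.S_d) - p.beta1 * pwl_output(u_in, p.S_p)
    c = ((bracket > 0) & (bracket < p.S_c)).astype(float)

    J = np.zeros((n + 1, n + 1))
    diag = np.arange(n)
    coup = c * p.alpha * d_dend
    J[diag, diag] = -1.0 + coup + c * p.beta1 * d_inh
    J[diag[:-1], diag[:-1] + 1] = coup[:-1]
    J[diag[1:], diag[1:] - 1] = coup[1:]
    if p.wraparound and n > 1:
        J[0, n - 1] += coup[0]
        J[n - 1, 0] += coup[n - 1]
    J[:n, n] = -c * p.beta1 * d_inh
    J[:n, :] /= p.tau_x

    u_exc = x - y - p.T_x
    d_exc = ((u_exc > 0) & (u_exc < p.S_p)).astype(float)
    total = p.beta2 * np.sum(pwl_output(u_exc, p.S_p))
    c_y = float((total > 0) & (total < p.S_c))
    J[n, :n] = c_y * p.beta2 * d_exc / p.tau_y
    J[n, n] = (-1.0 - c_y * p.beta2 * np.sum(d_exc)) / p.tau_y
    return J


def derivatives_pwl(state, I: np.ndarray, params: PWLParameters):
    """Right-hand side of the piecewise-linear variant at one state."""
    I = np.asarray(I, dtype=float)
    if I.shape != (params.n_units,) or state.x.shape != (params.n_units,):
        raise ValueError(
            f"shape mismatch: n_units={params.n_units}, "
            f"I.shape={I.shape}, x.shape={state.x.shape}"
        )
    return _pwl_rhs(state.x, state.y, I, params)
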