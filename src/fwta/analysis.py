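"""Closed-form fixed-point predictions, local stability, map readout.

At a converged selection state the winning nodes sit at

    x_M ~= I_M + alpha * S_d                       (input + saturated dendrite)

the inhibitory interneuron at

    y* = beta2 * k * (x_M - T_x) / (beta2 * k + 1)  -> x_M - T_x,

(``k`` = number of maximal-input nodes; the interneuron computes a MAX,
not a sum), and the two together set the quenching threshold

    QT = y* - T_y = x_M - T_x - T_y

that splits the remaining nodes into survivors (``I_i + alpha*S_d`` if
that value clears QT) and silenced nodes (0).

Because all nonlinearities are rectifiers (plus a dendrite pinned at its
asymptote), the Jacobian at such a fixed point is evaluated with dummy
derivatives in {0, 1} taken from the signs of the rectifier arguments;
at a proper selection fixed point every coupling term vanishes and the
matrix is diagonal with entries ``-1/tau_x`` and ``-1/tau_y``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import NetworkState, Trajectory, _core_jac, _core_rhs
from .params import NetworkParameters

__all__ = [
    "FixedPointPrediction",
    "BooleanMap",
    "JacobianResult",
    "predict_winner",
    "predict_inhibitory",
    "quenching_threshold",
    "predict_nonwinners",
    "predict_fixed_point",
    "jacobian_at",
    "read_boolean_map",
    "classify_outcome",
]


def predict_winner(I_M: float, params: NetworkParameters) -> float:
    """Steady activity of a maximal-input node: ``I_M + alpha * S_d``."""
    if I_M <= 0:
        raise ValueError("winner input I_M must be positive")
    return I_M + params.alpha * params.S_d


def predict_inhibitory(x_M: float, k: int, params: NetworkParameters) -> float:
    """Steady inhibitory activity with ``k`` winners at ``x_M``.

    ``beta2 * k * (x_M - T_x) / (beta2 * k + 1)``; increasing in ``k``
    and bounded above by ``x_M - T_x`` (the MAX computation).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    bk = params.beta2 * k
    return bk * (x_M - params.T_x) / (bk + 1.0)


def quenching_threshold(x_M: float, params: NetworkParameters) -> float:
    """Quenching threshold ``QT = x_M - T_x - T_y``."""
    if x_M <= params.T_x + params.T_y:
        raise ValueError("x_M must exceed T_x + T_y for a meaningful QT")
    return x_M - params.T_x - params.T_y


def predict_nonwinners(I: np.ndarray, qt: float, params: NetworkParameters) -> np.ndarray:
    """Predicted steady state of non-maximal nodes.

    Each node persists at ``I_i + alpha * S_d`` if that value clears the
    quenching threshold and is silenced to 0 otherwise.
    """
    v = np.asarray(I, dtype=float) + params.alpha * params.S_d
    return np.where(v >= qt, v, 0.0)


@dataclass
class FixedPointPrediction:
    """Closed-form prediction of the selection fixed point for a
    constant input vector."""

    x_winner: float
    y_star: float
    qt: float
    k: int
    nonwinner_states: np.ndarray

    def __post_init__(self) -> None:
        if not self.y_star < self.x_winner or not self.qt < self.x_winner:
            raise ValueError("inconsistent fixed point: need y*, QT < x_winner")

    def to_dict(self) -> dict:
        return {
            "x_winner": self.x_winner,
            "y_star": self.y_star,
            "qt": self.qt,
            "k": self.k,
            "nonwinner_states": np.asarray(self.nonwinner_states).tolist(),
        }


def predict_fixed_point(I: np.ndarray, params: NetworkParameters,
                        rtol: float = 1e-9) -> FixedPointPrediction:
    """Predict the full fixed point reached from rest under constant input."""
    I = np.asarray(I, dtype=float)
    I_M = float(I.max())
    winners = I >= I_M * (1.0 - rtol)
    k = int(np.count_nonzero(winners))
    x_w = predict_winner(I_M, params)
    y_star = predict_inhibitory(x_w, k, params)
    qt = quenching_threshold(x_w, params)
    non = predict_nonwinners(I, qt, params)
    non = np.where(winners, x_w, non)
    return FixedPointPrediction(x_winner=x_w, y_star=y_star, qt=qt, k=k,
                                nonwinner_states=non)


@dataclass
class JacobianResult:
    """Jacobian of the network at a candidate fixed point."""

    matrix: np.ndarray
    residual: float
    is_fixed_point: bool

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.matrix)

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    def offdiagonal_max(self) -> float:
        off = self.matrix - np.diag(np.diag(self.matrix))
        return float(np.abs(off).max())


def jacobian_at(state: NetworkState, I: np.ndarray, params: NetworkParameters,
                fp_tol: float = 1e-6,
                convention: str = "max_limit") -> JacobianResult:
    """Jacobian of the full ``(x, y)`` system at a candidate fixed point.

    Rectifier slopes are dummy derivatives in {0, 1} evaluated from the
    signs of their arguments (0 at exactly zero argument); the dendritic
    sigmoid contributes its analytic derivative, which is numerically
    zero at a converged selection state where the dendrite is pinned at
    its asymptote.

    ``convention`` controls the winners' presynaptic terminals onto the
    inhibitory unit.  At any equilibrium of the inhibitory equation the
    surviving terminal arguments equal their equilibrium residue
    ``(x_M - T_x)/(beta2*k + 1)`` — the finite-``beta2*k`` remainder of
    the MAX computation, which vanishes as the coupling or the winner
    count grows.  Under ``"max_limit"`` (default) these at-threshold
    terminals take dummy derivative 0, yielding the diagonal matrix
    ``diag(-1/tau_x, ..., -1/tau_y)``; under ``"exact"`` the dummy
    derivatives follow the literal signs, which keeps couplings
    ``beta2/tau_y`` in the inhibitory row (the matrix stays stable, with
    eigenvalues ``-1/tau_x`` and ``-(1 + beta2*k)/tau_y``) and matches a
    finite-difference Jacobian of the right-hand side.

    If the state is not a fixed point to within ``fp_tol`` (sup-norm of
    the time derivatives) the result is flagged and a warning is emitted
    rather than failing silently.
    """
    if convention not in ("max_limit", "exact"):
        raise ValueError(f"unknown convention {convention!r}")
    I = np.asarray(I, dtype=float)
    dx, dy = _core_rhs(state.x, state.y, I, params)
    residual = float(max(np.abs(dx).max(), abs(dy)))
    ok = residual < fp_tol
    if not ok:
        warnings.warn(
            f"jacobian_at called away from a fixed point "
            f"(residual {residual:.2e} >= {fp_tol:.0e})", stacklevel=2)
    J = _core_jac(state.x, state.y, I, params)
    if convention == "max_limit":
        n = params.n_units
        J[n, :n] = 0.0
        J[n, n] = -1.0 / params.tau_y
    return JacobianResult(matrix=J, residual=residual, is_fixed_point=ok)


@dataclass
class BooleanMap:
    """Binary per-location selection readout."""

    selected: np.ndarray
    threshold_used: float
    t_read: float = float("nan")
    outcome_label: str = "none"

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)

    def indices(self) -> np.ndarray:
        """0-based indices of the selected locations."""
        return np.flatnonzero(self.selected)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.astype(int).tolist(),
            "threshold_used": self.threshold_used,
            "t_read": self.t_read,
            "outcome_label": self.outcome_label,
        }


def read_boolean_map(traj: Trajectory, t_read: float,
                     threshold: Optional[float] = None,
                     mode: str = "half_max") -> BooleanMap:
    """Threshold the activity profile at ``t_read`` into a Boolean map.

    ``mode='half_max'`` (default) uses half the maximum activity at the
    readout time, which is robust to the activity scale set by the input
    magnitude and to the spontaneous floor; ``mode='qt'`` uses the
    quenching threshold implied by the instantaneous maximum.  An
    explicit ``threshold`` overrides both.  An all-quiet profile yields
    an all-false map.
    """
    i = traj.index_at(t_read)
    x = traj.x[i]
    if threshold is None:
        xmax = float(x.max())
        if xmax <= traj.params.T_d:
            # nothing has ignited: residual sub-threshold dendritic
            # activity does not constitute a selection
            return BooleanMap(selected=np.zeros_like(x, dtype=bool),
                              threshold_used=float(traj.params.T_d),
                              t_read=float(traj.times[i]))
        if mode == "half_max":
            threshold = 0.5 * xmax
        elif mode == "qt":
            threshold = xmax - traj.params.T_x - traj.params.T_y
        else:
            raise ValueError(f"unknown readout mode {mode!r}")
    return BooleanMap(selected=x > threshold, threshold_used=float(threshold),
                      t_read=float(traj.times[i]))


def classify_outcome(map1_expected: Sequence[int], map2_expected: Sequence[int],
                     observed: BooleanMap) -> str:
    """Label an observed selection against the two cued index sets.

    Returns one of ``intersection`` (= set1 & set2), ``union``
    (= set1 | set2), ``override`` (= set2 only: the second cue wiped the
    first map), ``first_map_only`` (= set1 only: the second cue never
    took), ``none`` (nothing selected) or ``other``.
    """
    s1 = frozenset(int(i) for i in map1_expected)
    s2 = frozenset(int(i) for i in map2_expected)
    got = frozenset(int(i) for i in observed.indices())
    if not got:
        return "none"
    if got == (s1 & s2):
        return "intersection"
    if got == (s1 | s2):
        return "union"
    if got == s2:
        return "override"
    if got == s1:
        return "first_map_only"
    return "other"
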