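"""Network parameter records.

All constants of the rate equations live in one validated, immutable
record so that a simulation, an analysis and a serialized artifact can
never disagree about which network they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any


@dataclass(frozen=True)
class NetworkParameters:
    """Constants of the F-WTA rate equations.

    Attributes
    ----------
    tau_x : float
        Integration time constant of the excitatory units. Must exceed
        ``tau_y``: inhibitory interneurons are faster than excitatory
        cells.
    tau_y : float
        Integration time constant of the single inhibitory interneuron.
    alpha : float
        Coupling strength of the dendritic compartment onto the soma.
    beta1 : float
        Strength of the inhibitory synapse onto the excitatory units.
    beta2 : float
        Strength of the excitatory drive onto the inhibitory unit. Any
        value above the default leaves the network behavior unchanged;
        it only sharpens the MAX computation of the interneuron.
    S_d : float
        Upper asymptote of the sigmoid dendritic output.
    lambda_ : float
        Steepness of the dendritic sigmoid. Set high so the dendrite
        behaves almost all-or-none around its threshold.
    T_d : float
        Dendritic threshold: the sigmoid midpoint.
    T_x : float
        Activation threshold of the presynaptic terminals of the
        excitatory units (the excitatory-to-inhibitory pathway).
    T_y : float
        Activation threshold of the presynaptic terminals of the
        inhibitory unit (the inhibitory-to-excitatory pathway).
    n_units : int
        Number of excitatory nodes in the 1-D map.
    wraparound : bool
        Close the 1-D chain into a ring. Off by default: edge nodes
        receive recurrent excitation from their single neighbor only.
    """

    tau_x: float = 5.0
    tau_y: float = 2.0
    alpha: float = 1.0
    beta1: float = 1.0
    beta2: float = 10.0
    S_d: float = 1.0
    lambda_: float = 100.0
    T_d: float = 0.1
    T_x: float = 0.1
    T_y: float = 0.1
    n_units: int = 200
    wraparound: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.tau_x > self.tau_y > 0:
            raise ValueError(
                f"time constants must satisfy tau_x > tau_y > 0, "
                f"got tau_x={self.tau_x}, tau_y={self.tau_y}"
            )
        for name in ("S_d", "lambda_", "T_d", "T_x", "T_y", "beta2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha < 0 or self.beta1 < 0:
            raise ValueError("alpha and beta1 must be nonnegative")
        if not (isinstance(self.n_units, int) and self.n_units >= 1):
            raise ValueError("n_units must be a positive integer")

    def replace(self, **changes: Any) -> "NetworkParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParameters":
        return cls(**d)


@dataclass(frozen=True)
class PWLParameters(NetworkParameters):
    """Parameters of the piecewise-linear saturating network variant.

    Adds somatic (``S_c``) and presynaptic-terminal (``S_p``) saturation
    points; ``S_d`` is reused as the dendritic saturation. The dendritic
    saturation must lie below the somatic one, otherwise the recurrent
    drive overshadows the feedforward input and the network loses its
    sensitivity to input changes.
    """

    S_c: float = 10.0
    S_p: float = 10.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.S_c > 0 or not self.S_p > 0:
            raise ValueError("S_c and S_p must be strictly positive")
        if not self.S_d < self.S_c:
            raise ValueError(
                f"dendritic saturation S_d={self.S_d} must be smaller "
                f"than somatic saturation S_c={self.S_c}"
            )
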