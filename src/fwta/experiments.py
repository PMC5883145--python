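"""Executable protocols: single-map formation, object spread, intersection,
union, bottom-up salience, abrupt-onset capture, and the parameter sweeps
that locate the gain and alpha/beta boundaries of each behavior.

Outcome criteria
----------------
A Boolean map counts as *formed* only when it is clean and prompt: at the
probe time the half-max-selected set equals the expected item set exactly
and every other item node has been quenched below 10% of the maximum
activity.  Formation is probed 30 time units after cue onset — a cue that
cannot segregate the display while it is on has failed, even if the
network sorts itself out later — and the outcome must persist in the
memory state at the simulation horizon.  The union protocol is the
exception on timing: its second map keeps growing after the overlapping
cue pair ends, so the union is probed 30 units after the second cue goes
off (and again at the horizon), while the first cue's map must already
be clean when the second cue arrives.

Every protocol is deterministic: two runs with identical configurations
produce identical trajectories and outcome labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .analysis import BooleanMap, classify_outcome, read_boolean_map
from .core import Trajectory, simulate
from .params import NetworkParameters
from .stimuli import StimulusSpec, make_layout

__all__ = [
    "SweepResult",
    "OnsetResult",
    "run_single_map",
    "single_map_success",
    "run_spatial_object",
    "run_intersection",
    "run_union",
    "run_salience",
    "run_onset",
    "sweep_gain",
    "sweep_onset",
    "sweep_alpha_beta",
]

HORIZON = 250.0
FORMATION_DELAY = 30.0   # time allowed for a cue to establish its map
QUENCH_FRACTION = 0.1    # non-selected item nodes must sit below this x max


def _map_formed(traj: Trajectory, t_read: float, cued: np.ndarray,
                noncued: np.ndarray, frac: float = QUENCH_FRACTION) -> bool:
    """True when the map at ``t_read`` selects exactly ``cued`` and every
    ``noncued`` item node is quenched below ``frac`` of the maximum."""
    bm = read_boolean_map(traj, t_read)
    if not np.array_equal(np.sort(bm.indices()), np.sort(cued)):
        return False
    i = traj.index_at(t_read)
    x = traj.x[i]
    return bool(noncued.size == 0 or x[noncued].max() < frac * x.max())


def _strict_outcome(spec: StimulusSpec, traj: Trajectory, t_read: float,
                    set1: np.ndarray, set2: np.ndarray) -> str:
    """Classify the map at ``t_read`` against the two cued sets, demanding
    that every item node outside the selection is quenched."""
    bm = read_boolean_map(traj, t_read)
    i = traj.index_at(t_read)
    x = traj.x[i]
    outside = np.setdiff1d(spec.item_indices(), bm.indices())
    if outside.size and x[outside].max() >= QUENCH_FRACTION * x.max():
        return "partial"
    return classify_outcome(set1, set2, bm)


def _stable_outcome(spec, traj, t_form, set1, set2) -> str:
    """Outcome that holds both when the map has formed and at the horizon."""
    l1 = _strict_outcome(spec, traj, t_form, set1, set2)
    l2 = _strict_outcome(spec, traj, traj.horizon, set1, set2)
    return l1 if l1 == l2 else "unstable"


# ---------------------------------------------------------------------
# single Boolean map (two sequential color cues)
# ---------------------------------------------------------------------

def run_single_map(
    G_A: float = 2.0,
    variant: str = "reciprocal",
    params: Optional[NetworkParameters] = None,
    t_read1: float = 140.0,
    t_read2: float = 240.0,
) -> Tuple[Trajectory, BooleanMap, BooleanMap]:
    """Sequential two-color cue protocol (red cued over [50, 100], green
    over [150, 200]); returns the trajectory and the Boolean maps read
    in the memory epoch after each cue.

    Variants: ``reciprocal`` (unattended maps at gain 1/G_A),
    ``no_reduction`` (unattended gain stays 1), ``large_items``
    (near-double item width, unattended gain 1).
    """
    if variant not in ("reciprocal", "no_reduction", "large_items"):
        raise ValueError(f"unknown variant {variant!r}")
    params = params or NetworkParameters()
    protocol = "single_map_large_items" if variant == "large_items" else "single_map"
    spec = make_layout(protocol, G_A=G_A, reciprocal=(variant == "reciprocal"),
                       n_units=params.n_units)
    traj = simulate(params, spec, horizon=HORIZON)
    bm1 = read_boolean_map(traj, t_read1)
    bm2 = read_boolean_map(traj, t_read2)
    red = spec.item_indices("red")
    green = spec.item_indices("green")
    bm1.outcome_label = ("single_map"
                         if np.array_equal(bm1.indices(), red) else "other")
    bm2.outcome_label = ("switch"
                         if np.array_equal(bm2.indices(), green) else "other")
    return traj, bm1, bm2


def single_map_success(G_A: float, variant: str = "reciprocal",
                       params: Optional[NetworkParameters] = None) -> bool:
    """True when the red cue forms its map and the green cue switches,
    each within :data:`FORMATION_DELAY` of cue onset."""
    params = params or NetworkParameters()
    protocol = "single_map_large_items" if variant == "large_items" else "single_map"
    spec = make_layout(protocol, G_A=G_A, reciprocal=(variant == "reciprocal"),
                       n_units=params.n_units)
    traj = simulate(params, spec, horizon=HORIZON)
    red = spec.item_indices("red")
    green = spec.item_indices("green")
    t1 = spec.gain_schedule.intervals[0][0] + FORMATION_DELAY
    t2 = spec.gain_schedule.intervals[1][0] + FORMATION_DELAY
    return (_map_formed(traj, t1, red, green)
            and _map_formed(traj, t2, green, red))


# ---------------------------------------------------------------------
# space/object-based selection
# ---------------------------------------------------------------------

def run_spatial_object(params: Optional[NetworkParameters] = None,
                       **layout_opts) -> Tuple[Trajectory, BooleanMap, BooleanMap]:
    """Spatial cue on a single location of one item (cue on over
    [50, 100]).  During the cue only the cued location is selected;
    after cue removal the selection spreads to the full item and stops
    at its boundaries.  Returns the trajectory plus the during-cue and
    after-cue Boolean maps."""
    params = params or NetworkParameters()
    spec = make_layout("spatial_object", n_units=params.n_units, **layout_opts)
    traj = simulate(params, spec, horizon=HORIZON)
    during = read_boolean_map(traj, 90.0)
    after = read_boolean_map(traj, HORIZON)
    return traj, during, after


# ---------------------------------------------------------------------
# intersection and union of two maps
# ---------------------------------------------------------------------

def run_intersection(G_A: float = 2.0, reciprocal: bool = True,
                     params: Optional[NetworkParameters] = None,
                     return_trajectory: bool = False):
    """Conjunction stimulus; red cued over [50, 100] then horizontal over
    [150, 200]; the outcome (probed once the second map has formed and
    again at the horizon) is classified against the red and horizontal
    item sets.  Target outcome: their intersection."""
    params = params or NetworkParameters()
    spec = make_layout("intersection", G_A=G_A, reciprocal=reciprocal,
                       n_units=params.n_units)
    traj = simulate(params, spec, horizon=HORIZON)
    t_form = spec.gain_schedule.intervals[1][0] + FORMATION_DELAY
    label = _stable_outcome(spec, traj, t_form,
                            spec.item_indices("red"),
                            spec.item_indices("horizontal"))
    if return_trajectory:
        bm = read_boolean_map(traj, HORIZON)
        bm.outcome_label = label
        return label, traj, bm
    return label


def run_union(G_A: float = 1.5, gap: float = -20.0, reciprocal: bool = True,
              params: Optional[NetworkParameters] = None,
              return_trajectory: bool = False):
    """Two-component stimulus (red squares 1..100, achromatic bars
    101..200); red cued over [50, 100] and horizontal for 50 units
    starting ``gap`` after the red cue ends (negative gap = the cues
    overlap, the default).  The red map must be cleanly formed when the
    horizontal cue arrives; the final map, probed 30 units after the
    second cue ends and at the horizon, is classified against the red
    and horizontal item sets.  Target outcome: their union.

    The default gain sits at the center of the union-capable range of
    this network; the union outcome only exists in a band of moderate
    attended gains, and only when the cues overlap or nearly so — with a
    large gap the second cue overrides the stored map.
    """
    params = params or NetworkParameters()
    spec = make_layout("union", G_A=G_A, gap=gap, reciprocal=reciprocal,
                       n_units=params.n_units)
    traj = simulate(params, spec, horizon=HORIZON)
    red = spec.item_indices("red")
    hor = spec.item_indices("horizontal")
    t2_on, t2_off = spec.gain_schedule.intervals[1][:2]
    if not _map_formed(traj, t2_on, red, np.setdiff1d(spec.item_indices(), red)):
        label = "no_first_map"
    else:
        label = _stable_outcome(spec, traj, t2_off + FORMATION_DELAY, red, hor)
    if return_trajectory:
        bm = read_boolean_map(traj, HORIZON)
        bm.outcome_label = label
        return label, traj, bm
    return label


# ---------------------------------------------------------------------
# bottom-up selection
# ---------------------------------------------------------------------

def run_salience(item_magnitudes: Optional[Sequence[float]] = None,
                 params: Optional[NetworkParameters] = None,
                 ) -> Tuple[Trajectory, BooleanMap, List[int]]:
    """No top-down guidance: the network selects the most salient
    item(s).  Returns the trajectory, the final Boolean map and the list
    of selected item indices (positions in the magnitude list)."""
    params = params or NetworkParameters()
    opts = {} if item_magnitudes is None else {"item_magnitudes": list(item_magnitudes)}
    spec = make_layout("salience", n_units=params.n_units, **opts)
    traj = simulate(params, spec, horizon=HORIZON)
    bm = read_boolean_map(traj, HORIZON)
    chosen = [k for k, it in enumerate(spec.item_layout)
              if bm.selected[it.indices()].all()]
    return traj, bm, chosen


@dataclass
class OnsetResult:
    captured: bool
    trajectory: Trajectory
    pulse_window: Tuple[float, float]


def run_onset(I_T: float = 4.0, I_W: float = 2.0,
              params: Optional[NetworkParameters] = None) -> OnsetResult:
    """Abrupt-onset protocol: attended item ``I_W`` at the center, other
    items at 1, transient blocks of amplitude ``I_T`` at the sides.
    Capture means the onset locations overtake the attended item at some
    sampled time during the pulse."""
    params = params or NetworkParameters()
    spec = make_layout("onset", I_T=I_T, I_W=I_W, n_units=params.n_units)
    traj = simulate(params, spec, horizon=HORIZON)
    pulse = spec.transient_pulses[0]
    t0, t1 = pulse.t_start, pulse.t_start + pulse.duration
    onset_idx = np.concatenate([np.arange(p.location_range[0] - 1,
                                          p.location_range[1])
                                for p in spec.transient_pulses])
    winner = max(spec.item_layout, key=lambda it: it.magnitude)
    win_idx = winner.indices()
    sel = (traj.times >= t0) & (traj.times <= t1)
    captured = bool(np.any(traj.x[np.ix_(sel, onset_idx)].max(axis=1)
                           > traj.x[np.ix_(sel, win_idx)].max(axis=1)))
    return OnsetResult(captured=captured, trajectory=traj, pulse_window=(t0, t1))


# ---------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------

@dataclass
class SweepResult:
    """Outcome of sweeping one parameter over a grid."""

    swept_parameter: str
    grid: np.ndarray
    outcomes: List[str]
    target: str
    boundary_low: Optional[float] = None
    boundary_high: Optional[float] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        hits = [g for g, o in zip(self.grid, self.outcomes) if o == self.target]
        self.boundary_low = float(min(hits)) if hits else None
        self.boundary_high = float(max(hits)) if hits else None

    def to_dict(self) -> dict:
        return {
            "swept_parameter": self.swept_parameter,
            "grid": self.grid.tolist(),
            "outcomes": list(self.outcomes),
            "target": self.target,
            "boundary_low": self.boundary_low,
            "boundary_high": self.boundary_high,
        }


def _grid(lo: float, hi: float, step: float = 0.1) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def sweep_gain(protocol: str, reciprocal: bool = True,
               grid: Optional[np.ndarray] = None,
               params: Optional[NetworkParameters] = None) -> SweepResult:
    """Sweep the attended-map gain ``G^A`` in 0.1 steps and classify each
    outcome.

    Targets: ``switch`` for the single-map protocol (form the first map,
    then switch to the second), ``intersection`` and ``union`` for the
    two-dimension protocols.
    """
    if grid is None:
        grid = _grid(1.0, 3.0) if protocol != "union" else _grid(1.0, 2.4)
    outcomes: List[str] = []
    if protocol == "single_map":
        variant = "reciprocal" if reciprocal else "no_reduction"
        for g in grid:
            ok = single_map_success(float(g), variant=variant, params=params)
            outcomes.append("switch" if ok else "fail")
        target = "switch"
    elif protocol == "intersection":
        for g in grid:
            outcomes.append(run_intersection(float(g), reciprocal, params=params))
        target = "intersection"
    elif protocol == "union":
        for g in grid:
            outcomes.append(run_union(float(g), reciprocal=reciprocal, params=params))
        target = "union"
    else:
        raise ValueError(f"unknown sweep protocol {protocol!r}")
    return SweepResult(swept_parameter="G_A", grid=grid, outcomes=outcomes,
                       target=target)


def sweep_onset(I_W: float = 2.0, grid: Optional[np.ndarray] = None,
                params: Optional[NetworkParameters] = None) -> SweepResult:
    """Sweep the transient amplitude ``I_T`` in 0.1 steps at fixed
    ``I_W``; the target outcome is attentional capture by the onset."""
    if grid is None:
        grid = _grid(I_W, I_W + 1.5)
    outcomes = ["capture" if run_onset(float(g), I_W, params=params).captured
                else "resist" for g in grid]
    return SweepResult(swept_parameter="I_T", grid=grid, outcomes=outcomes,
                       target="capture")


def sweep_alpha_beta(grid: Optional[np.ndarray] = None,
                     protocol: str = "intersection",
                     G_A: Optional[float] = None,
                     base: Optional[NetworkParameters] = None) -> SweepResult:
    """Vary ``alpha = beta1`` jointly (0.1 steps) and classify the given
    two-cue protocol at its default gain."""
    if grid is None:
        grid = _grid(0.5, 6.0) if protocol == "intersection" else _grid(0.5, 1.5)
    base = base or NetworkParameters()
    outcomes: List[str] = []
    for v in grid:
        p = base.replace(alpha=float(v), beta1=float(v))
        if protocol == "intersection":
            outcomes.append(run_intersection(G_A if G_A is not None else 2.0,
                                             reciprocal=True, params=p))
        elif protocol == "union":
            outcomes.append(run_union(G_A if G_A is not None else 1.5,
                                      reciprocal=True, params=p))
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
    return SweepResult(swept_parameter="alpha=beta1", grid=grid,
                       outcomes=outcomes, target=protocol)
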