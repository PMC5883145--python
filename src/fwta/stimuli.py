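"""Stimulus construction: feature maps, top-down gain schedules, layouts.

The input to excitatory node ``i`` is the gain-weighted sum over feature
maps,

    I_i(t) = sum_m I_i^(m) * G^(m)(t),

optionally perturbed by a single-location spatial cue (a multiplicative
boost of one map's value at one location) and by transient-channel
pulses that model the onset response to a newly appearing object.

Conventions
-----------
* Locations are 1-based and inclusive, matching the description of the
  layouts (a 200-unit map spans locations 1..200).
* Feature gains are piecewise-constant and global to a map: a cue
  multiplies the whole map, including the spontaneous-activity floor it
  carries in the empty space between items.
* The spontaneous floor (``background_level``, default 0.2) is split
  equally among the feature maps at every location not occupied by any
  item, so the summed background input is ``background_level``
  regardless of how many maps the stimulus uses.  Item locations carry
  exactly the item magnitude in their assigned map(s) and nothing in the
  others.
* A transient pulse *replaces* the sustained input over its location
  range for its duration: the printed pulse amplitude is the total input
  that the onset location receives while the transient channel fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FeatureMap",
    "GainSchedule",
    "Item",
    "TransientPulse",
    "SpatialCue",
    "StimulusSpec",
    "assemble_input",
    "make_layout",
    "PROTOCOLS",
]


@dataclass
class FeatureMap:
    """One retinotopic feature map: a label and its activity profile."""

    name: str
    activity: np.ndarray
    dimension: str = ""

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 1:
            raise ValueError("feature-map activity must be a 1-D vector")
        if np.any(self.activity < 0):
            raise ValueError("feature-map activity must be nonnegative")


@dataclass
class GainSchedule:
    """Piecewise-constant top-down gains ``G^(m)(t)``.

    ``intervals`` is a list of ``(t_start, t_end, map_name, gain)``; the
    gain of a map defaults to 1 outside its intervals.  In reciprocal
    mode, whenever some map is cued with gain ``G``, every map without
    an explicit cue at that time receives the reciprocal gain ``1/G``
    (feature-based attention boosts the attended value and suppresses
    unattended ones); with the flag off, uncued maps stay at gain 1.
    """

    intervals: List[Tuple[float, float, str, float]] = field(default_factory=list)
    reciprocal_mode: bool = False

    def __post_init__(self) -> None:
        seen: Dict[str, List[Tuple[float, float]]] = {}
        for t0, t1, name, g in self.intervals:
            if g <= 0:
                raise ValueError(f"gain must be strictly positive, got {g} for {name!r}")
            if t1 <= t0:
                raise ValueError(f"empty gain interval [{t0}, {t1}] for {name!r}")
            for a, b in seen.setdefault(name, []):
                if t0 < b and a < t1:
                    raise ValueError(f"overlapping gain intervals for map {name!r}")
            seen[name].append((t0, t1))

    def gains(self, map_names: Sequence[str], t: float) -> Dict[str, float]:
        """Gain of every map at time ``t``."""
        out = {name: None for name in map_names}
        active_gain = None
        for t0, t1, name, g in self.intervals:
            if t0 <= t < t1:
                if name not in out:
                    raise KeyError(f"gain schedule refers to unknown map {name!r}")
                out[name] = g
                active_gain = g
        default = 1.0
        if self.reciprocal_mode and active_gain is not None:
            default = 1.0 / active_gain
        return {name: (g if g is not None else default) for name, g in out.items()}

    def breakpoints(self) -> List[float]:
        pts = []
        for t0, t1, _, _ in self.intervals:
            pts += [t0, t1]
        return pts


@dataclass
class Item:
    """A contiguous block of one feature map: locations ``start..end``
    (1-based, inclusive) with the given input magnitude."""

    start: int
    end: int
    map_name: str
    magnitude: float = 1.0

    def indices(self) -> np.ndarray:
        return np.arange(self.start - 1, self.end)


@dataclass
class TransientPulse:
    """Transient-channel input: replaces the sustained input over
    ``location_range`` (1-based inclusive) during
    ``[t_start, t_start + duration)``."""

    t_start: float
    duration: float
    location_range: Tuple[int, int]
    amplitude: float
    mode: str = "replace"  # or "add"


@dataclass
class SpatialCue:
    """Single-location cue: multiplies ``map_name``'s value at
    ``location`` (1-based) by ``extra_gain`` during ``[t_start, t_end)``."""

    t_start: float
    t_end: float
    location: int
    extra_gain: float = 2.0
    map_name: str = ""


@dataclass
class StimulusSpec:
    """Complete specification of the input to one simulation run."""

    n_units: int = 200
    feature_maps: List[FeatureMap] = field(default_factory=list)
    gain_schedule: GainSchedule = field(default_factory=GainSchedule)
    background_level: float = 0.2
    item_layout: List[Item] = field(default_factory=list)
    transient_pulses: List[TransientPulse] = field(default_factory=list)
    spatial_cues: List[SpatialCue] = field(default_factory=list)
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        for it in self.item_layout:
            if not (1 <= it.start <= it.end <= self.n_units):
                raise ValueError(
                    f"item [{it.start}, {it.end}] outside map 1..{self.n_units}")

    # -- construction -------------------------------------------------
    @classmethod
    def from_items(
        cls,
        items: Sequence[Item],
        map_names: Sequence[str],
        n_units: int = 200,
        background_level: float = 0.2,
        dimensions: Optional[Dict[str, str]] = None,
        **kwargs,
    ) -> "StimulusSpec":
        """Build feature maps from an item layout plus a shared
        spontaneous floor in the empty space between items."""
        items = list(items)
        occupied = np.zeros(n_units, dtype=bool)
        for it in items:
            if not (1 <= it.start <= it.end <= n_units):
                raise ValueError(
                    f"item [{it.start}, {it.end}] outside map 1..{n_units}")
            occupied[it.indices()] = True
        maps = []
        share = background_level / max(len(map_names), 1)
        for name in map_names:
            act = np.where(occupied, 0.0, share)
            for it in items:
                if it.map_name == name:
                    act[it.indices()] = it.magnitude
            dim = (dimensions or {}).get(name, "")
            maps.append(FeatureMap(name=name, activity=act, dimension=dim))
        return cls(n_units=n_units, feature_maps=maps,
                   background_level=background_level,
                   item_layout=items, **kwargs)

    # -- evaluation ----------------------------------------------------
    def input_at(self, t: float) -> np.ndarray:
        return assemble_input(self, t)

    def breakpoints(self) -> List[float]:
        pts = list(self.gain_schedule.breakpoints())
        for p in self.transient_pulses:
            pts += [p.t_start, p.t_start + p.duration]
        for c in self.spatial_cues:
            pts += [c.t_start, c.t_end]
        return sorted(set(pts))

    def item_indices(self, map_name: Optional[str] = None) -> np.ndarray:
        """0-based indices covered by items (of one map, or of all)."""
        idx: List[int] = []
        for it in self.item_layout:
            if map_name is None or it.map_name == map_name:
                idx += list(it.indices())
        return np.unique(np.asarray(idx, dtype=int))

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "background_level": self.background_level,
            "stimulus_id": self.stimulus_id,
            "feature_maps": [
                {"name": m.name, "dimension": m.dimension,
                 "activity": m.activity.tolist()}
                for m in self.feature_maps
            ],
            "gain_schedule": {
                "intervals": [list(iv) for iv in self.gain_schedule.intervals],
                "reciprocal_mode": self.gain_schedule.reciprocal_mode,
            },
            "item_layout": [
                {"start": it.start, "end": it.end,
                 "map_name": it.map_name, "magnitude": it.magnitude}
                for it in self.item_layout
            ],
            "transient_pulses": [
                {"t_start": p.t_start, "duration": p.duration,
                 "location_range": list(p.location_range),
                 "amplitude": p.amplitude, "mode": p.mode}
                for p in self.transient_pulses
            ],
            "spatial_cues": [
                {"t_start": c.t_start, "t_end": c.t_end, "location": c.location,
                 "extra_gain": c.extra_gain, "map_name": c.map_name}
                for c in self.spatial_cues
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(
            n_units=d["n_units"],
            background_level=d["background_level"],
            stimulus_id=d.get("stimulus_id", ""),
            feature_maps=[
                FeatureMap(name=m["name"], activity=np.asarray(m["activity"]),
                           dimension=m.get("dimension", ""))
                for m in d["feature_maps"]
            ],
            gain_schedule=GainSchedule(
                intervals=[tuple(iv) for iv in d["gain_schedule"]["intervals"]],
                reciprocal_mode=d["gain_schedule"]["reciprocal_mode"],
            ),
            item_layout=[Item(**it) for it in d["item_layout"]],
            transient_pulses=[
                TransientPulse(t_start=p["t_start"], duration=p["duration"],
                               location_range=tuple(p["location_range"]),
                               amplitude=p["amplitude"], mode=p.get("mode", "replace"))
                for p in d["transient_pulses"]
            ],
            spatial_cues=[SpatialCue(**c) for c in d["spatial_cues"]],
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulusSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def assemble_input(spec: StimulusSpec, t: float) -> np.ndarray:
    """Evaluate the summed, gain-weighted input vector at time ``t``."""
    names = [m.name for m in spec.feature_maps]
    gains = spec.gain_schedule.gains(names, t)
    I = np.zeros(spec.n_units)
    for m in spec.feature_maps:
        act = m.activity
        for c in spec.spatial_cues:
            if c.t_start <= t < c.t_end and (c.map_name in ("", m.name)):
                act = act.copy()
                act[c.location - 1] *= c.extra_gain
        I += act * gains[m.name]
    for p in spec.transient_pulses:
        if p.t_start <= t < p.t_start + p.duration:
            lo, hi = p.location_range
            if p.mode == "replace":
                I[lo - 1:hi] = p.amplitude
            else:
                I[lo - 1:hi] += p.amplitude
    return I


# ---------------------------------------------------------------------
# named protocol layouts
# ---------------------------------------------------------------------

PROTOCOLS = (
    "single_map",
    "single_map_large_items",
    "spatial_object",
    "intersection",
    "union",
    "union_gap",
    "salience",
    "onset",
)


def _block_starts(n_items: int, width: int, gap: int, n_units: int) -> List[int]:
    """1-based start positions of ``n_items`` blocks of ``width`` units
    separated by ``gap`` units, centered in the map."""
    total = n_items * width + (n_items - 1) * gap
    if total > n_units:
        raise ValueError("layout does not fit the map")
    first = (n_units - total) // 2 + 1
    return [first + k * (width + gap) for k in range(n_items)]


def make_layout(protocol: str, **opts) -> StimulusSpec:
    """Build the stimulus for one of the named simulation protocols.

    Common options: ``n_units`` (default 200), ``G_A`` (attended-map
    gain, default 2), ``reciprocal`` (reciprocal gain on unattended
    maps, default True), ``background`` (default 0.2).

    Protocol-specific options are documented inline below; all default
    to the layouts used in the reported simulations.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    n_units = opts.pop("n_units", 200)
    G_A = opts.pop("G_A", 2.0)
    reciprocal = opts.pop("reciprocal", True)
    background = opts.pop("background", 0.2)

    def spec_from(items, map_names, schedule, dims=None, pulses=(), cues=(), sid=""):
        return StimulusSpec.from_items(
            items, map_names, n_units=n_units, background_level=background,
            dimensions=dims, gain_schedule=schedule,
            transient_pulses=list(pulses), spatial_cues=list(cues),
            stimulus_id=sid,
        )

    if protocol in ("single_map", "single_map_large_items", "spatial_object"):
        width = opts.pop("width", 18 if protocol == "single_map_large_items" else 10)
        gap = opts.pop("gap", 8 if protocol == "single_map_large_items" else 10)
        magnitude = opts.pop("magnitude", 1.0)
        cue1 = opts.pop("cue1", (50.0, 100.0))
        cue2 = opts.pop("cue2", (150.0, 200.0))
        starts = _block_starts(8, width, gap, n_units)
        items = [
            Item(s, s + width - 1, "red" if k % 2 == 0 else "green", magnitude)
            for k, s in enumerate(starts)
        ]
        dims = {"red": "color", "green": "color"}
        if protocol == "spatial_object":
            # no feature cue; a spatial cue on one location of a red item
            loc = opts.pop("cue_location", starts[2] + width // 2)
            t0, t1 = opts.pop("cue_interval", (50.0, 100.0))
            extra = opts.pop("extra_gain", 2.0)
            sched = GainSchedule(intervals=[], reciprocal_mode=False)
            cues = [SpatialCue(t0, t1, loc, extra, "red")]
            return spec_from(items, ["red", "green"], sched, dims,
                             cues=cues, sid=protocol)
        sched = GainSchedule(
            intervals=[(cue1[0], cue1[1], "red", G_A),
                       (cue2[0], cue2[1], "green", G_A)],
            reciprocal_mode=reciprocal,
        )
        return spec_from(items, ["red", "green"], sched, dims, sid=protocol)

    if protocol == "intersection":
        # 8 bars covering the four color x orientation conjunctions twice,
        # interleaved; each bar activates one color map and one
        # orientation map at the same locations.
        width = opts.pop("width", 10)
        gap = opts.pop("gap", 10)
        cue1 = opts.pop("cue1", (50.0, 100.0))
        cue2 = opts.pop("cue2", (150.0, 200.0))
        combos = [("red", "horizontal"), ("green", "horizontal"),
                  ("red", "vertical"), ("green", "vertical")] * 2
        starts = _block_starts(8, width, gap, n_units)
        items = []
        for s, (color, orient) in zip(starts, combos):
            items.append(Item(s, s + width - 1, color))
            items.append(Item(s, s + width - 1, orient))
        dims = {"red": "color", "green": "color",
                "horizontal": "orientation", "vertical": "orientation"}
        sched = GainSchedule(
            intervals=[(cue1[0], cue1[1], "red", G_A),
                       (cue2[0], cue2[1], "horizontal", G_A)],
            reciprocal_mode=reciprocal,
        )
        return spec_from(items, ["red", "green", "horizontal", "vertical"],
                         sched, dims, sid=protocol)

    if protocol in ("union", "union_gap"):
        # red squares in 1..100 (color maps only), achromatic horizontal /
        # vertical bars in 101..200 (orientation maps only).  The union
        # outcome requires the cues to overlap in time (or nearly so):
        # by default the second cue starts 20 time units before the
        # first one ends.  ``gap`` is the delay from first-cue offset to
        # second-cue onset; negative values mean overlap.
        width = opts.pop("width", 10)
        gap_t = opts.pop("gap", 50.0 if protocol == "union_gap" else -20.0)
        cue_len = opts.pop("cue_duration", 50.0)
        cue1 = opts.pop("cue1", (50.0, 100.0))
        red_starts = opts.pop("red_starts", [6, 26, 46, 66, 86])
        bar_starts = opts.pop("bar_starts", [106, 126, 146, 166, 186])
        items = [Item(s, s + width - 1, "red") for s in red_starts]
        for k, s in enumerate(bar_starts):
            items.append(Item(s, s + width - 1,
                              "horizontal" if k % 2 == 0 else "vertical"))
        dims = {"red": "color", "green": "color",
                "horizontal": "orientation", "vertical": "orientation"}
        t2 = cue1[1] + gap_t
        sched = GainSchedule(
            intervals=[(cue1[0], cue1[1], "red", G_A),
                       (t2, t2 + cue_len, "horizontal", G_A)],
            reciprocal_mode=reciprocal,
        )
        return spec_from(items, ["red", "green", "horizontal", "vertical"],
                         sched, dims, sid=protocol)

    if protocol == "salience":
        # no top-down cue; items differ in bottom-up input magnitude
        width = opts.pop("width", 10)
        gap = opts.pop("gap", 10)
        mags = list(opts.pop("item_magnitudes", [0.8, 1.0, 1.5, 1.1, 0.9]))
        starts = _block_starts(len(mags), width, gap, n_units)
        items = [Item(s, s + width - 1, "intensity", m)
                 for s, m in zip(starts, mags)]
        sched = GainSchedule(intervals=[], reciprocal_mode=False)
        return spec_from(items, ["intensity"], sched, sid=protocol)

    if protocol == "onset":
        # attended item at the center, weaker items around it, transient
        # onset blocks at both sides of the map
        width = opts.pop("width", 10)
        I_W = opts.pop("I_W", 2.0)
        I_other = opts.pop("I_other", 1.0)
        I_T = opts.pop("I_T", 4.0)
        t_pulse = opts.pop("pulse_start", 125.0)
        dur = opts.pop("pulse_duration", 25.0)
        starts = _block_starts(5, width, 10, n_units)
        mags = [I_other, I_other, I_W, I_other, I_other]
        items = [Item(s, s + width - 1, "intensity", m)
                 for s, m in zip(starts, mags)]
        side = opts.pop("onset_locations", [(6, 6 + width - 1),
                                            (n_units - width - 4, n_units - 5)])
        pulses = [TransientPulse(t_pulse, dur, rng, I_T) for rng in side]
        sched = GainSchedule(intervals=[], reciprocal_mode=False)
        return spec_from(items, ["intensity"], sched, pulses=pulses, sid=protocol)

    raise AssertionError("unreachable")
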