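# Methods

## Model

The network is the rate model described in the README: `N` excitatory
linear-threshold units on a 1-D chain, one inhibitory unit, retrograde
presynaptic inhibition on both recurrent pathways, and a steep sigmoid
dendrite (`λ = 100`) carrying self- plus nearest-neighbor excitation.
Edge units receive excitation from their single neighbor (open chain); a
ring topology is available behind `NetworkParameters(wraparound=True)`
but is never used by the named protocols.  Somatic and inhibitory
activation thresholds are zero.  All activity is deterministic; there
are no noise terms.

Key closed-form properties used throughout the analysis module:

* winners: `x_M ≈ I_M + α·S_d`;
* inhibitory unit: `y* = β₂k(x_M − T_x)/(β₂k + 1) → x_M − T_x` — a MAX,
  not a sum, of its inputs (`k` = number of winners);
* quenching threshold `QT = x_M − T_x − T_y`; non-winners persist at
  `I_i + α·S_d` if that clears QT, else are silenced;
* a silenced unit re-ignites only if its input exceeds `y − T_y` (the
  dendrite contributes essentially nothing below `3x ≈ T_d`); this
  single relation underlies the minimal-gain boundaries and the
  abrupt-onset capture margin `I_T ≥ I_W + α·S_d − T_x − T_y + ε
  = I_W + 0.8`.

## Numerics

The right-hand side is stiff (the dendritic sigmoid is nearly a step)
and piecewise-smooth in the state.  `simulate` integrates with
`scipy.integrate.solve_ivp(method="BDF")`, an analytic Jacobian
(rectifier slopes as 0/1 indicators, analytic sigmoid slope), relative
tolerance `1e-6` and absolute tolerance `1e-8` (config-overridable).
Cue schedules are piecewise-constant in time, so integration restarts at
every stimulus breakpoint; trajectories are sampled at unit intervals
plus breakpoints over `t ∈ [0, 250]` ("250 time steps" is read as a
continuous horizon of 250 time units).  The dynamics preserve
nonnegativity exactly; sampled states are clipped at 0 to remove solver
noise at the `1e-12` level.  Initial condition: the resting state
`x = 0, y = 0`, the no-input equilibrium.  `expit` evaluates the
sigmoid so extreme arguments saturate instead of overflowing.  A solver
failure raises `SimulationError` carrying the failure time.

The piecewise-linear variant (`PWLParameters`, `model="pwl"`) replaces
all three output functions by clamps `s_q(u) = clip(u, 0, S_q)` with
separate saturations for soma (`S_c`), dendrite (`S_d`) and terminals
(`S_p`).  Defaults `S_c = S_p = 10`, `S_d = 1` keep soma and terminals
far from saturation; with the dendrite instead saturating at the somatic
level the recurrent drive swamps the input and the network stops
switching — both regimes are exercised in the tests.

## Stimuli

Inputs are built from items (contiguous blocks of one feature map,
1-based inclusive locations) plus a spontaneous floor of 0.2 split
equally among the maps over the empty space between items, so the
summed floor is 0.2 however many maps a protocol uses; a map contributes
nothing at other maps' item locations.  Top-down gains multiply entire
maps, floor included.  In reciprocal mode every map without an explicit
cue at time `t` receives `1/G` of the active cue's gain — applying the
reduction to *all* uncued maps, not only the cued dimension, is what
makes the reciprocal and non-reciprocal union conditions differ at all
in a layout whose second feature dimension has no distractor items.
Conjunction items (a red horizontal bar) carry magnitude 1 in each of
their two maps, so their baseline input is 2.  Transient-channel pulses
*replace* the sustained input over their location range for their
duration: the pulse amplitude is the total input the onset location
receives while the transient channel fires.  Spatial cues multiply one
map's value at a single location.

## Protocols and outcome criteria

A Boolean map is read by thresholding the activity profile at half its
maximum (a quenching-threshold mode is available); a profile whose
maximum is below `T_d` reads as empty.  A map counts as **formed** only
when it is clean and prompt: probed 30 time units after cue onset, the
selected set must equal the cued item set exactly and every other item
node must be quenched below 10% of the maximum.  Outcomes must persist
at the horizon.  This formation-speed criterion — a cue that cannot
segregate the display while it is on has failed — is what the
minimal-gain boundaries measure; probing only the late memory epoch
instead yields boundaries one to two grid steps lower, because near the
boundary the network still sorts itself out slowly after the cue.

* **single_map** — 8 items of width 10 (alternating red/green, 10-unit
  gaps, centered), magnitude 1, floor 0.2; red cued over [50, 100],
  green over [150, 200].  The `large_items` variant uses width 18.
  `run_single_map` also returns figure-epoch maps at t = 140 and 240.
* **spatial_object** — same display, no feature cue; one location of a
  red item gets 2× input over [50, 100].  During the cue only that
  location is selected; after it, selection spreads along the item and
  stops at its boundary.
* **intersection** — 8 bars covering the four color × orientation
  conjunctions twice, interleaved; red cued over [50, 100], horizontal
  over [150, 200]; outcome classified against the red and horizontal
  sets at t = 180 and at the horizon.
* **union** — red squares at locations 1–100 (color maps only),
  achromatic horizontal/vertical bars at 101–200 (orientation maps
  only); red cued over [50, 100] and horizontal for 50 units starting
  at `100 + gap`.  The union-producing band was mapped with the cues
  **overlapping in time** (default `gap = −20`, i.e. the second cue
  spans [80, 130]); the red map must be cleanly formed at second-cue
  onset, and the outcome is probed 30 units after the second cue ends
  (the union's second half keeps growing after cue offset) and at the
  horizon.  A long positive gap (e.g. 50) always ends in override: the
  suppressed first map decays below the dendritic re-ignition level
  (`x ≈ 0.04`, where `f` can no longer reach the `≈ 0.8` recurrent
  drive needed against post-cue inhibition) before the second cue ends.
  The default attended gain for this protocol is 1.5, the center of the
  union-capable band of this model.
* **salience** — one intensity map, items of different magnitudes, no
  cues.  Items within `T_x + T_y = 0.2` of the maximum are co-selected;
  the winner's activity retains its own input amplitude.
* **onset** — five items (attended center item `I_W = 2`, others 1) and
  transient blocks at both flanks pulsed at amplitude `I_T` over
  [125, 150].  Capture = the onset locations overtake the attended item
  at some sample during the pulse.  The pulse lasts 25 time units
  (≈ 5 τ_x): at the capture margin the onset node initially grows at
  only ~0.03 per time unit, so a much shorter pulse cannot resolve the
  race and would inflate the measured margin.

Sweeps step the attended gain, the transient amplitude, or `α = β₁`
in 0.1 increments and report the smallest/largest grid values achieving
the target outcome.  Everything is deterministic; identical
configurations give identical results.

## Stability analysis

`jacobian_at` builds the Jacobian at a candidate fixed point from dummy
derivatives (0/1 by the sign of each rectifier argument; 0 at exactly
zero) plus the analytic dendritic slope, and refuses silently bad input:
states whose time derivative exceeds `1e-6` in sup-norm are flagged with
a warning.  At a selection fixed point the dendrite is pinned at its
asymptote (slope ≈ 0) and the winners block their inhibition, so all
excitatory rows are `−1/τ_x` times the identity.  The winners' terminals
onto the inhibitory unit, however, sit exactly at their equilibrium
residue `(x_M − T_x)/(β₂k + 1)` above threshold — the finite-`β₂k`
remainder of the MAX computation.  The default `"max_limit"` convention
treats these at-threshold terminals as having zero slope, giving the
diagonal matrix `diag(−1/τ_x, …, −1/τ_y)`; the `"exact"` convention
keeps them, leaving couplings `β₂/τ_y` in the inhibitory row and
eigenvalues `{−1/τ_x, −(1 + β₂k)/τ_y}`, and agrees entrywise with a
finite-difference Jacobian of the right-hand side.  Both spectra are
strictly negative: the fixed points are asymptotically stable either
way, with relaxation rates set by the time constants alone, not by
`α, β₁, β₂`.

## What the synthetic stimuli do and do not capture

The stimulus generator emulates idealized 1-D cross-sections of search
displays: rectangular items with sharp edges, spatially separated,
binary feature membership, a uniform spontaneous floor, step-function
cues, and a transient channel that responds only while the onset is
new.  Real inputs would add distance-dependent activity profiles,
feature similarity, adjacency between items (which lets activity spread
across item boundaries once cues are withdrawn), input noise, and
graded cue dynamics — none of which are modelled, so passing protocols
here demonstrate the circuit's computational repertoire, not
quantitative fits to neural or behavioral data.

## Known limitations and deviations

* The reciprocal-gain union band of this implementation is
  [1.4, ≈1.7], narrower at the top than the reported [1.4, 2.0]
  (the non-reciprocal band [1.6, 2.0] and all the sweep lower bounds
  reproduce exactly).  The upper edge is a delicate race between the
  suppression depth of the first map and its post-cue recovery, and is
  sensitive to the unprinted overlap geometry.
* The intersection gain band here is [1.4, 2.5] against the reported
  [1.5, 2.1].  The upper edge is structural: with summed conjunction
  inputs the dead distractor conjunctions re-ignite (merging all
  horizontal items into the selection) only once `G + 1/G` exceeds
  `y − T_y ≈ 2.79`, i.e. `G ≈ 2.6`.  Lowering that re-ignition
  threshold enough to merge at 2.2 would contradict the onset-capture
  margin, which the same threshold fixes at exactly 0.8.
* Joint `α = β₁` variation sustains the intersection outcome up to the
  top of the swept grid (6.0): raising `α` shifts all steady activity
  levels uniformly and `β₁ > 1` only accelerates suppression, so no
  dynamical boundary appears near 5.
* With the exact equations, a gap-10 cue sequence at `G = 2` ends in
  override, not union; union at moderate gaps exists only in the
  overlapping-cue regime described above.
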