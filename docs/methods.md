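# Methods

This note records the models the package implements, the defaults it ships,
and the design choices made where more than one reading was defensible.

## Colored Petri-net engine

A net is the bipartite triple (P, T; F) with three structural axioms —
place/transition id disjointness, non-emptiness, and bipartite flow — plus
color admissibility and per-place capacities. `validate_net` reports every
violation as data rather than raising, so malformed nets can be diagnosed
wholesale. Incidence I⁻/I⁺ is represented by weighted arcs; the matrix view
is derived read-only (`incidence_matrices`) for analysis and tests. One
extra well-formedness check is enforced beyond the three axioms: every
transition must touch at least one arc (the incidence conditions are stated
disjunctively in the classical presentation; we read them as "no fully
isolated transition" and flag exactly that).

Firing consumes arc-weight tokens per input place (FIFO among
interchangeable tokens; a seeded permutation when a seed is given), applies
per-arc content-transfer annotations, and appends a lineage record
`C(inputs:outputs)` to the produced tokens. No conflict-resolution rule is
inherent to the formalism, so the simulation driver offers two policies:
deterministic document-order priority (default) and seeded uniform random.
Both are replay-deterministic: the same seed yields a bit-identical event
log. Reachability on small capacity-bounded nets is validated against
brute-force breadth-first enumeration in the test suite.

Timed/stochastic extensions, inhibitor arcs and nested net refinement are
out of scope; the only hierarchy mechanism is the bridge (below).

## Hierarchy and bridges

Meta-nodes carry three attribute categories — circulation (stage, location,
supplier), processing (method, facility, operator, minute timestamp) and
environment (medium ∈ {air, liquid, solid}, temperature, moisture, logger
readings). Stages are validated sub-nets with designated begin/end nodes;
`build_chain` wires end(k) → begin(k+1) bridges, so k layers always carry
k − 1 bridges.

The bridge is described in the source material as two nodes plus a
reversible arc; a reversible place-to-place arc is unrepresentable under the
bipartite axiom, so the bridge is realised as a single transition with one
input (upper end place) and one output (lower begin place). A graph-cut test
confirms the flattened net is "seamless": every cross-layer path passes
through its bridge transition. Layer-internal ids are qualified as
`layer:node` on merging because the per-stage tables reuse P1, m1, ... in
every stage.

Timestamps are minutes from chain start (1 d = 1,440 min); conversion
helpers are provided because the calibration mixes days and minutes.

## Tilapia case fixture

The four stages (ship processing, transportation, shore processing, cold
storage) are embedded with their printed places, transitions and — where
printed — token relations. The storage and transportation stages follow
their printed `C(m_x:m_y)` relations verbatim; the two processing stages
print no relations, so their nets use a linear product backbone with
time-temperature side outputs (fixture engineering, not data). The bridge
endpoints use the printed letters and nodes: EF = (P13 → P1),
GH = (P21 → P1), IJ = (P12 → P1). Per-place capacity is 3 throughout the
case, the reading of "token counts limited to be less than 3 which is
available" that keeps the printed nets runnable; capacity is a per-place
setting, so stricter bounds are one argument away. The transportation stage
seeds three GPS tokens so that, under document-order priority, the
capacity-bounded loop quiesces with a token at the stage's end node for the
GH bridge to carry forward.

The three bridge logger grids hold 100, 150 and 300 readings. Columns are
concatenated column-major (all of Tem.1, then Tem.2, ...) because the
within-column sequences are physically smooth while rows jump between
loggers; all acceptance-facing statistics (extrema, counts, means) are
order-independent. The sampling interval is carried as metadata and defaults
to 30 s — the source stream's cadence is stated only loosely, so treat
absolute event durations from these grids as indicative. Negative signs in
the printed grids mix dash glyphs; values were normalised to numbers at
embed time and are pinned by SHA-256 checksums in the tests.

## Growth model

Units: the interface speaks log10 CFU/g (the reporting unit of predictive
microbiology); internally counts are converted to natural-log units via
ln 10 so the model's exponentials are exact.

Two printed-form corrections are deliberate, each exposed behind a flag:

* **Saturation sign.** The constant-temperature closed form is implemented
  with the standard Baranyi saturation term e^{−(ymax−y0)}. The
  as-printed variant with e^{+(ymax−y0)} drives the count *below* y0 and
  away from the ceiling — it contradicts the model's own description — and
  is available only via `sign="as-printed"` for comparison. The t → ∞ limit
  test (y → nmax to 1e−6) pins the corrected choice.
* **Secondary model.** The square-root model is implemented in its canonical
  Ratkowsky form √μmax = b(T − Tmin), i.e. μmax = b²(T − Tmin)²; the
  literal linear form is available via `form="linear"`. Below Tmin the rate
  clamps to zero with a warning.

`v` is a free curvature parameter defaulting to the common v = μmax
convention (applied per segment under fluctuation). `h0` is the
dimensionless initial physiological state (h0 = μmax·λ, so λ = h0/μmax,
which the test suite verifies by fitting the late-time tangent).

Under a fluctuating profile the recursion advances segment by segment: μᵢ
from the secondary model at the segment temperature, the primary-model
increment applied over Δtᵢ starting from the segment-start count N_{i−1}
(the segment-start value, not y0). h0 is held constant across segments, so
lag is re-applied per segment; consequently the recursion is exactly
split-invariant only in the lag-free case h0 = 0, and that is the only case
where split invariance is asserted (to 1e−10). The closed form is checked
against an independent fixed-step RK4 integration of the Baranyi
differential system (dy/dt = μ·q/(1+q)·(1 − e^{y−ymax}), q′ = vq,
q(0) = 1/(e^{h0} − 1)) to 1e−4 log10 CFU/g.

No microbial count observations exist in the embedded case, so kinetic
defaults used in examples (y0 = 3, nmax = 9 log10 CFU/g, b = 0.03,
Tmin = −5 °C, h0 = 1) are illustrative values typical of psychrotrophic
spoilage pseudomonads, not measurements. `fit_baranyi` recovers
(y0, nmax, μmax, h0) from noise-free curves to 1 % and exists for users
with real count data.

## Quality decay and shelf life

The case calibration names a quality-assessment model but prints no formula;
what it does print are three mutually consistent numbers — quality 0.8 at
6 d, 0.2 at 24 d, and expiration (quality 0.4) at 18 d. The only reading
that reproduces all three simultaneously is a straight line q(t) = 1 − t/30
through the two anchors, so the quality layer is anchored, piecewise-linear,
linearly extrapolated and clamped to [0, 1]. An exponential
SL(T) = SL_ref·e^{−k(T−T_ref)} hook is provided for users with real decay
parameters; it is off by default.

Quality is cut into five equal bands numbered 1 (worst, [0, 0.2)) to 5
(best, [0.8, 1]); band boundaries belong to the upper band (an artifact
tie-break, stated here and in the tests). The safe reference band is
[0.2, 0.4) — index 2 in this bottom-up numbering; the case text counts the
same band fourth from the top.

The shelf-life reference table ships one calibrated point — SL(1.5 °C) =
4.8 d — plus illustrative synthetic rows (marked as such in
`fixtures.TILAPIA_SL_TABLE`) so that interpolation is exercised;
temperatures outside the table raise rather than extrapolate. TTT
accounting is the plain sum Σ Δtᵢ/SL(Tᵢ): additive, subdivision-invariant,
and monotone under uniform cooling when SL(T) is monotone.

The headline composition is elapsed + residual: 17,753 min → 12.33 d
(two-decimal rounding, matching the printed chain arithmetic), plus
SL(1.5 °C) = 4.8 d, giving 17.13 d.

## Decisions

The HACCP gate is inclusive (duration ≤ limit is safe; default limit
40 min), mirroring the printed `θ(end) − θ(start) ≤ 40` rule; a safe
outcome enables the successor transition, an unsafe one demands quality
analysis. The same inclusive convention makes a reading exactly at a
temperature bound compliant in excursion detection. Excursions are maximal
runs of consecutive out-of-bound readings; a run is split when the violated
bound changes side (no mixed run occurs in the embedded data — the
transportation grid under bounds [−25, 10] °C violates only the upper
bound, in three runs of 1, 45 and 6 readings).

The regulation mechanism's physical dynamics are unspecified in the source
material, so the loop implements the minimal terminating realisation: from
each excursion onset the temperature is pulled linearly toward the violated
bound at a configurable rate (°C/min), held at the bound while the
uncontrolled readings remain out of range, and released when they return.
One decision record per cycle, labelled GMP (good-manufacturing-practice
regulation; the label carries no further operational content). Termination
is guaranteed by pull rate > 0 and a finite profile.

## Synthetic profiles

`generate_profile` emulates what a chain logger produces: per-stage constant
means with Gaussian reading noise (default sd 0.3 °C, the jitter scale of
the embedded grids), a configurable cadence (default 30 s), and
non-overlapping warm spikes placed by seeded rejection sampling. It
reproduces stage means/durations exactly and round-trips against
`detect_excursions` (k injected spikes ⇒ k detected events when bounds
clear the noise floor). It does **not** emulate sensor dropout, drift,
autocorrelated noise, or door-opening decay tails — so green tests on
synthetic data certify the detection/accounting logic, not robustness to
real logger pathology.

## Problem sizes and numerics

Test and acceptance workloads are desk-scale by construction: reachability
oracles run on nets of ≤ 6 places at capacity ≤ 2 (brute-force enumeration
stays in the hundreds of states), ODE oracles use a 1e−4 d fixed step over
a few days, and property tests cap at ≤ 100 examples each — the full suite
runs in seconds. Overflow-prone expressions (e^{μF} for large t) use
log-sum-exp forms; F(0) = 0 and the h0 = 0 identity are returned exactly
rather than through floating-point cancellation.

## Known limitations

* The quality layer is a calibration, not a mechanistic decay model; with
  different anchor data the five-band interpretation changes accordingly.
* Stage-based layering is the only hierarchy grouping exercised by the
  embedded case; grouping by location or supplier is representable via
  layer ids but untested against reference data.
* The Petri engine is untimed; durations live in token payloads and logger
  profiles, not in firing semantics.
* PNML round-trip is lossless only for the supported subset (capacities,
  color domains, token payloads, guard names via the registry).
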