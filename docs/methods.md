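# Methods

`surgecast` simulates the odor-source search of a walking male silkmoth as
a non-holonomic agent in a synthetic 2D odor plume, and reproduces the
comparison of three search algorithms — the multisensory MiM2 controller,
the classical surge-zigzagging reflex, and casting — together with the
trajectory analytics used to evaluate them.  This note records the model,
the parameter choices, and what the synthetic setting does and does not
establish.

## Agent model

The agent is a unicycle: pose (x, y, θ), forward speed v ≥ 0, turning rate
ω, no lateral slip.  Positive ω is a rightward (clockwise) turn, matching
the odor-direction sign convention (+1 = right antenna), so the
counterclockwise-positive world heading integrates θ̇ = −ω.  Integration is
heading-first Euler at dt = 0.01 s; the steep logistic below transitions
over ~0.01 s, so coarser steps blur the surge/turn switch (the circular-arc
error of the integrator at this step is below 1%).

Odor is sensed as binary puff containment at two antenna points (5 mm
ahead, ±5 mm lateral — adult-moth scale).  A *detection onset* is a
false→true transition of the combined (left OR right) antennal signal; the
side is read from the instantaneous hits (left / right / both).  Counting
combined rather than per-antenna rises keeps the measured detection
frequency f aligned with the 1 Hz odor-release ceiling; per-antenna
counting would double-count a passing puff whenever the agent turns.  The
frequency counter is a sliding window, f = onsets in (t−W, t] / W, with
W = 5 s by default (0.2 Hz resolution over the 0–1 Hz analysis range; the
window is configurable and the parameter-recovery protocol uses W = 10 s,
see below).  Between onsets the latched f and comparator flag persist.

Wind is perceived as the quadrant the wind comes *from* in the body frame
(front / back / left / right, 90° sectors centered on the body axes;
boundary bearings go to the more frontal quadrant).  The comparator
declares odor and wind "matched" when the odor side agrees with the wind
source side — left odor with wind from the left, right with right, and
bilateral odor with head-on wind.  The bilateral↔front pairing is a
modeling choice (the operational definition is not fixed by the behavioral
protocol this mirrors, which crossed left/right odor with four wind
directions); it makes "matched" mean "centered in the plume and heading
upwind", which is the regime the matched gain table rewards.

## The MiM2 controller

After a detection at time t_d, with τ = t − t_d:

    v(τ) = K_v(f) · exp(−τ) / (1 + exp(γ(τ − β)))
    ω(τ) = ω₀ · Rd(0) / (1 + exp(γ(τ − β)))
         + K_ω(f) · Rd(N) / (1 + exp(−γ(τ − β)))

with γ = 1000, β = 0.50 s, ω₀ = 0.57 rad/s.  The logistic pair switches
the motor program from a straight *surge* (duration β) to *zigzag* turning;
exponents are clamped to ±500 before exponentiation (γ = 1000 overflows
naive evaluation).  The turn counter

    N(τ) = ⌊0.0116 τ³ − 0.199 τ² + 1.1971 τ + 0.4482⌋,  clamped to [0, 3]

(bracket read as the floor function, which meshes N = 1 with the sigmoid
switch just after τ = 0.5 s) drives the turn direction Rd(N): Rd(0) is the
detected side; the first zigzag turn goes *toward* that side and
subsequent turns alternate, Rd(N) = Rd(0)·(−1)^(N+1), with looping (N
saturated at 3) keeping the last direction.  The alternation phase is not
fixed by the source material; continuing the surge-phase bias ω₀·Rd(0)
smoothly is the package's choice and the opposite phase is one sign flip
away in `_rd_of_turn`.

K_v and K_ω are piecewise-linear gains a·f + b (floored at 0), with
separate (a, b) per side of a frequency breakpoint and per comparator
condition; v is in mm/s and ω in rad/s, which puts surge speeds at
~13–17 mm/s and turn rates at ~1.4–1.7 rad/s — walking-moth scale.  The
coefficient table is the published behavioral fit.  The mismatched angular
gain uses a 0.2 Hz breakpoint by default: the two printed mismatched lines
intersect at ≈0.2 Hz (gap 0.007 rad/s) and the behavioral peak sits there,
whereas splitting at the printed 0.4 Hz row boundary leaves a 0.37 rad/s
discontinuity; `printed_gain_table()` selects the literal 0.4 Hz variant.

A vision "equalizer" multiplies leftward and rightward ω independently
(both 1 under veridical optic flow); it models the optomotor balancing of
turn amplitudes and is exposed for wind/vision-perturbation experiments.

Trial start: the motor equations need a defined t_d, so trials begin with
a virtual detection at t = 0 (random side, f = 0, matched = false), giving
a slow initial surge followed by exploratory looping until the first real
detection.

## Baselines

*Surge-zigzagging* is the constant-gain ablation of MiM2: identical τ, N,
Rd machinery and sigmoid switching, but K_v ≡ 12.9 mm/s and
K_ω ≡ 1.40 rad/s (the matched-condition zero-frequency intercepts),
independent of f and of the comparator.  It is implemented as its own
function so the ablation-equivalence test is a genuine cross-check.

*Casting* maps the flying-moth strategy to the plane with an explicit
track / hold / cast machine: while detecting, steer to upwind ± 30°
(toward the side of the last detection, random on bilateral hits); on
losing the plume, hold the heading for d_lost = 25 mm of travel; then
sweep crosswind (±90° from upwind), reversing sides every `cast_span`
traveled without a re-detection.  Speed is constant at 12.9 mm/s (the
surge-zigzag value, for comparability) and ω is a proportional steering
command toward the target heading (gain 5 s⁻¹, saturated at 3 rad/s).
The published description fixes only the 30° offset and d_lost = 2.5 cm;
leg length (100 mm), steering gains, and the pre-first-detection behavior
(cast immediately — the classic plume-finding sweep) are this package's
choices.

## Synthetic plume

The odor field emulates a 1 Hz point-source release advected by a uniform
left-to-right wind, as in the arena the model derives from.  Odor travels
in discrete circular puffs: puff k is born at the source at time k·(1 Hz)⁻¹
(none at t = 0), drifts downwind at the wind speed, and grows linearly.
Crosswind motion has two parts: a *shared* Ornstein–Uhlenbeck velocity
(Euler–Maruyama update; stationary σ = 24 mm/s, correlation time
τ = 2 s) that makes the whole puff train snake coherently like a smoke
filament, plus a small independent per-puff drift (σ = 5 mm/s) for
filament raggedness.  Purely independent per-puff wander was tried first
and rejected: it produces puff scatter rather than plume wander, so edge
positions receive isolated single hits with no burst structure and
detection-gated controllers starve.  Puffs are culled when their center
leaves the field bounds (x ∈ [−150, 450], y ∈ [−200, 200] mm) expanded by
their radius.  Each trial warms the plume up for 5 s before the agent
starts, emulating an established field.

Calibration targets, fixed before any comparison statistics were computed:
detection frequency ≈ 1 Hz at the source, decaying monotonically downwind
to ≈ 0.4 Hz at the 300 mm start; the crosswind-offset starts (300, ±100)
sit near the edge of odor reach (≈ 0.1–0.15 Hz) — rare but workable, as
the study design requires; and the casting baseline is the
lowest-success / shortest-time algorithm from the center start.  Wind
speed (100 mm/s) and the meander/growth parameters are free choices (the
source material never states the in-silico wind speed or field
dimensions); with a 1 Hz release this wind gives 100 mm puff spacing and
~40 mm puff radii at x = 300, i.e. a pulsing, non-merging filament whose
on-plume detection rate stays near the release rate.

What the synthetic plume does **not** reproduce: the recorded smoke
field's intermittency statistics, vertical structure, or concentration
dynamics (detection is binary).  Conclusions about algorithm rankings in
this plume therefore transfer to the original smoke-derived field only
qualitatively — see Limitations.

## Trial protocol and analytics

A trial runs at dt = 0.01 s for at most 300 s; success is entry into the
closed 10 mm ball around the source; the agent is clamped to the field
bounds (the arena had walls; failure is defined only by timeout).  Start
heading defaults to π (facing upwind; the original initial-heading
distribution is unstated and the option is configurable).  Batches run n
trials with seeds base_seed + i; the two standard scenarios start at
(300, 0) and alternate (300, +100)/(300, −100).

Analytics: migration probability maps on 1 mm cells (per-trial binary
occupancy, averaged over trials); earth mover's distance between
unit-normalized maps with Euclidean ground distance, solved as an exact
transportation LP (HiGHS) after block-sum coarsening to ≤ 30×20 bins
(exact transport on the native grid is infeasible; the original binning is
unstated); heading histograms of all samples re-expressed relative to the
windward direction (36 × 10° bins, unweighted); success rate, successful
search times, and SPT = success-percentage / *mean* successful search
time (mean rather than median is a choice; the source is silent).
Fisher's exact test (scipy), the Wilcoxon rank-sum test (scipy, normal
approximation, tie-corrected, p = 1 for fully tied data), and a
Steel–Dwass all-pairs test implemented here (pairwise midrank statistics
with exact tie-corrected variance, referred to the studentized range with
k groups and infinite df; for k = 2 it collapses to the two-sided normal
rank-sum p).

Parameter recovery: at a detection onset the surge envelope equals 1, so
the commanded speed is exactly K_v(f) for the f the controller measured.
The recovery protocol simulates ≥ 300 searches with the frequency window
at 10 s (0.1 Hz quantization, needed for three populated bins above the
0.7 Hz breakpoint), collects (f, v) at matched onsets, bins by f (bins
centered on the quantization grid), and fits two least-squares lines over
candidate breakpoints.  This recovers the matched translational table to
machine precision and closes the loop from simulated behavior back to the
controller's parameters.

## Numerical notes

- Logistic exponents clamped to ±500; the turn cubic is evaluated by
  Horner's rule; angles wrapped to (−π, π].
- Plume state is reproducible bit-for-bit from (config, seed, step
  schedule); trials spawn independent plume/controller RNG streams from
  the trial seed.
- The EMD LP drops the last (redundant) marginal constraint to keep the
  system full rank; integral marginals make the optimum equal a unit
  assignment, which the tests exploit as an independent oracle.
- Degenerate inputs raise: empty trial sets, all-zero maps, zero wind for
  the wind percept, non-positive dt, tables with a zero margin.

## Limitations

- The plume is a calibrated stand-in.  In it, the MiM2 controller's edge
  over the constant-gain surge-zigzag baseline is small: the matched-speed
  bonus (+5.36·f mm/s below 0.7 Hz) and the mismatched-speed penalty
  (−2.4 mm/s) nearly cancel on typical hit mixtures, and at 300 trials per
  condition the success-rate difference (center 296 vs 295 of 300, offset
  115 vs 96 of 300 at seed 0) does not reach the p < 0.01 separation the
  original smoke-field experiment reports; the center start saturates for
  both surge-driven controllers.  The casting baseline, which never stops
  moving, out-succeeds the detection-gated controllers at the offset start
  in this plume, while matching the reported pattern (lowest success,
  shortest times) from the center start.
- Sensing is binary and instantaneous: no receptor dynamics, adaptation,
  or concentration coding; vision enters only as left/right gain scaling.
- The casting flowchart details beyond β and d_lost are reconstructed, not
  transcribed.
- Body dynamics (legs, slip, inertia) are absent by design.
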