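# Methods

## Scope and assumptions

`mufatigue` simulates *isometric* contractions of a single muscle
modeled as a pool of independent motor units (MUs) sharing one
excitatory drive. The model is phenomenological: it reproduces the
empirically described time courses of force loss, contractile slowing,
and firing-rate adaptation without representing metabolites,
excitation–contraction coupling, or descending-drive dynamics.
Recovery is not modeled — capacity is non-increasing within a run —
so the simulator answers "how long until this task fails, and which
units pay for it", not "what happens after rest". Discharge is
described by smooth rates, not spike trains; force follows from a
force–frequency transform rather than twitch summation, so no
stochastic variability enters anywhere and every run is exactly
reproducible.

## Pool construction

Unit properties are deterministic functions of the 1-based index
*i* ∈ {1..n}:

| quantity | form | default endpoints |
|---|---|---|
| twitch force P(i) | exp(ln RP·(i−1)/(n−1)) | 1 → 100 force units |
| threshold RTE(i) | exp(ln RR·(i−1)/(n−1)) | 1 → 50 excitation units |
| contraction time CT(i) | CT_max·P(i)^(−ln CT_range/ln RP) | 90 → 30 ms |
| max rate maxR(i) | linear in (RTE(i)−1)/(RR−1) | 35 → 25 imp/s |
| fatigability FAT(i) | FAT(1)·exp(ln RFR·(i−1)/(n−1)) | 0.0125 → 2.25 %/s |

Two constructions here were genuinely open choices:

- **Contraction times.** The inverse association between twitch force
  and contraction time is implemented as the power law
  CT(i) = CT_max·(1/P(i))^(1/c) with c = ln RP / ln CT_range, which
  pins both endpoints and reproduces the intermediate values commonly
  quoted for this pool (MU40 ≈ 63 ms, MU80 ≈ 43 ms).
- **Maximum firing rates.** "Decreasing uniformly" from 35 to 25
  imp/s is implemented linearly in *normalized recruitment threshold*,
  maxR(i) = 35 − 10·(RTE(i)−1)/(RR−1), not in unit index. Because
  thresholds are exponential in index, most units keep relatively high
  maximum rates under this reading. It is the choice that reproduces
  the reference rested maximal force of 2216 units (the index-linear
  alternative gives 2092) and matches the threshold-based assignment
  of the underlying population model; both choices agree at the
  endpoints and leave E_max = 67 unchanged.

## Force generation

Firing rate is R = g·(E − RTE) + minR above threshold, capped at
maxR(i). The normalized rate NR = R·CT collapses all units onto one
force–frequency curve: NF = 0.3·NR for NR ≤ 0.4, else
NF = 1 − exp(−2·NR³). The two branches differ by 1.5·10⁻⁴ at the
seam; we keep the printed piecewise form without smoothing (the jump
is upward, so monotonicity is preserved). Unit force is NF times the
unit's *current* capacity, and muscle force is the unweighted sum.

A documented inconsistency of the source formulation: the rested pool
is described as producing 1 force unit at E = 1, but the equations
give MU1 ≈ 0.53 units there (NF(8 × 0.09 s) × 1). We implement the
equations and do not tune toward the descriptive sentence.

## Peripheral fatigue

Nominal fatigability converts a 2-minute fatigue index FI into a mean
loss rate, ((1 − FI)/2 min)·100, times a ×3 duty-cycle adjustment
that translates the intermittent (33 % duty) test into sustained
contraction conditions. Instantaneous fatigability is the nominal
value scaled by the unit's current normalized force, so unloaded
units do not fatigue. Capacity integrates

    PE(t) = PE(t − dt) − dt · FAT(i)·NF(i)/100 · P(i),

with the percent loss taken **relative to rested capacity P(i)**.
The alternative (relative to current capacity) gives exponential decay
that never reaches zero, which contradicts the model's finite-time
"exhausted unit" behaviour; the rested-capacity base makes decline
exactly linear under constant load and lets the 2-minute NF = 1
integration return precisely the assigned fatigue index. Capacity is
floored at zero. Contraction time slows by ct_slope = 0.379 % per
percent of capacity lost, capping at 1.379× the rested CT for an
exhausted unit; this feeds back into NR and partially offsets
rate-related force loss.

## Central fatigue (firing-rate adaptation)

Each recruited unit accumulates an inhibitory adaptation current
A = q·(1 − exp(−(t − TR)/τ)), τ = 22 s, where TR is the time of first
recruitment (never reset: the protocols here never lower excitation).
The ceiling q = φ·(R − minR + d)·(RTE(i) − 1)/(RR − 1) uses the
**unadapted, maxR-capped** rate at the current excitation, recomputed
each step — feeding the adapted rate back into q would be circular.
Capping before subtraction means units driven above saturation still
adapt downward from maxR, as observed in the reference behaviour. The
adapted rate is floored at minR − d (d = 2 imp/s), letting rates sag
slightly below the recruitment minimum. The lowest-threshold unit
(RTE = 1) never adapts. With `adaptation_enabled=False` the engine is
exactly the unadapted pool model.

## Closed-loop engine

Each dt = 0.1 s sample proceeds causally:

1. capacity loss is applied using the normalized forces accepted at
   the *previous* solved step (the source is silent on same-step vs
   previous-step NF; previous-step is held fixed here and keeps each
   step explicit);
2. contraction times are recomputed from the new percent loss;
3. excitation is solved on the grid {0} ∪ {1, 1.01, …, 67} for the
   smallest value whose total force meets the target, with adaptation
   currents evaluated at the current time and trial recruitments
   entering with zero adaptation. Total force is non-decreasing in E
   (the adaptation ceiling grows with slope φ·(RTE−1)/(RR−1) ≤ φ < 1
   of the rate), so grid bisection returns the same point as the
   specified bottom-up 0.01-increment scan — this equivalence is
   asserted in the tests.

The first sample (t = 0) is fully rested. Force capacity is the
counterfactual total force at E = E_max under the current state, and
the endurance time is the first sample at which capacity falls below
the target. Termination: sustained targets stop at endurance;
maximal-effort runs pin E = E_max for a fixed duration; staircase
targets interpolate linearly across each ramp and stop at endurance;
run-to-capacity-floor tasks pin E = E_max after endurance and stop
when produced force falls below the floor.

Because the within-sample update order is a convention, endurance
times are reproducible only to a step or two; regression tests accept
±2 % or ±1 s, whichever is larger. With defaults the simulator yields
511.3 / 95.4 / 14.7 s for sustained 20/50/80 % targets, 773.9 s at
15 %, 101.6 s for the 20-40-60 % staircase, and 206.3 / 234.3 s for
the 85 %→15 % and 50 %→15 % capacity-floor runs — each within 0.2 s
of the reference values.

## Parameters

All defaults are the reference parameterization: n = 120, RP = 100,
RR = 50, minR = 8 imp/s, maxR 35→25 imp/s, g = 1 imp/s per excitation
unit, CT 90→30 ms, FAT 0.0125→2.25 %/s (RFR = 180), ct_slope = 0.379,
τ = 22 s, φ = 0.67, d = 2 imp/s, dt = 0.1 s, dE = 0.01. Any field can
be overridden from a YAML/JSON file (`load_config`); validation
enforces positivity, n ≥ 2, and maxR_first > maxR_last > minR.

## Numerical choices and degenerate inputs

- Excitation grid comparisons use exact float thresholds (E ≥ RTE);
  grid points are generated as 1 + k·dE to avoid accumulation drift.
- A target of zero force returns E = 0 immediately; targets beyond
  capacity return E_max with an unattainable flag rather than failing.
- Exhausted units stay recruited (rate > 0, force = 0) and never
  recover; capacity is clamped at exactly 0.
- CSV output carries 6 significant digits; the JSON summary is exact
  and schema-versioned.

## What the tests do and do not show

The suite checks the model against its own published worked examples,
rested-pool identities, endurance regressions, and structural
invariants (monotone recruitment, linear capacity decline, adaptation
ordering). Passing shows the implementation reproduces the reference
model's behaviour under its "one size fits all" parameterization; it
does not validate the model against any particular human muscle, nor
cover intermittent tasks, dynamic contractions, or recovery, all of
which are outside the model's stated domain.
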