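# Methods

## Event-log model and cleaning

An event is (case id, activity, resource, role, timestamp); a trace is one
case's events sorted by timestamp with ties broken by stable input order;
timestamps are timezone-naive local clinic time truncated to whole seconds
(EMR exports rarely carry zones, and duplicate detection is defined at
second resolution). Roles are restricted to {dosimetrist, physicist,
physician, therapist, other}; unrecognized values map to "other".

Cleaning applies four steps in a fixed order and reports a count for each:

1. remove events with unparseable timestamps (collected at read time, never
   silently dropped), timestamps after the declared collection end, or
   before an earliest-plausible date (default 2000-01-01 — "obviously
   incorrect" needs an operational definition and future dates alone do not
   cover degenerate epoch values);
2. consolidate events identical in (timestamp, activity) within a case,
   keeping the first occurrence (deterministic and order-stable);
3. normalize activity labels through a configurable synonym table
   (defaults: "CT Sim"/"CTSim" → "CT-Sim", "Plan" → "Planning",
   "QA" → "QA Check", "Tx" → "Treatment");
4. discard cases missing any required activity (default: the four-stage
   pathway), since an incomplete pathway cannot be assessed for conformance.

Out-of-sequence events (a pathway stage regressing relative to an earlier
event) are flagged by `validate_log` and retained: correction rules are
site-specific and flagging is lossless. A config switch (`drop_out_of_sequence`,
default off) removes them instead. Cleaning is idempotent, and the report
reconciles exactly: output = input − bad-timestamp − duplicates − events of
discarded cases.

## Synthetic generators

The generators emulate the *structure* of departmental event data, not any
particular department's empirical distribution. What passing tests show is
that the pipeline measures what the generators injected; they say nothing
about effect sizes in real EMR data, which carry ancillary activities,
shared-resource confounding and non-stationary case mix that the generators
deliberately omit.

**Pathway logs.** Each case is the four-stage pathway with log-normal
inter-stage gaps (median 1 day, σ_ln = 0.5 — order-of-days planning
turnaround; only timestamp *order* matters downstream, so the scale is
presentational). With per-case probability δ one deviation is applied:
skip (drop Planning or QA Check), swap (transpose an adjacent stage pair),
repeat (log one stage twice at distinct times), or replan-loop (a second
Planning → QA Check pass before Treatment, mirroring the rework loop of the
feedback model). Data defects are injected independently per case: an extra
future-dated event, an exact duplicate, or a dropped Treatment. Per-case
random streams are derived from (seed, case index, stream id), so the
deviant case set at δ₁ is a subset of the set at δ₂ > δ₁ under the same
seed — this is what makes mean replay fitness strictly monotone in δ
testable without averaging over seeds.

**Role-drift logs.** Events are drawn per calendar month with roles sampled
i.i.d. from that month's share vector; 4 consecutive events form one
pathway-ordered case. The bundled demonstration schedule has the
dosimetrist share falling 0.51 → 0.43 over September–December while the
physicist share rises to 0.23, the physician share holds ≈0.25, and the
therapist share absorbs the remainder (the drifting shares are the
demonstration's anchor values; the two filler roles are the package's own
choice to make each month sum to 1).

**Growing networks.** Snapshots start from a complete graph on an
eight-member team; each period adds artifact and information nodes that
attach 1..8 links (uniform draw) preferentially by degree with +1
smoothing. The heterogeneous link count is deliberate: a new accelerator
touches nearly everyone, a minor protocol update touches one person. Under
the bundled growth scenario ((2, 6, 18) artifacts, (3, 9, 27) information
items over three periods) the entropy series rises period over period;
with a *fixed* link count per new node the degree distribution concentrates
and entropy saturates or fluctuates, which is a property of the measure,
not a bug.

## Degree-distribution entropy

`H = −Σ p(k) log₂ p(k)` with `p(k) = n_k/n` over the undirected simple
graph; `0·log 0 := 0`; isolated nodes count at degree 0. Base 2 (bits) is a
convention — any base rescales H and preserves ratios and orderings, and
the reported growth *ratio* H_last/H_first is base-free. H is invariant
under node relabeling and under disjoint duplication of the network, is 0
iff there is a single degree class, and is bounded by log₂(#degree
classes). No estimation from sampled networks is attempted.

## Workload–pressure dynamics

`Ṅp = a·Np − b·Np·P`, `Ṗ = −c·P + d·b·Np·P`, `Performance = e·b·Np·P`.
Equilibria: (0, 0) and the interior point (c/(d·b), a/b). The first
integral `V = d·b·Np − c·ln Np + b·P − a·ln P` is constant along exact
trajectories and minimized at the interior equilibrium; its numerical drift
is the built-in accuracy oracle. Integration is classical fixed-step RK4,
chosen over adaptive stepping for bit-reproducibility; tests separately
verify 4th-order convergence (dt-halving error ratio ≈16) and agreement
with an adaptive high-accuracy reference within 1e−6 relative max-norm on
t ∈ [0, 50]. The model is qualitative: no empirical parameter values exist,
so the demonstration defaults a=1, b=0.5, c=1, d=0.5, e=1, (Np₀, P₀)=(2, 1),
dt=0.01, t_end=50 are illustrative, carry arbitrary time units, and are
labelled as such in run manifests. An optional sinusoidal calendar
modulation a(t) = a(1 + ε·sin 2πt/period) is available (default off) as the
simplest form of workload seasonality. A straight-line baseline
Performance = slope·P provides the no-feedback contrast: it is monotone in
P where the coupled system oscillates.

## Feedback simulation

One step applies, in order: `p_err = min(1, ε·Pr)`; an error draw
(Bernoulli in stochastic mode, the probability itself in expectation mode);
`Perf' = f0·Pr`; completions `κ·Perf'·dt`; arrivals `λ·S·dt`;
`W' = max(0, W − completions + ρ·err + arrivals)`;
`Pr' = clamp(π·W'/W_ref, 0, Pr_max)`;
`S' = clamp(S − σ·err·dt + γ(1−S)(1−err)·dt, 0, 1)`. Performance is the
memoryless read-out f0·Pr (no inertia state of its own — the simplest form
consistent with the causal loops; a performance state with its own dynamics
is a possible extension, not implemented). The update order is fixed as
listed; simultaneous-update variants are out of scope, as are staff
attrition and multi-agent extensions.

Defaults are order-unity values around the normalized initial state
Pr = Perf = S = 1: ε=0.1, T=20, dt=1, f0=1, κ=0.5, ρ=1, λ=0.5, π=1,
W_ref=W₀=10, σ=0.5, γ=0.1, Pr_max=5. The clamps guarantee S ∈ [0, 1],
Pr ∈ [0, Pr_max], W ≥ 0 for every parameterization.

**Known limitation.** Expectation mode is a mean-field approximation, not
the expectation of the stochastic process: p_err depends on the (random)
pressure state, the satisfaction update multiplies two err-dependent terms
across steps, and the clamps are nonlinear. At ε = 0.1 the stochastic mean
of final satisfaction sits measurably above the expectation-mode value
(≈0.586 vs ≈0.542 over 2000 runs); the bias is systematic and does not
shrink with more runs. Both numbers are reported side by side by the
acceptance script; expectation mode should be read as the deterministic
skeleton used for exact regression tests and monotonicity analysis, not as
an unbiased predictor of stochastic means.

## Token-replay conformance

The reference model is a workflow net; the default is the linear four-stage
net (n transitions, n+1 places), and arbitrary nets load from a JSON
description. Replay counts produced/consumed/missing/remaining tokens with
two explicitly committed conventions: the initial token placed on the
source counts in p, and the final consumption from the sink counts in c
(conventions differ between tools and change the denominators; e.g. a
skip-one-stage trace on the four-stage net gives p=c=4, m=r=1, fitness
0.75 under this convention). Fitness = ½(1−m/c) + ½(1−r/p) ∈ [0, 1], equal
to 1 exactly when the trace is in the net's language. Labels with no
matching transition are skipped and logged (ancillary EMR events should not
crash a replay); strict mode penalizes them instead. When a label maps to
several transitions the lowest transition id fires (deterministic
tie-break; the bundled linear nets have unique labels). Histograms use
right-open bins of configurable width (default 10 percentage points) with
fitness 1.0 in the top bin. The package's replay is cross-checked in the
test suite against an independent naive token-bag simulator on seeded
corpora; alignment-based fitness, precision/generalization metrics and
inductive-miner discovery are out of scope. Process discovery is the
directly-follows graph only.

## Organizational mining

"Activities" are counted as events: a role's share in a window is its event
count over the window's event count (durations and distinct-activity-type
denominators are defensible alternatives; the event-count denominator is
the simplest consistent reading and is recorded in output metadata).
Windows default to calendar months, with ISO weeks as an option. Roles with
zero events in a window get an explicit share of 0; interior windows with
no events at all are omitted with a warning record. Drift summaries report
first/last shares, absolute change, and the sign pattern of successive
differences. Handover networks count directed actor-to-actor transitions
between consecutive events within a case (self-loops included), at role or
resource granularity; centrality and community analysis are out of scope.

## Problem sizes

Default analysis sizes — 40–500 generated cases, 10,000 events/month for
drift recovery, 2000 stochastic feedback runs, 50,001-state ODE
trajectories, ~150-node networks — were chosen so every stage's sampling
error is small relative to the effects being demonstrated while the whole
suite and the acceptance script each run in seconds on a laptop.
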